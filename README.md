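# flybait

Fly photoreceptor excitation modelling and colour-opponency analysis of
visual baits for tsetse flies.

Insecticide-treated targets, screens and traps are core tools for
controlling riverine tsetse flies (*Glossina* spp.), the vectors of human
African trypanosomiasis. How many flies a bait attracts depends strongly on
its colour — but "colour" for a fly means the excitations its reflectance
spectrum elicits in the five photoreceptor classes of the compound eye
(R1-6, R7p, R7y, R8p, R8y), after adaptation to the green-vegetation
background, not reflectance in human-defined wavelength bands. `flybait`
implements that receptor-level analysis for entomologists and vector-control
researchers who want to screen candidate bait fabrics from reflectance
spectra alone, or to analyse catch experiments receptor-wise.

## The model

For a bait with reflectance spectrum *I*<sub>S</sub>(λ) viewed against a
background *I*<sub>B</sub>(λ) under illuminant *D*(λ), each receptor class
*c* with peak-normalised spectral sensitivity *S*<sub>c</sub>(λ) responds
with

```
R_c = 1 / ∫ I_B(λ) S_c(λ) D(λ) dλ          (range sensitivity: background adaptation)
P_c = R_c · ∫ I_S(λ) S_c(λ) D(λ) dλ        (effective quantum catch)
E_c = P_c^n / (P_c^n + 1)                   (excitation; n = 1 when light-adapted)
```

so the adapting background itself always elicits a half-maximal response
(*E* = 0.5) in every class. Integrals are rectangular sums on a 310–600 nm
grid at 2 nm resolution. Tsetse attraction is then summarised by a colour
opponency index over the excitations,

```
index = + E_R7y − E_R8y − E_R7p
```

to which the UV-blue receptor R7y contributes positively and the
green-yellow (R8y) and low-UV (R7p) receptors negatively: effectively a
"not-vegetation" detector turned towards blue. Higher index → more
attractive bait; the background scores −0.5.

The statistics layer reproduces the analysis pipeline used to derive that
index from field-catch data: collation of normalised catches
(log₁₀(x+1) of percent-of-standard, one row per bait), Spearman
correlation of excitations, multivariate PLS2 regression with leave-one-out
PRESS factor selection, sequential OLS with F-tests of r² change and VIFs,
and dummy-coded Troje colour-category comparisons. Models follow the
statsmodels convention: build from a DataFrame, `fit()`, inspect a results
object with `summary()`.

The packaged illuminant, leaf-background and sensitivity curves are
synthetic stand-ins generated by `flybait.fixtures` (documented in
`docs/methods.md`); substitute your own measured CSVs anywhere a fixture is
accepted.

## Worked example

```python
import numpy as np
from flybait import *
from flybait import fixtures

grid = DEFAULT_GRID                       # 310–600 nm, 2 nm, 146 points
illuminant = fixtures.load_illuminant()   # daylight as normalised quanta
background = fixtures.load_background()   # typical green leaf
receptors = fixtures.load_receptors()     # five sensitivity curves
state = adapt(background, illuminant, receptors)

wl = grid.wavelengths
blue = Spectrum(grid=grid, values=0.05 + 0.55*np.exp(-0.5*((wl-460)/35)**2),
                name="blue_cloth")
green = Spectrum(grid=grid, values=0.05 + 0.40*np.exp(-0.5*((wl-550)/40)**2),
                 name="green_cloth")

table = excite_panel([blue, green], state, receptors)
print(table.filter(like="E_").round(3))
for bait in table.index:
    idx = opponency_index({c: table.loc[bait, f"E_{c}"] for c in RECEPTOR_CLASSES})
    print(f"{bait}: opponency index {idx:+.3f}")
```

prints

```
             E_R1-6  E_R7p  E_R7y  E_R8p  E_R8y
bait_id
blue_cloth    0.808   0.52  0.806  0.881  0.655
green_cloth   0.703   0.50  0.562  0.673  0.747
blue_cloth: opponency index -0.370
green_cloth: opponency index -0.685
```

The blue cloth drives the UV-blue receptor R7y hard relative to R8y and
R7p and scores 0.3 higher on the opponency index than the leaf-like green
cloth — the model's prediction of its greater attractiveness to tsetse.
(Both exceed the background's −0.5; a strongly green or UV-reflecting bait
falls below it.)

The same operations are available from a shell:

```sh
flybait excite --spectra baits.csv --out run/      # per-bait E and P
flybait rank --excitations run/excitations.csv     # sort by predicted attractiveness
flybait reproduce --dataset collated.csv --out report/   # full statistics
flybait simulate --seed 1 --out sim/               # synthetic panel + catches
```

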