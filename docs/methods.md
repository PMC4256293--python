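# Methods

## Photoreceptor excitation model

The model treats a visual bait as a reflectance spectrum *I*<sub>S</sub>(λ)
seen against an adapting background *I*<sub>B</sub>(λ) under an illuminant
*D*(λ). Each of the five receptor classes of the higher-fly retina (R1-6,
R7p, R7y, R8p, R8y) has a peak-normalised spectral sensitivity
*S*<sub>c</sub>(λ); its state is summarised by three quantities:

* **Range sensitivity** R<sub>c</sub> = 1 / ∫ I_B S_c D dλ. This is the
  von-Kries-style background adaptation step: it scales each class so that
  the steady background elicits quantum catch 1 and hence a half-maximal
  response. Modelling assumption: the fly is fully adapted to a single,
  spatially uniform background.
* **Quantum catch** P<sub>c</sub> = R<sub>c</sub> ∫ I_S S_c D dλ, the
  background-relative photon capture of the bait.
* **Excitation** E<sub>c</sub> = P<sub>c</sub>ⁿ / (P<sub>c</sub>ⁿ + 1), a
  saturating transduction non-linearity bounded in [0, 1). The exponent n
  defaults to 1 (fully light-adapted photoreceptors), where the closed form
  E = P/(P+1) holds and background excitation is exactly 0.5.

All five classes use identical machinery — no per-class gain parameters —
reflecting the equalisation of voltage gain per unit contrast across fly
photoreceptor types. Two exact invariances follow and are exploited by the
test suite: scaling the illuminant by any k > 0, or scaling bait *and*
background reflectance by one common k > 0, leaves every E unchanged.

### Numerical conventions

* Working grid: 310–600 nm in 2 nm steps (146 points), the range over which
  fly sensitivities are reliably characterised; configurable for
  sensitivity analyses.
* Spectra at other resolutions are brought onto the grid by linear
  interpolation; native data outside the grid are truncated. A native range
  that fails to cover the grid is an error by default (`clamp` extends with
  the boundary value and logs).
* Integration is the rectangular sum Σ f(λᵢ)·Δλ over grid points — the
  spreadsheet convention. Numerically this is the midpoint rule on
  [309, 601] nm (width 292 nm; three flat unit spectra integrate to 292.0).
  The test suite bounds its discretisation error against a 0.1 nm trapezoid
  oracle over the same support: < 1% relative for every class on the
  packaged curves (measured ≈ 0.02%), and < 0.02 absolute on any excitation
  (measured ≈ 2 × 10⁻⁴).
* Reflectances supplied in percent (any value > 1.5) are auto-detected and
  divided by 100, logged. The model is invariant to a *common* rescaling of
  bait and background, not to rescaling one of them, so both must share a
  scale.
* Degenerate inputs fail loudly: a background invisible to a class
  (zero catch) names the class; negative values, grid mismatches and
  duplicate bait ids are errors.

## Packaged fixture spectra (synthetic stand-ins)

The packaged CSVs under `flybait/data/` are generated by `flybait.fixtures`
and are synthetic stand-ins for measured tables:

* **Illuminant**: photon flux of a 6500 K Planckian radiator,
  peak-normalised, tabulated at 5 nm — a standard-daylight approximation.
  Because excitations are invariant to illuminant scale, only its shape
  matters; the Planckian shape has somewhat more near-UV content than
  measured ground-level daylight.
* **Leaf background**: flat ~5% reflectance plus a Gaussian chlorophyll
  reflectance peak at 555 nm and a red edge beyond 690 nm, at 10 nm.
* **Receptor sensitivities**: Govardovskii-style A1 rhodopsin α-band
  templates plus Gaussian accessory bands (R1-6: α 490 nm + UV sensitising
  band at 350 nm; R7p: α 335 nm; R7y: α 355 nm + blue shoulder at 430 nm;
  R8p: α 460 nm; R8y: α 540 nm + UV band at 350 nm), peak-normalised, at
  2 nm.

These reproduce the qualitative structure that drives the analysis — a
double-peaked R1-6, the UV/blue split of the R7 pair, the blue vs
green-yellow split of the R8 pair — but not the exact digitised curves from
electrophysiological recordings. Consequently the package's quantitative
guarantees are all *properties and oracle agreements computed on its own
curves*; absolute excitation values for a given fabric will differ from
values computed with measured curves, and users holding measured
sensitivities should substitute their CSVs. Every numbered output of the
acceptance script is computed fresh from these fixtures at run time.

## Opponency layer

The default attraction index is the unweighted combination
+E_R7y − E_R8y − E_R7p; with weights summing to −1 it maps the background
point (all E = 0.5) to −0.5 and is confined to (−2, 1). A two-term variant
+E_R7y − E_R8y and arbitrary weightings (e.g. study-fitted regression
coefficients) use the same machinery. Troje categorisation reduces a
spectrum to the signs of R7y−R8y and R7p−R8p; a zero difference maps to
"+" so the categorisation is total, and boundary cases are flagged in
tabular output.

## Statistics layer

* **Collation**: catches are normalised field counts (percent of a standard
  bait); repeat presentations of a bait are averaged and the mean is
  log₁₀(x+1)-transformed (base 10 is consistent with intercepts near 2 for
  a 100% standard catch; configurable).
* **Sequential OLS** (`SequentialExcitationOLS`): nested models add
  receptor excitations in blocks (default R7y+R8y together, then R7p, R8p,
  R1-6 — the cross-study importance order). Each step reports r², adjusted
  r², the overall F, a partial F-test of the r² change with
  (q, n−p−1) degrees of freedom, standardised coefficients
  (b·sd_x/sd_y) and VIFs. Exactly collinear designs fail naming the block.
  Fits are delegated to statsmodels.
* **PLS2** (`CatchPLS`): NIPALS on z-scored predictors *and* responses
  (both sexes' log catches simultaneously), coefficients back-transformed
  to the raw scale. Factor extraction stops early if the predictor residual
  is exhausted (rank deficiency). Leave-one-out PRESS is computed per
  candidate factor count with the standardisation refitted inside every
  fold; predicted r² = 1 − PRESS/SS_tot per response. The selected factor
  count minimises total PRESS, subject to a parsimony override: a factor is
  kept only if it improves PRESS by more than 2% relative to the simpler
  model. The 2% threshold is this package's operationalisation of
  rejecting marginal improvements as over-fitting; it is a parameter of
  `fit()`. With maximal factors on a full-rank design PLS reproduces the
  per-response OLS solution to machine precision (asserted to 1e-8);
  scikit-learn's PLSRegression serves as an independent cross-check of the
  NIPALS dialect in the test suite.
* **Coefficient ranking**: within each analysis, predictors are ranked by
  |standardised coefficient| (1 = largest, average ranks for ties); the
  median rank across studies summarises cross-study importance.
* **Colour-category regression**: OLS of log catch on 1-0 dummies with
  y+p− (the category of phthalogen-blue standards) as the reference level;
  equivalent to one-way ANOVA, which the tests use as the oracle.

## Synthetic data generator

`generate_panel` emulates dyed-cloth reflectances as a flat baseline
(default U(0.01, 0.12)) plus two Gaussian peaks (centres U(320, 600) nm,
widths U(20, 80) nm, signed heights U(−0.05, 0.25)), clipped to [0, 1] with
a log message. These ranges were chosen so that a panel's excitations span
roughly 0.1–0.9 across classes against the packaged leaf background while
keeping the three model predictors (E_R7y, E_R8y, E_R7p) away from the
near-singular collinearity regime. What the generator does *not* emulate:
measurement noise in spectra, fabrics with sharp absorption edges, or the
specific colour distribution of any published bait panel — so passing
recovery tests demonstrate the correctness of the pipeline under its own
assumptions, not field performance of a particular fabric set.

`simulate_catches` draws log₁₀(catch+1) = β₀ + β₁E_R7y + β₂E_R8y +
β₃E_R7p + N(0, σ) per presentation and back-transforms, clipping (and
logging) negative percentages. Defaults β = (2.0, +1.5, −1.8, −1.2),
σ = 0.15, two presentations per bait: intercept near 2 matches a ~100%
standard catch, the signs and magnitudes mirror the fitted attraction
model, and σ is of the order of the residual scatter in collated field
data. Noise lives on the log scale, the scale of the analysis. All
randomness flows from the explicit seed in each spec; no global state.

A caveat the recovery suite reflects: with one presentation per bait the
collated response equals the simulated log catch exactly and ordinary
least squares is correctly specified (the Monte-Carlo study measures ≈ 95%
confidence-interval coverage and < 3% relative bias over 200 replicates of
40 baits at σ = 0.15). With multiple presentations the field convention of
averaging *percentages* before the log transform introduces a small Jensen
effect — the error term becomes slightly skewed and the measured coverage
drops by a couple of points. This is a property of the collation
convention, not a defect of the estimator.

## Problem sizes

The test suite and acceptance script size their simulations as a
statistician would for a smoke-level Monte-Carlo audit: 200 replicates of
40-bait panels for the recovery study, a 101-bait panel for the
end-to-end reproduction pipeline (matching the scale of the collated field
datasets), 20 baits × 5 classes for the high-resolution excitation
cross-check. The whole suite completes in well under a minute.

## Known limitations

* The packaged spectra are synthetic stand-ins (above); absolute
  excitations are fixture-dependent even though every anchor property and
  invariance is exact.
* The model is steady-state: no temporal adaptation dynamics, photon noise,
  polarisation, or the specialised dorsal-rim/male-specific eye regions;
  the 70/30 y:p ommatidial abundance is not used as a weighting.
* The opponency index is a statistical summary of attraction, not a claim
  about neural wiring; whether R7p interacts directly with the R7y/R8y
  channel or through a separate pathway is not identifiable from catch
  data.
* PLS dialects differ across software in convergence and standardisation
  details; comparisons with other implementations are tolerance-based.
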