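"""Background-adapted excitations of the five fly photoreceptor classes.

Each ommatidium of the higher-fly compound eye carries the outer receptors
R1-6 plus a central R7/R8 pair occurring in 'y' (yellow) and 'p' (pale)
subtypes, giving five spectral classes over the main retina: R1-6, R7p, R7y,
R8p, R8y. For a bait with reflectance I_S(λ) viewed against a background
I_B(λ) under illuminant D(λ), each class c with sensitivity S_c(λ) responds
with

    quantum catch   P_c = R_c * ∫ I_S(λ) S_c(λ) D(λ) dλ
    excitation      E_c = P_c^n / (P_c^n + 1)

where the range-sensitivity factor R_c = 1 / ∫ I_B(λ) S_c(λ) D(λ) dλ
implements adaptation: the background itself yields P = 1 and hence a
half-maximal response E = 0.5 in every class. The transduction exponent n
defaults to 1 (fully light-adapted photoreceptors), for which E = P/(P+1)
exactly. All five classes are modelled with identical machinery — voltage
gain per unit contrast is equalised across fly photoreceptor types, so no
per-class gain parameters are introduced.

Useful invariances of E, exploited by the tests: multiplying the illuminant
by any k > 0 cancels between R and P; multiplying bait *and* background
reflectance by one common k > 0 likewise cancels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .spectra import Spectrum, SpectrumError, integrate_product

#: Canonical ordering of the five photoreceptor classes.
RECEPTOR_CLASSES: tuple[str, ...] = ("R1-6", "R7p", "R7y", "R8p", "R8y")


class ReceptorModelError(ValueError):
    """Raised for invalid receptor sets, degenerate backgrounds, or bad baits."""


def _check_classes(mapping: Mapping[str, object], what: str) -> None:
    missing = [c for c in RECEPTOR_CLASSES if c not in mapping]
    extra = [c for c in mapping if c not in RECEPTOR_CLASSES]
    if missing or extra:
        raise ReceptorModelError(
            f"{what} must cover exactly {RECEPTOR_CLASSES}; "
            f"missing {missing or 'none'}, unexpected {extra or 'none'}"
        )


@dataclass(frozen=True)
class ReceptorSet:
    """The five spectral sensitivity functions, peak-normalised, on one grid."""

    sensitivities: Mapping[str, Spectrum]

    def __post_init__(self) -> None:
        _check_classes(self.sensitivities, "ReceptorSet")
        grids = {s.grid for s in self.sensitivities.values()}
        if len(grids) != 1:
            raise ReceptorModelError("all sensitivity spectra must share one grid")
        for label, s in self.sensitivities.items():
            peak = s.values.max()
            if not np.isclose(peak, 1.0, atol=1e-6):
                raise ReceptorModelError(
                    f"sensitivity of {label} is not peak-normalised (max {peak:.6g})"
                )

    @property
    def grid(self):
        return next(iter(self.sensitivities.values())).grid

    def __getitem__(self, label: str) -> Spectrum:
        return self.sensitivities[label]


@dataclass(frozen=True)
class AdaptationState:
    """Range-sensitivity factors R_c fixing the background at half response.

    Built by :func:`adapt`; carries the background and illuminant it was
    derived from so baits can be checked against the same grid.
    """

    background: Spectrum
    illuminant: Spectrum
    R: Mapping[str, float]

    def __post_init__(self) -> None:
        _check_classes(self.R, "AdaptationState.R")
        for label, r in self.R.items():
            if not (np.isfinite(r) and r > 0):
                raise ReceptorModelError(f"range sensitivity for {label} must be positive")


@dataclass(frozen=True)
class ExcitationVector:
    """Quantum catches P and excitations E of one bait, per receptor class."""

    E: Mapping[str, float]
    P: Mapping[str, float]
    bait_id: str = ""

    def __post_init__(self) -> None:
        _check_classes(self.E, "ExcitationVector.E")
        _check_classes(self.P, "ExcitationVector.P")

    def as_array(self) -> np.ndarray:
        """Excitations in canonical class order."""
        return np.array([self.E[c] for c in RECEPTOR_CLASSES])


def adapt(background: Spectrum, illuminant: Spectrum, receptors: ReceptorSet) -> AdaptationState:
    """Compute per-class range-sensitivity factors for a viewing background.

    R_c = 1 / ∫ I_B S_c D dλ, so that the background elicits quantum catch 1
    (half-maximal excitation at n = 1) in every class.

    Raises :class:`ReceptorModelError`, naming the class, if the background
    catch is zero for any class (degenerate background).
    """
    R: dict[str, float] = {}
    for label in RECEPTOR_CLASSES:
        catch = integrate_product(background, receptors[label], illuminant)
        if catch <= 0:
            raise ReceptorModelError(
                f"background quantum catch is zero for receptor {label}; "
                "cannot adapt to a background invisible to this class"
            )
        R[label] = 1.0 / catch
    return AdaptationState(background=background, illuminant=illuminant, R=R)


def excite(
    bait: Spectrum,
    state: AdaptationState,
    receptors: ReceptorSet,
    n: float = 1.0,
    bait_id: str = "",
) -> ExcitationVector:
    """Excitations of all five receptor classes for one bait spectrum.

    ``n`` is the transduction exponent; at the default n = 1 the closed form
    E = P/(P+1) is used directly.
    """
    if bait.grid != receptors.grid:
        raise ReceptorModelError(
            f"bait '{bait.name or bait_id}' is on grid {bait.grid}, "
            f"receptors on {receptors.grid}"
        )
    P: dict[str, float] = {}
    E: dict[str, float] = {}
    for label in RECEPTOR_CLASSES:
        p = state.R[label] * integrate_product(bait, receptors[label], state.illuminant)
        P[label] = p
        if n == 1.0:
            E[label] = p / (p + 1.0)
        else:
            pn = p ** n
            E[label] = pn / (pn + 1.0)
    return ExcitationVector(E=E, P=P, bait_id=bait_id or bait.name)


def excite_panel(
    baits: Sequence[Spectrum] | Mapping[str, Spectrum],
    state: AdaptationState,
    receptors: ReceptorSet,
    n: float = 1.0,
) -> pd.DataFrame:
    """Excite every bait in a panel; one row per bait, order preserved.

    Returns a DataFrame indexed by ``bait_id`` with columns ``E_<class>`` and
    ``P_<class>``. Duplicate bait identifiers are an error.
    """
    if isinstance(baits, Mapping):
        items = [(bid, s) for bid, s in baits.items()]
    else:
        items = [(s.name or f"bait_{i}", s) for i, s in enumerate(baits)]
    ids = [bid for bid, _ in items]
    dupes = sorted({b for b in ids if ids.count(b) > 1})
    if dupes:
        raise ReceptorModelError(f"duplicate bait identifiers: {dupes}")

    rows = []
    for bid, spectrum in items:
        ev = excite(spectrum, state, receptors, n=n, bait_id=bid)
        row: dict[str, float | str] = {"bait_id": bid}
        for c in RECEPTOR_CLASSES:
            row[f"E_{c}"] = ev.E[c]
        for c in RECEPTOR_CLASSES:
            row[f"P_{c}"] = ev.P[c]
        rows.append(row)
    cols = (["bait_id"] + [f"E_{c}" for c in RECEPTOR_CLASSES]
            + [f"P_{c}" for c in RECEPTOR_CLASSES])
    table = pd.DataFrame(rows, columns=cols).set_index("bait_id")
    return table


def excitation_columns(prefix: str = "E_") -> list[str]:
    """Column names used for per-class excitations in tabular outputs."""
    return [f"{prefix}{c}" for c in RECEPTOR_CLASSES]
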