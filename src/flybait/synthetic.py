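"""Synthetic bait panels and catch data with the assumed statistical structure.

Real visual-bait reflectances (dyed cloths) are smooth functions of
wavelength; the generator emulates them as a flat baseline plus a small
number of Gaussian peaks (possibly negative, i.e. absorption dips), clipped
to [0, 1]. Catches are then generated exactly under the model the analysis
fits: log10(catch+1) is a linear function of the R7y, R8y and R7p
excitations plus Gaussian noise on the log scale, back-transformed to a
percent-of-standard catch. This closes the loop — panel → excitations →
simulated catches → collation → regression recovers the generating
coefficients — which is what the parameter-recovery suite checks.

All randomness flows from the explicit ``seed`` in each spec; the same seed
gives bitwise-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import fixtures
from .spectra import DEFAULT_GRID, Spectrum, WavelengthGrid

logger = logging.getLogger(__name__)

#: (centre nm, width nm, height) ranges for panel peaks. Two peaks with
#: centres anywhere on the grid and signed heights give well-spread
#: excitations (roughly 0.1–0.8 across receptor classes) while keeping the
#: predictor correlations below the near-singular regime.
DEFAULT_PEAK_RANGES: tuple[tuple[tuple[float, float], ...], ...] = (
    ((320.0, 600.0), (20.0, 80.0), (-0.05, 0.25)),
    ((320.0, 600.0), (20.0, 80.0), (-0.05, 0.25)),
)


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for a panel of smooth synthetic bait reflectance spectra."""

    n_baits: int = 40
    baseline_range: tuple[float, float] = (0.01, 0.12)
    peak_ranges: Sequence[tuple[tuple[float, float], ...]] = DEFAULT_PEAK_RANGES
    seed: int = 0
    grid: WavelengthGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        if self.n_baits < 0:
            raise SyntheticError("n_baits must be >= 0")
        lo, hi = self.baseline_range
        if not (0 <= lo <= hi <= 1):
            raise SyntheticError(f"baseline range {self.baseline_range} outside [0, 1]")
        for pk in self.peak_ranges:
            for rng_lo, rng_hi in pk:
                if rng_lo > rng_hi:
                    raise SyntheticError(f"impossible range ({rng_lo}, {rng_hi})")
            if pk[1][0] <= 0:
                raise SyntheticError("peak widths must be positive")


@dataclass(frozen=True)
class CatchSimSpec:
    """Generating model for catches: log10(catch+1) = β0 + β·E + N(0, σ).

    Default coefficients mirror the attraction model — positive R7y,
    negative R8y and R7p — at magnitudes that give catch percentages of the
    same order as field data normalised to a standard bait (log-catch
    intercept near 2, i.e. ~100%).
    """

    beta0: float = 2.0
    beta_R7y: float = 1.5
    beta_R8y: float = -1.8
    beta_R7p: float = -1.2
    sigma: float = 0.15
    n_presentations: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise SyntheticError("sigma must be >= 0")
        if self.n_presentations < 1:
            raise SyntheticError("n_presentations must be >= 1")

    @property
    def beta(self) -> np.ndarray:
        """Slopes in predictor order (E_R7y, E_R8y, E_R7p)."""
        return np.array([self.beta_R7y, self.beta_R8y, self.beta_R7p])


def generate_panel(spec: PanelSpec) -> dict[str, Spectrum]:
    """Draw ``spec.n_baits`` smooth reflectance spectra, keyed by bait id.

    Each spectrum is baseline + Gaussian peaks with parameters drawn
    uniformly from the spec's ranges, clipped to [0, 1] (clipping logged).
    Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    wl = spec.grid.wavelengths
    panel: dict[str, Spectrum] = {}
    n_clipped = 0
    for i in range(spec.n_baits):
        values = np.full(wl.shape, rng.uniform(*spec.baseline_range))
        for (c_rng, w_rng, h_rng) in spec.peak_ranges:
            centre = rng.uniform(*c_rng)
            width = rng.uniform(*w_rng)
            height = rng.uniform(*h_rng)
            values = values + height * np.exp(-0.5 * ((wl - centre) / width) ** 2)
        if values.min() < 0 or values.max() > 1:
            n_clipped += 1
            values = np.clip(values, 0.0, 1.0)
        bait_id = f"synthetic_{i:03d}"
        panel[bait_id] = Spectrum(grid=spec.grid, values=values,
                                  role="reflectance", name=bait_id)
    if n_clipped:
        logger.info("clipped %d/%d synthetic spectra into [0, 1]", n_clipped, spec.n_baits)
    return panel


def leaf_like_background(
    grid: WavelengthGrid = DEFAULT_GRID,
    *,
    use_fixture: bool = True,
) -> Spectrum:
    """The adapting green-leaf background.

    Fixture mode returns the packaged leaf table resampled to ``grid``;
    synthetic mode builds a minimal stand-in directly on the grid — a low
    baseline with a single chlorophyll reflectance peak at 555 nm.
    """
    if use_fixture:
        return fixtures.load_background(grid)
    wl = grid.wavelengths
    values = 0.05 + 0.10 * np.exp(-0.5 * ((wl - 555.0) / 30.0) ** 2)
    return Spectrum(grid=grid, values=values, role="reflectance", name="leaf_synthetic")


def simulate_catches(
    excitations: pd.DataFrame,
    spec: CatchSimSpec,
    *,
    study: str = "synthetic",
    species: str = "synthetic",
    sex: str = "F",
) -> pd.DataFrame:
    """Generate catch records for every bait in an excitation table.

    One record per (bait, presentation): log10(catch+1) is drawn from the
    generating model and back-transformed; negative percentages (possible
    only under large negative noise) are clipped at 0 and logged.
    """
    for col in ("E_R7y", "E_R8y", "E_R7p"):
        if col not in excitations.columns:
            raise SyntheticError(f"excitation table lacks column {col}")
    rng = np.random.default_rng(spec.seed)
    E = excitations[["E_R7y", "E_R8y", "E_R7p"]].to_numpy(dtype=float)
    mu = spec.beta0 + E @ spec.beta
    rows = []
    n_clipped = 0
    for pres in range(spec.n_presentations):
        log_catch = mu + rng.normal(0.0, spec.sigma, size=len(E)) if spec.sigma > 0 else mu
        catch = 10.0 ** log_catch - 1.0
        neg = catch < 0
        n_clipped += int(neg.sum())
        catch = np.where(neg, 0.0, catch)
        for bait_id, c in zip(excitations.index, catch):
            rows.append({"study": study, "species": species, "sex": sex,
                         "bait_id": bait_id, "catch_pct": float(c),
                         "presentation": pres})
    if n_clipped:
        logger.info("clipped %d simulated catches at 0%%", n_clipped)
    return pd.DataFrame(rows)
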