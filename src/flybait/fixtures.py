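"""Packaged illuminant, background and receptor-sensitivity spectra.

The excitation model needs three standing inputs besides the bait spectra:
a daylight illuminant expressed as normalised quanta, a typical green-leaf
background reflectance (the adapting background of riverine tsetse habitat),
and the five photoreceptor sensitivity curves. The CSVs packaged under
``flybait/data/`` are *synthetic stand-ins* generated by the functions in
this module:

* ``daylight_quanta.csv`` — photon flux of a 6500 K Planckian radiator
  (a standard-daylight approximation), peak-normalised, tabulated at 5 nm;
* ``leaf_reflectance.csv`` — a green-leaf template: low flat reflectance
  with a chlorophyll reflectance peak at 555 nm and a red-edge rise beyond
  690 nm, tabulated at 10 nm;
* ``receptor_sensitivities.csv`` — the five fly receptor classes built from
  Govardovskii-style A1 rhodopsin templates plus Gaussian accessory bands:
  R1-6 (α-peak 490 nm + UV sensitising band at 350 nm), R7p (α 335 nm),
  R7y (α 355 nm + blue shoulder near 430 nm), R8p (α 460 nm), R8y (α 540 nm
  + UV band at 350 nm), peak-normalised, tabulated at 2 nm.

Excitations are invariant to the illuminant's absolute scale, and every
quantitative guarantee in the test suite is a property or an oracle
comparison on these same curves, so none depends on the stand-ins matching
any particular measured dataset. Users with their own measured curves can
substitute them anywhere a fixture is accepted.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .receptors import RECEPTOR_CLASSES, ReceptorSet
from .spectra import DEFAULT_GRID, Spectrum, WavelengthGrid, resample

_NATIVE_LO, _NATIVE_HI = 300.0, 700.0


# ---------------------------------------------------------------------------
# synthetic generators

def _govardovskii_alpha(wavelengths: np.ndarray, lambda_max: float) -> np.ndarray:
    """A1 visual-pigment α-band template (Govardovskii et al. 2000 form)."""
    x = lambda_max / wavelengths
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    b, c = 0.922, 1.104
    return 1.0 / (
        np.exp(69.7 * (a - x)) + np.exp(28.0 * (b - x))
        + np.exp(-14.9 * (c - x)) + 0.674
    )


def _gaussian_band(wavelengths: np.ndarray, centre: float, width: float,
                   height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((wavelengths - centre) / width) ** 2)


def synthetic_daylight_quanta(step: float = 5.0) -> tuple[np.ndarray, np.ndarray]:
    """Photon flux of a 6500 K Planckian radiator, peak-normalised.

    Planck's law in photon units: N(λ) ∝ λ⁻⁴ / (exp(hc/λkT) − 1). Synthetic
    standard-daylight approximation; tabulated at ``step`` nm over 300–700 nm.
    """
    wl = np.arange(_NATIVE_LO, _NATIVE_HI + step / 2, step)
    hc_over_k = 1.4388e7  # nm·K, second radiation constant
    lam = wl  # nm
    quanta = lam ** -4 / np.expm1(hc_over_k / (lam * 6500.0))
    return wl, quanta / quanta.max()


def synthetic_leaf_reflectance(step: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Green-leaf reflectance template with a 555 nm chlorophyll peak.

    Low flat reflectance (~5%) across UV–blue, a reflectance peak at 555 nm,
    a dip through the red chlorophyll absorption and the near-infrared red
    edge rising beyond ~690 nm. Values are fractions.
    """
    wl = np.arange(_NATIVE_LO, _NATIVE_HI + step / 2, step)
    base = 0.05 * np.ones_like(wl)
    green_peak = _gaussian_band(wl, 555.0, 30.0, 0.10)
    red_edge = 0.35 / (1.0 + np.exp(-(wl - 705.0) / 8.0))
    return wl, base + green_peak + red_edge


_SENSITIVITY_RECIPES: dict[str, tuple[float, list[tuple[float, float, float]]]] = {
    # label: (alpha-band peak nm, [(centre, width, height) accessory Gaussians])
    "R1-6": (490.0, [(350.0, 28.0, 1.00)]),   # UV sensitising band ~ equal height
    "R7p": (335.0, []),
    "R7y": (355.0, [(430.0, 40.0, 0.40)]),    # blue shoulder
    "R8p": (460.0, []),
    "R8y": (540.0, [(350.0, 25.0, 0.30)]),    # UV accessory band
}


def synthetic_receptor_sensitivities(step: float = 2.0) -> pd.DataFrame:
    """The five receptor sensitivity curves, peak-normalised, as a table.

    Returns a DataFrame with a ``wavelength_nm`` column and one column per
    receptor class in canonical order.
    """
    wl = np.arange(_NATIVE_LO, _NATIVE_HI + step / 2, step)
    out = {"wavelength_nm": wl}
    for label in RECEPTOR_CLASSES:
        peak, bands = _SENSITIVITY_RECIPES[label]
        curve = _govardovskii_alpha(wl, peak)
        for centre, width, height in bands:
            curve = curve + _gaussian_band(wl, centre, width, height)
        out[label] = curve / curve.max()
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# packaged CSVs

_PROVENANCE = {
    "daylight_quanta.csv": (
        "# Synthetic standard-daylight illuminant expressed as normalised quanta.\n"
        "# Photon flux of a 6500 K Planckian radiator, peak-normalised; 5 nm steps.\n"
        "# Generated by flybait.fixtures.synthetic_daylight_quanta(); a stand-in\n"
        "# for measured D65 quanta tables (excitations are invariant to scale).\n"
    ),
    "leaf_reflectance.csv": (
        "# Synthetic typical green-leaf background reflectance (fractions).\n"
        "# Flat ~5% base + chlorophyll reflectance peak at 555 nm + red edge; 10 nm steps.\n"
        "# Generated by flybait.fixtures.synthetic_leaf_reflectance(); a stand-in\n"
        "# for measured leaf reflectance tables.\n"
    ),
    "receptor_sensitivities.csv": (
        "# Synthetic fly photoreceptor spectral sensitivities, peak-normalised; 2 nm steps.\n"
        "# Govardovskii A1 rhodopsin templates plus Gaussian accessory bands:\n"
        "# R1-6 alpha 490 nm + UV band 350 nm; R7p alpha 335 nm; R7y alpha 355 nm +\n"
        "# blue shoulder 430 nm; R8p alpha 460 nm; R8y alpha 540 nm + UV band 350 nm.\n"
        "# Generated by flybait.fixtures.synthetic_receptor_sensitivities(); stand-ins\n"
        "# for curves digitised from electrophysiological recordings.\n"
    ),
}


def _data_path(filename: str):
    return resources.files("flybait").joinpath("data", filename)


def write_packaged_data(directory: str | Path) -> None:
    """(Re)generate the packaged fixture CSVs into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    wl, q = synthetic_daylight_quanta()
    frames = {
        "daylight_quanta.csv": pd.DataFrame(
            {"wavelength_nm": wl, "daylight_quanta": q}),
        "leaf_reflectance.csv": pd.DataFrame(
            dict(zip(["wavelength_nm", "leaf"],
                     synthetic_leaf_reflectance()))),
        "receptor_sensitivities.csv": synthetic_receptor_sensitivities(),
    }
    for name, frame in frames.items():
        path = directory / name
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_PROVENANCE[name])
            frame.to_csv(fh, index=False, float_format="%.8g")


def _read_fixture(filename: str) -> pd.DataFrame:
    with _data_path(filename).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, comment="#")


def load_illuminant(grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Packaged daylight-quanta illuminant, resampled onto ``grid``."""
    table = _read_fixture("daylight_quanta.csv")
    return resample(table["wavelength_nm"], table["daylight_quanta"], grid,
                    role="illuminant", name="daylight_quanta")


def load_background(grid: WavelengthGrid = DEFAULT_GRID) -> Spectrum:
    """Packaged leaf-background reflectance, resampled onto ``grid``."""
    table = _read_fixture("leaf_reflectance.csv")
    return resample(table["wavelength_nm"], table["leaf"], grid,
                    role="reflectance", name="leaf")


def load_receptors(grid: WavelengthGrid = DEFAULT_GRID) -> ReceptorSet:
    """Packaged five-class sensitivity curves, resampled and re-normalised.

    Peaks are re-normalised to 1 after resampling (interpolation can shave
    a grid-resolution peak slightly).
    """
    table = _read_fixture("receptor_sensitivities.csv")
    sens = {}
    for label in RECEPTOR_CLASSES:
        s = resample(table["wavelength_nm"], table[label], grid,
                     role="sensitivity", name=label)
        sens[label] = Spectrum(grid=grid, values=s.values / s.values.max(),
                               role="sensitivity", name=label)
    return ReceptorSet(sensitivities=sens)
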