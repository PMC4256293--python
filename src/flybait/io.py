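"""Readers/writers for spectra, excitation tables and collated catch datasets.

Spectra CSV dialect: first column ``wavelength_nm`` (strictly ascending),
one column per spectrum, header row with spectrum identifiers; ``#`` lines
are comments. Reflectances supplied in percent (values > 1.5) are divided
by 100 and the rescaling is logged.

The collated catch dataset is one row per bait presentation with catch as a
percentage of the standard bait plus the five calculated excitations; both
CSV and spreadsheet (.xlsx) input are accepted, spreadsheets read-only. The
column mapping is configurable because supplementary-data layouts vary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .receptors import RECEPTOR_CLASSES
from .spectra import (DEFAULT_GRID, Spectrum, SpectrumError, WavelengthGrid,
                      normalise_reflectance_scale, resample)

logger = logging.getLogger(__name__)


class DataFormatError(ValueError):
    pass


#: Expected unique-bait counts per study in a full collated dataset
#: (targets / screens / biconical traps / F2 traps).
EXPECTED_STUDY_COUNTS = {"targets": 37, "screens": 27, "biconical": 26, "F2": 30}

DEFAULT_COLLATED_COLUMNS = {
    "study": "study", "species": "species", "sex": "sex", "bait_id": "bait_id",
    "catch_pct": "catch_pct", "presentation": "presentation",
    **{f"E_{c}": f"E_{c}" for c in RECEPTOR_CLASSES},
}


# ---------------------------------------------------------------------------
# spectra

def read_spectra(
    path: str | Path,
    grid: WavelengthGrid | None = None,
    *,
    role: str = "reflectance",
) -> dict[str, Spectrum] | dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read a multi-spectrum CSV; resample onto ``grid`` when given.

    Returns a dict keyed by spectrum identifier. Without a grid, values are
    ``(wavelengths, values)`` arrays at native resolution; with one, each is
    a :class:`Spectrum` on that grid. Percent-scale reflectances are
    auto-rescaled. Errors carry offending row numbers.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, comment="#")
    except ValueError as exc:
        raise DataFormatError(f"{path}: cannot parse CSV: {exc}") from exc
    if table.shape[1] < 2:
        raise DataFormatError(f"{path}: need a wavelength column plus >= 1 spectrum")
    wl_col = table.columns[0]
    for col in table.columns:
        bad = pd.to_numeric(table[col], errors="coerce").isna() & table[col].notna()
        if bad.any():
            rows = (table.index[bad] + 2).tolist()  # +2: header + 1-based
            raise DataFormatError(f"{path}: non-numeric cells in '{col}' at rows {rows}")
    wl = table[wl_col].to_numpy(dtype=float)
    diffs = np.diff(wl)
    if (diffs == 0).any():
        rows = (np.nonzero(diffs == 0)[0] + 3).tolist()
        raise DataFormatError(f"{path}: duplicate wavelengths at rows {rows}")
    if (diffs < 0).any():
        rows = (np.nonzero(diffs < 0)[0] + 3).tolist()
        raise DataFormatError(f"{path}: descending wavelengths at rows {rows}")

    out: dict = {}
    for col in table.columns[1:]:
        values = table[col].to_numpy(dtype=float)
        if role == "reflectance":
            values = normalise_reflectance_scale(values, name=str(col))
        if grid is None:
            out[str(col)] = (wl, values)
        else:
            out[str(col)] = resample(wl, values, grid, role=role, name=str(col))
    logger.info("read %d spectra from %s", len(out), path)
    return out


def write_spectra(path: str | Path, spectra: Mapping[str, Spectrum]) -> None:
    """Write spectra sharing one grid to the CSV dialect ``read_spectra`` accepts."""
    spectra = dict(spectra)
    if not spectra:
        raise DataFormatError("nothing to write")
    grids = {s.grid for s in spectra.values()}
    if len(grids) != 1:
        raise DataFormatError("all spectra must share one grid to be written together")
    grid = grids.pop()
    frame = pd.DataFrame({"wavelength_nm": grid.wavelengths})
    for name, s in spectra.items():
        frame[name] = s.values
    frame.to_csv(path, index=False)


def write_excitations(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=True)


def read_excitations(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="bait_id")


# ---------------------------------------------------------------------------
# collated catch dataset

def read_collated_dataset(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a collated catch dataset (CSV or XLSX).

    Returns ``(records, excitations)``: per-presentation catch records
    (study, species, sex, bait_id, catch_pct, presentation) and a per-bait
    excitation table indexed by bait_id. ``column_map`` maps the canonical
    names to the file's actual column headers. Missing columns fail naming
    them; a per-study unique-bait count differing from the expected full
    dataset is logged as a warning, not an error.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path, comment="#")
    colmap = dict(DEFAULT_COLLATED_COLUMNS)
    if column_map:
        colmap.update(column_map)

    required = [k for k in colmap if k not in ("presentation", "species")]
    missing = [k for k in required if colmap[k] not in raw.columns]
    if missing:
        raise DataFormatError(f"{path}: missing columns: {missing}")

    records = pd.DataFrame({
        "study": raw[colmap["study"]],
        "species": raw[colmap["species"]] if colmap["species"] in raw.columns else "unknown",
        "sex": raw[colmap["sex"]],
        "bait_id": raw[colmap["bait_id"]].astype(str),
        "catch_pct": pd.to_numeric(raw[colmap["catch_pct"]]),
    })
    if colmap["presentation"] in raw.columns:
        records["presentation"] = raw[colmap["presentation"]]
    else:
        records["presentation"] = records.groupby(
            ["study", "sex", "bait_id"]).cumcount()

    exc_cols = {f"E_{c}": colmap[f"E_{c}"] for c in RECEPTOR_CLASSES}
    excitations = (
        raw.assign(bait_id=raw[colmap["bait_id"]].astype(str))
        .drop_duplicates("bait_id")
        .set_index("bait_id")[list(exc_cols.values())]
        .rename(columns={v: k for k, v in exc_cols.items()})
        .astype(float)
    )

    for study, expected in EXPECTED_STUDY_COUNTS.items():
        subset = records.loc[records["study"] == study, "bait_id"]
        if len(subset) == 0:
            continue
        n_unique = subset.nunique()
        logger.info("study '%s': %d unique baits", study, n_unique)
        if n_unique != expected:
            logger.warning("study '%s' has %d unique baits, expected %d",
                           study, n_unique, expected)
    return records, excitations


# ---------------------------------------------------------------------------
# run configuration / provenance

@dataclass
class RunConfig:
    """Serialisable configuration echoed into every output directory."""

    grid_start: float = DEFAULT_GRID.start
    grid_stop: float = DEFAULT_GRID.stop
    grid_step: float = DEFAULT_GRID.step
    n_exponent: float = 1.0
    illuminant: str = "daylight"       # fixture name or CSV path
    background: str = "leaf"           # fixture name or CSV path
    sensitivities: str = "packaged"    # 'packaged' or CSV path
    index: str = "R7y-R8y-R7p"
    seed: int = 0
    log_level: str = "INFO"
    out_dir: str = "."

    def grid(self) -> WavelengthGrid:
        return WavelengthGrid(self.grid_start, self.grid_stop, self.grid_step)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise DataFormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


def write_provenance(out_dir: str | Path, config: RunConfig,
                     inputs: Sequence[str | Path] = ()) -> Path:
    """Write a machine-readable provenance record for a CLI run."""
    import flybait

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    checksums = {}
    for p in inputs:
        p = Path(p)
        if p.is_file():
            checksums[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    record = {
        "package": "flybait",
        "version": flybait.__version__,
        "config": asdict(config),
        "input_sha256": checksums,
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2))
    config.to_yaml(out_dir / "config.yaml")
    return path
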