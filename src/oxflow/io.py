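"""File readers/writers for every stream the pipeline consumes or emits.

Formats (headered CSV, UTF-8, '.' decimal):

* spectra directory — ``spectra.csv`` (column ``wavelength_nm`` plus one
  column per acquisition named ``t=<seconds>``; per-cycle frame averages),
  ``dark.csv`` and ``reference.csv`` (two columns: wavelength_nm, counts);
* g2 curves — one file per acquisition, columns ``tau_s, g2`` with
  ``# timestamp=`` / ``# duration=`` comment headers;
* DCE — ``time_s, Ca_uM, Cb_uM``;
* concentration time series — ``time, dHb, dHbO2, dCCO, StO2, pathlength``;
* result summaries — JSON with a ``schema_version`` field and the config
  hash for provenance.

Write→read round trips are lossless to 1e-9; malformed rows are reported
with their line numbers and non-monotone grids rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SCHEMA_VERSION
from .dce import DCERecord
from .dcs import AutocorrelationCurve
from .errors import InvalidInputError

_FLOAT_FMT = "%.12g"


def _read_table(path: Path, n_cols: int) -> np.ndarray:
    """Parse a whitespace/comma table, reporting bad rows by line number."""
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        parts = s.replace(",", " ").split()
        if not rows and not _is_float(parts[0]):
            continue  # header row (first non-comment line before any data)
        try:
            vals = [float(p) for p in parts]
        except ValueError as e:
            raise InvalidInputError(f"{path}:{lineno}: unparseable row ({e})") from None
        if len(vals) != n_cols:
            raise InvalidInputError(
                f"{path}:{lineno}: expected {n_cols} columns, got {len(vals)}"
            )
        rows.append(vals)
    if not rows:
        raise InvalidInputError(f"{path}: no data rows")
    return np.asarray(rows)


def _is_float(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Spectra

def write_spectra_dir(directory: str | Path, seq) -> None:
    """Write a rendered :class:`~oxflow.synthetic.SpectraSequence`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    counts = seq.frames.mean(axis=1)  # per-cycle frame average
    df = pd.DataFrame(counts.T, columns=[f"t={t:.3f}" for t in seq.times])
    df.insert(0, "wavelength_nm", seq.grid)
    df.to_csv(directory / "spectra.csv", index=False, float_format=_FLOAT_FMT)
    for name, vals in (("dark", seq.dark), ("reference", seq.reference)):
        pd.DataFrame({"wavelength_nm": seq.grid, "counts": vals}).to_csv(
            directory / f"{name}.csv", index=False, float_format=_FLOAT_FMT
        )


def read_spectra_dir(directory: str | Path):
    """Read a spectra directory → (grid, times, counts[n_t×n_λ], dark, ref)."""
    directory = Path(directory)
    df = pd.read_csv(directory / "spectra.csv")
    if "wavelength_nm" not in df.columns:
        raise InvalidInputError(f"{directory}/spectra.csv: missing wavelength_nm column")
    grid = df["wavelength_nm"].to_numpy(float)
    if np.any(np.diff(grid) <= 0):
        raise InvalidInputError(f"{directory}/spectra.csv: non-monotone wavelength grid")
    tcols = [c for c in df.columns if c.startswith("t=")]
    if not tcols:
        raise InvalidInputError(f"{directory}/spectra.csv: no frame columns (t=...)")
    times = np.array([float(c[2:]) for c in tcols])
    counts = df[tcols].to_numpy(float).T
    dark = _read_two_col(directory / "dark.csv", grid)
    reference = _read_two_col(directory / "reference.csv", grid)
    return grid, times, counts, dark, reference


def _read_two_col(path: Path, grid: np.ndarray) -> np.ndarray:
    tbl = _read_table(path, 2)
    if tbl.shape[0] != grid.size or not np.allclose(tbl[:, 0], grid):
        raise InvalidInputError(f"{path}: wavelength grid differs from spectra.csv")
    return tbl[:, 1]


# ---------------------------------------------------------------------------
# g2 curves

def write_g2_curves(directory: str | Path, curves: list) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, c in enumerate(curves):
        p = directory / f"g2_{i:05d}.csv"
        with p.open("w") as fh:
            fh.write(f"# timestamp={c.timestamp:.6g}\n# duration={c.duration:.6g}\n")
            fh.write("tau_s,g2\n")
            for t, g in zip(c.tau, c.g2):
                fh.write(f"{t:.12g},{g:.12g}\n")


def read_g2_curve(path: str | Path) -> AutocorrelationCurve:
    path = Path(path)
    meta = {"timestamp": 0.0, "duration": 5.0}
    for line in path.read_text().splitlines():
        if line.startswith("#") and "=" in line:
            k, v = line.lstrip("# ").split("=", 1)
            if k in meta:
                meta[k] = float(v)
    tbl = _read_table(path, 2)
    return AutocorrelationCurve(tau=tbl[:, 0], g2=tbl[:, 1], **meta)


def read_g2_dir(directory: str | Path) -> list:
    files = sorted(Path(directory).glob("g2_*.csv"))
    if not files:
        raise InvalidInputError(f"{directory}: no g2_*.csv files")
    return [read_g2_curve(p) for p in files]


# ---------------------------------------------------------------------------
# DCE and time series

def write_dce(path: str | Path, record: DCERecord) -> None:
    pd.DataFrame({
        "time_s": record.time, "Ca_uM": record.ca, "Cb_uM": record.cb,
    }).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_dce(path: str | Path) -> DCERecord:
    tbl = _read_table(Path(path), 3)
    return DCERecord(time=tbl[:, 0], ca=tbl[:, 1], cb=tbl[:, 2])


def write_timeseries(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_timeseries(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# JSON results

def write_result_json(path: str | Path, payload: dict, config_hash: str = "") -> None:
    out = {"schema_version": SCHEMA_VERSION, "config_hash": config_hash}
    out.update(payload)
    Path(path).write_text(json.dumps(out, indent=2, default=float))


def read_result_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
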