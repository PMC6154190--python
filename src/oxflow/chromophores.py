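"""Chromophore extinction spectra and wavelength-grid utilities.

All fitting stages share one :class:`ChromophoreLibrary`: extinction
coefficients for deoxy- and oxy-hemoglobin (µM⁻¹·mm⁻¹, natural-log
convention, i.e. the species' contribution to µa per µM), water absorption
per unit volume fraction (mm⁻¹), and the signed oxidised-minus-reduced
cytochrome-c-oxidase (oxCCO) difference spectrum (µM⁻¹·mm⁻¹).

The bundled tables are *synthetic*: smooth parametric spectra whose band
positions and magnitudes follow the well-known qualitative features of the
real compilations (Hb peak near 758 nm, HbO₂ rise towards 900–950 nm, water
bands near 740/836/970 nm, oxCCO difference peak near 835 nm).  Every
simulation and fit in this package uses the same library on both sides, so
results are self-consistent regardless of the exact table values.

Spectral derivatives use Savitzky–Golay local-polynomial filtering
(default window 11 points, order 3 on the 1-nm grid), the standard choice
in derivative spectroscopy; edges use polynomial extrapolation of the last
full window (``mode="interp"``), which is exact for polynomial inputs of
degree ≤ the filter order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter

from .errors import ExtrapolationError, InvalidInputError

# Instrument spectral range (nm) and default analysis resolution.
INSTRUMENT_MIN_NM = 548.0
INSTRUMENT_MAX_NM = 1085.0
DEFAULT_STEP_NM = 1.0

LN10 = math.log(10.0)

# Savitzky-Golay defaults for derivative spectroscopy on the 1-nm grid.
SG_WINDOW = 11
SG_POLYORDER = 3

_DATA_DIR = Path(__file__).parent / "data"


# ---------------------------------------------------------------------------
# Wavelength grid

def make_grid(
    lo: float = INSTRUMENT_MIN_NM,
    hi: float = INSTRUMENT_MAX_NM,
    step: float = DEFAULT_STEP_NM,
) -> np.ndarray:
    """Uniform wavelength grid in nm, clipped to the instrument range."""
    if step <= 0:
        raise InvalidInputError("grid step must be > 0")
    if lo < INSTRUMENT_MIN_NM or hi > INSTRUMENT_MAX_NM or hi <= lo:
        raise InvalidInputError(
            f"grid [{lo}, {hi}] nm outside instrument range "
            f"[{INSTRUMENT_MIN_NM}, {INSTRUMENT_MAX_NM}] nm"
        )
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def grid_step(grid: np.ndarray) -> float:
    """Step of a uniform, strictly increasing grid; validates uniformity."""
    d = np.diff(grid)
    if d.size == 0 or np.any(d <= 0):
        raise InvalidInputError("wavelength grid must be strictly increasing")
    if not np.allclose(d, d[0], rtol=1e-8, atol=1e-9):
        raise InvalidInputError("wavelength grid must be uniform")
    return float(d[0])


def window_slice(grid: np.ndarray, lo: float, hi: float) -> slice:
    """Index slice of ``grid`` covering [lo, hi] nm (inclusive)."""
    i0 = int(np.searchsorted(grid, lo - 1e-9, side="left"))
    i1 = int(np.searchsorted(grid, hi + 1e-9, side="right"))
    if i1 - i0 < 2:
        raise InvalidInputError(f"window [{lo}, {hi}] nm not covered by grid")
    return slice(i0, i1)


# ---------------------------------------------------------------------------
# Synthetic parametric spectra (see module docstring)

def _gauss(lam: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((lam - center) / sigma) ** 2)


def water_absorption(lam: np.ndarray) -> np.ndarray:
    """Synthetic pure-water absorption, mm⁻¹ (per unit volume fraction).

    Bands near 740, 830 and 970 nm.  The 830-nm band is narrow so that its
    curvature dominates the 815–845 nm second-derivative window — the
    property of the real ~835-nm water feature relative to the smooth
    hemoglobin tails, and what makes the water-anchored pathlength and WF
    fits identifiable.
    """
    lam = np.asarray(lam, dtype=float)
    return (
        0.0006
        + 0.0022 * _gauss(lam, 740.0, 16.0)
        + 0.0045 * _gauss(lam, 830.0, 8.0)
        + 0.0420 * _gauss(lam, 970.0, 40.0)
        + 0.0120 * _gauss(lam, 1160.0, 60.0)
    )


def hb_extinction(lam: np.ndarray) -> np.ndarray:
    """Synthetic deoxy-hemoglobin extinction, µM⁻¹·mm⁻¹ (natural log)."""
    lam = np.asarray(lam, dtype=float)
    return (
        3.0e-3 * np.exp(-(lam - 548.0) / 20.0)
        + 1.0e-4
        + 7.0e-4 * np.exp(-(lam - 650.0) / 120.0)
        + 1.1e-4 * _gauss(lam, 758.0, 15.0)
        + 0.5e-4 * _gauss(lam, 905.0, 45.0)
    )


def hbo2_extinction(lam: np.ndarray) -> np.ndarray:
    """Synthetic oxy-hemoglobin extinction, µM⁻¹·mm⁻¹ (natural log)."""
    lam = np.asarray(lam, dtype=float)
    return (
        3.4e-3 * np.exp(-(lam - 548.0) / 16.0)
        + 0.55e-4
        + 2.0e-4 * _gauss(lam, 960.0, 90.0)
    )


def cco_difference(lam: np.ndarray) -> np.ndarray:
    """Synthetic oxidised−reduced CCO difference spectrum, µM⁻¹·mm⁻¹.

    Signed; broad positive peak near 835 nm (the copper-A band of the
    oxidised enzyme), weak negative lobe at the red end.
    """
    lam = np.asarray(lam, dtype=float)
    return 4.6e-4 * _gauss(lam, 835.0, 48.0) - 0.8e-4 * _gauss(lam, 620.0, 55.0)


_SPECIES_FUNCS = {
    "hb": hb_extinction,
    "hbo2": hbo2_extinction,
    "water": water_absorption,
    "cco_diff": cco_difference,
}


# ---------------------------------------------------------------------------
# Resampling and derivatives

def resample(
    src_lam: np.ndarray, src_val: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Linearly interpolate a tabulated spectrum onto ``grid``.

    Raises :class:`ExtrapolationError` if the grid exceeds the source span.
    """
    src_lam = np.asarray(src_lam, dtype=float)
    src_val = np.asarray(src_val, dtype=float)
    if np.any(np.diff(src_lam) <= 0):
        raise InvalidInputError("source wavelengths must be strictly increasing")
    if grid[0] < src_lam[0] - 1e-9 or grid[-1] > src_lam[-1] + 1e-9:
        raise ExtrapolationError(
            f"grid [{grid[0]}, {grid[-1]}] nm outside source span "
            f"[{src_lam[0]}, {src_lam[-1]}] nm"
        )
    return np.interp(grid, src_lam, src_val)


def spectral_derivative(
    values: np.ndarray,
    order: int,
    *,
    delta: float = DEFAULT_STEP_NM,
    window: int = SG_WINDOW,
    polyorder: int = SG_POLYORDER,
    axis: int = -1,
) -> np.ndarray:
    """Smoothed spectral derivative (per nm^order) on the same grid.

    Savitzky-Golay filtering; exact for polynomials of degree ≤ polyorder,
    including at the edges.
    """
    if order not in (1, 2):
        raise InvalidInputError(f"derivative order must be 1 or 2, got {order}")
    values = np.asarray(values, dtype=float)
    if values.shape[axis] < window:
        raise InvalidInputError(
            f"need ≥ {window} points for the derivative window, got {values.shape[axis]}"
        )
    return savgol_filter(
        values, window, polyorder, deriv=order, delta=delta, mode="interp", axis=axis
    )


def smooth_spectrum(
    values: np.ndarray,
    *,
    window: int = SG_WINDOW,
    polyorder: int = SG_POLYORDER,
) -> np.ndarray:
    """Zeroth-order Savitzky-Golay smoother (optional de-noising step)."""
    values = np.asarray(values, dtype=float)
    if values.shape[-1] < window:
        raise InvalidInputError("spectrum shorter than smoothing window")
    return savgol_filter(values, window, polyorder, mode="interp")


# ---------------------------------------------------------------------------
# Library

@dataclass(frozen=True)
class ChromophoreLibrary:
    """Extinction spectra for all species on one shared wavelength grid.

    hb, hbo2, cco_diff in µM⁻¹·mm⁻¹ (natural-log convention); water in mm⁻¹
    per unit volume fraction.  ``provenance`` tags each table's origin.
    """

    grid: np.ndarray
    hb: np.ndarray
    hbo2: np.ndarray
    water: np.ndarray
    cco_diff: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.grid.size
        for name in ("hb", "hbo2", "water", "cco_diff"):
            arr = getattr(self, name)
            if arr.size != n:
                raise InvalidInputError(f"{name} not on the shared grid")
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError(f"{name} contains non-finite values")
        for name in ("hb", "hbo2", "water"):
            if np.any(getattr(self, name) < 0):
                raise InvalidInputError(f"{name} extinction must be ≥ 0")
        grid_step(self.grid)

    @property
    def step(self) -> float:
        return grid_step(self.grid)

    @classmethod
    def default(cls, grid: np.ndarray | None = None) -> "ChromophoreLibrary":
        """Library evaluated from the bundled synthetic parametric spectra."""
        if grid is None:
            grid = make_grid()
        return cls(
            grid=grid,
            hb=hb_extinction(grid),
            hbo2=hbo2_extinction(grid),
            water=water_absorption(grid),
            cco_diff=cco_difference(grid),
            provenance={k: "synthetic parametric compilation" for k in _SPECIES_FUNCS},
        )

    @classmethod
    def from_files(
        cls,
        paths: dict[str, str | Path] | None = None,
        grid: np.ndarray | None = None,
    ) -> "ChromophoreLibrary":
        """Load two-column (λ_nm, value) tables and resample onto ``grid``.

        ``paths`` maps species names {hb, hbo2, water, cco_diff} to files;
        defaults to the bundled synthetic tables.
        """
        if grid is None:
            grid = make_grid()
        if paths is None:
            paths = {
                "hb": _DATA_DIR / "hb_extinction_synthetic.tsv",
                "hbo2": _DATA_DIR / "hbo2_extinction_synthetic.tsv",
                "water": _DATA_DIR / "water_absorption_synthetic.tsv",
                "cco_diff": _DATA_DIR / "cco_difference_synthetic.tsv",
            }
        missing = set(_SPECIES_FUNCS) - set(paths)
        if missing:
            raise InvalidInputError(f"missing extinction tables for: {sorted(missing)}")
        spectra = {}
        provenance = {}
        for name, p in paths.items():
            tbl = np.loadtxt(p)
            spectra[name] = resample(tbl[:, 0], tbl[:, 1], grid)
            provenance[name] = str(p)
        return cls(grid=grid, provenance=provenance, **spectra)

    def on_window(self, lo: float, hi: float) -> "ChromophoreLibrary":
        """Restrict the library to wavelengths in [lo, hi] nm."""
        sl = window_slice(self.grid, lo, hi)
        return ChromophoreLibrary(
            grid=self.grid[sl],
            hb=self.hb[sl],
            hbo2=self.hbo2[sl],
            water=self.water[sl],
            cco_diff=self.cco_diff[sl],
            provenance=dict(self.provenance),
        )

    def extinction_matrix(self, species: tuple[str, ...]) -> np.ndarray:
        """(n_wavelengths × n_species) matrix of the requested spectra."""
        cols = []
        for name in species:
            if name not in _SPECIES_FUNCS:
                raise InvalidInputError(f"unknown species {name!r}")
            cols.append(getattr(self, name))
        return np.column_stack(cols)


def write_bundled_tables(directory: str | Path = _DATA_DIR) -> None:
    """(Re)generate the bundled synthetic extinction tables on the 1-nm grid."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    grid = make_grid()
    names = {
        "hb": "hb_extinction_synthetic.tsv",
        "hbo2": "hbo2_extinction_synthetic.tsv",
        "water": "water_absorption_synthetic.tsv",
        "cco_diff": "cco_difference_synthetic.tsv",
    }
    for key, fname in names.items():
        vals = _SPECIES_FUNCS[key](grid)
        header = (
            f"synthetic parametric {key} spectrum; columns: wavelength_nm value\n"
            "units: water mm^-1 per unit volume fraction; others uM^-1 mm^-1 (natural log)"
        )
        np.savetxt(
            directory / fname,
            np.column_stack([grid, vals]),
            fmt=("%.1f", "%.8e"),
            header=header,
        )
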