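"""Differential chromophore tracking (modified Beer-Lambert / UCLn).

After the baseline fit, concentration *changes* ΔHb, ΔHbO₂ and ΔoxCCO are
tracked with a linear multi-wavelength solver over 770–900 nm:

    ΔA(λ, t) = L(t)·w(λ) · [ε_Hb, ε_HbO2, ε_oxCCO](λ) · Δc(t)

where ΔA is the attenuation change (optical density) relative to the mean
baseline-period spectrum, L(t) is a dynamic optical pathlength estimated
per spectrum from the 2nd-derivative water feature at 815–845 nm, and w(λ)
is an optional wavelength-dependence factor of the pathlength (identity by
default; optionally derived from the baseline tissue model's differential
pathlength).  The system is solved by Moore-Penrose pseudoinverse — no
regularisation is needed at 1-nm sampling.

Time-resolved saturation combines the baseline absolutes with the tracked
changes:  StO₂(t) = (HbO2_b + ΔHbO₂)/((Hb_b + ΔHb) + (HbO2_b + ΔHbO₂)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chromophores import (
    LN10,
    ChromophoreLibrary,
    grid_step,
    spectral_derivative,
    window_slice,
)
from .bnirs_baseline import BaselineFitResult, _window_with_margin
from .errors import InvalidInputError
from .forward_models import TissueModel, musp, reflectance_cw

UCLN_WINDOW = (770.0, 900.0)
WATER_WINDOW = (815.0, 845.0)


# ---------------------------------------------------------------------------
# Dynamic pathlength from the water feature

def dynamic_pathlength(
    grid: np.ndarray,
    r_spectrum: np.ndarray,
    wf: float,
    lib: ChromophoreLibrary,
    window: tuple[float, float] = WATER_WINDOW,
) -> float:
    """Scalar optical pathlength (mm) from the 2nd-derivative water fit.

    Finds L minimising ‖d²A(λ) − L·WF·d²(µa_w(λ)/ln10)‖² over the water
    window, where A = −R is the measured attenuation in OD.  Closed form:
    the normal-equation projection of the data derivative on the water
    derivative shape.
    """
    if wf <= 0:
        raise InvalidInputError("water fraction must be > 0 for pathlength estimation")
    outer, inner = _window_with_margin(grid, *window)
    step = grid_step(grid)
    d2a = spectral_derivative(-np.asarray(r_spectrum, dtype=float)[outer], 2, delta=step)[inner]
    water_od = wf * lib.water[outer] / LN10
    d2w = spectral_derivative(water_od, 2, delta=step)[inner]
    denom = float(d2w @ d2w)
    if denom < 1e-30:
        raise InvalidInputError("degenerate (flat) water feature in the fit window")
    return float(d2a @ d2w) / denom


def pathlength_wavelength_factor(
    tissue: TissueModel,
    lib: ChromophoreLibrary,
    rho: float = 30.0,
    reference_nm: float = 830.0,
) -> np.ndarray:
    """Wavelength dependence w(λ) of the differential pathlength.

    Computed from the diffusion model at the baseline optical properties:
    DP(λ) = −∂ln R/∂µa (mm), normalised to 1 at ``reference_nm`` (the centre
    of the water-fit window, where the dynamic pathlength is anchored).
    Returned on the library grid.  The identity factor (all ones) is the
    default elsewhere; this model-derived factor is a pluggable refinement.
    """
    from .forward_models import mua_from_arrays

    mu_a = mua_from_arrays(tissue.WF, tissue.Hb_b, tissue.HbO2_b, lib)
    mu_s = musp(lib.grid, tissue.A, tissue.alpha)
    h = 1e-6
    dp = -(np.log(reflectance_cw(rho, mu_a + h, mu_s)) -
           np.log(reflectance_cw(rho, np.maximum(mu_a - h, 0.0), mu_s))) / (2 * h)
    i_ref = int(np.argmin(np.abs(lib.grid - reference_nm)))
    return dp / dp[i_ref]


# ---------------------------------------------------------------------------
# UCLn linear solver

def _design_matrix(
    lib: ChromophoreLibrary,
    sl: slice,
    pathlength: float,
    wavelength_factor: np.ndarray | None,
    species: tuple[str, ...],
) -> np.ndarray:
    E = lib.extinction_matrix(species)[sl, :] / LN10  # OD per µM per mm
    w = np.ones(sl.stop - sl.start) if wavelength_factor is None else wavelength_factor[sl]
    return (pathlength * w)[:, None] * E


def ucln_solve(
    grid: np.ndarray,
    delta_a: np.ndarray,
    pathlength: float,
    lib: ChromophoreLibrary,
    window: tuple[float, float] = UCLN_WINDOW,
    wavelength_factor: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Solve ΔA(λ) for (ΔHb, ΔHbO₂, ΔoxCCO) in µM via pseudoinverse."""
    if pathlength <= 0:
        raise InvalidInputError("pathlength must be > 0")
    sl = window_slice(grid, *window)
    if sl.stop - sl.start < 3:
        raise InvalidInputError("need ≥ 3 wavelengths for the 3-species solve")
    M = _design_matrix(lib, sl, pathlength, wavelength_factor, ("hb", "hbo2", "cco_diff"))
    if np.linalg.matrix_rank(M) < 3:
        raise InvalidInputError("rank-deficient extinction matrix on this grid")
    dc = np.linalg.pinv(M) @ np.asarray(delta_a, dtype=float)[sl]
    return tuple(map(float, dc))


@dataclass
class ComponentComparison:
    """2- vs 3-component modified Beer-Lambert fits of one ΔA spectrum."""

    grid: np.ndarray
    delta_a: np.ndarray
    fit2: np.ndarray
    fit3: np.ndarray
    residual2: np.ndarray
    residual3: np.ndarray
    norm2: float
    norm3: float
    deltas2: tuple[float, float]
    deltas3: tuple[float, float, float]


def compare_component_models(
    grid: np.ndarray,
    delta_a: np.ndarray,
    pathlength: float,
    lib: ChromophoreLibrary,
    window: tuple[float, float] = UCLN_WINDOW,
    wavelength_factor: np.ndarray | None = None,
) -> ComponentComparison:
    """Fit ΔA with {Hb, HbO₂} and {Hb, HbO₂, oxCCO}; report residuals.

    A residual of the 2-component fit that is structured like the oxCCO
    difference spectrum (peak near 820–835 nm) is the signature of the
    missing chromophore.
    """
    sl = window_slice(grid, *window)
    y = np.asarray(delta_a, dtype=float)[sl]
    out = {}
    for tag, species in (("2", ("hb", "hbo2")), ("3", ("hb", "hbo2", "cco_diff"))):
        M = _design_matrix(lib, sl, pathlength, wavelength_factor, species)
        dc = np.linalg.pinv(M) @ y
        fit = M @ dc
        out[tag] = (tuple(map(float, dc)), fit, y - fit)
    return ComponentComparison(
        grid=grid[sl],
        delta_a=y,
        fit2=out["2"][1],
        fit3=out["3"][1],
        residual2=out["2"][2],
        residual3=out["3"][2],
        norm2=float(np.linalg.norm(out["2"][2])),
        norm3=float(np.linalg.norm(out["3"][2])),
        deltas2=out["2"][0],
        deltas3=out["3"][0],
    )


# ---------------------------------------------------------------------------
# Time series assembly

def sto2_timeseries(
    baseline: BaselineFitResult,
    delta_hb: np.ndarray,
    delta_hbo2: np.ndarray,
) -> np.ndarray:
    """StO₂(t) combining baseline absolutes with tracked changes.

    Samples where total hemoglobin becomes non-positive are masked to NaN.
    """
    hb = baseline.tissue.Hb_b + np.asarray(delta_hb, dtype=float)
    hbo2 = baseline.tissue.HbO2_b + np.asarray(delta_hbo2, dtype=float)
    total = hb + hbo2
    with np.errstate(invalid="ignore", divide="ignore"):
        sto2 = np.where(total > 0, hbo2 / np.where(total > 0, total, 1.0), np.nan)
    return sto2


def track_timeseries(
    grid: np.ndarray,
    r_frames: np.ndarray,
    times: np.ndarray,
    baseline: BaselineFitResult,
    lib: ChromophoreLibrary,
    baseline_mask: np.ndarray | None = None,
    wavelength_factor: np.ndarray | None = None,
    smooth_pathlength: bool = False,
) -> pd.DataFrame:
    """Run the full differential chain over a sequence of R(λ) spectra.

    ΔA is computed against the mean of the baseline-period spectra
    (``baseline_mask``; defaults to the first frame).  Pathlength is
    estimated per spectrum; ``smooth_pathlength`` replaces it with its
    running median over 5 cycles.
    Returns a DataFrame: time, dHb, dHbO2, dCCO, StO2, pathlength.
    """
    r_frames = np.atleast_2d(np.asarray(r_frames, dtype=float))
    times = np.asarray(times, dtype=float)
    if baseline_mask is None:
        baseline_mask = np.zeros(len(times), dtype=bool)
        baseline_mask[0] = True
    r_base = r_frames[baseline_mask].mean(axis=0)

    paths = np.array([
        dynamic_pathlength(grid, r, baseline.tissue.WF, lib) for r in r_frames
    ])
    if smooth_pathlength:
        paths = pd.Series(paths).rolling(5, center=True, min_periods=1).median().to_numpy()

    deltas = np.empty((len(times), 3))
    for i, r in enumerate(r_frames):
        # attenuation change in OD: ΔA = −ΔR
        da = -(r - r_base)
        deltas[i] = ucln_solve(
            grid, da, paths[i], lib, wavelength_factor=wavelength_factor
        )
    sto2 = sto2_timeseries(baseline, deltas[:, 0], deltas[:, 1])
    return pd.DataFrame({
        "time": times,
        "dHb": deltas[:, 0],
        "dHbO2": deltas[:, 1],
        "dCCO": deltas[:, 2],
        "StO2": sto2,
        "pathlength": paths,
    })
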