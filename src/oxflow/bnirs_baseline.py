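"""Baseline broadband-NIRS analysis: reflectance and the three-step fit.

The baseline reflectance spectrum is computed from raw spectrometer counts
as R(λ) = log10((spectrum − dark)/(reference − dark)).  Note this is the
measurement-over-reference convention (the sign is opposite to conventional
attenuation); every downstream step uses R consistently, so results are
invariant to the convention.

The five tissue parameters {WF, Hb_b, HbO2_b, A, α} are recovered by a
three-step constrained least-squares fit of the spectral derivatives of R
against the derivatives of the semi-infinite diffusion model:

1. 2nd derivative over 815–845 nm (water band); all five parameters are
   fitted but only WF is retained — scattering and the other chromophores
   contribute no significant curvature in this window.
2. WF fixed; 2nd derivative over 680–800 nm; Hb_b retained.
3. WF and Hb_b fixed; 1st derivative over 680–845 nm; HbO2_b, A and α
   retained.

Each step is a bounded Nelder–Mead simplex minimisation of the sum of
squared derivative differences (mirroring a bounded-simplex search), with
the same Savitzky–Golay derivative operator applied to the model and the
data so the operator's pass-band bias cancels.  Baseline tissue saturation
follows as StO₂ = HbO2_b/(Hb_b + HbO2_b).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, minimize

from . import chromophores as chrom
from .chromophores import ChromophoreLibrary, spectral_derivative, grid_step
from .config import DEFAULT_BOUNDS, DEFAULT_INITIALS, PARAM_ORDER
from .errors import InvalidInputError
from .forward_models import TissueModel, musp, reflectance_cw

#: points of margin kept on each side of a fit window so the smoothed
#: derivative inside the window is free of edge effects
_EDGE_MARGIN = chrom.SG_WINDOW // 2

# (window key, derivative order, free parameters, retained parameters)
_STEPS = (
    ("window_water", 2, PARAM_ORDER, ("WF",)),
    ("window_hb", 2, ("Hb_b", "HbO2_b", "A", "alpha"), ("Hb_b",)),
    ("window_first_deriv", 1, ("HbO2_b", "A", "alpha"), ("HbO2_b", "A", "alpha")),
)

_DEFAULT_WINDOWS = {
    "window_water": (815.0, 845.0),
    "window_hb": (680.0, 800.0),
    "window_first_deriv": (680.0, 845.0),
}


@dataclass
class RawSpectrumSet:
    """Raw counts: measured, dark and reference on one wavelength grid.

    ``measured`` may be 1-D (single frame) or 2-D (frames × wavelengths);
    ``integration_time`` is per frame in seconds.
    """

    grid: np.ndarray
    measured: np.ndarray
    dark: np.ndarray
    reference: np.ndarray
    integration_time: float = 0.25

    def __post_init__(self) -> None:
        n = self.grid.size
        if self.dark.shape[-1] != n or self.reference.shape[-1] != n:
            raise InvalidInputError("dark/reference not on the spectrum grid")
        if np.atleast_2d(self.measured).shape[-1] != n:
            raise InvalidInputError("measured counts not on the spectrum grid")


@dataclass
class BaselineFitResult:
    tissue: TissueModel
    sto2: float
    residual_norms: tuple[float, float, float]
    converged: bool
    at_bounds: list = field(default_factory=list)
    n_evaluations: int = 0

    def to_dict(self) -> dict:
        return {
            "WF": self.tissue.WF,
            "Hb_b": self.tissue.Hb_b,
            "HbO2_b": self.tissue.HbO2_b,
            "A": self.tissue.A,
            "alpha": self.tissue.alpha,
            "StO2_b": self.sto2,
            "residual_norms": list(self.residual_norms),
            "converged": self.converged,
            "at_bounds": self.at_bounds,
            "n_evaluations": self.n_evaluations,
        }


# ---------------------------------------------------------------------------
# Reflectance (Eq.-style ratio of background-corrected counts)

def compute_reflectance(raw: RawSpectrumSet, average: bool = True) -> np.ndarray:
    """R(λ) = log10((spectrum − dark)/(reference − dark)).

    Frames are averaged before the log when ``average`` is true.  Channels
    with a non-positive numerator or denominator are masked to NaN with a
    warning; if every channel is invalid an error is raised.
    """
    meas = np.atleast_2d(np.asarray(raw.measured, dtype=float))
    signal = (meas - raw.dark).mean(axis=0) if average else meas - raw.dark
    denom = raw.reference - raw.dark
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = signal / denom
        r = np.where(ratio > 0, np.log10(np.where(ratio > 0, ratio, 1.0)), np.nan)
    bad = ~np.isfinite(r)
    if bad.all():
        raise InvalidInputError("no valid channels: spectrum−dark or reference−dark ≤ 0")
    if bad.any():
        warnings.warn(
            f"{int(np.sum(bad))} channels masked (non-positive background-corrected counts)",
            stacklevel=2,
        )
    return r


def compute_sto2(hb: float, hbo2: float) -> float:
    """Hemoglobin oxygen saturation HbO₂/(Hb + HbO₂), as a fraction."""
    total = hb + hbo2
    if total <= 0:
        raise InvalidInputError("StO2 undefined: Hb + HbO2 must be > 0")
    return hbo2 / total


# ---------------------------------------------------------------------------
# Three-step derivative fit

def _window_with_margin(grid: np.ndarray, lo: float, hi: float) -> tuple[slice, slice]:
    """Grid slice extended by the smoothing margin, plus the interior trim."""
    sl = chrom.window_slice(grid, lo, hi)
    i0 = max(sl.start - _EDGE_MARGIN, 0)
    i1 = min(sl.stop + _EDGE_MARGIN, grid.size)
    return slice(i0, i1), slice(sl.start - i0, sl.stop - i0)


def _windowed_derivative(
    grid: np.ndarray, values: np.ndarray, lo: float, hi: float, order: int
) -> np.ndarray:
    """Savitzky–Golay derivative of ``values`` restricted to [lo, hi] nm."""
    outer, inner = _window_with_margin(grid, lo, hi)
    step = grid_step(grid)
    d = spectral_derivative(values[outer], order, delta=step)
    return d[inner]


class _StepObjective:
    """Sum-of-squares objective of one fitting step (precomputed slices)."""

    def __init__(
        self,
        grid: np.ndarray,
        r_measured: np.ndarray,
        lib: ChromophoreLibrary,
        lo: float,
        hi: float,
        order: int,
        rho: float,
        free: tuple[str, ...],
        fixed: dict[str, float],
    ) -> None:
        outer, inner = _window_with_margin(grid, lo, hi)
        self.lam = grid[outer]
        self.step = grid_step(grid)
        self.inner = inner
        self.order = order
        self.rho = rho
        self.free = free
        self.fixed = dict(fixed)
        self.ew = lib.water[outer]
        self.eh = lib.hb[outer]
        self.eo = lib.hbo2[outer]
        seg = r_measured[outer]
        if not np.all(np.isfinite(seg)):
            raise InvalidInputError(
                f"masked or non-finite reflectance inside fit window [{lo}, {hi}] nm"
            )
        # Savitzky-Golay differentiation is linear: precompute it as a matrix
        # (columns = operator response to unit impulses) so each objective
        # evaluation is a single mat-vec.
        n = self.lam.size
        self._dmat = spectral_derivative(np.eye(n), order, delta=self.step, axis=0)[inner, :]
        self.target = self._dmat @ seg
        self.n_evaluations = 0

    def params(self, x: np.ndarray) -> dict[str, float]:
        p = dict(self.fixed)
        p.update(zip(self.free, x))
        return p

    def model_derivative(self, p: dict[str, float]) -> np.ndarray:
        mu_a = p["WF"] * self.ew + p["Hb_b"] * self.eh + p["HbO2_b"] * self.eo
        mu_s = musp(self.lam, p["A"], p["alpha"])
        r_model = np.log10(reflectance_cw(self.rho, mu_a, mu_s))
        return self._dmat @ r_model

    def __call__(self, x: np.ndarray) -> float:
        self.n_evaluations += 1
        resid = self.model_derivative(self.params(x)) - self.target
        return float(resid @ resid)


def _run_simplex(obj: _StepObjective, x0: np.ndarray, bounds: list, maxiter: int):
    res = minimize(
        obj,
        x0,
        method="Nelder-Mead",
        bounds=bounds,
        options={
            "xatol": 1e-9,
            "fatol": 1e-9,
            "maxiter": maxiter,
            "maxfev": maxiter,
        },
    )
    # Polish the incumbent with bounded trust-region least squares on the
    # residual vector: the simplex contracts prematurely in the shallow
    # derivative-space valley of noisy spectra, while the polish converges
    # tightly on the smooth objective.
    lower = np.array([b[0] for b in bounds])
    upper = np.array([b[1] for b in bounds])

    def resid_vec(x: np.ndarray) -> np.ndarray:
        obj.n_evaluations += 1
        return obj.model_derivative(obj.params(x)) - obj.target

    x_start = np.clip(res.x, lower + 1e-12, upper - 1e-12)
    polish = least_squares(
        resid_vec, x_start, bounds=(lower, upper),
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=maxiter,
    )
    if 2.0 * polish.cost <= res.fun:
        polish.fun = 2.0 * polish.cost  # align scale: NM minimises Σr²
        return polish
    return res


def fit_baseline(
    grid: np.ndarray,
    r_measured: np.ndarray,
    lib: ChromophoreLibrary,
    rho: float = 30.0,
    initials: dict | None = None,
    bounds: dict | None = None,
    windows: dict | None = None,
    maxiter: int = 2000,
    joint_refine: bool = True,
) -> BaselineFitResult:
    """Three-step constrained derivative fit of a baseline reflectance spectrum.

    After the classic three-step sequence, a final simultaneous refinement
    re-fits all five parameters against the concatenated derivative
    residuals of the three windows (bounded least squares started from the
    step estimates).  The refinement is what makes WF identifiable on noisy
    spectra: within the water window alone, a lower WF can be compensated
    almost exactly by a longer optical pathlength (through the scattering
    amplitude), whereas the joint problem pins the scattering parameters
    with the feature-rich first-derivative window and thereby fixes the
    water-band scale.  ``joint_refine=False`` reproduces the plain
    sequential behaviour.

    Returns the fitted :class:`TissueModel`, baseline StO₂, per-step residual
    norms and convergence diagnostics.  Estimates never leave the bounds;
    an estimate pinned at a bound is flagged in ``at_bounds``.
    """
    initials = dict(DEFAULT_INITIALS if initials is None else initials)
    bounds = {k: tuple(v) for k, v in (DEFAULT_BOUNDS if bounds is None else bounds).items()}
    windows = dict(_DEFAULT_WINDOWS if windows is None else windows)
    if grid[0] > 680.0 or grid[-1] < 845.0:
        raise InvalidInputError("reflectance must span at least 680–845 nm")

    current = dict(initials)
    residual_norms = []
    converged = True
    n_eval = 0
    step_objs = []
    for window_key, order, free, retained in _STEPS:
        lo, hi = windows[window_key]
        obj = _StepObjective(
            grid, r_measured, lib, lo, hi, order, rho,
            free=tuple(free), fixed={k: v for k, v in current.items() if k not in free},
        )
        step_objs.append(obj)
        x0 = np.array([current[k] for k in free])
        bnd = [bounds[k] for k in free]
        res = _run_simplex(obj, x0, bnd, maxiter)
        n_eval += obj.n_evaluations
        converged = converged and bool(res.success)
        residual_norms.append(float(np.sqrt(res.fun)))
        solution = dict(zip(free, res.x))
        for k in retained:
            current[k] = float(solution[k])

    if joint_refine:
        lower = np.array([bounds[k][0] for k in PARAM_ORDER])
        upper = np.array([bounds[k][1] for k in PARAM_ORDER])

        def joint_residual(x: np.ndarray) -> np.ndarray:
            p = dict(zip(PARAM_ORDER, x))
            return np.concatenate([o.model_derivative(p) - o.target for o in step_objs])

        x0 = np.clip(
            np.array([current[k] for k in PARAM_ORDER]), lower + 1e-12, upper - 1e-12
        )
        joint = least_squares(
            joint_residual, x0, bounds=(lower, upper),
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=maxiter,
        )
        n_eval += joint.nfev
        if joint.cost * 2.0 <= sum(r**2 for r in residual_norms):
            current = dict(zip(PARAM_ORDER, map(float, joint.x)))
            splits = np.cumsum([o.target.size for o in step_objs])[:-1]
            residual_norms = [
                float(np.linalg.norm(seg)) for seg in np.split(joint.fun, splits)
            ]
            converged = converged and bool(joint.success)

    at_bounds = [
        k for k in PARAM_ORDER
        if np.isclose(current[k], bounds[k][0]) or np.isclose(current[k], bounds[k][1])
    ]
    tissue = TissueModel(**{
        "WF": current["WF"], "Hb_b": current["Hb_b"], "HbO2_b": current["HbO2_b"],
        "A": current["A"], "alpha": current["alpha"],
    })
    sto2 = compute_sto2(tissue.Hb_b, tissue.HbO2_b)
    return BaselineFitResult(
        tissue=tissue,
        sto2=sto2,
        residual_norms=tuple(residual_norms),
        converged=converged,
        at_bounds=at_bounds,
        n_evaluations=n_eval,
    )
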