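"""DCS autocorrelation fitting and calibration to absolute blood flow.

Each measured intensity autocorrelation curve g2(τ) is fitted with the
semi-infinite correlation-diffusion model through the Siegert relation,
yielding the coherence factor β and the blood flow index BFi — identified
with the effective Brownian diffusion coefficient Db (cm²/s).  Fitting uses
the source-detector distance (20 mm) and the µa/µs′ values at 785 nm from
the broadband analysis: time-varying µa with the baseline µs′.

The BFi time series is converted to absolute cerebral blood flow
(ml/100g/min) by a single multiplicative factor anchored to a DCE-NIRS
bolus measurement:  CBF(t) = BFi(t) · CBF_anchor / ⟨BFi⟩_anchor-window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InvalidInputError
from .forward_models import DCSModelParams, g2_model

#: fraction of the zero-lag amplitude defining the fit window cut-off
FIT_WINDOW_FRACTION = 0.01
#: initial values and bounds of the two fitted parameters
BETA_INIT, DB_INIT = 0.5, 1e-8
BETA_BOUNDS = (1e-6, 1.2)
DB_BOUNDS = (1e-11, 1e-5)


@dataclass
class AutocorrelationCurve:
    """One correlator acquisition: lag grid τ (s), g2 values, duration (s)."""

    tau: np.ndarray
    g2: np.ndarray
    duration: float = 5.0
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.g2 = np.asarray(self.g2, dtype=float)
        if self.tau.size == 0 or self.tau.size != self.g2.size:
            raise InvalidInputError("tau and g2 must be equal-length, non-empty")
        if np.any(self.tau <= 0) or np.any(np.diff(self.tau) <= 0):
            raise InvalidInputError("tau must be positive and strictly increasing")
        if not np.all(np.isfinite(self.g2)):
            raise InvalidInputError("g2 contains non-finite values")


@dataclass
class DCSFitResult:
    beta: float
    BFi: float            # cm²/s
    residual_norm: float
    converged: bool
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "BFi_cm2_s": self.BFi,
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "flags": list(self.flags),
        }


@dataclass
class CBFTimeSeries:
    time: np.ndarray
    cbf: np.ndarray                 # ml/100g/min
    calibration_factor: float       # (ml/100g/min) per (cm²/s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "CBF": self.cbf})


def fit_g2(
    curve: AutocorrelationCurve,
    mua_785: float,
    musp_785: float,
    rho: float = 20.0,
) -> DCSFitResult:
    """Nonlinear least-squares fit of one g2 curve for (β, BFi).

    The plateau is tail-anchored to 1 (mean of the last decade of lags) and
    the fit window keeps lags where g2 − 1 exceeds 1% of the zero-lag
    amplitude.  Degenerate curves (no decaying correlation) are returned
    flagged rather than raising.
    """
    if mua_785 <= 0 or musp_785 <= 0:
        raise InvalidInputError("optical properties must be positive")
    tail = curve.g2[curve.tau >= curve.tau[-1] / 10.0]
    g2n = curve.g2 - (np.mean(tail) - 1.0)  # tail-anchored normalisation
    amp0 = g2n[0] - 1.0
    if amp0 < 1e-3:
        return DCSFitResult(
            beta=np.nan, BFi=np.nan, residual_norm=np.nan,
            converged=False, flags=["no-correlation"],
        )
    window = (g2n - 1.0) > FIT_WINDOW_FRACTION * amp0
    window[0] = True
    tau_fit, g2_fit = curve.tau[window], g2n[window]

    def residuals(x: np.ndarray) -> np.ndarray:
        beta, log_db = x
        p = DCSModelParams(
            beta=beta, BFi=10.0 ** log_db, mua_785=mua_785,
            musp_785=musp_785, rho=rho,
        )
        return g2_model(tau_fit, p) - g2_fit

    res = least_squares(
        residuals,
        x0=[BETA_INIT, np.log10(DB_INIT)],
        bounds=([BETA_BOUNDS[0], np.log10(DB_BOUNDS[0])],
                [BETA_BOUNDS[1], np.log10(DB_BOUNDS[1])]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    beta, bfi = float(res.x[0]), float(10.0 ** res.x[1])
    flags = []
    if np.isclose(beta, BETA_BOUNDS[1]) or np.isclose(beta, BETA_BOUNDS[0]):
        flags.append("beta-at-bound")
    if not res.success:
        flags.append("optimizer-not-converged")
    return DCSFitResult(
        beta=beta,
        BFi=bfi,
        residual_norm=float(np.linalg.norm(res.fun)),
        converged=res.success and not flags,
        flags=flags,
    )


def calibrate_bfi(
    times: np.ndarray,
    bfi: np.ndarray,
    cbf_anchor: float,
    anchor_window: tuple[float, float],
) -> CBFTimeSeries:
    """Scale a BFi series to absolute CBF using a bolus-derived anchor.

    The calibration factor is CBF_anchor divided by the mean BFi inside the
    anchor window; applying the calibration to an already-calibrated series
    with its own mean as anchor is the identity (idempotence).
    """
    times = np.asarray(times, dtype=float)
    bfi = np.asarray(bfi, dtype=float)
    t0, t1 = anchor_window
    mask = (times >= t0) & (times <= t1)
    if not mask.any():
        raise InvalidInputError("anchor window contains no samples")
    mean_bfi = float(np.nanmean(bfi[mask]))
    if mean_bfi <= 0:
        raise InvalidInputError("mean BFi in the anchor window must be > 0")
    factor = cbf_anchor / mean_bfi
    return CBFTimeSeries(time=times, cbf=bfi * factor, calibration_factor=factor)
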