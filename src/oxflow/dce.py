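"""Absolute CBF from dye-bolus tracking (DCE-NIRS deconvolution).

The cerebral dye concentration is the arterial input convolved with the
flow-scaled impulse residue function:

    Cb(t) = CBF · R(t) ∗ Ca(t)

The product CBF·R(t) is recovered by deconvolution — truncated SVD of the
lower-triangular Toeplitz convolution matrix built from Ca, with singular
values below 10% of the largest discarded (standard bolus-tracking
regularisation).  Since R(0) = 1 by definition, CBF is read off the initial
value of the recovered residue; to guard against regularisation-induced
smoothing of the leading edge, the initial value is taken as the maximum of
the first three samples.

Concentrations may be in any shared unit (the ratio cancels); internal flow
is per second and is reported in ml/100g/min (× 6000, unit tissue density).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz

from .errors import InvalidInputError

#: TSVD truncation threshold as a fraction of the largest singular value
TSVD_THRESHOLD = 0.10
#: (ml/100g/min) per (ml/g/s) at unit tissue density
FLOW_UNIT = 6000.0


@dataclass
class DCERecord:
    """Paired arterial (Ca) and cerebral (Cb) dye-concentration curves."""

    time: np.ndarray   # s, uniform step
    ca: np.ndarray     # µM
    cb: np.ndarray     # µM

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ca = np.asarray(self.ca, dtype=float)
        self.cb = np.asarray(self.cb, dtype=float)
        if not (self.time.size == self.ca.size == self.cb.size):
            raise InvalidInputError("time, Ca, Cb must have equal length")
        d = np.diff(self.time)
        if d.size == 0 or np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-6):
            raise InvalidInputError("time grid must be uniform and increasing")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class FlowScaledResidue:
    """CBF·R(t) in ml/100g/min; R(0) = 1 so the initial value is CBF."""

    time: np.ndarray
    values: np.ndarray           # ml/100g/min
    truncation_rank: int = 0
    flags: list = field(default_factory=list)


def deconvolve(record: DCERecord, threshold: float = TSVD_THRESHOLD) -> FlowScaledResidue:
    """Recover CBF·R(t) from a DCE record by truncated-SVD deconvolution."""
    if not np.any(record.ca > 0):
        raise InvalidInputError("arterial curve Ca is identically zero")
    dt = record.dt
    # discrete convolution: Cb = (A Δt) · (CBF·R), A lower-triangular Toeplitz in Ca
    A = toeplitz(record.ca, np.zeros_like(record.ca)) * dt
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    keep = s >= threshold * s[0]
    rank = int(np.sum(keep))
    flags = []
    if rank == 0:
        flags.append("ill-conditioned")
        rank = 1
        keep = np.arange(s.size) == 0
    inv_s = np.where(keep, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    residue_per_s = Vt.T @ (inv_s * (U.T @ record.cb))
    values = residue_per_s * FLOW_UNIT
    if values[0] < 0:
        flags.append("negative-initial-value")
    return FlowScaledResidue(
        time=record.time - record.time[0],
        values=values,
        truncation_rank=rank,
        flags=flags,
    )


def extract_cbf(residue: FlowScaledResidue) -> float:
    """CBF (ml/100g/min) as the initial value of the flow-scaled residue.

    Uses the maximum of the first three samples; regularisation smooths the
    leading edge, so the strict t=0 sample can undershoot.
    """
    if residue.values.size == 0:
        raise InvalidInputError("empty residue")
    head = residue.values[:3]
    cbf = float(np.max(head))
    if cbf < 0:
        residue.flags.append("negative-cbf")
    return cbf


def quantify_cbf(record: DCERecord) -> float:
    """Convenience: deconvolve a DCE record and extract CBF."""
    return extract_cbf(deconvolve(record))
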