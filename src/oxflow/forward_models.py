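"""Diffusion-approximation forward models on a semi-infinite homogeneous medium.

Two closed forms, used both as fitting kernels and as synthetic-data oracles:

* continuous-wave diffuse reflectance ``R(ρ; µa, µs′)`` with an extrapolated
  boundary and refractive-index mismatch (tissue n = 1.4 against air), and
* the normalised intensity autocorrelation ``g2(τ)`` of the
  correlation-diffusion equation under Brownian scatterer dynamics
  (mean-square displacement ⟨Δr²⟩ = 6·Db·τ), via the Siegert relation
  ``g2 = 1 + β·|g1|²``.

The tissue is parameterised by {WF, Hb_b, HbO2_b, A, α}: water volume
fraction, baseline deoxy-/oxy-hemoglobin concentrations (µM), µs′ at 800 nm
(mm⁻¹), and the scattering power of the µs′ power law.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .chromophores import ChromophoreLibrary
from .errors import InvalidInputError

#: Tissue refractive index (config knob; the standard soft-tissue value).
N_TISSUE = 1.4
#: Exterior (air) refractive index.
N_EXTERIOR = 1.0
#: DCS laser wavelength, nm.
DCS_WAVELENGTH_NM = 785.0
#: µs′ power-law reference wavelength, nm.
MUSP_REFERENCE_NM = 800.0


def _boundary_coefficient(n_tissue: float = N_TISSUE, n_out: float = N_EXTERIOR) -> float:
    """Internal-reflection boundary coefficient A = (1+Reff)/(1−Reff).

    Reff from the Groenhuis/Haskell polynomial fit in the relative index
    n = n_tissue/n_out; ≈ 3.25 for n = 1.4.
    """
    n = n_tissue / n_out
    r_eff = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_eff) / (1.0 - r_eff)


@dataclass(frozen=True)
class TissueModel:
    """Baseline tissue parameters {WF, Hb_b, HbO2_b, A, alpha}."""

    WF: float        # water volume fraction, unitless
    Hb_b: float      # deoxy-hemoglobin, µM
    HbO2_b: float    # oxy-hemoglobin, µM
    A: float         # µs′ at 800 nm, mm⁻¹
    alpha: float     # scattering power, unitless

    def as_array(self) -> np.ndarray:
        return np.array([self.WF, self.Hb_b, self.HbO2_b, self.A, self.alpha])

    @classmethod
    def from_array(cls, x: np.ndarray) -> "TissueModel":
        return cls(*map(float, x))

    def to_json(self) -> str:
        return json.dumps(asdict(self))


@dataclass(frozen=True)
class DCSModelParams:
    """Parameters of the DCS g2 forward model."""

    beta: float            # coherence factor, (0, 1]
    BFi: float             # effective Brownian diffusion coefficient Db, cm²/s
    mua_785: float         # mm⁻¹
    musp_785: float        # mm⁻¹
    rho: float = 20.0      # source-detector distance, mm
    lambda0: float = DCS_WAVELENGTH_NM
    n_tissue: float = N_TISSUE

    def __post_init__(self) -> None:
        if not (0.0 < self.beta <= 1.2):
            raise InvalidInputError(f"beta {self.beta} outside (0, 1.2]")
        if self.BFi <= 0 or self.rho <= 0:
            raise InvalidInputError("BFi and rho must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self))


# ---------------------------------------------------------------------------
# Optical coefficients

def musp(lam, A: float, alpha: float):
    """Reduced scattering power law: µs′(λ) = A·(λ/800)^(−α), mm⁻¹."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0):
        raise InvalidInputError("wavelength must be positive")
    out = A * (lam / MUSP_REFERENCE_NM) ** (-alpha)
    return out if out.ndim else float(out)


def mua(lam, tissue: TissueModel, lib: ChromophoreLibrary):
    """Baseline absorption µa(λ) = WF·µa_w + Hb_b·ε_Hb + HbO2_b·ε_HbO2, mm⁻¹.

    CCO is excluded from the baseline model (its concentration is too small
    to contribute resolvable derivative features).
    """
    lam = np.asarray(lam, dtype=float)
    from .chromophores import resample  # local import to avoid cycle noise

    eh = resample(lib.grid, lib.hb, np.atleast_1d(lam))
    eo = resample(lib.grid, lib.hbo2, np.atleast_1d(lam))
    ew = resample(lib.grid, lib.water, np.atleast_1d(lam))
    out = tissue.WF * ew + tissue.Hb_b * eh + tissue.HbO2_b * eo
    return out if lam.ndim else float(out[0])


def mua_from_arrays(
    wf: float, hb: float, hbo2: float, lib: ChromophoreLibrary
) -> np.ndarray:
    """µa on the library's own grid (fast path used inside fitting loops)."""
    return wf * lib.water + hb * lib.hb + hbo2 * lib.hbo2


# ---------------------------------------------------------------------------
# CW reflectance

def reflectance_cw(rho, mua_val, musp_val, n_tissue: float = N_TISSUE):
    """Extrapolated-boundary semi-infinite CW reflectance, mm⁻².

    Isotropic source at depth z0 = 1/(µa+µs′); image source mirrored about
    the extrapolated boundary z = −2·zb with zb = 2A/(3(µa+µs′)); reflectance
    as the sum of the two dipole flux terms.  Strictly positive and strictly
    decreasing in µa.
    """
    mua_val = np.asarray(mua_val, dtype=float)
    musp_val = np.asarray(musp_val, dtype=float)
    if np.any(musp_val <= 0):
        raise InvalidInputError("musp must be > 0")
    if np.any(mua_val < 0):
        raise InvalidInputError("mua must be ≥ 0")
    if np.any(np.asarray(rho) <= 0):
        raise InvalidInputError("rho must be > 0")

    mut = mua_val + musp_val
    z0 = 1.0 / mut
    zb = 2.0 * _boundary_coefficient(n_tissue) / (3.0 * mut)
    mueff = np.sqrt(3.0 * mua_val * mut)
    r1 = np.sqrt(rho**2 + z0**2)
    r2 = np.sqrt(rho**2 + (z0 + 2.0 * zb) ** 2)
    term1 = z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1**2
    term2 = (z0 + 2.0 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2**2
    out = (term1 + term2) / (4.0 * np.pi)
    return out if out.ndim else float(out)


def reflectance_spectrum(
    rho: float,
    tissue: TissueModel,
    lib: ChromophoreLibrary,
    extra_mua: np.ndarray | float = 0.0,
) -> np.ndarray:
    """CW reflectance across the library grid for one tissue model.

    ``extra_mua`` adds a time-varying absorption term (e.g. the oxCCO
    contribution or hemoglobin changes) on top of the baseline µa.
    """
    mu_a = mua_from_arrays(tissue.WF, tissue.Hb_b, tissue.HbO2_b, lib) + extra_mua
    mu_s = musp(lib.grid, tissue.A, tissue.alpha)
    return reflectance_cw(rho, np.maximum(mu_a, 0.0), mu_s)


# ---------------------------------------------------------------------------
# DCS field autocorrelation

def g1_model(tau: np.ndarray, p: DCSModelParams) -> np.ndarray:
    """Normalised field autocorrelation g1(τ) for Brownian dynamics.

    Semi-infinite correlation-diffusion solution: the CW dipole form with
    µa replaced by µa + 2·µs′·k0²·Db·τ, normalised so g1(0) = 1.
    """
    tau = np.asarray(tau, dtype=float)
    if tau.size == 0:
        raise InvalidInputError("empty tau grid")
    if np.any(tau < 0):
        raise InvalidInputError("tau must be ≥ 0")

    k0 = 2.0 * np.pi * p.n_tissue / (p.lambda0 * 1e-6)  # mm⁻¹
    db_mm2 = p.BFi * 100.0  # cm²/s → mm²/s
    mut = p.mua_785 + p.musp_785
    z0 = 1.0 / mut
    zb = 2.0 * _boundary_coefficient(p.n_tissue) / (3.0 * mut)
    r1 = np.sqrt(p.rho**2 + z0**2)
    r2 = np.sqrt(p.rho**2 + (z0 + 2.0 * zb) ** 2)

    def _phi(kd: np.ndarray) -> np.ndarray:
        return np.exp(-kd * r1) / r1 - np.exp(-kd * r2) / r2

    kd_tau = np.sqrt(3.0 * mut * (p.mua_785 + 2.0 * p.musp_785 * k0**2 * db_mm2 * tau))
    kd_0 = np.sqrt(3.0 * mut * p.mua_785)
    return _phi(kd_tau) / _phi(kd_0)


def g2_model(tau: np.ndarray, p: DCSModelParams) -> np.ndarray:
    """Siegert relation: g2(τ) = 1 + β·|g1(τ)|²; g2(0) = 1 + β."""
    g1 = g1_model(tau, p)
    return 1.0 + p.beta * g1**2
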