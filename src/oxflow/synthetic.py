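"""Seeded synthetic hypoxia-ischemia (HI) experiments.

Emulates the piglet HI protocol and the instrument's multiplexed
acquisition: carotid occlusion (region i) causes an immediate CBF and StO₂
drop; subsequent hypoxia (region ii) brings both to a nadir held for at
least ten minutes; the oxCCO oxidation state responds with a *delayed*
first-order decline that continues after CBF reaches its nadir; recovery
restores baseline.  Control runs are flat.

Three measurement streams are rendered from the ground-truth trajectories
with the same forward models the fitting stages invert:

* broadband spectra — semi-infinite diffusion reflectance times a halogen
  source shape, converted to counts with Poisson noise at each wavelength,
  on the 14-s cycle (12 spectra over 3 s);
* DCS autocorrelation curves — Brownian correlation-diffusion g2 with a
  simplified lag-dependent correlator noise that shrinks as 1/√T with
  integration time (2 curves per cycle over 10 s);
* a DCE bolus record — gamma-variate arterial input convolved with an
  exponential residue function, sampled at 400 ms.

All randomness flows through one seeded generator; the seed is recorded in
the experiment metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bnirs_baseline import RawSpectrumSet
from .chromophores import ChromophoreLibrary
from .dce import DCERecord, FLOW_UNIT
from .dcs import AutocorrelationCurve
from .errors import InvalidInputError
from .forward_models import (
    DCSModelParams,
    TissueModel,
    g1_model,
    g2_model,
    musp,
    reflectance_spectrum,
)

#: canonical baseline tissue (the Monte Carlo truth; StO₂ = 75.5%)
DEFAULT_TISSUE = TissueModel(WF=0.8, Hb_b=13.0, HbO2_b=40.0, A=0.8, alpha=2.6)
#: typical piglet baseline CBF, ml/100g/min
DEFAULT_BASELINE_CBF = 28.0
#: baseline blood flow index, cm²/s (phantom-scale Brownian diffusion coeff.)
DEFAULT_BASELINE_BFI = 1.5e-8


# ---------------------------------------------------------------------------
# Protocol and schedule

@dataclass
class HIProtocol:
    """Timing and magnitude of the simulated hypoxia-ischemia insult."""

    baseline_s: float = 300.0        # 5 min pre-clamp baseline
    occlusion_s: float = 120.0       # region (i): clamp only
    hypoxia_s: float = 900.0         # region (ii): clamp + 8% O2, ≥600 s at nadir
    recovery_s: float = 600.0
    nadir_cbf_fraction: float = 0.10
    occlusion_cbf_fraction: float = 0.45   # >40% immediate drop on clamping
    sto2_occlusion: float = 0.60
    sto2_nadir: float = 0.25
    cco_delay_s: float = 60.0        # delay of the oxCCO response
    cco_tau_s: float = 150.0         # first-order time constant
    cco_drop_uM: float = 5.0         # asymptotic ΔoxCCO at full flow deficit
    transition_s: float = 15.0       # sigmoid width of the CBF/StO2 steps
    insult: bool = True

    def __post_init__(self) -> None:
        for name in ("baseline_s", "occlusion_s", "hypoxia_s", "recovery_s",
                     "cco_tau_s", "transition_s"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        if not (0.0 < self.nadir_cbf_fraction < 1.0):
            raise InvalidInputError("nadir_cbf_fraction must be in (0, 1)")

    @classmethod
    def control(cls, **kw) -> "HIProtocol":
        return cls(insult=False, **kw)

    @property
    def duration_s(self) -> float:
        return self.baseline_s + self.occlusion_s + self.hypoxia_s + self.recovery_s


@dataclass
class AcquisitionSchedule:
    """The 14-s multiplex cycle: 12 spectra / 3 s, 2 DCS curves / 10 s,
    with a 0.5-s shutter guard before and after the spectra block."""

    cycle_s: float = 14.0
    n_spectra: int = 12
    spectra_window_s: float = 3.0
    n_dcs: int = 2
    dcs_window_s: float = 10.0
    guard_s: float = 0.5

    def __post_init__(self) -> None:
        total = self.spectra_window_s + self.dcs_window_s + 2.0 * self.guard_s
        if not np.isclose(total, self.cycle_s):
            raise InvalidInputError(
                f"schedule does not close: {self.spectra_window_s} + "
                f"{self.dcs_window_s} + 2×{self.guard_s} ≠ {self.cycle_s}"
            )

    def n_cycles(self, duration_s: float) -> int:
        return int(duration_s // self.cycle_s)

    def spectra_times(self, cycle: int) -> np.ndarray:
        start = cycle * self.cycle_s + self.guard_s
        dt = self.spectra_window_s / self.n_spectra
        return start + (np.arange(self.n_spectra) + 0.5) * dt

    def dcs_times(self, cycle: int) -> np.ndarray:
        start = cycle * self.cycle_s + 2.0 * self.guard_s + self.spectra_window_s
        dt = self.dcs_window_s / self.n_dcs
        return start + (np.arange(self.n_dcs) + 0.5) * dt

    @property
    def dcs_integration_s(self) -> float:
        return self.dcs_window_s / self.n_dcs


# ---------------------------------------------------------------------------
# Ground-truth trajectories

def _sigmoid(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - t0) / width))


def simulate_timecourse(
    protocol: HIProtocol,
    tissue: TissueModel = DEFAULT_TISSUE,
    baseline_cbf: float = DEFAULT_BASELINE_CBF,
    dt: float = 1.0,
) -> pd.DataFrame:
    """Ground-truth {CBF, StO2, dCCO, Hb, HbO2} trajectories on a ``dt`` grid.

    Deterministic (the noise lives in the renderers).  CBF and StO₂
    step-respond at the occlusion and hypoxia onsets; ΔoxCCO integrates a
    delayed first-order response to the flow deficit, so its half-decline
    lags CBF's and it keeps falling after the CBF nadir.
    """
    t = np.arange(0.0, protocol.duration_s + dt / 2, dt)
    sto2_b = tissue.HbO2_b / (tissue.Hb_b + tissue.HbO2_b)
    if not protocol.insult:
        f = np.ones_like(t)
        sto2 = np.full_like(t, sto2_b)
        dcco = np.zeros_like(t)
    else:
        t_occl = protocol.baseline_s
        t_hyp = t_occl + protocol.occlusion_s
        t_rec = t_hyp + protocol.hypoxia_s
        w = protocol.transition_s
        f = (
            1.0
            - (1.0 - protocol.occlusion_cbf_fraction) * _sigmoid(t, t_occl, w)
            - (protocol.occlusion_cbf_fraction - protocol.nadir_cbf_fraction)
            * _sigmoid(t, t_hyp, w)
            + (1.0 - protocol.nadir_cbf_fraction) * _sigmoid(t, t_rec, 2 * w)
        )
        f = np.clip(f, protocol.nadir_cbf_fraction, 1.0)
        sto2 = (
            sto2_b
            - (sto2_b - protocol.sto2_occlusion) * _sigmoid(t, t_occl, w)
            - (protocol.sto2_occlusion - protocol.sto2_nadir) * _sigmoid(t, t_hyp, w)
            + (sto2_b - protocol.sto2_nadir) * _sigmoid(t, t_rec, 2 * w)
        )
        sto2 = np.clip(sto2, protocol.sto2_nadir, sto2_b)
        # delayed first-order oxCCO response to the flow deficit
        deficit = np.clip(
            (1.0 - f) / (1.0 - protocol.nadir_cbf_fraction), 0.0, 1.0
        )
        shift = int(round(protocol.cco_delay_s / dt))
        target = -protocol.cco_drop_uM * np.concatenate(
            [np.zeros(shift), deficit[: t.size - shift]]
        )
        dcco = np.empty_like(t)
        dcco[0] = 0.0
        k = dt / protocol.cco_tau_s
        for i in range(1, t.size):
            dcco[i] = dcco[i - 1] + k * (target[i] - dcco[i - 1])

    total_hb = tissue.Hb_b + tissue.HbO2_b
    hbo2 = sto2 * total_hb
    hb = total_hb - hbo2
    return pd.DataFrame({
        "time": t,
        "CBF": baseline_cbf * f,
        "StO2": sto2,
        "dCCO": dcco,
        "Hb": hb,
        "HbO2": hbo2,
    })


# ---------------------------------------------------------------------------
# Broadband spectra renderer

def _halogen_shape(grid: np.ndarray, temp_k: float = 3000.0) -> np.ndarray:
    """Normalised blackbody source shape over the instrument grid."""
    x = 1.4388e7 / (grid * temp_k)  # hc/(λ k T) with λ in nm
    b = grid**-5 / np.expm1(x)
    return b / b.max()


@dataclass
class SpectraSequence:
    """Rendered raw-count frames: (n_cycles × n_spectra × n_λ) + channels."""

    grid: np.ndarray
    times: np.ndarray                    # cycle-centre timestamps, s
    frames: np.ndarray                   # counts
    dark: np.ndarray
    reference: np.ndarray
    frame_times: np.ndarray              # (n_cycles × n_spectra)
    integration_time: float

    def cycle_raw(self, i: int) -> RawSpectrumSet:
        return RawSpectrumSet(
            grid=self.grid,
            measured=self.frames[i],
            dark=self.dark,
            reference=self.reference,
            integration_time=self.integration_time,
        )

    def reflectance(self) -> np.ndarray:
        """Per-cycle R(λ) from the 12-frame average (n_cycles × n_λ)."""
        from .bnirs_baseline import compute_reflectance

        return np.vstack([
            compute_reflectance(self.cycle_raw(i)) for i in range(len(self.times))
        ])


def noisy_raw_spectra(
    tissue: TissueModel,
    lib: ChromophoreLibrary,
    rng: np.random.Generator,
    rho: float = 30.0,
    photon_scale: float = 3.5e3,
    n_frames: int = 1,
    extra_mua: np.ndarray | float = 0.0,
    noise: bool = True,
) -> RawSpectrumSet:
    """One raw acquisition (``n_frames`` Poisson-noised frames) plus exact
    dark and reference channels; the Monte Carlo error study's generator."""
    refl = reflectance_spectrum(rho, tissue, lib, extra_mua=extra_mua)
    source = _halogen_shape(lib.grid)
    reference = photon_scale * source + 200.0
    gain = photon_scale / (source * refl).max()
    mean_counts = gain * source * refl + 200.0
    if noise:
        measured = rng.poisson(np.broadcast_to(mean_counts, (n_frames, lib.grid.size))
                               ).astype(float)
    else:
        measured = np.broadcast_to(mean_counts, (n_frames, lib.grid.size)).copy()
    return RawSpectrumSet(
        grid=lib.grid,
        measured=measured,
        dark=np.full(lib.grid.size, 200.0),
        reference=reference,
    )


def render_spectra(
    truth: pd.DataFrame,
    tissue: TissueModel,
    schedule: AcquisitionSchedule,
    lib: ChromophoreLibrary,
    rng: np.random.Generator,
    rho: float = 30.0,
    photon_scale: float = 3.5e3,
    noise: bool = True,
) -> SpectraSequence:
    """Render the broadband stream over the whole protocol.

    Each frame's µa(λ) uses the instantaneous Hb/HbO₂ concentrations and
    the oxCCO contribution through the signed difference spectrum.
    """
    n_cycles = schedule.n_cycles(float(truth["time"].iloc[-1]))
    source = _halogen_shape(lib.grid)
    reference = photon_scale * source + 200.0
    refl_base = reflectance_spectrum(rho, tissue, lib)
    gain = photon_scale / (source * refl_base).max()
    mu_s = musp(lib.grid, tissue.A, tissue.alpha)

    t_truth = truth["time"].to_numpy()
    interp = {k: truth[k].to_numpy() for k in ("Hb", "HbO2", "dCCO")}

    frames = np.empty((n_cycles, schedule.n_spectra, lib.grid.size))
    frame_times = np.empty((n_cycles, schedule.n_spectra))
    from .forward_models import reflectance_cw

    for c in range(n_cycles):
        ts = schedule.spectra_times(c)
        frame_times[c] = ts
        hb = np.interp(ts, t_truth, interp["Hb"])
        hbo2 = np.interp(ts, t_truth, interp["HbO2"])
        dcco = np.interp(ts, t_truth, interp["dCCO"])
        for j in range(schedule.n_spectra):
            mu_a = (
                tissue.WF * lib.water
                + hb[j] * lib.hb
                + hbo2[j] * lib.hbo2
                + dcco[j] * lib.cco_diff
            )
            refl = reflectance_cw(rho, np.maximum(mu_a, 0.0), mu_s)
            mean_counts = gain * source * refl + 200.0
            frames[c, j] = rng.poisson(mean_counts) if noise else mean_counts
    return SpectraSequence(
        grid=lib.grid,
        times=frame_times.mean(axis=1),
        frames=frames,
        dark=np.full(lib.grid.size, 200.0),
        reference=reference,
        frame_times=frame_times,
        integration_time=schedule.spectra_window_s / schedule.n_spectra,
    )


# ---------------------------------------------------------------------------
# DCS renderer

def default_tau_grid(n_per_decade: int = 18) -> np.ndarray:
    """Multi-tau-style log-spaced correlator lag grid, 1e-7–1 s."""
    return np.geomspace(1e-7, 1.0, 7 * n_per_decade + 1)


def render_dcs(
    truth: pd.DataFrame,
    base_params: DCSModelParams,
    schedule: AcquisitionSchedule,
    rng: np.random.Generator,
    noise_scale: float = 0.07,
    tau: np.ndarray | None = None,
    noise: bool = True,
) -> list[AutocorrelationCurve]:
    """Render two autocorrelation curves per cycle; Db(t) ∝ CBF(t).

    Correlator noise is a simplified lag-dependent Gaussian model,
    σ(τ) = noise_scale·(0.05 + |g1(τ)|)/√T: largest where the correlation
    is strong, shrinking with integration time T as 1/√T.
    """
    if tau is None:
        tau = default_tau_grid()
    t_truth = truth["time"].to_numpy()
    cbf = truth["CBF"].to_numpy()
    cbf_base = cbf[t_truth <= t_truth[0] + 1.0].mean()
    n_cycles = schedule.n_cycles(float(t_truth[-1]))
    T = schedule.dcs_integration_s
    curves = []
    for c in range(n_cycles):
        for ts in schedule.dcs_times(c):
            frac = float(np.interp(ts, t_truth, cbf)) / cbf_base
            p = DCSModelParams(
                beta=base_params.beta,
                BFi=base_params.BFi * frac,
                mua_785=base_params.mua_785,
                musp_785=base_params.musp_785,
                rho=base_params.rho,
            )
            g2 = g2_model(tau, p)
            if noise:
                sigma = noise_scale * (0.05 + np.abs(g1_model(tau, p))) / np.sqrt(T)
                g2 = g2 + rng.normal(0.0, sigma)
            curves.append(AutocorrelationCurve(tau=tau, g2=g2, duration=T, timestamp=ts))
    return curves


# ---------------------------------------------------------------------------
# DCE renderer

def render_dce(
    true_cbf: float,
    rng: np.random.Generator,
    duration_s: float = 90.0,
    dt: float = 0.4,
    bolus_onset_s: float = 10.0,
    bolus_shape: float = 2.0,
    bolus_scale_s: float = 0.8,
    arterial_area_uM_s: float = 40.0,
    mtt_s: float = 6.0,
    noise_frac: float = 0.01,
    noise: bool = True,
) -> tuple[DCERecord, dict]:
    """Gamma-variate bolus record sampled at 400 ms.

    Ca is a gamma-variate normalised to a fixed area (dose bookkeeping);
    Cb = CBF·R ∗ Ca with an exponential residue R(t) = exp(−t/MTT).
    Returns the record and the generator's ground truth.
    """
    if true_cbf <= 0:
        raise InvalidInputError("true CBF must be > 0")
    t = np.arange(0.0, duration_s, dt)
    tau = np.maximum(t - bolus_onset_s, 0.0)
    ca = tau**bolus_shape * np.exp(-tau / bolus_scale_s)
    ca *= arterial_area_uM_s / np.trapezoid(ca, t)
    residue = np.exp(-t / mtt_s)
    cbf_per_s = true_cbf / FLOW_UNIT
    cb = dt * np.convolve(cbf_per_s * residue, ca)[: t.size]
    if noise:
        cb = cb + rng.normal(0.0, noise_frac * cb.max(), cb.size)
        cb = np.maximum(cb, 0.0)
    truth = {"CBF": true_cbf, "mtt_s": mtt_s, "residue": residue}
    return DCERecord(time=t, ca=ca, cb=cb), truth


# ---------------------------------------------------------------------------
# Full experiment

@dataclass
class SyntheticExperiment:
    truth: pd.DataFrame
    spectra: SpectraSequence
    dcs_curves: list
    dce_record: DCERecord
    tissue: TissueModel
    dcs_params: DCSModelParams
    protocol: HIProtocol
    schedule: AcquisitionSchedule
    metadata: dict = field(default_factory=dict)


def simulate_experiment(
    protocol: HIProtocol | None = None,
    schedule: AcquisitionSchedule | None = None,
    lib: ChromophoreLibrary | None = None,
    tissue: TissueModel = DEFAULT_TISSUE,
    baseline_cbf: float = DEFAULT_BASELINE_CBF,
    baseline_bfi: float = DEFAULT_BASELINE_BFI,
    beta: float = 0.5,
    photon_scale: float = 3.5e3,
    dcs_noise_scale: float = 0.07,
    seed: int = 0,
    noise: bool = True,
) -> SyntheticExperiment:
    """Generate one complete seeded experiment (all three data streams)."""
    protocol = protocol or HIProtocol()
    schedule = schedule or AcquisitionSchedule()
    lib = lib or ChromophoreLibrary.default()
    rng = np.random.default_rng(seed)

    truth = simulate_timecourse(protocol, tissue=tissue, baseline_cbf=baseline_cbf)
    from .forward_models import mua_from_arrays

    i785 = int(np.argmin(np.abs(lib.grid - 785.0)))
    mua785 = float(mua_from_arrays(tissue.WF, tissue.Hb_b, tissue.HbO2_b, lib)[i785])
    musp785 = float(musp(785.0, tissue.A, tissue.alpha))
    dcs_params = DCSModelParams(
        beta=beta, BFi=baseline_bfi, mua_785=mua785, musp_785=musp785, rho=20.0
    )
    spectra = render_spectra(
        truth, tissue, schedule, lib, rng, photon_scale=photon_scale, noise=noise
    )
    dcs_curves = render_dcs(
        truth, dcs_params, schedule, rng, noise_scale=dcs_noise_scale, noise=noise
    )
    # the bolus calibration is performed after recovery, when CBF is back at
    # baseline
    dce_record, dce_truth = render_dce(baseline_cbf, rng, noise=noise)
    return SyntheticExperiment(
        truth=truth,
        spectra=spectra,
        dcs_curves=dcs_curves,
        dce_record=dce_record,
        tissue=tissue,
        dcs_params=dcs_params,
        protocol=protocol,
        schedule=schedule,
        metadata={"seed": seed, "noise": noise, "dce_truth_cbf": dce_truth["CBF"]},
    )
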