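"""Synthetic hypoxia-ischemia experiment generator."""

import numpy as np
import pytest

from oxflow.bnirs_baseline import compute_reflectance
from oxflow.errors import InvalidInputError
from oxflow.forward_models import DCSModelParams
from oxflow.synthetic import (
    AcquisitionSchedule,
    HIProtocol,
    noisy_raw_spectra,
    render_dce,
    render_dcs,
    render_spectra,
    simulate_timecourse,
    simulate_experiment,
)

SHORT = HIProtocol(baseline_s=60, occlusion_s=60, hypoxia_s=180, recovery_s=60,
                   cco_delay_s=30, cco_tau_s=60)


class TestSchedule:
    def test_cycle_closes_at_14_seconds(self):
        s = AcquisitionSchedule()
        assert s.spectra_window_s + s.dcs_window_s + 2 * s.guard_s == pytest.approx(14.0)
        assert s.cycle_s == 14.0

    def test_inconsistent_schedule_rejected(self):
        with pytest.raises(InvalidInputError):
            AcquisitionSchedule(cycle_s=14.0, spectra_window_s=4.0)

    def test_timestamps_fall_inside_their_windows(self):
        s = AcquisitionSchedule()
        for cycle in (0, 3):
            start = cycle * s.cycle_s
            ts = s.spectra_times(cycle)
            assert np.all(ts >= start + s.guard_s)
            assert np.all(ts <= start + s.guard_s + s.spectra_window_s)
            td = s.dcs_times(cycle)
            assert np.all(td >= start + 2 * s.guard_s + s.spectra_window_s)
            assert np.all(td <= start + s.cycle_s)


class TestTimecourse:
    def test_control_protocol_is_flat(self):
        truth = simulate_timecourse(HIProtocol.control())
        for col in ("CBF", "StO2", "dCCO", "Hb", "HbO2"):
            assert truth[col].std() == pytest.approx(0.0, abs=1e-12)
        assert truth["dCCO"].iloc[0] == 0.0

    def test_cco_half_decline_lags_cbf(self):
        """The metabolic (oxCCO) response is delayed relative to flow."""
        truth = simulate_timecourse(SHORT)
        t = truth["time"].to_numpy()
        insult = t < SHORT.baseline_s + SHORT.occlusion_s + SHORT.hypoxia_s
        cbf = truth["CBF"].to_numpy()
        cco = truth["dCCO"].to_numpy()

        def half_time(y, final):
            half = 0.5 * (y[0] + final)
            idx = np.flatnonzero((y <= half) & insult)
            return t[idx[0]]

        t_cbf = half_time(cbf, cbf[insult].min())
        t_cco = half_time(cco, cco[insult].min())
        assert t_cco > t_cbf

    def test_cco_keeps_declining_after_cbf_nadir(self):
        truth = simulate_timecourse(SHORT)
        t = truth["time"].to_numpy()
        cbf = truth["CBF"].to_numpy()
        nadir_val = cbf.min()
        t_nadir = t[np.flatnonzero(cbf <= nadir_val * 1.01)[0]]
        window = (t >= t_nadir) & (t <= t_nadir + 60.0)
        cco = truth["dCCO"].to_numpy()[window]
        assert cco[-1] < cco[0]  # still falling after the flow nadir

    def test_nadir_matches_target_fraction(self):
        # default protocol holds the nadir ≥ 600 s, long after transients
        proto = HIProtocol()
        truth = simulate_timecourse(proto)
        assert truth["CBF"].min() == pytest.approx(
            proto.nadir_cbf_fraction * 28.0, rel=0.02
        )

    def test_invalid_nadir_fraction_rejected(self):
        with pytest.raises(InvalidInputError):
            HIProtocol(nadir_cbf_fraction=1.5)


class TestRenderSpectra:
    def test_noiseless_limit_reproduces_forward_model(self, lib, truth_tissue, rng):
        from oxflow.forward_models import reflectance_spectrum

        raw = noisy_raw_spectra(truth_tissue, lib, rng, noise=False)
        r = compute_reflectance(raw)
        refl = reflectance_spectrum(30.0, truth_tissue, lib)
        # R equals log10(reflectance) up to the constant instrument gain.
        # Below ~650 nm the strong green hemoglobin bands push the simulated
        # counts to the float rounding floor of the dark offset, so compare
        # over the analysis range.
        sel = lib.grid >= 650.0
        diff = (r - np.log10(refl))[sel]
        np.testing.assert_allclose(diff, diff[0], atol=1e-8)

    def test_averaging_reduces_noise_as_sqrt_n(self, lib, truth_tissue):
        """Per-wavelength scatter of the frame average shrinks ~1/√N."""
        rng = np.random.default_rng(7)
        stds = {}
        for n in (1, 16):
            reps = [
                compute_reflectance(
                    noisy_raw_spectra(truth_tissue, lib, rng, n_frames=n)
                )
                for _ in range(30)
            ]
            i = np.argmin(np.abs(lib.grid - 800.0))
            stds[n] = np.std([r[i] for r in reps], ddof=1)
        ratio = stds[1] / stds[16]
        assert 2.5 < ratio < 6.5  # ideal √16 = 4

    def test_sequence_shapes_follow_schedule(self, lib, truth_tissue, rng):
        truth = simulate_timecourse(SHORT)
        sched = AcquisitionSchedule()
        seq = render_spectra(truth, truth_tissue, sched, lib, rng)
        n_cycles = sched.n_cycles(truth["time"].iloc[-1])
        assert seq.frames.shape == (n_cycles, sched.n_spectra, lib.grid.size)
        assert seq.frame_times.shape == (n_cycles, sched.n_spectra)


class TestRenderDCS:
    def _params(self):
        return DCSModelParams(beta=0.5, BFi=1.5e-8, mua_785=0.006, musp_785=0.84)

    def test_noise_off_round_trips_db(self, rng):
        from oxflow.dcs import fit_g2

        truth = simulate_timecourse(HIProtocol.control())
        curves = render_dcs(truth, self._params(), AcquisitionSchedule(), rng,
                            noise=False)
        # constant flow: the fitted Db equals the configured baseline BFi
        res = fit_g2(curves[0], 0.006, 0.84)
        assert res.BFi == pytest.approx(1.5e-8, rel=1e-3)

    def test_two_curves_per_cycle(self, rng):
        truth = simulate_timecourse(SHORT)
        sched = AcquisitionSchedule()
        curves = render_dcs(truth, self._params(), sched, rng)
        assert len(curves) == 2 * sched.n_cycles(truth["time"].iloc[-1])

    def test_noise_magnitude_decreases_with_integration_time(self):
        truth = simulate_timecourse(HIProtocol.control(baseline_s=60, occlusion_s=1,
                                                       hypoxia_s=1, recovery_s=1))
        resid = {}
        from oxflow.forward_models import g2_model

        for dcs_window, n in ((10.0, 2), (10.0, 10)):
            sched = AcquisitionSchedule(dcs_window_s=dcs_window, n_dcs=n)
            rng = np.random.default_rng(3)
            curves = render_dcs(truth, self._params(), sched, rng)
            model = g2_model(curves[0].tau, self._params())
            resid[n] = np.mean([np.std(c.g2 - model) for c in curves])
        # n=10 → 1-s integration; n=2 → 5-s integration: noisier
        assert resid[10] > resid[2]


class TestRenderDCE:
    def test_arterial_area_bookkeeping(self, rng):
        rec, _ = render_dce(28.0, rng, noise=False)
        assert np.trapezoid(rec.ca, rec.time) == pytest.approx(40.0, rel=1e-6)

    def test_sampling_interval_is_400_ms(self, rng):
        rec, _ = render_dce(28.0, rng)
        assert rec.dt == pytest.approx(0.4)

    def test_seeding_contract(self):
        a, ta = render_dce(28.0, np.random.default_rng(1))
        b, tb = render_dce(28.0, np.random.default_rng(2))
        np.testing.assert_allclose(a.ca, b.ca)          # same truth curves
        assert not np.allclose(a.cb, b.cb)              # different noise
        assert ta["CBF"] == tb["CBF"]


class TestFullExperiment:
    def test_streams_are_consistent_and_seeded(self):
        exp1 = simulate_experiment(protocol=SHORT, seed=4)
        exp2 = simulate_experiment(protocol=SHORT, seed=4)
        np.testing.assert_array_equal(exp1.spectra.frames, exp2.spectra.frames)
        np.testing.assert_array_equal(exp1.dcs_curves[0].g2, exp2.dcs_curves[0].g2)
        assert exp1.metadata["seed"] == 4
        exp3 = simulate_experiment(protocol=SHORT, seed=5)
        assert not np.array_equal(exp1.spectra.frames, exp3.spectra.frames)
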