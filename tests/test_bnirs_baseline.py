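"""Baseline reflectance computation and the three-step derivative fit."""

import numpy as np
import pytest

from oxflow.bnirs_baseline import (
    RawSpectrumSet,
    compute_reflectance,
    compute_sto2,
    fit_baseline,
)
from oxflow.config import DEFAULT_BOUNDS, PARAM_ORDER
from oxflow.errors import InvalidInputError
from oxflow.forward_models import TissueModel, reflectance_spectrum


def _raw(grid, measured, dark=None, reference=None):
    n = grid.size
    return RawSpectrumSet(
        grid=grid,
        measured=measured,
        dark=np.full(n, 100.0) if dark is None else dark,
        reference=np.full(n, 50_000.0) if reference is None else reference,
    )


class TestComputeReflectance:
    def test_spectrum_equals_reference_gives_zero(self, lib):
        ref = np.full(lib.grid.size, 50_000.0)
        raw = _raw(lib.grid, ref.copy(), reference=ref)
        np.testing.assert_allclose(compute_reflectance(raw), 0.0, atol=1e-12)

    def test_decade_ratio_gives_one(self, lib):
        n = lib.grid.size
        dark = np.full(n, 100.0)
        ref = np.full(n, 5_000.0)
        meas = dark + 10.0 * (ref - dark)
        raw = _raw(lib.grid, meas, dark=dark, reference=ref)
        np.testing.assert_allclose(compute_reflectance(raw), 1.0, atol=1e-12)

    def test_invariance_under_dark_consistent_shift(self, lib, rng):
        """Adding a constant offset to all three raw channels leaves R
        unchanged; adding it to dark alone does not."""
        n = lib.grid.size
        dark = np.full(n, 100.0)
        ref = np.full(n, 5_000.0) + rng.uniform(0, 100, n)
        meas = np.full(n, 2_000.0) + rng.uniform(0, 100, n)
        r0 = compute_reflectance(_raw(lib.grid, meas, dark, ref))
        c = 250.0
        r_shift_all = compute_reflectance(_raw(lib.grid, meas + c, dark + c, ref + c))
        np.testing.assert_allclose(r_shift_all, r0, rtol=1e-12)
        r_shift_dark = compute_reflectance(_raw(lib.grid, meas, dark + c, ref))
        assert not np.allclose(r_shift_dark, r0)

    def test_nonpositive_channels_masked_with_warning(self, lib):
        n = lib.grid.size
        meas = np.full(n, 2_000.0)
        meas[:5] = 50.0  # below dark
        with pytest.warns(UserWarning, match="masked"):
            r = compute_reflectance(_raw(lib.grid, meas))
        assert np.isnan(r[:5]).all() and np.isfinite(r[5:]).all()

    def test_fully_invalid_input_rejected(self, lib):
        meas = np.zeros(lib.grid.size)
        with pytest.raises(InvalidInputError):
            compute_reflectance(_raw(lib.grid, meas))


class TestStO2:
    def test_monte_carlo_truth_gives_75_5_percent(self):
        assert compute_sto2(13.0, 40.0) == pytest.approx(0.755, abs=5e-4)

    def test_symmetry_gives_half(self):
        assert compute_sto2(7.3, 7.3) == pytest.approx(0.5)

    def test_pure_oxyhemoglobin_gives_one(self):
        assert compute_sto2(0.0, 25.0) == pytest.approx(1.0)

    def test_undefined_saturation_rejected(self):
        with pytest.raises(InvalidInputError):
            compute_sto2(0.0, 0.0)


class TestFitBaseline:
    def test_noiseless_recovery_of_simulation_truth(self, lib, truth_tissue):
        """Forward-model oracle: all five parameters recovered within 1%."""
        r = np.log10(reflectance_spectrum(30.0, truth_tissue, lib))
        res = fit_baseline(lib.grid, r, lib)
        rel = np.abs(res.tissue.as_array() - truth_tissue.as_array()) / np.abs(
            truth_tissue.as_array()
        )
        assert np.all(rel < 0.01)
        assert res.converged
        assert 0.0 <= res.sto2 <= 1.0

    @pytest.mark.parametrize("sample", range(4))
    def test_noiseless_recovery_latin_hypercube(self, lib, sample):
        """Recovery across a Latin hypercube of truths inside the bounds
        (10% interior margin keeps the media physically sensible)."""
        from scipy.stats import qmc

        sampler = qmc.LatinHypercube(d=5, seed=99)
        pts = sampler.random(4)
        lows = np.array([DEFAULT_BOUNDS[k][0] for k in PARAM_ORDER])
        highs = np.array([DEFAULT_BOUNDS[k][1] for k in PARAM_ORDER])
        span = highs - lows
        x = lows + span * (0.1 + 0.8 * pts[sample])
        truth = TissueModel.from_array(x)
        r = np.log10(reflectance_spectrum(30.0, truth, lib))
        res = fit_baseline(lib.grid, r, lib)
        rel = np.abs(res.tissue.as_array() - x) / np.abs(x)
        assert np.all(rel < 0.01)

    def test_insensitive_to_initial_values(self, lib, truth_tissue):
        """Perturbing the initial values within bounds leaves the noiseless
        recovery unchanged within tolerance."""
        r = np.log10(reflectance_spectrum(30.0, truth_tissue, lib))
        perturbed = {"WF": 0.7, "Hb_b": 25.0, "HbO2_b": 20.0, "A": 0.5, "alpha": 3.5}
        res = fit_baseline(lib.grid, r, lib, initials=perturbed)
        rel = np.abs(res.tissue.as_array() - truth_tissue.as_array()) / np.abs(
            truth_tissue.as_array()
        )
        assert np.all(rel < 0.01)

    def test_estimates_respect_bounds_on_noisy_input(self, lib, truth_tissue, rng):
        from oxflow.synthetic import noisy_raw_spectra

        raw = noisy_raw_spectra(truth_tissue, lib, rng, n_frames=1)
        res = fit_baseline(lib.grid, compute_reflectance(raw), lib)
        for k in PARAM_ORDER:
            lo, hi = DEFAULT_BOUNDS[k]
            v = getattr(res.tissue, {"WF": "WF", "Hb_b": "Hb_b", "HbO2_b": "HbO2_b",
                                     "A": "A", "alpha": "alpha"}[k])
            assert lo - 1e-12 <= v <= hi + 1e-12
        assert 0.0 <= res.sto2 <= 1.0

    def test_insufficient_span_rejected(self, lib):
        sl = slice(200, 260)
        with pytest.raises(InvalidInputError):
            fit_baseline(lib.grid[sl], np.zeros(60), lib)
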