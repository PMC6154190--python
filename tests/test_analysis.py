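"""Monte Carlo error study and CBF-binned correlation analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oxflow.analysis import (
    BIN_EDGES,
    assign_bins,
    bin_by_cbf,
    flag_departures,
    normalize_to_baseline,
    run_mc_study,
)
from oxflow.errors import InvalidInputError


class TestMCStudy:
    def test_noise_off_gives_identical_repetitions(self, truth_tissue, lib):
        res = run_mc_study(truth_tissue, lib, reps=3, levels=(1,), seed=0, noise=False)
        df = res.estimates[1]
        assert df.std(ddof=1).max() == pytest.approx(0.0, abs=1e-9)
        # and the noiseless fit sits on the truth
        assert df["WF"].iloc[0] == pytest.approx(0.8, rel=1e-3)

    def test_summary_table_shape(self, truth_tissue, lib):
        res = run_mc_study(truth_tissue, lib, reps=2, levels=(1, 8), seed=1, noise=False)
        summary = res.summary()
        assert set(summary["level"]) == {1, 8}
        assert len(summary) == 12  # 6 parameters × 2 levels


def _brute_force_bins(df):
    """Exhaustive-grouping oracle: independently classify every sample."""
    out = {}
    for b in range(10):
        hi, lo = BIN_EDGES[b], BIN_EDGES[b + 1]
        rows = []
        for _, row in df.iterrows():
            v = row["CBF_norm"]
            if (lo < v <= hi) or (b == 0 and v > 1.0):
                rows.append(row)
        if rows:
            sub = pd.DataFrame(rows)
            out[b] = (sub["CBF_norm"].mean(), sub["dCCO"].mean(), sub["StO2"].mean())
    return out


class TestBinning:
    def test_constant_baseline_flow_fills_only_top_bin(self):
        df = pd.DataFrame({
            "CBF_norm": np.ones(20), "dCCO": np.zeros(20), "StO2": np.full(20, 0.75),
        })
        binned = bin_by_cbf({"a": df})
        assert binned.table.loc[0, "n"] == 1
        assert (binned.table.loc[1:, "n"] == 0).all()

    def test_linear_ramp_matches_brute_force_oracle(self):
        """Bin means must equal an exhaustive grouping with ΔoxCCO a known
        function of flow."""
        cbf = np.linspace(1.0, 0.001, 400)
        df = pd.DataFrame({
            "CBF_norm": cbf,
            "dCCO": -5.0 * (1 - cbf) ** 2,
            "StO2": 0.25 + 0.5 * cbf,
        })
        binned = bin_by_cbf({"a": df})
        oracle = _brute_force_bins(df)
        for b, (cbf_m, dcco_m, sto2_m) in oracle.items():
            row = binned.table.set_index("bin").loc[b]
            assert row["cbf_mean"] == pytest.approx(cbf_m)
            assert row["dcco_mean"] == pytest.approx(dcco_m)
            assert row["sto2_mean"] == pytest.approx(sto2_m)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_series_match_oracle_and_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n = 120
        df = pd.DataFrame({
            "CBF_norm": rng.uniform(0.01, 1.2, n),
            "dCCO": rng.normal(-2, 1, n),
            "StO2": rng.uniform(0.2, 0.9, n),
        })
        binned = bin_by_cbf({"a": df})
        shuffled = df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        binned2 = bin_by_cbf({"a": shuffled})
        pd.testing.assert_frame_equal(binned.table, binned2.table)
        oracle = _brute_force_bins(df)
        for b, (cbf_m, dcco_m, _) in oracle.items():
            row = binned.table.set_index("bin").loc[b]
            assert row["dcco_mean"] == pytest.approx(dcco_m)

    def test_bins_partition_unit_interval(self):
        assert BIN_EDGES[0] == 1.0 and BIN_EDGES[-1] == 0.0
        widths = -np.diff(BIN_EDGES)
        np.testing.assert_allclose(widths, 0.1)
        # every sample in (0, 1.2] lands in exactly one bin
        samples = np.linspace(0.001, 1.2, 777)
        idx = assign_bins(samples)
        assert np.all((idx >= 0) & (idx <= 9))

    def test_partial_animal_coverage_bookkeeping(self):
        full = pd.DataFrame({
            "CBF_norm": np.linspace(1.0, 0.05, 100),
            "dCCO": np.zeros(100), "StO2": np.full(100, 0.5),
        })
        shallow = full[full["CBF_norm"] > 0.7].reset_index(drop=True)
        binned = bin_by_cbf({"deep": full, "shallow": shallow})
        tbl = binned.table.set_index("bin")
        assert tbl.loc[0, "n"] == 2
        assert (tbl.loc[4:, "n"] == 1).all()

    def test_series_without_baseline_rejected(self):
        df = pd.DataFrame({"time": [400.0, 500.0], "CBF": [10.0, 12.0]})
        with pytest.raises(InvalidInputError):
            normalize_to_baseline(df, baseline_end=300.0)


class TestFlagDepartures:
    def _series(self, effect, rng, n_animals=5):
        out = {}
        for a in range(n_animals):
            cbf = np.linspace(1.0, 0.05, 200)
            dcco = np.where(cbf < 0.5, effect, 0.0) + rng.normal(0, 0.05, 200)
            out[f"animal{a}"] = pd.DataFrame({
                "CBF_norm": cbf, "dCCO": dcco, "StO2": np.full(200, 0.5),
            })
        return out

    def test_no_flags_when_identical_to_baseline(self, rng):
        flags = flag_departures(bin_by_cbf(self._series(0.0, rng)))
        assert not flags["flagged"].any()

    def test_large_step_below_threshold_is_flagged(self, rng):
        """ΔoxCCO steps down once flow falls below half of baseline: bins
        below the threshold flag, bins above do not."""
        flags = flag_departures(bin_by_cbf(self._series(-3.0, rng))).set_index("bin")
        assert flags.loc[7:9, "flagged"].all()     # deep-reduction bins
        assert not flags.loc[1:3, "flagged"].any() # near-baseline bins

    def test_single_animal_bins_untestable(self):
        full = pd.DataFrame({
            "CBF_norm": np.linspace(1.0, 0.05, 100),
            "dCCO": np.linspace(0, -5, 100), "StO2": np.full(100, 0.5),
        })
        shallow = full[full["CBF_norm"] > 0.85].reset_index(drop=True)
        flags = flag_departures(bin_by_cbf({"a": full, "b": shallow})).set_index("bin")
        deep = flags.loc[5]
        assert not deep["testable"]
        assert not deep["flagged"]
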