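"""Evaluation procedures: Monte Carlo fitting-error study and CBF binning.

The Monte Carlo study quantifies the precision of the three-step baseline
fit: spectra are simulated from a known tissue model with Poisson photon
noise, averaged over N repetitions (N ∈ {1, 8, …, 512}), fitted, and the
per-parameter mean ± standard deviation over many repeats reported.  Error
bars shrink with averaging, which is the study's central pattern.

The binned correlation analysis relates metabolic (ΔoxCCO) and oxygenation
(StO₂) responses to flow reduction: each animal's CBF series is normalised
to its own baseline, divided into ten bins of successive 10% reductions,
averaged within bins per animal, then summarised across animals
(mean ± standard error, with the per-bin animal count).  Bins are flagged
as departing from baseline by animal-wise paired comparisons against the
baseline bin with Holm multiplicity adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bnirs_baseline import compute_reflectance, compute_sto2, fit_baseline
from .chromophores import ChromophoreLibrary
from .errors import InvalidInputError
from .forward_models import TissueModel
from .synthetic import noisy_raw_spectra

DEFAULT_LEVELS = (1, 8, 64, 512)
PARAM_COLUMNS = ("WF", "Hb_b", "HbO2_b", "A", "alpha", "StO2")


# ---------------------------------------------------------------------------
# Monte Carlo error study

@dataclass
class MCStudyResult:
    truth: TissueModel
    levels: tuple
    reps: int
    estimates: dict            # level -> DataFrame of per-rep estimates
    n_failures: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Mean and std of every parameter at every averaging level."""
        rows = []
        for level in self.levels:
            df = self.estimates[level]
            for col in PARAM_COLUMNS:
                rows.append({
                    "level": level,
                    "parameter": col,
                    "mean": df[col].mean(),
                    "std": df[col].std(ddof=1) if len(df) > 1 else 0.0,
                })
        return pd.DataFrame(rows)

    def sto2_std_by_level(self) -> dict:
        return {
            level: float(self.estimates[level]["StO2"].std(ddof=1))
            for level in self.levels
        }


def run_mc_study(
    truth: TissueModel,
    lib: ChromophoreLibrary | None = None,
    reps: int = 500,
    levels: tuple = DEFAULT_LEVELS,
    seed: int = 0,
    rho: float = 30.0,
    photon_scale: float = 3.5e3,
    noise: bool = True,
    maxiter: int = 2000,
) -> MCStudyResult:
    """Monte Carlo assessment of the three-step fit's accuracy/precision.

    For each averaging level N and each repetition: simulate a spectrum as
    the average of N Poisson-noised acquisitions, run the full baseline
    fit, and record the five parameters plus StO₂.  Fit repetitions that
    fail to converge are counted and excluded from the summaries.
    """
    lib = lib or ChromophoreLibrary.default()
    rng = np.random.default_rng(seed)
    estimates: dict = {}
    n_failures: dict = {}
    for level in levels:
        rows = []
        failures = 0
        for _ in range(reps):
            raw = noisy_raw_spectra(
                truth, lib, rng, rho=rho, photon_scale=photon_scale,
                n_frames=level, noise=noise,
            )
            r = compute_reflectance(raw)
            res = fit_baseline(lib.grid, r, lib, rho=rho, maxiter=maxiter)
            if not res.converged:
                failures += 1
            t = res.tissue
            rows.append({
                "WF": t.WF, "Hb_b": t.Hb_b, "HbO2_b": t.HbO2_b,
                "A": t.A, "alpha": t.alpha,
                "StO2": 100.0 * compute_sto2(t.Hb_b, t.HbO2_b),
            })
        estimates[level] = pd.DataFrame(rows)
        n_failures[level] = failures
    return MCStudyResult(
        truth=truth, levels=tuple(levels), reps=reps,
        estimates=estimates, n_failures=n_failures,
    )


# ---------------------------------------------------------------------------
# CBF-binned correlation

#: bin edges on normalised CBF: (1.0, 0.9], (0.9, 0.8], …, (0.1, 0.0]
BIN_EDGES = np.round(np.linspace(1.0, 0.0, 11), 10)


@dataclass
class BinnedCorrelation:
    """Cross-animal per-bin summaries of CBF, ΔoxCCO and StO₂."""

    table: pd.DataFrame          # bin, cbf_mean, dcco_mean/sem, sto2_mean/sem, n
    per_animal: pd.DataFrame     # animal, bin, per-animal within-bin means


def assign_bins(normalized_cbf: np.ndarray) -> np.ndarray:
    """Bin index 0..9 for each normalised-CBF sample.

    Bin i covers (1 − 0.1·(i+1), 1 − 0.1·i]; flow above baseline (> 1.0)
    falls in the top bin (index 0).
    """
    cbf = np.asarray(normalized_cbf, dtype=float)
    idx = np.ceil((1.0 - cbf) / 0.1 - 1e-12).astype(int) - 1
    idx[cbf > 1.0] = 0
    return np.clip(idx, 0, 9)


def normalize_to_baseline(
    series: pd.DataFrame, baseline_end: float, time_col: str = "time"
) -> pd.DataFrame:
    """Normalise a CBF series to its mean over the pre-occlusion window."""
    mask = series[time_col] <= baseline_end
    if not mask.any():
        raise InvalidInputError("series has no baseline period")
    out = series.copy()
    out["CBF_norm"] = series["CBF"] / series.loc[mask, "CBF"].mean()
    return out


def bin_by_cbf(animal_series: dict[str, pd.DataFrame]) -> BinnedCorrelation:
    """Per-animal within-bin averages, then cross-animal mean ± SEM.

    ``animal_series`` maps animal id → DataFrame with columns CBF_norm,
    dCCO, StO2.  Empty bins are skipped per animal, and the per-bin count
    of contributing animals is recorded.
    """
    per_animal_rows = []
    for animal, df in animal_series.items():
        idx = assign_bins(df["CBF_norm"].to_numpy())
        for b in np.unique(idx):
            sub = df.iloc[np.flatnonzero(idx == b)]
            per_animal_rows.append({
                "animal": animal,
                "bin": int(b),
                "cbf": sub["CBF_norm"].mean(),
                "dcco": sub["dCCO"].mean(),
                "sto2": sub["StO2"].mean(),
            })
    per_animal = pd.DataFrame(per_animal_rows)
    rows = []
    for b in range(10):
        sub = per_animal[per_animal["bin"] == b]
        n = len(sub)
        sem = (lambda x: x.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan)
        rows.append({
            "bin": b,
            "cbf_lo": float(BIN_EDGES[b + 1]),
            "cbf_hi": float(BIN_EDGES[b]),
            "n": n,
            "cbf_mean": sub["cbf"].mean() if n else np.nan,
            "dcco_mean": sub["dcco"].mean() if n else np.nan,
            "dcco_sem": sem(sub["dcco"]) if n else np.nan,
            "sto2_mean": sub["sto2"].mean() if n else np.nan,
            "sto2_sem": sem(sub["sto2"]) if n else np.nan,
        })
    return BinnedCorrelation(table=pd.DataFrame(rows), per_animal=per_animal)


def flag_departures(
    binned: BinnedCorrelation,
    variable: str = "dcco",
    baseline_bin: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Which bins differ from the baseline bin, by paired animal-wise tests.

    For each bin, animals present in both that bin and the baseline bin
    contribute a paired difference; a one-sample t-test on the differences
    with Holm adjustment across bins gives the flags.  Bins with fewer than
    two paired animals are marked untestable, never flagged.
    """
    pa = binned.per_animal
    base = pa[pa["bin"] == baseline_bin].set_index("animal")[variable]
    rows = []
    pvals = []
    for b in sorted(pa["bin"].unique()):
        if b == baseline_bin:
            continue
        cur = pa[pa["bin"] == b].set_index("animal")[variable]
        common = base.index.intersection(cur.index)
        diffs = (cur.loc[common] - base.loc[common]).to_numpy()
        if len(diffs) < 2 or np.allclose(diffs, diffs[0]):
            # degenerate paired samples are untestable unless identical-zero
            if len(diffs) >= 2 and np.allclose(diffs, 0.0):
                rows.append({"bin": b, "n_pairs": len(diffs), "p_raw": 1.0,
                             "testable": True})
                pvals.append(1.0)
            else:
                rows.append({"bin": b, "n_pairs": len(diffs), "p_raw": np.nan,
                             "testable": False})
            continue
        p = float(stats.ttest_1samp(diffs, 0.0).pvalue)
        rows.append({"bin": b, "n_pairs": len(diffs), "p_raw": p, "testable": True})
        pvals.append(p)
    out = pd.DataFrame(rows)
    # Holm step-down over the testable bins
    out["p_adj"] = np.nan
    out["flagged"] = False
    testable = out[out["testable"]].sort_values("p_raw")
    m = len(testable)
    running_max = 0.0
    for rank, (i, row) in enumerate(testable.iterrows()):
        p_adj = min(1.0, (m - rank) * row["p_raw"])
        running_max = max(running_max, p_adj)
        out.loc[i, "p_adj"] = running_max
        out.loc[i, "flagged"] = running_max < alpha
    return out
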