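"""Per-recording summaries, grand averages, and the group test battery.

Aggregation follows the two-level scheme used for cohort
electrophysiology: unit-level metrics are averaged within each
recording (responsive-only denominators for phase fractions), and the
per-recording values are then averaged, unweighted, into grand means
with n-1 standard deviations.

Paired group comparisons auto-select the test: Wilcoxon signed rank
for n >= 6 pairs, paired Student's t below that; the Friedman test
(minimum n = 4) with Dunn-Sidak post hocs covers one-way repeated
measures across >= 3 conditions.  Families of p-values are adjusted
with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig, DEFAULT_CONFIG

SUMMARY_METRICS = (
    "baseline_hz", "frac_responsive_pct", "onset_latency_ms",
    "peak_latency_ms", "peak_amplitude_hz", "duration_ms",
    "frac_suppressed_pct", "suppression_pct_baseline",
    "frac_rebound_pct", "rebound_amplitude_hz", "rebound_latency_ms",
)


@dataclass(frozen=True)
class GroupComparison:
    test_name: str          # signed_rank | paired_t | friedman
    statistic: float        # W, t, or chi2
    p: float
    n: int
    adjusted_p: Optional[float] = None
    label: str = ""


def summarize_experiment(unit_metrics: pd.DataFrame,
                         recording_id: str) -> pd.Series:
    """Recording-level means from a per-unit metrics table.

    Expects the tidy per-unit table produced by
    :func:`triphasic.pipelines.analyze_session` (one row per unit with
    ``responsive``/``suppressed``/``rebounding`` flags and metric
    columns).  Means of onset/peak/amplitude/duration are taken over
    responsive units; suppression and rebound quantities over the units
    showing that phase; fractions use responsive-only denominators.
    Metrics with no qualifying unit are NaN (flagged, not zero).
    """
    df = unit_metrics
    resp = df[df["responsive"]]
    out = {
        "recording_id": recording_id,
        "n_units": len(df),
        "n_responsive": len(resp),
        "baseline_hz": df["baseline_hz"].mean(),
        "frac_responsive_pct": 100.0 * len(resp) / len(df) if len(df) else np.nan,
    }
    for col in ("onset_latency_ms", "peak_latency_ms", "peak_amplitude_hz",
                "duration_ms"):
        out[col] = resp[col].mean() if len(resp) else np.nan
    if len(resp):
        supp = resp[resp["suppressed"]]
        reb = resp[resp["rebounding"]]
        out["frac_suppressed_pct"] = 100.0 * len(supp) / len(resp)
        out["frac_rebound_pct"] = 100.0 * len(reb) / len(resp)
        out["suppression_pct_baseline"] = (
            supp["suppression_pct_baseline"].mean() if len(supp) else np.nan)
        out["rebound_amplitude_hz"] = (
            reb["rebound_amplitude_hz"].mean() if len(reb) else np.nan)
        out["rebound_latency_ms"] = (
            reb["rebound_latency_ms"].mean() if len(reb) else np.nan)
    else:
        for col in ("frac_suppressed_pct", "frac_rebound_pct",
                    "suppression_pct_baseline", "rebound_amplitude_hz",
                    "rebound_latency_ms"):
            out[col] = np.nan
    return pd.Series(out)


def grand_average(summaries: pd.DataFrame,
                  metrics: Sequence[str] = SUMMARY_METRICS) -> pd.DataFrame:
    """Cohort table: unweighted mean and n-1 s.d. across recordings."""
    if len(summaries) < 1:
        raise ValueError("need at least one recording summary")
    rows = []
    for m in metrics:
        if m not in summaries.columns:
            continue
        vals = summaries[m].dropna()
        rows.append({
            "metric": m,
            "mean": vals.mean() if len(vals) else np.nan,
            "sd": vals.std(ddof=1) if len(vals) > 1 else
                  (0.0 if len(vals) == 1 else np.nan),
            "n": len(vals),
        })
    return pd.DataFrame(rows).set_index("metric")


def compare_paired(x, y, label: str = "",
                   config: AnalysisConfig = DEFAULT_CONFIG) -> GroupComparison:
    """Paired two-sided comparison with automatic test selection.

    Signed rank (exact null where scipy allows) for n >= 6 pairs;
    paired Student's t for smaller samples.  All-tied pairs carry no
    evidence against the null and return p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    n = x.size
    if n >= config.min_trials_signed_rank:
        d = x - y
        if np.all(d == 0):
            return GroupComparison("signed_rank", 0.0, 1.0, n, label=label)
        from .phases import signed_rank_method

        res = sps.wilcoxon(x, y, zero_method="wilcox",
                           alternative="two-sided", correction=True,
                           method=signed_rank_method(d[d != 0]))
        return GroupComparison("signed_rank", float(res.statistic),
                               float(res.pvalue), n, label=label)
    res = sps.ttest_rel(x, y)
    return GroupComparison("paired_t", float(res.statistic),
                           float(res.pvalue), n, label=label)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg FDR-adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def adjust_family(comparisons: Sequence[GroupComparison]
                  ) -> List[GroupComparison]:
    """BH-adjust a declared family of comparisons."""
    adj = bh_adjust([c.p for c in comparisons])
    return [GroupComparison(c.test_name, c.statistic, c.p, c.n,
                            adjusted_p=float(a), label=c.label)
            for c, a in zip(comparisons, adj)]


def friedman_dunn_sidak(data: np.ndarray,
                        config: AnalysisConfig = DEFAULT_CONFIG):
    """Friedman test across >= 3 repeated conditions + Dunn-Sidak post hocs.

    ``data`` is subjects x conditions (min 4 subjects).  Post-hoc
    pairwise contrasts on mean ranks are computed only when the
    Friedman test is significant (gatekeeping) and are Sidak-adjusted
    over all pairs.  Returns ``(GroupComparison, list_of_posthocs)``
    where each post hoc is ``(i, j, adjusted_p)``.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if n < 4:
        raise ValueError("Friedman test requires at least 4 subjects")
    if k < 3:
        raise ValueError("Friedman test requires at least 3 conditions")
    chi2, p = sps.friedmanchisquare(*[data[:, j] for j in range(k)])
    result = GroupComparison("friedman", float(chi2), float(p), n)

    posthocs = []
    if p < config.alpha:
        ranks = np.apply_along_axis(sps.rankdata, 1, data)
        mean_ranks = ranks.mean(axis=0)
        se = np.sqrt(k * (k + 1) / (6.0 * n))
        m = k * (k - 1) // 2
        for i in range(k):
            for j in range(i + 1, k):
                z = abs(mean_ranks[i] - mean_ranks[j]) / se
                p_raw = 2.0 * sps.norm.sf(z)
                p_adj = min(1.0, 1.0 - (1.0 - min(p_raw, 1.0)) ** m)
                posthocs.append((i, j, float(p_adj)))
    return result, posthocs


def spearman_matrix(summaries: pd.DataFrame, metrics: Sequence[str],
                    config: AnalysisConfig = DEFAULT_CONFIG):
    """Pairwise Spearman rho across recordings, with t-test p-values.

    Returns ``(rho_df, p_df, significant_mask_df)``.  Constant columns
    yield NaN (flagged undefined) off the diagonal.
    """
    if len(summaries) < 4:
        raise ValueError("need at least 4 recordings for correlations")
    cols = [m for m in metrics if m in summaries.columns]
    k = len(cols)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            paired = summaries[[cols[i], cols[j]]].dropna()
            xi, yj = paired[cols[i]], paired[cols[j]]
            if xi.nunique() < 2 or yj.nunique() < 2 or len(paired) < 4:
                r, p = np.nan, np.nan
            else:
                r, p = sps.spearmanr(xi, yj)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(pval, index=cols, columns=cols)
    mask = (p_df < config.alpha) & np.isfinite(rho_df)
    np.fill_diagonal(mask.values, False)
    return rho_df, p_df, mask
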