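"""Post-peak suppression and post-suppression rebound metrics.

Both phases are tested per unit by pairing each trial's mean rate in
the phase window against the same trial's baseline mean (two-sided
Wilcoxon signed-rank, zero-differences discarded per the classical
convention).  The trial is the paired observation — the only
replication available within a unit.  A unit is *suppressed* when the
test is significant and the window mean lies below baseline;
*rebounding* when significant and above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Set

import numpy as np
from scipy import stats as sps

from .config import AnalysisConfig, DEFAULT_CONFIG
from .psth import PSTH, BaselineStats, per_trial_window_means
from .response import ResponseMetrics


@dataclass(frozen=True)
class SuppressionMetrics:
    suppressed: bool
    suppression_rate_hz: float
    suppression_pct_baseline: Optional[float]  # None if baseline mean is 0
    p_value: Optional[float]                   # None if the test was skipped
    test_skipped: bool = False


@dataclass(frozen=True)
class ReboundMetrics:
    rebounding: bool
    rebound_amplitude_hz: float       # raw mean in the +/-20 ms window
    rebound_latency_ms: float
    p_value: Optional[float]
    window_clipped: bool = False
    test_skipped: bool = False


def signed_rank_method(d: np.ndarray, max_exact_n: int = 25) -> str:
    """Exact null when |d| are tie-free and n is small, else normal approx."""
    return ("exact" if d.size <= max_exact_n
            and np.unique(np.abs(d)).size == d.size else "approx")


def paired_signed_rank(x: np.ndarray, y: np.ndarray):
    """Two-sided Wilcoxon signed-rank on paired vectors; (p, skipped).

    Zero differences are discarded (Wilcoxon convention); if fewer
    than one nonzero pair remains the test is skipped.  Uses the exact
    null distribution for n <= 25 tie-free differences and the
    tie-corrected normal approximation otherwise.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return None, True
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided", correction=True,
                       method=signed_rank_method(d))
    return float(res.pvalue), False


def suppression_metrics(psth: PSTH, baseline: BaselineStats,
                        config: AnalysisConfig = DEFAULT_CONFIG
                        ) -> SuppressionMetrics:
    """Quantify the 110-170 ms suppression phase of one unit."""
    if psth.n_trials < config.min_trials_signed_rank:
        raise ValueError(
            f"need >= {config.min_trials_signed_rank} trials for the "
            "signed-rank test")
    win = per_trial_window_means(psth, config.suppression_window_ms)
    base = per_trial_window_means(psth, config.baseline_ms)
    p, skipped = paired_signed_rank(win, base)
    win_mean = float(win.mean())
    pct = (100.0 * win_mean / baseline.mean) if baseline.mean > 0 else None
    suppressed = (not skipped and p < config.alpha
                  and win_mean < baseline.mean)
    return SuppressionMetrics(
        suppressed=bool(suppressed),
        suppression_rate_hz=win_mean,
        suppression_pct_baseline=pct,
        p_value=p,
        test_skipped=skipped,
    )


def rebound_metrics(psth: PSTH, baseline: BaselineStats,
                    config: AnalysisConfig = DEFAULT_CONFIG) -> ReboundMetrics:
    """Quantify the 190-400 ms rebound phase of one unit.

    Rebound latency is the bin-start time of the rebound-window maximum
    of the trial-averaged trace (earliest on ties); the amplitude is
    the mean of the trace from 20 ms before to 20 ms after that time,
    clipped at the span edge if necessary.
    """
    if psth.n_trials < config.min_trials_signed_rank:
        raise ValueError(
            f"need >= {config.min_trials_signed_rank} trials for the "
            "signed-rank test")
    starts = psth.bin_starts_ms
    wmask = psth.bin_mask_ms(config.rebound_window_ms)
    vals = psth.mean_rate[wmask]
    i_max = int(np.argmax(vals))
    latency = float(starts[wmask][i_max])

    halfw = config.rebound_halfwidth_ms
    lo = latency - halfw
    hi = latency + halfw + config.bin_ms  # include the bin at +20 ms
    clipped = hi > psth.bin_edges_ms[-1] or lo < psth.bin_edges_ms[0]
    amask = (starts >= lo) & (starts < hi)
    amplitude = float(psth.mean_rate[amask].mean())

    win = psth.per_trial_rates[:, amask].mean(axis=1)
    base = per_trial_window_means(psth, config.baseline_ms)
    p, skipped = paired_signed_rank(win, base)
    rebounding = (not skipped and p < config.alpha
                  and amplitude > baseline.mean)
    return ReboundMetrics(
        rebounding=bool(rebounding),
        rebound_amplitude_hz=amplitude,
        rebound_latency_ms=latency,
        p_value=p,
        window_clipped=bool(clipped),
        test_skipped=skipped,
    )


def classify_triphasic(response: ResponseMetrics,
                       suppression: Optional[SuppressionMetrics],
                       rebound: Optional[ReboundMetrics]) -> Set[str]:
    """Set-valued phase label: subset of {'peak', 'suppression', 'rebound'}.

    Non-responsive units get the empty set and are excluded from the
    phase-fraction denominators downstream.
    """
    if not response.responsive:
        return set()
    labels = {"peak"}
    if suppression is not None and suppression.suppressed:
        labels.add("suppression")
    if rebound is not None and rebound.rebounding:
        labels.add("rebound")
    return labels
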