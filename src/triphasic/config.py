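"""Analysis configuration.

All windows are expressed in milliseconds relative to stimulus onset;
spike and event times elsewhere in the package are in seconds.  The
conversion lives in :func:`ms_to_s` / :func:`s_to_ms` and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

MS_PER_S = 1000.0


def ms_to_s(t_ms: float) -> float:
    """Convert milliseconds to seconds."""
    return t_ms / MS_PER_S


def s_to_ms(t_s: float) -> float:
    """Convert seconds to milliseconds."""
    return t_s * MS_PER_S


@dataclass(frozen=True)
class AnalysisConfig:
    """Windows and thresholds for stimulus-aligned analysis.

    Defaults implement the standard recipe for brief-stimulus evoked
    responses in mouse S1/M1: 5-ms bins spanning ±0.5 s around stimulus
    onset, a 250-ms pre-stimulus baseline, responsiveness defined by the
    z-scored PSTH exceeding ``z_threshold`` baseline s.d., a fixed
    110–170 ms suppression window and a 190–400 ms rebound window.

    Parameters
    ----------
    bin_ms:
        PSTH bin width (ms).  Bins are half-open ``[a, a + bin)``.
    span_ms:
        Alignment window around each stimulus (ms).
    baseline_ms:
        Pre-stimulus window used for baseline mean/s.d.
    peak_window_ms:
        Window in which the initial-peak amplitude is measured.
    responsive_window_ms:
        Window searched by the max-z responsiveness criterion.  The
        default matches the peak window so that rebound-only units do
        not enter the "stimulus-responsive" denominator; ``(0, 500)``
        is the documented alternative.
    z_threshold, off_threshold:
        Onset (2.5 s.d.) and offset (1 s.d.) thresholds on the z-trace.
    detection_sd_floor_quantum:
        If True (default), the z denominator used for the *responsive
        yes/no decision* is floored at the one-spike rate quantum
        ``1 / (n_trials * bin_s)``.  At near-silent baselines the
        empirical baseline s.d. is so granular that one or two
        coincident spikes anywhere in the search window would otherwise
        exceed ``z_threshold``; the floor makes the decision demand an
        elevation worth ``z_threshold`` spikes-worth of rate.  Latency
        read-outs always use the unfloored s.d. (with the quantum as a
        fallback only when the baseline s.d. is exactly zero).
    suppression_window_ms, rebound_window_ms, rebound_halfwidth_ms:
        Late-phase windows; rebound amplitude is the mean of the trace
        within ``rebound_halfwidth_ms`` of the rebound-window maximum.
    integral_window_ms:
        Window of the firing-rate integral used by the silencing
        analysis (Hz·ms).
    alpha:
        Significance level for all per-unit and group tests.
    min_trials_signed_rank:
        Minimum paired sample size for the signed-rank test; below it
        group comparisons fall back to a paired t-test.
    laminar_peak_halfwidth_bins:
        "Around the time of the peak" for laminar profiles = peak bin
        ± this many bins.
    """

    bin_ms: float = 5.0
    span_ms: Tuple[float, float] = (-500.0, 500.0)
    baseline_ms: Tuple[float, float] = (-250.0, 0.0)
    peak_window_ms: Tuple[float, float] = (0.0, 100.0)
    responsive_window_ms: Tuple[float, float] = (0.0, 100.0)
    z_threshold: float = 2.5
    off_threshold: float = 1.0
    detection_sd_floor_quantum: bool = True
    suppression_window_ms: Tuple[float, float] = (110.0, 170.0)
    rebound_window_ms: Tuple[float, float] = (190.0, 400.0)
    rebound_halfwidth_ms: float = 20.0
    integral_window_ms: Tuple[float, float] = (15.0, 50.0)
    alpha: float = 0.05
    min_trials_signed_rank: int = 6
    laminar_peak_halfwidth_bins: int = 2
    # opto-tagging (1-ms bins: the 20-ms light pulse spans only four
    # 5-ms bins, too coarse for latency)
    tag_bin_ms: float = 1.0
    tag_latency_max_ms: float = 5.0
    tag_sustained_min: float = 0.75
    tag_reliability_min: float = 0.5
    pulse_duration_ms: float = 20.0

    def __post_init__(self) -> None:
        for name in ("span_ms", "baseline_ms", "peak_window_ms",
                     "responsive_window_ms", "suppression_window_ms",
                     "rebound_window_ms", "integral_window_ms"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be increasing, got {(lo, hi)}")
        if self.bin_ms <= 0:
            raise ValueError("bin_ms must be positive")
        span_w = self.span_ms[1] - self.span_ms[0]
        if abs(span_w / self.bin_ms - round(span_w / self.bin_ms)) > 1e-9:
            raise ValueError("bin_ms must divide the span width")
        if not self.baseline_ms[0] >= self.span_ms[0]:
            raise ValueError("baseline window must lie inside the span")

    @property
    def n_bins(self) -> int:
        return int(round((self.span_ms[1] - self.span_ms[0]) / self.bin_ms))

    def bin_edges_ms(self):
        import numpy as np

        return self.span_ms[0] + self.bin_ms * np.arange(self.n_bins + 1)

    def with_(self, **kwargs) -> "AnalysisConfig":
        """Return a copy with fields replaced."""
        return replace(self, **kwargs)


DEFAULT_CONFIG = AnalysisConfig()
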