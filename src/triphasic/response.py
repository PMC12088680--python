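"""Responsiveness classification and initial-peak metrics.

A unit is stimulus-responsive when the maximum of its z-scored PSTH
inside the responsive window exceeds ``z_threshold`` (strictly).  At
near-silent baselines the empirical baseline s.d. under-resolves the
spike-count granularity — a single coincident spike can exceed 2.5
"s.d." — so the *detection* denominator is floored at the one-spike
rate quantum ``1/(n_trials * bin)`` (see ``AnalysisConfig``).  Latency
read-outs for responsive units use the classical unfloored rule: onset
is the start of the first bin whose z exceeds the threshold, duration
runs until z first falls below the off-threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import AnalysisConfig, DEFAULT_CONFIG
from .psth import PSTH, BaselineStats, ZScoredTrace, rate_quantum_hz


class InconsistentResponseError(RuntimeError):
    """Metrics were requested for a unit that shows no exceedance."""


@dataclass(frozen=True)
class ResponseMetrics:
    """Initial-peak metrics of one unit; latencies are bin-start times.

    Fields other than ``responsive`` are None for non-responsive units.
    ``duration_censored`` marks responses still above the off-threshold
    at the end of the span.
    """

    responsive: bool
    onset_latency_ms: Optional[float] = None
    peak_latency_ms: Optional[float] = None
    peak_amplitude_hz: Optional[float] = None
    duration_ms: Optional[float] = None
    duration_censored: bool = False


def detection_z(psth: PSTH, trace: ZScoredTrace,
                config: AnalysisConfig = DEFAULT_CONFIG) -> np.ndarray:
    """z-trace with the quantum-floored denominator used for detection."""
    if not config.detection_sd_floor_quantum:
        return trace.z
    floor = rate_quantum_hz(psth, config)
    sd = max(trace.baseline.sd, floor)
    return trace.baseline_subtracted / sd


def classify_responsive(z_trace: np.ndarray, bin_starts_ms: np.ndarray,
                        config: AnalysisConfig = DEFAULT_CONFIG) -> bool:
    """True iff max z inside the responsive window strictly exceeds 2.5."""
    lo, hi = config.responsive_window_ms
    mask = (bin_starts_ms >= lo) & (bin_starts_ms < hi)
    if not mask.any():
        return False
    return bool(np.max(z_trace[mask]) > config.z_threshold)


def initial_peak_metrics(trace: ZScoredTrace,
                         config: AnalysisConfig = DEFAULT_CONFIG):
    """(peak_amplitude_hz, peak_latency_ms, onset_latency_ms).

    Peak amplitude is the maximum of the baseline-subtracted trace in
    the peak window; peak latency is the start time of the argmax bin
    (earliest on ties); onset latency is the start of the first bin
    with z above threshold inside the responsive window.
    """
    starts = trace.bin_starts_ms
    lo, hi = config.peak_window_ms
    peak_mask = (starts >= lo) & (starts < hi)
    sub = trace.baseline_subtracted[peak_mask]
    i_peak = int(np.argmax(sub))  # argmax returns the earliest maximum
    peak_amplitude = float(sub[i_peak])
    peak_latency = float(starts[peak_mask][i_peak])

    rlo, rhi = config.responsive_window_ms
    resp_mask = (starts >= rlo) & (starts < rhi)
    exceed = np.flatnonzero(trace.z[resp_mask] > config.z_threshold)
    if exceed.size == 0:
        raise InconsistentResponseError(
            "no bin exceeds the onset threshold; unit cannot be responsive")
    onset_latency = float(starts[resp_mask][exceed[0]])
    return peak_amplitude, peak_latency, onset_latency


def response_duration(trace: ZScoredTrace, onset_latency_ms: float,
                      config: AnalysisConfig = DEFAULT_CONFIG):
    """(duration_ms, censored): onset until z first drops below 1 s.d.

    Duration = start of the first post-onset bin with z below the
    off-threshold, minus onset.  If z never falls below before the end
    of the span the duration is censored there and flagged.
    """
    starts = trace.bin_starts_ms
    after = starts > onset_latency_ms
    low = np.flatnonzero(after & (trace.z < config.off_threshold))
    if low.size == 0:
        end = float(starts[-1] + (starts[1] - starts[0]))
        return end - onset_latency_ms, True
    return float(starts[low[0]] - onset_latency_ms), False


def response_metrics(psth: PSTH, trace: ZScoredTrace,
                     config: AnalysisConfig = DEFAULT_CONFIG) -> ResponseMetrics:
    """Full initial-peak characterization of one unit."""
    det_z = detection_z(psth, trace, config)
    if not classify_responsive(det_z, trace.bin_starts_ms, config):
        return ResponseMetrics(responsive=False)
    amp, peak_lat, onset = initial_peak_metrics(trace, config)
    duration, censored = response_duration(trace, onset, config)
    return ResponseMetrics(
        responsive=True,
        onset_latency_ms=onset,
        peak_latency_ms=peak_lat,
        peak_amplitude_hz=amp,
        duration_ms=duration,
        duration_censored=censored,
    )
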