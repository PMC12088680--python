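"""Stimulus-aligned binning, trial-averaged PSTHs, baseline z-scoring."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig, DEFAULT_CONFIG


@dataclass
class PSTH:
    """Per-trial binned rates plus the trial-averaged trace.

    ``per_trial_rates`` is trials x bins in Hz; ``mean_rate`` /
    ``sd_rate`` are the across-trial mean and s.d. per bin.
    ``bin_edges_ms`` has ``n_bins + 1`` entries.
    """

    bin_edges_ms: np.ndarray
    per_trial_rates: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.per_trial_rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.per_trial_rates.shape[1]

    @property
    def mean_rate(self) -> np.ndarray:
        return self.per_trial_rates.mean(axis=0)

    @property
    def sd_rate(self) -> np.ndarray:
        if self.n_trials < 2:
            return np.zeros(self.n_bins)
        return self.per_trial_rates.std(axis=0, ddof=1)

    @property
    def bin_starts_ms(self) -> np.ndarray:
        return self.bin_edges_ms[:-1]

    def bin_mask_ms(self, window_ms) -> np.ndarray:
        """Boolean mask of bins whose *start* lies in ``[lo, hi)``."""
        lo, hi = window_ms
        starts = self.bin_starts_ms
        return (starts >= lo) & (starts < hi)


@dataclass(frozen=True)
class BaselineStats:
    """Baseline mean and s.d. (n-1) across pre-stimulus bins."""

    mean: float
    sd: float
    n_bins: int


@dataclass
class ZScoredTrace:
    """z-trace and baseline-subtracted trace of a trial-averaged PSTH.

    ``degenerate`` flags a baseline with zero variance, in which case
    the z denominator fell back to ``fallback_sd_hz`` (the one-spike
    rate quantum when available, else 1 Hz).
    """

    z: np.ndarray
    baseline_subtracted: np.ndarray
    baseline: BaselineStats
    bin_starts_ms: np.ndarray
    degenerate: bool
    sd_used_hz: float


def bin_spike_counts(spike_times, event_times,
                     config: AnalysisConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Bin spikes around each event; returns trials x bins rates in Hz.

    Bins are half-open ``[a, a + bin)`` in ms relative to event onset;
    a spike exactly at a bin edge belongs to the bin starting there.
    Rate = count / bin width.
    """
    events = np.asarray(event_times, dtype=float)
    if events.size == 0:
        raise ValueError("event list is empty")
    spikes = np.asarray(spike_times, dtype=float)
    span_w_s = (config.span_ms[1] - config.span_ms[0]) / 1000.0
    if events.size > 1 and np.min(np.diff(np.sort(events))) < span_w_s:
        warnings.warn("events are closer than the alignment span; "
                      "windows overlap", stacklevel=2)
    n_bins = config.n_bins
    bin_s = config.bin_ms / 1000.0
    lo_s = config.span_ms[0] / 1000.0
    counts = np.zeros((events.size, n_bins))
    # 1-ns epsilon guards the half-open edges against float round-off;
    # spike times live on a microsecond grid, so no real spike moves.
    eps = 1e-9
    for i, ev in enumerate(events):
        rel = spikes - (ev + lo_s)
        idx = np.floor((rel + eps) / bin_s).astype(int)
        idx = idx[(idx >= 0) & (idx < n_bins)]
        if idx.size:
            counts[i] = np.bincount(idx, minlength=n_bins)
    return counts / bin_s


def compute_psth(per_trial_rates, config: AnalysisConfig = DEFAULT_CONFIG) -> PSTH:
    """Wrap a trials x bins rate matrix as a :class:`PSTH`."""
    rates = np.atleast_2d(np.asarray(per_trial_rates, dtype=float))
    if rates.shape[0] < 1:
        raise ValueError("need at least one trial")
    if rates.shape[1] != config.n_bins:
        raise ValueError(
            f"expected {config.n_bins} bins, got {rates.shape[1]}")
    return PSTH(bin_edges_ms=config.bin_edges_ms(), per_trial_rates=rates)


def psth_from_spikes(spike_times, event_times,
                     config: AnalysisConfig = DEFAULT_CONFIG) -> PSTH:
    """Convenience: bin and wrap in one call."""
    return compute_psth(bin_spike_counts(spike_times, event_times, config),
                        config)


def baseline_stats(psth: PSTH,
                   config: AnalysisConfig = DEFAULT_CONFIG) -> BaselineStats:
    """Baseline mean/s.d. across the baseline bins of the trial average.

    The s.d. is taken over the baseline bins of the *trial-averaged*
    PSTH with ddof = 1 (the alternative — pooling single-trial bins —
    would change only this function).
    """
    mask = psth.bin_mask_ms(config.baseline_ms)
    if not mask.any():
        raise ValueError("baseline window is outside the span")
    vals = psth.mean_rate[mask]
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    if sd < 1e-9:  # numerically flat baseline counts as degenerate
        sd = 0.0
    return BaselineStats(mean=float(vals.mean()), sd=sd, n_bins=int(mask.sum()))


def per_trial_window_means(psth: PSTH, window_ms) -> np.ndarray:
    """Per-trial mean rate inside a window (one value per trial)."""
    mask = psth.bin_mask_ms(window_ms)
    return psth.per_trial_rates[:, mask].mean(axis=1)


def rate_quantum_hz(psth: PSTH, config: AnalysisConfig = DEFAULT_CONFIG) -> float:
    """Rate of one spike in one bin across all trials, in Hz."""
    return 1.0 / (psth.n_trials * config.bin_ms / 1000.0)


def zscore_psth(psth: PSTH, baseline: BaselineStats,
                config: AnalysisConfig = DEFAULT_CONFIG) -> ZScoredTrace:
    """z-score the trial-averaged PSTH against its baseline statistics.

    ``z = (mean_rate - baseline.mean) / baseline.sd``; a zero-variance
    baseline is flagged and the one-spike rate quantum substitutes for
    the s.d. so that silent-but-driven units remain detectable.
    """
    degenerate = baseline.sd == 0.0
    sd = baseline.sd if not degenerate else max(rate_quantum_hz(psth, config), 1.0)
    sub = psth.mean_rate - baseline.mean
    return ZScoredTrace(
        z=sub / sd,
        baseline_subtracted=sub,
        baseline=baseline,
        bin_starts_ms=psth.bin_starts_ms,
        degenerate=degenerate,
        sd_used_hz=sd,
    )


def psth_table(psth: PSTH, trace: ZScoredTrace, unit_id: str) -> pd.DataFrame:
    """Tidy export: unit_id, bin_start_ms, mean_hz, sd_hz, z."""
    return pd.DataFrame({
        "unit_id": unit_id,
        "bin_start_ms": psth.bin_starts_ms,
        "mean_hz": psth.mean_rate,
        "sd_hz": psth.sd_rate,
        "z": trace.z,
    })
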