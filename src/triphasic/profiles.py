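"""Parametric evoked-rate model and inhomogeneous-Poisson spike sampling.

The generative stand-in for the triphasic evoked response is a small
piecewise rate function with one parameter per measured metric:

* baseline rate before stimulus onset;
* a linear rise from ``onset_latency`` to ``peak_latency``, a short
  plateau of ``peak_hold_ms`` at ``baseline + peak_amplitude``, then an
  exponential decay with time constant ``decay_tau`` (the plateau makes
  the configured amplitude commensurate with 5-ms bin measurements);
* multiplicative suppression (``baseline * suppression_fraction``)
  inside ``suppression_window``;
* a Gaussian rebound bump of height ``rebound_amplitude`` centred at
  ``rebound_latency`` after the suppression window, with compact
  support (±4 sigma) so that the rate returns exactly to baseline.

Rates are clipped at zero.  Spike trains are drawn from the profile by
thinning against the profile's declared ceiling, which yields an exact
inhomogeneous Poisson process.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Tuple

import numpy as np

REBOUND_SUPPORT_SIGMAS = 4.0


@dataclass(frozen=True)
class TriphasicRateProfile:
    """Triphasic evoked firing-rate profile (times in ms, rates in Hz).

    ``peak_amplitude`` and ``rebound_amplitude`` are elevations above
    baseline; ``suppression_fraction`` multiplies the baseline inside
    the suppression window.
    """

    baseline_rate: float
    onset_latency: float
    peak_amplitude: float
    peak_latency: float
    decay_tau: float
    suppression_window: Tuple[float, float]
    suppression_fraction: float
    rebound_latency: float
    rebound_amplitude: float
    rebound_sigma: float
    peak_hold_ms: float = 5.0

    def __post_init__(self) -> None:
        if min(self.baseline_rate, self.peak_amplitude,
               self.rebound_amplitude) < 0:
            raise ValueError("rate parameters must be non-negative")
        if not 0.0 <= self.suppression_fraction <= 1.0:
            raise ValueError("suppression_fraction must lie in [0, 1]")
        if self.decay_tau <= 0 or self.rebound_sigma <= 0:
            raise ValueError("decay_tau and rebound_sigma must be positive")
        if not self.onset_latency < self.peak_latency:
            raise ValueError("onset_latency must precede peak_latency")
        if not self.suppression_window[0] > self.peak_latency:
            raise ValueError("suppression must start after the peak")
        if not self.suppression_window[0] < self.suppression_window[1]:
            raise ValueError("suppression_window must be increasing")

    # -- derived quantities -------------------------------------------------

    @property
    def max_rate(self) -> float:
        """Upper bound on the rate, used as the thinning ceiling."""
        return max(self.baseline_rate + self.peak_amplitude,
                   self.baseline_rate + self.rebound_amplitude)

    @property
    def rebound_support(self) -> Tuple[float, float]:
        halfw = REBOUND_SUPPORT_SIGMAS * self.rebound_sigma
        return (self.rebound_latency - halfw, self.rebound_latency + halfw)

    def scaled(self, factor: float) -> "TriphasicRateProfile":
        """Scale the evoked (above-baseline) components by ``factor``."""
        return replace(
            self,
            peak_amplitude=self.peak_amplitude * factor,
            rebound_amplitude=self.rebound_amplitude * factor,
        )

    def rate(self, t_ms) -> np.ndarray:
        """Evaluate the profile at times ``t_ms`` (ms after stimulus)."""
        return evoked_rate_profile(self, t_ms)

    def baseline_only(self) -> "TriphasicRateProfile":
        return replace(self, peak_amplitude=0.0, suppression_fraction=1.0,
                       rebound_amplitude=0.0)


def evoked_rate_profile(params: TriphasicRateProfile, t_ms) -> np.ndarray:
    """Evaluate the piecewise triphasic rate at ``t_ms``.

    Returns the baseline rate before onset and beyond the rebound
    support; never negative.
    """
    t = np.asarray(t_ms, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    p = params
    rate = np.full(t.shape, p.baseline_rate)

    hold_end = p.peak_latency + p.peak_hold_ms
    supp_start, supp_end = p.suppression_window

    rising = (t >= p.onset_latency) & (t < p.peak_latency)
    rate[rising] = p.baseline_rate + p.peak_amplitude * (
        (t[rising] - p.onset_latency) / (p.peak_latency - p.onset_latency))

    holding = (t >= p.peak_latency) & (t < min(hold_end, supp_start))
    rate[holding] = p.baseline_rate + p.peak_amplitude

    decaying = (t >= hold_end) & (t < supp_start)
    rate[decaying] = p.baseline_rate + p.peak_amplitude * np.exp(
        -(t[decaying] - hold_end) / p.decay_tau)

    suppressed = (t >= supp_start) & (t < supp_end)
    rate[suppressed] = p.baseline_rate * p.suppression_fraction

    lo, hi = p.rebound_support
    rebound = (t >= supp_end) & (t >= lo) & (t <= hi)
    rate[rebound] = p.baseline_rate + p.rebound_amplitude * np.exp(
        -0.5 * ((t[rebound] - p.rebound_latency) / p.rebound_sigma) ** 2)

    np.clip(rate, 0.0, None, out=rate)
    return rate if rate.ndim else float(rate)


def simulate_spike_train(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    duration_s: float,
    rng: np.random.Generator,
    rate_ceiling_hz: float,
) -> np.ndarray:
    """Draw one inhomogeneous-Poisson spike train by thinning.

    ``rate_fn`` maps times in seconds to rates in Hz and must be
    bounded above by ``rate_ceiling_hz``; a candidate homogeneous train
    at the ceiling rate is thinned with probability ``rate/ceiling``.
    Returns strictly increasing times in ``[0, duration_s)``.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if not np.isfinite(rate_ceiling_hz) or rate_ceiling_hz < 0:
        raise ValueError("rate ceiling must be finite and non-negative")
    if rate_ceiling_hz == 0:
        return np.empty(0)
    n_cand = rng.poisson(rate_ceiling_hz * duration_s)
    cand = np.sort(rng.uniform(0.0, duration_s, size=n_cand))
    rates = np.asarray(rate_fn(cand), dtype=float)
    if np.any(rates > rate_ceiling_hz * (1 + 1e-9)):
        raise ValueError("rate_fn exceeds the declared ceiling")
    keep = rng.uniform(0.0, rate_ceiling_hz, size=n_cand) < rates
    spikes = cand[keep]
    # microsecond grid: keeps text serialization lossless; drop collisions
    spikes = np.unique(np.round(spikes, 6))
    return spikes
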