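"""Synthetic recording sessions with known ground truth.

The generator emulates the statistical structure of awake paired S1/M1
probe recordings during brief ("phototactile") hand stimulation: low
baseline rates (~1.2 Hz in S1, ~0.6 Hz in M1), a responsive subset of
units with triphasic evoked profiles whose presets come from the
measured grand averages (onset 14.7/24.3 ms, peak amplitude 83.0/25.8
Hz, suppression to ~8 % of baseline in 110-170 ms, rebound ~31/20 Hz
near 289/275 ms), blocks of 25 trials at 1 s inter-stimulus interval,
and the special protocols: PV opto-tag blocks with sham events,
paired-pulse blocks (lags 150/250/350 ms), and hand + cortex
"silencing" blocks.

Between-unit heterogeneity is lognormal (mean-preserving) on
amplitudes and baseline rates and Gaussian (clipped) on latencies,
which produces realistically skewed amplitude distributions.  Every
generated unit carries exactly one ground-truth record.  Spike trains
are exact inhomogeneous Poisson draws (thinning); trial-to-trial
over-dispersion beyond Poisson is deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .io import Cohort, RecordingSession, StimulusEvent, Unit
from .profiles import TriphasicRateProfile, simulate_spike_train

SeedLike = Union[int, np.random.SeedSequence]


# ---------------------------------------------------------------------------
# presets: grand-average response parameters per area

S1_PROFILE = TriphasicRateProfile(
    baseline_rate=1.2,
    onset_latency=14.7,
    peak_amplitude=83.0,
    peak_latency=21.4,
    decay_tau=7.0,          # reproduces the ~27 ms measured duration
    suppression_window=(110.0, 170.0),
    suppression_fraction=0.082,
    rebound_latency=289.0,
    rebound_amplitude=31.4,
    rebound_sigma=30.0,
)

M1_PROFILE = TriphasicRateProfile(
    baseline_rate=0.6,
    onset_latency=24.3,
    peak_amplitude=25.8,
    peak_latency=31.2,
    decay_tau=9.0,          # reproduces the ~22 ms measured duration
    suppression_window=(110.0, 170.0),
    suppression_fraction=0.056,
    rebound_latency=274.7,
    rebound_amplitude=20.2,
    rebound_sigma=30.0,
)


@dataclass(frozen=True)
class UnitJitter:
    """Between-unit heterogeneity scales.

    Amplitudes and baselines get mean-preserving lognormal multipliers
    (``exp(N(-s^2/2, s))``); latencies get a common Gaussian shift
    clipped at ``latency_clip_ms``.
    """

    amplitude_sigma: float = 0.5
    baseline_sigma: float = 0.4
    latency_sd_ms: float = 2.5
    latency_clip_ms: float = 5.0


@dataclass(frozen=True)
class PopulationSpec:
    """One probe's unit population.

    ``responsive_fraction`` etc. are expectations: each unit draws its
    labels independently.  ``suppressed_fraction`` / ``rebound_fraction``
    are conditional on being responsive.  Depths are Beta-distributed
    over normalized cortical depth and modulate evoked amplitude via a
    Gaussian laminar bias (mean-normalized, so the population-average
    amplitude stays at the preset).
    """

    n_units: int = 40
    area: str = "S1"
    profile: TriphasicRateProfile = S1_PROFILE
    responsive_fraction: float = 0.367
    suppressed_fraction: float = 0.223
    rebound_fraction: float = 0.309
    pv_fraction: float = 0.47
    single_fraction: float = 0.30
    jitter: UnitJitter = UnitJitter()
    depth_beta_ab: Tuple[float, float] = (2.0, 2.0)
    depth_bias_center: float = 0.5
    depth_bias_width: float = 0.18
    depth_bias_gain: float = 0.8

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        for name in ("responsive_fraction", "suppressed_fraction",
                     "rebound_fraction", "pv_fraction", "single_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


def s1_population(**overrides) -> PopulationSpec:
    return replace(PopulationSpec(), **overrides)


def m1_population(**overrides) -> PopulationSpec:
    base = PopulationSpec(
        area="M1", profile=M1_PROFILE, responsive_fraction=0.256,
        suppressed_fraction=0.084, rebound_fraction=0.081,
        depth_bias_center=0.30, depth_bias_width=0.15)
    return replace(base, **overrides)


@dataclass(frozen=True)
class ProtocolSpec:
    """Stimulation block layout.

    A block is ``n_trials`` events of ``stimulus_kind`` starting at
    ``lead_in_s`` with spacing ``inter_stimulus_interval``.
    ``second_pulse_lag_ms`` must be present iff the kind is
    ``paired_pulse``.
    """

    n_trials: int = 25
    inter_stimulus_interval: float = 1.0
    stimulus_kind: str = "hand"
    stimulus_duration_ms: float = 5.0
    intensity_mw: float = 5.0
    lead_in_s: float = 2.0
    second_pulse_lag_ms: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        kinds = ("hand", "cortical", "hand_plus_cortical", "sham",
                 "hand_off_bar", "paired_pulse")
        if self.stimulus_kind not in kinds:
            raise ValueError(f"unknown stimulus kind {self.stimulus_kind!r}")
        if (self.second_pulse_lag_ms is not None) != (
                self.stimulus_kind == "paired_pulse"):
            raise ValueError(
                "second_pulse_lag_ms must be given iff kind is paired_pulse")


@dataclass
class GroundTruthRecord:
    unit_id: str
    area: str
    normalized_depth: float
    is_pv: bool
    responsive: bool
    suppressed: bool
    rebounding: bool
    profile: TriphasicRateProfile


@dataclass
class SyntheticGroundTruth:
    """Per-unit true profiles and labels for one simulated session."""

    records: List[GroundTruthRecord]
    seed_entropy: int

    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append({
                "unit_id": r.unit_id, "area": r.area,
                "normalized_depth": r.normalized_depth,
                "is_pv": r.is_pv, "responsive": r.responsive,
                "suppressed": r.suppressed, "rebounding": r.rebounding,
                "baseline_hz": r.profile.baseline_rate,
                "peak_amplitude_hz": r.profile.peak_amplitude,
                "onset_latency_ms": r.profile.onset_latency,
                "peak_latency_ms": r.profile.peak_latency,
                "suppression_fraction": r.profile.suppression_fraction,
                "rebound_amplitude_hz": r.profile.rebound_amplitude,
                "rebound_latency_ms": r.profile.rebound_latency,
            })
        return pd.DataFrame(rows)

    def by_unit(self) -> Dict[str, GroundTruthRecord]:
        return {r.unit_id: r for r in self.records}


# ---------------------------------------------------------------------------
# unit synthesis


def _seed_sequence(seed: SeedLike) -> np.random.SeedSequence:
    if seed is None:
        raise ValueError("a seed is mandatory: synthetic sessions must be "
                         "reproducible")
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(int(seed))


def _lognormal_mult(rng: np.random.Generator, sigma: float) -> float:
    """Mean-preserving lognormal multiplier."""
    if sigma == 0:
        return 1.0
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def _depth_bias(pop: PopulationSpec, depth: float) -> float:
    g, c, w = pop.depth_bias_gain, pop.depth_bias_center, pop.depth_bias_width
    return 1.0 + g * math.exp(-0.5 * ((depth - c) / w) ** 2)


def _depth_bias_norm(pop: PopulationSpec) -> float:
    """Population mean of the laminar bias under the depth Beta law."""
    from scipy import stats as sps

    d = np.linspace(0.0, 1.0, 501)
    pdf = sps.beta.pdf(d, *pop.depth_beta_ab)
    bias = 1.0 + pop.depth_bias_gain * np.exp(
        -0.5 * ((d - pop.depth_bias_center) / pop.depth_bias_width) ** 2)
    return float(np.trapezoid(bias * pdf, d) / np.trapezoid(pdf, d))


def draw_unit_truth(pop: PopulationSpec, unit_id: str,
                    rng: np.random.Generator,
                    bias_norm: Optional[float] = None) -> GroundTruthRecord:
    """Draw one unit's ground-truth labels and jittered profile."""
    if bias_norm is None:
        bias_norm = _depth_bias_norm(pop)
    j = pop.jitter
    # microsecond-style grid keeps the TSV round trip lossless
    depth = float(np.round(rng.beta(*pop.depth_beta_ab), 6))
    is_pv = rng.random() < pop.pv_fraction
    responsive = rng.random() < pop.responsive_fraction
    suppressed = responsive and rng.random() < pop.suppressed_fraction
    rebounding = responsive and rng.random() < pop.rebound_fraction

    base = pop.profile.baseline_rate * _lognormal_mult(rng, j.baseline_sigma)
    amp_mult = (_lognormal_mult(rng, j.amplitude_sigma)
                * _depth_bias(pop, depth) / bias_norm)
    reb_mult = _lognormal_mult(rng, j.amplitude_sigma)
    shift = float(np.clip(rng.normal(0.0, j.latency_sd_ms),
                          -j.latency_clip_ms, j.latency_clip_ms))

    profile = replace(
        pop.profile,
        baseline_rate=base,
        onset_latency=pop.profile.onset_latency + shift,
        peak_latency=pop.profile.peak_latency + shift,
        peak_amplitude=(pop.profile.peak_amplitude * amp_mult
                        if responsive else 0.0),
        suppression_fraction=(pop.profile.suppression_fraction
                              if suppressed else 1.0),
        rebound_amplitude=(pop.profile.rebound_amplitude * reb_mult
                           if rebounding else 0.0),
        rebound_latency=pop.profile.rebound_latency + shift,
    )
    return GroundTruthRecord(
        unit_id=unit_id, area=pop.area, normalized_depth=depth,
        is_pv=is_pv, responsive=responsive, suppressed=suppressed,
        rebounding=rebounding, profile=profile)


# ---------------------------------------------------------------------------
# composing session rate functions


def _effect_support_ms(profile: TriphasicRateProfile) -> float:
    tail = profile.peak_latency + profile.peak_hold_ms + 8.0 * profile.decay_tau
    return max(tail, profile.suppression_window[1], profile.rebound_support[1])


@dataclass
class _Effect:
    """One event's evoked contribution for one unit."""

    t_event_s: float
    profile: TriphasicRateProfile

    @property
    def end_s(self) -> float:
        return self.t_event_s + _effect_support_ms(self.profile) / 1000.0


def _session_rate_fn(baseline_hz: float, effects: Sequence[_Effect]):
    """Rate(t) with later events overriding earlier ones in overlap."""
    starts = np.array([e.t_event_s for e in effects])

    def rate(t_s: np.ndarray) -> np.ndarray:
        t = np.asarray(t_s, dtype=float)
        out = np.full(t.shape, baseline_hz)
        if starts.size == 0:
            return out
        # index of the most recent effect at or before t
        idx = np.searchsorted(starts, t, side="right") - 1
        for k, eff in enumerate(effects):
            sel = (idx == k) & (t < eff.end_s)
            if sel.any():
                out[sel] = eff.profile.rate((t[sel] - eff.t_event_s) * 1000.0)
        return out

    return rate


def _ceiling(baseline_hz: float, effects: Sequence[_Effect]) -> float:
    m = baseline_hz
    for e in effects:
        m = max(m, e.profile.max_rate)
    return m


def _simulate_unit(truth: GroundTruthRecord, effects: Sequence[_Effect],
                   duration_s: float, rng: np.random.Generator) -> np.ndarray:
    base = truth.profile.baseline_rate
    fn = _session_rate_fn(base, effects)
    return simulate_spike_train(fn, duration_s, rng, _ceiling(base, effects))


def _event_defaults(kind: str) -> Tuple[float, float, bool]:
    """(duration_ms, intensity_mw, hand_on_bar) per stimulus kind."""
    if kind in ("hand", "hand_plus_cortical"):
        return 5.0, 5.0, True
    if kind == "hand_off_bar":
        return 5.0, 5.0, False
    if kind == "cortical":
        return 20.0, 1.0, True
    return 5.0, 0.0, True  # sham: light off


# ---------------------------------------------------------------------------
# session / cohort generators


def simulate_session(pop: PopulationSpec, protocol: ProtocolSpec,
                     seed: SeedLike
                     ) -> Tuple[RecordingSession, SyntheticGroundTruth]:
    """Simulate one probe recording under a plain single-pulse protocol.

    ``hand`` events drive the evoked profile of responsive units;
    ``sham`` and ``hand_off_bar`` events leave every unit at baseline.
    Use :func:`simulate_special_blocks` for opto-tag, paired-pulse and
    silencing protocols.
    """
    if protocol.stimulus_kind == "paired_pulse":
        raise ValueError("use simulate_special_blocks for paired_pulse")
    ss = _seed_sequence(seed)
    rng = np.random.default_rng(ss)

    kind = protocol.stimulus_kind
    dur, mw, on_bar = _event_defaults(kind)
    ev_kind = "hand_off_bar" if kind == "hand_off_bar" else kind
    times = protocol.lead_in_s + protocol.inter_stimulus_interval * np.arange(
        protocol.n_trials)
    events = [StimulusEvent(time=float(t), kind=ev_kind, duration_ms=dur,
                            intensity_mw=mw, hand_on_bar=on_bar)
              for t in times]
    evoking = kind in ("hand", "hand_plus_cortical")
    duration = (protocol.lead_in_s + protocol.n_trials
                * protocol.inter_stimulus_interval + 1.0)

    bias_norm = _depth_bias_norm(pop)
    units, records = [], []
    for i in range(pop.n_units):
        uid = f"{pop.area.lower()}u{i:03d}"
        truth = draw_unit_truth(pop, uid, rng, bias_norm)
        effects = ([_Effect(t, truth.profile) for t in times]
                   if (evoking and truth.responsive) else [])
        spikes = _simulate_unit(truth, effects, duration, rng)
        units.append(Unit(
            unit_id=uid, area=pop.area, channel=i, spike_times=spikes,
            depth_um=float(np.round(truth.normalized_depth * 1400.0, 6)),
            normalized_depth=truth.normalized_depth,
            unit_type="single" if rng.random() < pop.single_fraction
            else "multi"))
        records.append(truth)

    session = RecordingSession(
        session_id=f"sim-{pop.area}-{ss.entropy}",
        animal_id=f"mouse{ss.entropy % 1000:03d}",
        area=pop.area, units=units, events=events)
    return session, SyntheticGroundTruth(records, int(ss.entropy))


def simulate_cohort(n_recordings: int = 13,
                    s1: Optional[PopulationSpec] = None,
                    m1: Optional[PopulationSpec] = None,
                    protocol: Optional[ProtocolSpec] = None,
                    seed: SeedLike = None,
                    n_animals: int = 9):
    """Simulate a cohort of paired S1 + M1 recordings.

    Child seeds are spawned per recording index, so extending the
    cohort leaves earlier recordings bit-identical.  Returns
    ``(Cohort, list of (S1 truth, M1 truth))``.
    """
    if n_recordings < 1:
        raise ValueError("n_recordings must be >= 1")
    s1 = s1 or s1_population()
    m1 = m1 or m1_population()
    protocol = protocol or ProtocolSpec()
    ss = _seed_sequence(seed)
    children = ss.spawn(n_recordings)

    pairs, truths = [], []
    for k, child in enumerate(children):
        ss_s1, ss_m1 = child.spawn(2)
        sess_s1, gt_s1 = simulate_session(s1, protocol, ss_s1)
        sess_m1, gt_m1 = simulate_session(m1, protocol, ss_m1)
        animal = f"mouse{k % n_animals:03d}"
        for sess, area in ((sess_s1, "S1"), (sess_m1, "M1")):
            sess.session_id = f"rec{k:02d}-{area}"
            sess.animal_id = animal
        pairs.append((sess_s1, sess_m1))
        truths.append((gt_s1, gt_m1))
    return Cohort(pairs), truths


# ---------------------------------------------------------------------------
# special protocol blocks


@dataclass(frozen=True)
class OptoTagSpec:
    """PV opto-tag block parameters (20-ms light pulses + sham)."""

    pv_opto_rate_hz: float = 150.0
    pv_opto_latency_ms: float = 1.0
    nonpv_suppression_fraction: float = 0.1
    nonpv_suppression_window_ms: Tuple[float, float] = (2.0, 60.0)


@dataclass(frozen=True)
class SilencingSpec:
    """Hand + cortex silencing block: evoked attenuation on combined trials."""

    attenuation: float = 0.7
    pv_attenuation: Optional[float] = None  # defaults to `attenuation`


@dataclass(frozen=True)
class PairedPulseSpec:
    """Paired-pulse block: per-lag second-pulse amplitude scaling."""

    lags_ms: Tuple[float, ...] = (150.0, 250.0, 350.0)
    scaling: Tuple[float, ...] = (0.5, 1.0, 1.0)
    trial_spacing_s: float = 1.5


def _opto_profile(base_hz: float, spec: OptoTagSpec, pv: bool,
                  pulse_ms: float) -> TriphasicRateProfile:
    """Evoked profile during a cortical light pulse.

    PV units fire a sustained barrage for the pulse duration; non-PV
    units are transiently silenced by the evoked GABAergic inhibition.
    Modelled with the same piecewise machinery (no rebound term).
    """
    if pv:
        lat = spec.pv_opto_latency_ms
        return TriphasicRateProfile(
            baseline_rate=base_hz, onset_latency=lat,
            peak_amplitude=spec.pv_opto_rate_hz, peak_latency=lat + 0.5,
            peak_hold_ms=pulse_ms - 0.5, decay_tau=1.0,
            suppression_window=(pulse_ms + 2.0, pulse_ms + 3.0),
            suppression_fraction=1.0,
            rebound_latency=pulse_ms + 10.0, rebound_amplitude=0.0,
            rebound_sigma=5.0)
    lo, hi = spec.nonpv_suppression_window_ms
    return TriphasicRateProfile(
        baseline_rate=base_hz, onset_latency=0.5, peak_amplitude=0.0,
        peak_latency=1.0, peak_hold_ms=0.5, decay_tau=1.0,
        suppression_window=(lo, hi),
        suppression_fraction=spec.nonpv_suppression_fraction,
        rebound_latency=hi + 40.0, rebound_amplitude=0.0, rebound_sigma=10.0)


def simulate_special_blocks(kind: str, pop: PopulationSpec,
                            seed: SeedLike,
                            protocol: Optional[ProtocolSpec] = None,
                            opto: OptoTagSpec = OptoTagSpec(),
                            silencing: SilencingSpec = SilencingSpec(),
                            paired: PairedPulseSpec = PairedPulseSpec(),
                            ) -> Tuple[RecordingSession, SyntheticGroundTruth]:
    """Simulate an opto-tag, silencing, or paired-pulse block.

    * ``optotag``: alternating 20-ms laser pulses (kind ``cortical``)
      and laser-off ``sham`` events; PV units respond with short-latency
      sustained firing, non-PV units are suppressed.
    * ``silencing``: interleaved ``hand`` / ``cortical`` /
      ``hand_plus_cortical`` trials (27 each); on combined trials the
      hand-evoked profile is scaled by the configured attenuation.
    * ``paired_pulse``: interleaved single-pulse trials and pairs at
      each configured lag; the second pulse's evoked profile is scaled
      by the per-lag factor.
    """
    if kind not in ("optotag", "silencing", "paired_pulse"):
        raise ValueError(f"unknown special block kind {kind!r}")
    ss = _seed_sequence(seed)
    rng = np.random.default_rng(ss)
    bias_norm = _depth_bias_norm(pop)

    # ---- event layout -----------------------------------------------------
    events: List[StimulusEvent] = []
    if kind == "optotag":
        # 25 laser pulses, then sham events at the same cadence, laser off
        proto = protocol or ProtocolSpec(stimulus_kind="cortical",
                                         stimulus_duration_ms=20.0,
                                         intensity_mw=1.0)
        pulse_ms = proto.stimulus_duration_ms
        for k in range(2 * proto.n_trials):
            t = proto.lead_in_s + k * proto.inter_stimulus_interval
            ev_kind = "cortical" if k < proto.n_trials else "sham"
            dur = pulse_ms if ev_kind == "cortical" else 5.0
            mw = proto.intensity_mw if ev_kind == "cortical" else 0.0
            events.append(StimulusEvent(time=float(t), kind=ev_kind,
                                        duration_ms=dur, intensity_mw=mw,
                                        hand_on_bar=False))
    elif kind == "silencing":
        proto = protocol or ProtocolSpec(n_trials=27)
        cycle = ("hand", "cortical", "hand_plus_cortical")
        for k in range(3 * proto.n_trials):
            t = proto.lead_in_s + k * proto.inter_stimulus_interval
            ckind = cycle[k % 3]
            dur, mw, on_bar = _event_defaults(ckind)
            events.append(StimulusEvent(time=float(t), kind=ckind,
                                        duration_ms=dur, intensity_mw=mw,
                                        hand_on_bar=on_bar))
    else:  # paired_pulse
        proto = protocol or ProtocolSpec(n_trials=28)
        conditions = [None] + list(paired.lags_ms)
        for k in range(proto.n_trials):
            t = proto.lead_in_s + k * paired.trial_spacing_s
            lag = conditions[k % len(conditions)]
            events.append(StimulusEvent(time=float(t), kind="hand"))
            if lag is not None:
                events.append(StimulusEvent(
                    time=float(t + lag / 1000.0), kind="paired_pulse_second",
                    lag_ms=float(lag)))
    duration = events[-1].time + 1.5

    # ---- unit responses ---------------------------------------------------
    scale_by_lag = dict(zip(paired.lags_ms, paired.scaling))
    pv_att = (silencing.pv_attenuation if silencing.pv_attenuation is not None
              else silencing.attenuation)

    units, records = [], []
    for i in range(pop.n_units):
        uid = f"{pop.area.lower()}u{i:03d}"
        truth = draw_unit_truth(pop, uid, rng, bias_norm)
        base = truth.profile.baseline_rate
        effects: List[_Effect] = []
        for e in events:
            if kind == "optotag":
                if e.kind == "cortical":
                    effects.append(_Effect(e.time, _opto_profile(
                        base, opto, truth.is_pv, e.duration_ms)))
            elif kind == "silencing":
                if e.kind == "hand" and truth.responsive:
                    effects.append(_Effect(e.time, truth.profile))
                elif e.kind == "cortical":
                    effects.append(_Effect(e.time, _opto_profile(
                        base, opto, truth.is_pv, 20.0)))
                elif e.kind == "hand_plus_cortical" and truth.responsive:
                    att = pv_att if truth.is_pv else silencing.attenuation
                    effects.append(_Effect(e.time, truth.profile.scaled(att)))
            else:  # paired_pulse
                if not truth.responsive:
                    continue
                if e.kind == "hand":
                    effects.append(_Effect(e.time, truth.profile))
                elif e.kind == "paired_pulse_second":
                    effects.append(_Effect(
                        e.time, truth.profile.scaled(scale_by_lag[e.lag_ms])))
        spikes = _simulate_unit(truth, effects, duration, rng)
        units.append(Unit(
            unit_id=uid, area=pop.area, channel=i, spike_times=spikes,
            depth_um=float(np.round(truth.normalized_depth * 1400.0, 6)),
            normalized_depth=truth.normalized_depth,
            unit_type="single" if rng.random() < pop.single_fraction
            else "multi"))
        records.append(truth)

    session = RecordingSession(
        session_id=f"sim-{kind}-{pop.area}-{ss.entropy}",
        animal_id=f"mouse{ss.entropy % 1000:03d}",
        area=pop.area, units=units, events=events)
    return session, SyntheticGroundTruth(records, int(ss.entropy))


# ---------------------------------------------------------------------------
# declarative generator configuration


def population_from_dict(d: dict) -> PopulationSpec:
    d = dict(d)
    area = d.get("area", "S1")
    base = s1_population() if area == "S1" else m1_population()
    profile_over = d.pop("profile", {})
    jitter_over = d.pop("jitter", {})
    spec = replace(base, **d)
    if profile_over:
        spec = replace(spec, profile=replace(spec.profile, **{
            k: (tuple(v) if isinstance(v, list) else v)
            for k, v in profile_over.items()}))
    if jitter_over:
        spec = replace(spec, jitter=replace(spec.jitter, **jitter_over))
    return spec


def load_generator_config(path) -> dict:
    """Load a YAML generator config into spec objects.

    Recognized top-level keys: ``seed``, ``n_recordings``, ``s1``,
    ``m1`` (population mappings), ``protocol``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {"seed": raw.get("seed"),
           "n_recordings": raw.get("n_recordings", 13)}
    out["s1"] = population_from_dict({"area": "S1", **raw.get("s1", {})})
    out["m1"] = population_from_dict({"area": "M1", **raw.get("m1", {})})
    out["protocol"] = ProtocolSpec(**raw.get("protocol", {}))
    return out
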