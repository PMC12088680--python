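"""Protocol-level analyses and the end-to-end pipeline.

Covers per-unit session analysis, effective propagation speed,
paired-pulse excitability, partial-silencing quantification (integral
firing rate 15-50 ms), the video motion index, and ``run_pipeline``,
which chains generate -> load -> PSTH -> metrics -> phases -> summary
-> grand averages and writes tables plus a machine-readable JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import AnalysisConfig, DEFAULT_CONFIG
from .io import (Cohort, RecordingSession, write_session_bundle)
from .laminar import laminar_profile
from .optotag import OptoTagResult
from .phases import rebound_metrics, suppression_metrics
from .psth import (PSTH, baseline_stats, psth_from_spikes, zscore_psth)
from .response import response_metrics
from .stats import (bh_adjust, compare_paired, friedman_dunn_sidak,
                    grand_average, summarize_experiment)


# ---------------------------------------------------------------------------
# per-session unit analysis


def analyze_session(session: RecordingSession,
                    config: AnalysisConfig = DEFAULT_CONFIG,
                    event_kinds: Sequence[str] = ("hand",),
                    recording_id: Optional[str] = None) -> pd.DataFrame:
    """Per-unit metrics table for one session, one row per unit.

    Aligns every unit to the events of ``event_kinds``, computes the
    PSTH, baseline statistics, responsiveness, initial-peak metrics,
    and the suppression/rebound phase metrics.  Laminar amplitude
    columns (peak-bin ± 2 bins; rebound window mean minus baseline)
    are filled for units showing the respective phase.
    """
    events = session.event_times(*event_kinds)
    if events.size == 0:
        raise ValueError(f"session has no events of kinds {event_kinds}")
    rows = []
    half_bins = config.laminar_peak_halfwidth_bins
    for unit in session.units:
        psth = psth_from_spikes(unit.spike_times, events, config)
        base = baseline_stats(psth, config)
        trace = zscore_psth(psth, base, config)
        resp = response_metrics(psth, trace, config)
        supp = suppression_metrics(psth, base, config)
        reb = rebound_metrics(psth, base, config)

        laminar_peak = np.nan
        if resp.responsive:
            i_peak = int(np.searchsorted(psth.bin_starts_ms,
                                         resp.peak_latency_ms))
            lo = max(0, i_peak - half_bins)
            hi = min(psth.n_bins, i_peak + half_bins + 1)
            laminar_peak = float(trace.baseline_subtracted[lo:hi].mean())
        laminar_reb = (reb.rebound_amplitude_hz - base.mean
                       if reb.rebounding else np.nan)

        def _f(v):
            return np.nan if v is None else v

        rows.append({
            "recording_id": recording_id or session.session_id,
            "unit_id": unit.unit_id,
            "area": unit.area,
            "unit_type": unit.unit_type,
            "normalized_depth": unit.normalized_depth,
            "n_trials": psth.n_trials,
            "baseline_hz": base.mean,
            "baseline_sd_hz": base.sd,
            "degenerate_baseline": trace.degenerate,
            "responsive": resp.responsive,
            "onset_latency_ms": _f(resp.onset_latency_ms),
            "peak_latency_ms": _f(resp.peak_latency_ms),
            "peak_amplitude_hz": _f(resp.peak_amplitude_hz),
            "duration_ms": _f(resp.duration_ms),
            "duration_censored": resp.duration_censored,
            "suppressed": supp.suppressed,
            "suppression_rate_hz": supp.suppression_rate_hz,
            "suppression_pct_baseline": _f(supp.suppression_pct_baseline),
            "suppression_p": _f(supp.p_value),
            "rebounding": reb.rebounding,
            "rebound_amplitude_hz": reb.rebound_amplitude_hz,
            "rebound_amplitude_above_baseline_hz":
                reb.rebound_amplitude_hz - base.mean,
            "rebound_latency_ms": reb.rebound_latency_ms,
            "rebound_p": _f(reb.p_value),
            "laminar_peak_amp_hz": laminar_peak,
            "laminar_rebound_amp_hz": laminar_reb,
        })
    return pd.DataFrame(rows)


def analyze_cohort(cohort: Cohort, config: AnalysisConfig = DEFAULT_CONFIG,
                   event_kinds: Sequence[str] = ("hand",)):
    """Unit tables, per-recording summaries and grand averages per area.

    Returns ``(unit_df, summary_df, grand_df)`` where ``grand_df`` is
    indexed by (area, metric).
    """
    unit_tables, summaries = [], []
    for s1, m1 in cohort:
        for sess in (s1, m1):
            rec = sess.session_id
            df = analyze_session(sess, config, event_kinds, recording_id=rec)
            unit_tables.append(df)
            summ = summarize_experiment(df, rec)
            summ["area"] = sess.area
            summaries.append(summ)
    unit_df = pd.concat(unit_tables, ignore_index=True)
    summary_df = pd.DataFrame(summaries)
    grands = []
    for area, grp in summary_df.groupby("area"):
        g = grand_average(grp)
        g["area"] = area
        grands.append(g.reset_index())
    grand_df = pd.concat(grands, ignore_index=True).set_index(
        ["area", "metric"])
    return unit_df, summary_df, grand_df


# ---------------------------------------------------------------------------
# propagation speed


HAND_TO_S1_DISTANCE_MM = 44.3  # palm -> C6 cord -> S1, morphometric estimate


def propagation_speed(distance_mm: float, latency_ms: float) -> float:
    """Effective propagation speed in m/s (mm and ms cancel to m/s)."""
    if distance_mm <= 0 or latency_ms <= 0:
        raise ValueError("distance and latency must be positive")
    return distance_mm / latency_ms


def cohort_propagation_speed(distances_mm, latencies_ms) -> Dict[str, object]:
    """Per-recording speeds with both aggregation conventions.

    Returns mean-of-ratios (primary), ratio-of-means, the per-recording
    speeds, and indices of recordings excluded for non-positive
    latency differences.
    """
    d = np.asarray(distances_mm, dtype=float)
    l = np.asarray(latencies_ms, dtype=float)
    if d.shape != l.shape:
        raise ValueError("distances and latencies must pair up")
    valid = l > 0
    speeds = np.full(l.shape, np.nan)
    speeds[valid] = d[valid] / l[valid]
    return {
        "speeds_m_per_s": speeds,
        "mean_of_ratios": float(np.nanmean(speeds)) if valid.any() else np.nan,
        "ratio_of_means": (float(d[valid].mean() / l[valid].mean())
                           if valid.any() else np.nan),
        "excluded": np.flatnonzero(~valid).tolist(),
    }


# ---------------------------------------------------------------------------
# paired-pulse analysis


@dataclass(frozen=True)
class PairedPulseResult:
    lag_ms: float
    first_peak_hz: float
    second_peak_hz: float
    normalized_second: float
    n_trials: int


def _population_peak(session: RecordingSession, unit_ids: Set[str],
                     align_times: np.ndarray, baseline_times: np.ndarray,
                     config: AnalysisConfig) -> float:
    """Peak of the responsive-population mean baseline-subtracted PSTH."""
    traces = []
    for unit in session.units:
        if unit.unit_id not in unit_ids:
            continue
        psth = psth_from_spikes(unit.spike_times, align_times, config)
        base_psth = psth_from_spikes(unit.spike_times, baseline_times, config)
        base = baseline_stats(base_psth, config)
        traces.append(psth.mean_rate - base.mean)
    pop = np.mean(traces, axis=0)
    starts = config.bin_edges_ms()[:-1]
    lo, hi = config.peak_window_ms
    mask = (starts >= lo) & (starts < hi)
    return float(np.max(pop[mask]))


def paired_pulse_analysis(session: RecordingSession,
                          config: AnalysisConfig = DEFAULT_CONFIG
                          ) -> List[PairedPulseResult]:
    """Second-pulse peak amplitude, normalized to the first pulse.

    The second-pulse response is measured in the standard peak window
    re-aligned to the second pulse; its baseline is taken from the
    pre-*first*-pulse window of the corresponding trials.  Lags present
    in the event table define the conditions; missing lags are simply
    absent.  Lags shorter than the peak window are an error (the first
    and second analysis windows would overlap).
    """
    import warnings

    first_times = session.event_times("hand")
    second = [e for e in session.events if e.kind == "paired_pulse_second"]
    if first_times.size == 0:
        raise ValueError("no first-pulse events")
    lags = sorted({e.lag_ms for e in second})
    for lag in lags:
        if lag < config.peak_window_ms[1]:
            raise ValueError(f"lag {lag} ms overlaps the peak window")

    unit_df = analyze_session(session, config, ("hand",))
    resp_ids = set(unit_df.loc[unit_df["responsive"], "unit_id"])
    if not resp_ids:
        raise ValueError("no responsive units on the first pulse")

    # restrict first-pulse amplitude to single-pulse trials when possible
    paired_firsts = {round(e.time - e.lag_ms / 1000.0, 6) for e in second}
    single_firsts = np.array(
        [t for t in first_times if round(t, 6) not in paired_firsts])
    ref_times = single_firsts if single_firsts.size else first_times
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        first_peak = _population_peak(session, resp_ids, ref_times,
                                      ref_times, config)
        results = []
        for lag in lags:
            sec_times = np.array([e.time for e in second if e.lag_ms == lag])
            base_times = sec_times - lag / 1000.0
            second_peak = _population_peak(session, resp_ids, sec_times,
                                           base_times, config)
            results.append(PairedPulseResult(
                lag_ms=float(lag),
                first_peak_hz=first_peak,
                second_peak_hz=second_peak,
                normalized_second=second_peak / first_peak,
                n_trials=len(sec_times),
            ))
    return results


def paired_pulse_cohort_test(per_recording: Sequence[Sequence[float]],
                             config: AnalysisConfig = DEFAULT_CONFIG):
    """Friedman + Dunn-Sidak across (first, lag...) amplitude conditions.

    ``per_recording`` is recordings x conditions (first pulse plus one
    column per lag).
    """
    return friedman_dunn_sidak(np.asarray(per_recording, float), config)


# ---------------------------------------------------------------------------
# silencing analysis (integral firing rate 15-50 ms)


def integral_firing_rate(psth: PSTH, config: AnalysisConfig = DEFAULT_CONFIG,
                         baseline: Optional[float] = None) -> float:
    """Integral of the trial-averaged rate over the integral window, Hz*ms.

    Rectangle rule over 5-ms bins, window half-open.  With ``baseline``
    given, the trace is baseline-subtracted first.
    """
    mask = psth.bin_mask_ms(config.integral_window_ms)
    trace = psth.mean_rate - (baseline or 0.0)
    return float(trace[mask].sum() * config.bin_ms)


def silencing_analysis(sessions, tags_by_session=None,
                       config: AnalysisConfig = DEFAULT_CONFIG
                       ) -> pd.DataFrame:
    """Hand vs hand+cortex integral-FR comparison per recording.

    For each session the stimulus-responsive set is defined on the
    hand-alone condition; per unit, the integral of the trial-averaged
    firing rate over 15-50 ms is computed for the ``hand`` and
    ``hand_plus_cortical`` conditions (raw, matching the positive
    printed integrals; a baseline-subtracted copy is also emitted).
    Population means, their ratio (%), a per-recording signed-rank
    across units, and BH adjustment over the recording-level p family
    are returned, stratified all/PV/non-PV when tags are provided.
    """
    import warnings

    if tags_by_session is None:
        tags_by_session = [None] * len(sessions)
    rows = []
    for sess, tags in zip(sessions, tags_by_session):
        hand_t = sess.event_times("hand")
        comb_t = sess.event_times("hand_plus_cortical")
        if hand_t.size == 0 or comb_t.size == 0:
            raise ValueError(
                f"session {sess.session_id} lacks hand/hand+cortex events")
        unit_df = analyze_session(sess, config, ("hand",))
        resp_ids = set(unit_df.loc[unit_df["responsive"], "unit_id"])
        if not resp_ids:
            raise ValueError(f"no responsive units in {sess.session_id}")
        pv_ids = ({t.unit_id for t in tags if t.is_pv}
                  if tags is not None else set())

        per_unit = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for unit in sess.units:
                if unit.unit_id not in resp_ids:
                    continue
                h_psth = psth_from_spikes(unit.spike_times, hand_t, config)
                c_psth = psth_from_spikes(unit.spike_times, comb_t, config)
                h_base = baseline_stats(h_psth, config).mean
                c_base = baseline_stats(c_psth, config).mean
                per_unit.append({
                    "unit_id": unit.unit_id,
                    "is_pv": unit.unit_id in pv_ids,
                    "hand_int": integral_firing_rate(h_psth, config),
                    "combined_int": integral_firing_rate(c_psth, config),
                    "hand_int_sub": integral_firing_rate(h_psth, config, h_base),
                    "combined_int_sub": integral_firing_rate(c_psth, config,
                                                             c_base),
                })
        pu = pd.DataFrame(per_unit)

        groups = {"all": pu}
        if tags is not None:
            groups["pv"] = pu[pu["is_pv"]]
            groups["non_pv"] = pu[~pu["is_pv"]]
        for gname, g in groups.items():
            if len(g) == 0:
                continue
            hand_mean = g["hand_int"].mean()
            comb_mean = g["combined_int"].mean()
            if len(g) >= config.min_trials_signed_rank and not np.all(
                    g["hand_int"].values == g["combined_int"].values):
                from .phases import signed_rank_method

                d = (g["hand_int"] - g["combined_int"]).to_numpy()
                res = sps.wilcoxon(g["hand_int"], g["combined_int"],
                                   zero_method="wilcox",
                                   alternative="two-sided", correction=True,
                                   method=signed_rank_method(d[d != 0]))
                w, p = float(res.statistic), float(res.pvalue)
            else:
                w, p = np.nan, np.nan
            rows.append({
                "recording_id": sess.session_id,
                "group": gname,
                "n_units": len(g),
                "hand_int": hand_mean,
                "combined_int": comb_mean,
                "ratio_pct": 100.0 * comb_mean / hand_mean,
                "W": w,
                "p": p,
            })
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    has_p = out["p"].notna()
    if has_p.any():
        out.loc[has_p, "p_adj"] = bh_adjust(out.loc[has_p, "p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# video motion index


@dataclass(frozen=True)
class MotionIndexResult:
    per_trial: np.ndarray
    mean_index: float
    p_value: float


def motion_index(frames: np.ndarray, roi: Tuple[int, int, int, int],
                 event_frames: Sequence[int], fps: float = 1000.0,
                 baseline_ms: float = 100.0,
                 post_window_ms: Tuple[float, float] = (6.0, 100.0),
                 ) -> MotionIndexResult:
    """Stimulus-locked motion index from a grayscale frame stack.

    For each trial, every post-stimulus frame is differenced against
    the per-pixel average of the 100-ms pre-stimulus baseline; the
    index is the ROI-mean difference averaged over the 6-100 ms
    post-stimulus window (the LED-on frames before 6 ms are excluded).
    Tested across trials against zero with a signed-rank test.
    """
    frames = np.asarray(frames, dtype=float)
    n_frames, h, w = frames.shape
    x, y, rw, rh = roi
    if x < 0 or y < 0 or x + rw > w or y + rh > h or rw <= 0 or rh <= 0:
        raise ValueError("ROI lies outside the frame")
    base_n = int(round(baseline_ms * fps / 1000.0))
    lo = int(np.ceil(post_window_ms[0] * fps / 1000.0))
    hi = int(np.floor(post_window_ms[1] * fps / 1000.0))

    per_trial = []
    for ev in event_frames:
        if ev - base_n < 0 or ev + hi >= n_frames:
            raise ValueError(f"event frame {ev} lacks baseline/post frames")
        roi_frames = frames[:, y:y + rh, x:x + rw]
        baseline = roi_frames[ev - base_n:ev].mean(axis=0)
        post = roi_frames[ev + lo:ev + hi + 1]
        per_trial.append(float((post - baseline).mean()))
    per_trial = np.asarray(per_trial)
    nz = per_trial[per_trial != 0]
    if nz.size == 0:
        p = 1.0
    else:
        p = float(sps.wilcoxon(nz, alternative="two-sided",
                               method="auto").pvalue)
    return MotionIndexResult(per_trial=per_trial,
                             mean_index=float(per_trial.mean()), p_value=p)


# ---------------------------------------------------------------------------
# end-to-end pipeline


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: Union[str, Path, dict], out_dir: Union[str, Path],
                 analysis_config: AnalysisConfig = DEFAULT_CONFIG) -> dict:
    """Generate a synthetic cohort, analyze it, and write the report bundle.

    ``config`` is a generator configuration (YAML path or mapping; see
    :func:`triphasic.synth.load_generator_config`) and must carry a
    seed.  Writes session bundles, the per-unit metrics table, the
    per-recording summaries, grand averages, and ``results.json``;
    returns the results dictionary.  Identical seeds produce identical
    outputs, byte for byte.
    """
    from . import synth

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        if isinstance(config, (str, Path)):
            gen = synth.load_generator_config(config)
        else:
            raw = dict(config)
            gen = {
                "seed": raw.get("seed"),
                "n_recordings": raw.get("n_recordings", 13),
                "s1": synth.population_from_dict(
                    {"area": "S1", **raw.get("s1", {})}),
                "m1": synth.population_from_dict(
                    {"area": "M1", **raw.get("m1", {})}),
                "protocol": synth.ProtocolSpec(**raw.get("protocol", {})),
            }
        if gen["seed"] is None:
            raise ValueError("generator config must set a seed")
    except Exception as exc:
        raise PipelineError(f"config: {exc}") from exc

    try:
        cohort, truths = synth.simulate_cohort(
            n_recordings=gen["n_recordings"], s1=gen["s1"], m1=gen["m1"],
            protocol=gen["protocol"], seed=gen["seed"])
    except Exception as exc:
        raise PipelineError(f"simulate: {exc}") from exc

    try:
        bundles = out_dir / "sessions"
        for s1_sess, m1_sess in cohort:
            write_session_bundle(s1_sess, bundles / s1_sess.session_id)
            write_session_bundle(m1_sess, bundles / m1_sess.session_id)
    except Exception as exc:
        raise PipelineError(f"write-bundles: {exc}") from exc

    try:
        unit_df, summary_df, grand_df = analyze_cohort(cohort, analysis_config)
        unit_df.to_csv(out_dir / "unit_metrics.tsv", sep="\t", index=False)
        summary_df.to_csv(out_dir / "recording_summaries.tsv", sep="\t",
                          index=False)
        grand_df.to_csv(out_dir / "grand_averages.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError(f"analyze: {exc}") from exc

    try:
        profiles = {}
        for area in ("S1", "M1"):
            sub = unit_df[unit_df["area"] == area]
            prof = laminar_profile(sub, area, "peak")
            prof.table().to_csv(out_dir / f"laminar_{area}.tsv", sep="\t",
                                index=False)
            profiles[area] = prof
    except Exception as exc:
        raise PipelineError(f"laminar: {exc}") from exc

    try:
        results = {
            "seed": int(gen["seed"]),
            "n_recordings": int(gen["n_recordings"]),
            "grand_averages": {
                f"{area}.{metric}": {"mean": float(row["mean"]),
                                     "sd": float(row["sd"]),
                                     "n": int(row["n"])}
                for (area, metric), row in grand_df.iterrows()
            },
        }
        results = _round_floats(results)
        with open(out_dir / "results.json", "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise PipelineError(f"report: {exc}") from exc
    return results
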