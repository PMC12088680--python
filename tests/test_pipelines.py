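"""Protocol-level pipelines: speed, paired pulse, silencing, motion, e2e."""

import json

import numpy as np
import pandas as pd
import pytest

from triphasic import datasets, pipelines, synth
from triphasic.config import AnalysisConfig
from triphasic.io import RecordingSession, StimulusEvent, Unit
from triphasic.pipelines import (PipelineError, cohort_propagation_speed,
                                 integral_firing_rate, motion_index,
                                 paired_pulse_analysis, propagation_speed,
                                 run_pipeline, silencing_analysis)
from triphasic.psth import compute_psth, psth_from_spikes

CFG = AnalysisConfig()


class TestPropagationSpeed:
    def test_hand_to_s1_worked_examples(self):
        d = datasets.PATHWAY_DISTANCES_MM["hand_to_s1"]
        lat = datasets.RESPONSE_LATENCIES_MS
        assert propagation_speed(d, lat["s1_onset"]) == pytest.approx(
            3.0, abs=0.05)
        assert propagation_speed(d, lat["s1_peak"]) == pytest.approx(
            2.1, abs=0.05)

    def test_unit_identity(self):
        # distance (mm) numerically equal to latency (ms) -> exactly 1 m/s
        assert propagation_speed(7.3, 7.3) == 1.0

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            propagation_speed(0.0, 5.0)
        with pytest.raises(ValueError):
            propagation_speed(5.0, 0.0)

    def test_cohort_excludes_non_positive_latencies(self):
        out = cohort_propagation_speed([0.9, 0.9, 0.9], [9.0, -1.0, 11.0])
        assert out["excluded"] == [1]
        assert np.isnan(out["speeds_m_per_s"][1])

    def test_mean_of_ratios_bounds_ratio_of_means(self, rng):
        """Jensen: for a fixed distance, E[d/l] >= d/E[l]."""
        lats = rng.uniform(5.0, 30.0, 13)
        out = cohort_propagation_speed(np.full(13, 44.3), lats)
        assert out["mean_of_ratios"] >= out["ratio_of_means"] - 1e-12


class TestIntegralFiringRate:
    def test_additive_over_disjoint_subwindows(self, rng):
        rates = rng.uniform(0, 30, (5, CFG.n_bins))
        psth = compute_psth(rates, CFG)
        whole = integral_firing_rate(psth, CFG.with_(
            integral_window_ms=(15.0, 50.0)))
        part1 = integral_firing_rate(psth, CFG.with_(
            integral_window_ms=(15.0, 30.0)))
        part2 = integral_firing_rate(psth, CFG.with_(
            integral_window_ms=(30.0, 50.0)))
        assert whole == pytest.approx(part1 + part2)


class TestSilencingWorkedExample:
    def test_printed_integrals_reproduce_ratios_and_means(self):
        table = datasets.summarize_silencing_table(
            datasets.silencing_example_integrals())
        row = table.set_index(["group", "recording"])
        assert row.loc[("s1_all", "mouse1"), "ratio_pct"] == pytest.approx(
            83.3, abs=0.05)
        assert row.loc[("s1_all", "mouse2"), "ratio_pct"] == pytest.approx(
            49.0, abs=0.05)
        assert row.loc[("m1_all", "mouse1"), "ratio_pct"] == pytest.approx(
            87.2, abs=0.05)
        assert row.loc[("s1_non_pv", "mouse3"), "ratio_pct"] == pytest.approx(
            62.7, abs=0.05)
        assert row.loc[("s1_all", "mean"), "hand_int"] == pytest.approx(
            187.2, abs=0.05)
        assert row.loc[("s1_pv", "mean"), "hand_int"] == pytest.approx(
            239.8, abs=0.05)
        assert row.loc[("m1_all", "mean"), "hand_int"] == pytest.approx(
            63.8, abs=0.05)
        assert row.loc[("m1_all", "sd"), "hand_int"] == pytest.approx(
            19.8, abs=0.05)


def _deterministic_dual_condition_session(scale_combined=1.0):
    """Hand and hand+cortex trials with identical (or scaled) spike
    patterns placed at fixed latencies -> exact ratio arithmetic."""
    events, spikes = [], []
    t = 2.0
    for k in range(20):
        kind = "hand" if k % 2 == 0 else "hand_plus_cortical"
        events.append(StimulusEvent(time=t, kind=kind, duration_ms=5.0))
        n = 10 if kind == "hand" else int(round(10 * scale_combined))
        spikes.extend(t + 0.020 + 0.002 * np.arange(n))
        t += 1.0
    unit = Unit(unit_id="u0", area="S1", channel=0,
                spike_times=np.round(np.sort(spikes), 6))
    # a second quiet-but-present unit keeps the session realistic
    unit2 = Unit(unit_id="u1", area="S1", channel=1,
                 spike_times=np.round(np.arange(30) * 0.7 + 0.05, 6))
    return RecordingSession(session_id="det", animal_id="m", area="S1",
                            units=[unit, unit2],
                            events=events)


class TestSilencingAnalysis:
    def test_identical_conditions_give_ratio_100(self):
        sess = _deterministic_dual_condition_session(1.0)
        res = silencing_analysis([sess])
        assert res.loc[0, "ratio_pct"] == pytest.approx(100.0)

    def test_configured_attenuation_recovered(self):
        sess, _ = synth.simulate_special_blocks(
            "silencing", synth.s1_population(n_units=30), seed=6)
        res = silencing_analysis([sess])
        assert res.loc[0, "ratio_pct"] == pytest.approx(70.0, abs=7.0)

    def test_pv_stratification_and_bh_adjustment(self):
        sess, gt = synth.simulate_special_blocks(
            "silencing", synth.s1_population(n_units=40), seed=8)
        from triphasic.optotag import OptoTagResult
        tags = [OptoTagResult(r.unit_id, r.is_pv, 1.0, 1.0, 1.0, False)
                for r in gt.records]
        res = silencing_analysis([sess], [tags])
        assert set(res["group"]) <= {"all", "pv", "non_pv"}
        has_p = res["p"].notna()
        assert (res.loc[has_p, "p_adj"] >= res.loc[has_p, "p"] - 1e-12).all()

    def test_missing_condition_is_error(self, small_s1_session):
        sess, _ = small_s1_session
        with pytest.raises(ValueError, match="hand"):
            silencing_analysis([sess])


class TestPairedPulse:
    def test_identical_first_and_second_pulse_gives_ratio_one(self):
        events, spikes = [], []
        t = 2.0
        for k in range(12):
            events.append(StimulusEvent(time=t, kind="hand"))
            events.append(StimulusEvent(time=t + 0.25,
                                        kind="paired_pulse_second",
                                        lag_ms=250.0))
            for base in (t, t + 0.25):
                spikes.extend(base + 0.020 + 0.002 * np.arange(8))
            t += 1.5
        unit = Unit(unit_id="u0", area="S1", channel=0,
                    spike_times=np.round(np.sort(spikes), 6))
        sess = RecordingSession(session_id="pp", animal_id="m", area="S1",
                                units=[unit], events=events)
        results = paired_pulse_analysis(sess)
        assert len(results) == 1
        assert results[0].lag_ms == 250.0
        assert results[0].normalized_second == pytest.approx(1.0)

    def test_configured_scaling_recovered_at_150_ms(self):
        sess, _ = synth.simulate_special_blocks(
            "paired_pulse", synth.s1_population(n_units=60), seed=11,
            protocol=synth.ProtocolSpec(n_trials=80))
        by_lag = {r.lag_ms: r for r in paired_pulse_analysis(sess)}
        assert by_lag[150.0].normalized_second == pytest.approx(0.5,
                                                                abs=0.15)
        assert by_lag[350.0].normalized_second == pytest.approx(1.0,
                                                                abs=0.25)

    def test_missing_lag_is_simply_absent(self):
        sess, _ = synth.simulate_special_blocks(
            "paired_pulse", synth.s1_population(n_units=40), seed=12,
            paired=synth.PairedPulseSpec(lags_ms=(150.0,), scaling=(0.5,)))
        results = paired_pulse_analysis(sess)
        assert [r.lag_ms for r in results] == [150.0]

    def test_lag_overlapping_peak_window_is_error(self):
        events = [StimulusEvent(time=2.0, kind="hand"),
                  StimulusEvent(time=2.05, kind="paired_pulse_second",
                                lag_ms=50.0)]
        unit = Unit(unit_id="u", area="S1", channel=0,
                    spike_times=np.array([2.02]))
        sess = RecordingSession(session_id="s", animal_id="m", area="S1",
                                units=[unit], events=events)
        with pytest.raises(ValueError, match="overlap"):
            paired_pulse_analysis(sess)


class TestMotionIndex:
    def _frames(self, n=3000, h=32, w=48):
        return np.full((n, h, w), 100.0)

    def test_static_frames_give_zero_index(self):
        frames = self._frames()
        res = motion_index(frames, roi=(8, 8, 16, 12),
                           event_frames=[500, 1500, 2500])
        assert res.mean_index == 0.0
        assert res.p_value == 1.0

    def test_brightness_step_is_detected(self):
        frames = self._frames()
        events = [500, 1000, 1500, 2000, 2500]
        for ev in events:
            frames[ev + 50:ev + 90, 10:18, 12:20] += 25.0  # movement at 50 ms
        res = motion_index(frames, roi=(8, 8, 16, 12), event_frames=events)
        assert res.mean_index > 0
        assert res.p_value < 0.05 or len(events) < 6  # signed rank floor

    def test_led_on_frames_excluded(self):
        frames = self._frames()
        events = [500, 1500, 2500]
        for ev in events:
            frames[ev:ev + 5] += 200.0  # LED artifact, first 5 ms only
        res = motion_index(frames, roi=(8, 8, 16, 12), event_frames=events)
        assert res.mean_index == 0.0

    def test_roi_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="ROI"):
            motion_index(self._frames(), roi=(40, 8, 16, 12),
                         event_frames=[500])


class TestRunPipeline:
    CONFIG = {"seed": 11, "n_recordings": 2,
              "s1": {"n_units": 8}, "m1": {"n_units": 8}}

    def test_end_to_end_outputs_present(self, tmp_path):
        results = run_pipeline(self.CONFIG, tmp_path / "out")
        for name in ("unit_metrics.tsv", "recording_summaries.tsv",
                     "grand_averages.tsv", "results.json",
                     "laminar_S1.tsv", "laminar_M1.tsv"):
            assert (tmp_path / "out" / name).exists()
        assert "grand_averages" in results
        assert (tmp_path / "out" / "sessions" / "rec00-S1" /
                "spikes.tsv").exists()

    def test_same_seed_gives_identical_results_json(self, tmp_path):
        run_pipeline(self.CONFIG, tmp_path / "a")
        run_pipeline(self.CONFIG, tmp_path / "b")
        assert (tmp_path / "a" / "results.json").read_bytes() == \
            (tmp_path / "b" / "results.json").read_bytes()

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = tmp_path / "gen.yaml"
        cfg.write_text("seed: 4\nn_recordings: 1\n"
                       "s1:\n  n_units: 6\nm1:\n  n_units: 6\n")
        results = run_pipeline(cfg, tmp_path / "out")
        assert results["seed"] == 4

    def test_missing_seed_aborts_with_stage_named_error(self, tmp_path):
        with pytest.raises(PipelineError, match="config"):
            run_pipeline({"n_recordings": 1}, tmp_path / "out")
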