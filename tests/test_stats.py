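"""Grand averages, paired tests, BH-FDR, Spearman matrix — with oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from triphasic.config import AnalysisConfig
from triphasic.stats import (bh_adjust, compare_paired, friedman_dunn_sidak,
                             grand_average, spearman_matrix,
                             summarize_experiment)


def bh_closed_form(p):
    """Textbook step-up BH: p_(i) * m / i with downstream monotonicity."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        running_min = min(running_min, p[i] * m / (rank_from_top + 1))
        adj[i] = running_min
    return adj


class TestGrandAverage:
    def test_worked_example_mean_and_sd(self):
        df = pd.DataFrame({"peak_amplitude_hz": [81.9, 46.1, 79.8, 47.2]})
        g = grand_average(df, metrics=("peak_amplitude_hz",))
        assert g.loc["peak_amplitude_hz", "mean"] == pytest.approx(63.8,
                                                                   abs=0.05)
        assert g.loc["peak_amplitude_hz", "sd"] == pytest.approx(19.8,
                                                                 abs=0.05)

    def test_identical_recordings_have_zero_sd(self):
        df = pd.DataFrame({"onset_latency_ms": [14.7] * 5})
        g = grand_average(df, metrics=("onset_latency_ms",))
        assert g.loc["onset_latency_ms", "sd"] == 0.0

    def test_recording_order_is_irrelevant(self, rng):
        vals = rng.uniform(0, 50, 13)
        a = grand_average(pd.DataFrame({"duration_ms": vals}),
                          metrics=("duration_ms",))
        b = grand_average(pd.DataFrame({"duration_ms": vals[::-1]}),
                          metrics=("duration_ms",))
        assert a.loc["duration_ms", "mean"] == pytest.approx(
            b.loc["duration_ms", "mean"])
        assert a.loc["duration_ms", "sd"] == pytest.approx(
            b.loc["duration_ms", "sd"])

    def test_empty_summary_table_rejected(self):
        with pytest.raises(ValueError):
            grand_average(pd.DataFrame())


class TestComparePaired:
    def test_identical_vectors_are_not_significant(self):
        res = compare_paired(np.arange(8.0), np.arange(8.0))
        assert res.p == 1.0 and res.test_name == "signed_rank"

    def test_small_samples_fall_back_to_paired_t(self, rng):
        res = compare_paired(rng.normal(0, 1, 4), rng.normal(0, 1, 4))
        assert res.test_name == "paired_t" and res.n == 4

    def test_w_statistic_matches_rank_arithmetic(self, rng):
        """scipy's two-sided W equals min(T+, T-) from explicit ranks."""
        for _ in range(20):
            x = rng.normal(0, 1, 13)
            y = rng.normal(0.4, 1, 13)
            res = compare_paired(x, y)
            d = x - y
            ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
            t_plus, t_minus = ranks[d > 0].sum(), ranks[d < 0].sum()
            assert res.statistic == pytest.approx(min(t_plus, t_minus))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_paired([1.0, 2.0], [1.0])


class TestBenjaminiHochberg:
    def test_closed_form_example(self):
        adj = bh_adjust([0.01, 0.02, 0.04])
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.04])

    def test_matches_closed_form_on_random_families(self, rng):
        for _ in range(25):
            p = rng.uniform(0, 1, rng.integers(1, 12))
            np.testing.assert_allclose(bh_adjust(p), bh_closed_form(p),
                                       atol=1e-12)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(0, 1, 20)
        assert (bh_adjust(p) >= p - 1e-12).all()


class TestFriedman:
    def test_needs_four_subjects_and_three_conditions(self, rng):
        with pytest.raises(ValueError):
            friedman_dunn_sidak(rng.normal(0, 1, (3, 4)))
        with pytest.raises(ValueError):
            friedman_dunn_sidak(rng.normal(0, 1, (6, 2)))

    def test_strong_condition_effect_detected_with_posthocs(self, rng):
        base = rng.normal(10, 1, (8, 1))
        data = np.hstack([base, base + 5.0, base + 10.0, base + 0.1])
        res, posthocs = friedman_dunn_sidak(data)
        assert res.test_name == "friedman" and res.p < 0.05
        assert len(posthocs) == 6  # all pairwise contrasts, Sidak-adjusted
        assert all(0.0 <= p <= 1.0 for _, _, p in posthocs)

    def test_null_data_yields_no_posthocs(self, rng):
        data = rng.normal(0, 1, (10, 4))
        res, posthocs = friedman_dunn_sidak(data)
        if res.p >= 0.05:  # gatekeeping: no post hocs without an effect
            assert posthocs == []


class TestSpearman:
    @staticmethod
    def brute_force_rho(x, y):
        rx = np.argsort(np.argsort(x)) + 1
        ry = np.argsort(np.argsort(y)) + 1
        d2 = ((rx - ry) ** 2).sum()
        n = len(x)
        return 1.0 - 6.0 * d2 / (n * (n * n - 1))

    def test_matrix_diagonal_symmetry_and_signs(self, rng):
        df = pd.DataFrame({
            "a": np.arange(13.0),
            "b": -np.arange(13.0),          # perfectly anti-ranked with a
            "c": rng.normal(0, 1, 13),
        })
        rho, p, mask = spearman_matrix(df, ("a", "b", "c"))
        assert rho.loc["a", "a"] == 1.0
        assert rho.loc["a", "b"] == pytest.approx(-1.0)
        np.testing.assert_allclose(rho.values, rho.values.T)
        assert not mask.values.diagonal().any()

    def test_rho_matches_rank_formula(self, rng):
        for _ in range(20):
            x = rng.normal(0, 1, 13)
            y = rng.normal(0, 1, 13)
            df = pd.DataFrame({"x": x, "y": y})
            rho, _, _ = spearman_matrix(df, ("x", "y"))
            assert rho.loc["x", "y"] == pytest.approx(
                self.brute_force_rho(x, y), abs=1e-12)

    def test_constant_column_flagged_undefined(self):
        df = pd.DataFrame({"x": np.arange(8.0), "k": np.ones(8)})
        rho, p, mask = spearman_matrix(df, ("x", "k"))
        assert np.isnan(rho.loc["x", "k"])
        assert not mask.loc["x", "k"]

    def test_too_few_recordings_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "y": [2.0, 1.0, 3.0]})
        with pytest.raises(ValueError):
            spearman_matrix(df, ("x", "y"))


class TestSummarizeExperiment:
    def _unit_row(self, **over):
        row = dict(responsive=True, baseline_hz=1.0, onset_latency_ms=15.0,
                   peak_latency_ms=20.0, peak_amplitude_hz=50.0,
                   duration_ms=25.0, suppressed=False,
                   suppression_pct_baseline=np.nan, rebounding=False,
                   rebound_amplitude_hz=np.nan, rebound_latency_ms=np.nan)
        row.update(over)
        return row

    def test_single_responsive_unit_summary_equals_that_unit(self):
        df = pd.DataFrame([self._unit_row()])
        s = summarize_experiment(df, "r0")
        assert s["onset_latency_ms"] == 15.0
        assert s["frac_responsive_pct"] == 100.0
        assert s["frac_suppressed_pct"] == 0.0

    def test_phase_fractions_use_responsive_denominator(self):
        rows = [self._unit_row(),
                self._unit_row(suppressed=True,
                               suppression_pct_baseline=8.0),
                self._unit_row(responsive=False, onset_latency_ms=np.nan,
                               peak_latency_ms=np.nan,
                               peak_amplitude_hz=np.nan,
                               duration_ms=np.nan)]
        s = summarize_experiment(pd.DataFrame(rows), "r0")
        assert s["frac_responsive_pct"] == pytest.approx(200.0 / 3)
        assert s["frac_suppressed_pct"] == 50.0
        assert s["suppression_pct_baseline"] == 8.0

    def test_zero_responsive_units_flagged_with_nans(self):
        df = pd.DataFrame([self._unit_row(responsive=False)])
        s = summarize_experiment(df, "r0")
        assert s["n_responsive"] == 0
        assert np.isnan(s["onset_latency_ms"])
        assert np.isnan(s["frac_suppressed_pct"])
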