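"""Summary statistics, quantile-range means and delta plots."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antirace import SubjectData, delta_plot, group_compare, quantile_range_means, summary_stats
from antirace.behavior import DEFAULT_RANGES, group_delta_plot
from tests.conftest import make_subject


def _subject(pro, anti, correct, **kw):
    return SubjectData("x", np.asarray(pro), np.asarray(anti), np.asarray(correct), **kw)


class TestSummaryStats:
    def test_accuracy_from_counts(self):
        s = _subject([0.3], [0.4, 0.41, 0.42, 0.25], [True, True, True, False])
        assert summary_stats(s).anti_accuracy == pytest.approx(0.75)

    def test_mean_and_sample_sd(self):
        s = _subject([0.30, 0.35, 0.40], [0.5], [True])
        ss = summary_stats(s)
        assert ss.pro_rt_mean == pytest.approx(0.35)
        assert ss.pro_rt_sd == pytest.approx(0.05)

    def test_empty_cells_reported_missing(self):
        s = _subject([], [0.4, 0.5], [True, True])
        ss = summary_stats(s)
        assert ss.pro_rt_mean is None
        assert ss.anti_error_rt_mean is None
        assert ss.n_anti_error == 0

    def test_no_anti_trials_is_an_error(self):
        with pytest.raises(ValueError):
            summary_stats(_subject([0.3], [], []))

    def test_matches_independent_recomputation(self, control_params):
        s = make_subject(control_params, 25, 25, seed=31)
        ss = summary_stats(s)
        # spreadsheet-style recomputation straight from the trial arrays
        cor = s.anti_rts[s.anti_correct]
        err = s.anti_rts[~s.anti_correct]
        assert ss.pro_rt_mean == pytest.approx(sum(s.pro_rts) / len(s.pro_rts))
        assert ss.anti_correct_rt_mean == pytest.approx(float(np.mean(cor)))
        assert ss.anti_error_rt_sd == pytest.approx(float(np.std(err, ddof=1)))
        assert ss.anti_accuracy == pytest.approx(len(cor) / 25)


def brute_force_range_means(rts, ranges):
    """Independent re-implementation of the assignment rule."""
    rts = sorted(rts)
    n = len(rts)
    out = []
    for j, (lo, hi) in enumerate(ranges):
        vals = []
        for i, rt in enumerate(rts, start=1):
            pos = (i - 0.5) / n
            inside = lo <= pos <= hi if j == len(ranges) - 1 else lo <= pos < hi
            if inside:
                vals.append(rt)
        out.append(np.mean(vals) if vals else np.nan)
    return np.array(out)


class TestQuantileRangeMeans:
    def test_decile_endpoints(self):
        means = quantile_range_means(np.arange(1, 11))
        assert means[0] == 1.0  # position 0.05 alone in [0, 0.1)
        assert means[-1] == 10.0  # position 0.95 alone in [0.9, 1]

    def test_constant_rts(self):
        means = quantile_range_means(np.full(20, 0.42))
        assert np.allclose(means[np.isfinite(means)], 0.42)

    def test_matches_brute_force_oracle(self):
        rts = np.random.default_rng(37).uniform(0.2, 0.8, size=37)
        np.testing.assert_allclose(
            quantile_range_means(rts, DEFAULT_RANGES),
            brute_force_range_means(rts, DEFAULT_RANGES),
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0.1, 2.0), min_size=6, max_size=60))
    def test_permutation_invariant_and_monotone(self, rts):
        rts = np.asarray(rts)
        a = quantile_range_means(rts)
        b = quantile_range_means(rts[::-1])
        np.testing.assert_allclose(a, b)
        finite = a[np.isfinite(a)]
        assert np.all(np.diff(finite) >= -1e-12)


class TestDeltaPlot:
    def test_identical_conditions_give_zero_delta(self):
        rts = np.linspace(0.25, 0.6, 30)
        s = _subject(rts, rts, np.ones(30, dtype=bool))
        dp = delta_plot(s)
        np.testing.assert_allclose(dp.y, 0.0, atol=1e-12)

    def test_constant_shift(self):
        pro = np.linspace(0.25, 0.6, 30)
        s = _subject(pro, pro + 0.05, np.ones(30, dtype=bool))
        dp = delta_plot(s)
        np.testing.assert_allclose(dp.y, 0.05, atol=1e-12)
        np.testing.assert_allclose(dp.x, quantile_range_means(pro) + 0.025, atol=1e-12)

    def test_common_additive_constant_invariance(self):
        rng = np.random.default_rng(5)
        pro = rng.uniform(0.2, 0.5, 40)
        anti = rng.uniform(0.3, 0.7, 40)
        ok = np.ones(40, dtype=bool)
        y1 = delta_plot(_subject(pro, anti, ok)).y
        y2 = delta_plot(_subject(pro + 0.3, anti + 0.3, ok)).y
        np.testing.assert_allclose(y1, y2, atol=1e-12)

    def test_too_few_trials_gives_missing_points(self):
        s = _subject([0.3, 0.4], [0.5] * 10, [True] * 10)
        assert np.all(np.isnan(delta_plot(s).y))

    def test_x_strictly_increasing_on_real_subject(self, small_subject):
        dp = delta_plot(small_subject)
        assert np.all(np.diff(dp.x) > 0)

    def test_model_simulation_shows_decreasing_delta_slope(self, control_params):
        """Conflict resolves over time: first delta point above the last.

        In the behaviorally calibrated regime the executive drift exceeds
        the prepotent drift, so correct antisaccades are tightly distributed
        and their slow tail is right-censored (a slow executive finish tends
        to resolve as an error instead); the anti-minus-pro difference
        therefore shrinks toward the upper quantiles.
        """
        subjects = [make_subject(control_params, 1500, 1500, seed=60 + i) for i in range(8)]
        _, y_mean, _ = group_delta_plot(subjects)
        assert y_mean[0] > y_mean[-1]


class TestGroupCompare:
    def test_identical_groups(self):
        res = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_clear_separation(self):
        res = group_compare([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert abs(res.statistic) > 5
        assert res.pvalue < 0.001

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        res = group_compare(a, b)
        n1, n2 = len(a), len(b)
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
        t_manual = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        assert res.statistic == pytest.approx(t_manual, abs=1e-10)
        assert res.df == n1 + n2 - 2

    def test_degenerate_variance_flagged(self):
        res = group_compare([1.0, 1.0], [2.0, 2.0])
        assert res.degenerate
        assert np.isinf(res.statistic)

    def test_welch_uses_noninteger_df(self):
        rng = np.random.default_rng(9)
        res = group_compare(rng.normal(0, 1, 10), rng.normal(0, 3, 40), welch=True)
        assert res.df != 48


def test_delta_plot_figure_renders(tmp_path, control_params):
    from antirace.behavior import group_delta_plot
    from antirace.plotting import plot_group_delta

    subjects = [make_subject(control_params, 50, 50, seed=200 + i) for i in range(3)]
    x, y, se = group_delta_plot(subjects)
    ax = plot_group_delta(x, y, se, label="controls")
    out = tmp_path / "delta.png"
    ax.figure.savefig(out)
    assert out.stat().st_size > 0
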