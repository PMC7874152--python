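"""LOWESS smoothing and Chow sup-F breakpoint detection."""

import numpy as np
import pytest
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from elnthresh.breakpoint import (
    DomainError,
    chow_f,
    find_breakpoint,
    lowess_smooth,
)


class TestLowess:
    def test_reproduces_constants(self):
        x = np.arange(1.0, 21.0)
        out = lowess_smooth(x, np.full(20, 3.25))
        np.testing.assert_allclose(out.y_fit, 3.25, atol=1e-12)

    def test_reproduces_linear_signal(self):
        x = np.arange(1.0, 31.0)
        out = lowess_smooth(x, 2 * x + 1)
        np.testing.assert_allclose(out.y_fit, 2 * x + 1, atol=1e-9)

    def test_matches_independent_oracle_on_noisy_sine(self):
        """Agreement with the reference LOWESS implementation at every
        point of a fixed 40-point noisy-sine fixture."""
        rng = np.random.default_rng(42)
        x = np.arange(1.0, 41.0)
        y = np.sin(x / 6) + rng.normal(0, 0.3, 40)
        for frac, it in [(2 / 3, 3), (0.5, 0), (0.4, 2)]:
            mine = lowess_smooth(x, y, bandwidth=frac, robustify_iterations=it).y_fit
            oracle = sm_lowess(y, x, frac=frac, it=it, delta=0.0, return_sorted=False)
            np.testing.assert_allclose(mine, oracle, atol=1e-6)

    def test_input_contracts(self):
        with pytest.raises(DomainError):
            lowess_smooth([1, 2, 3, 4], [1, 2, 3, 4])  # < 5 points
        with pytest.raises(DomainError):
            lowess_smooth([1, 2, 2, 3, 4], [0, 0, 0, 0, 0])  # not increasing
        with pytest.raises(DomainError):
            lowess_smooth(np.arange(10.0), np.zeros(10), bandwidth=0.0)

    def test_robustification_downweights_gross_outlier(self):
        x = np.arange(1.0, 31.0)
        y = 0.5 * x
        y_out = y.copy()
        y_out[14] += 20.0
        robust = lowess_smooth(x, y_out, robustify_iterations=3).y_fit
        naive = lowess_smooth(x, y_out, robustify_iterations=0).y_fit
        clean_err_robust = np.abs(robust - 0.5 * x)[np.arange(30) != 14].max()
        clean_err_naive = np.abs(naive - 0.5 * x)[np.arange(30) != 14].max()
        assert clean_err_robust < clean_err_naive


SEVEN_X = np.arange(1.0, 8.0)
SEVEN_Y = np.array([1.0, 1.1, 1.2, 1.3, 2.3, 3.3, 4.3])


def _segmented_ols_f(x, y, split):
    """Independent two-segment least-squares Chow oracle.

    Residual sums below numerical zero are treated as exact zeros, so a
    noiseless piecewise-linear series yields an infinite F."""
    left, right = x <= split, x > split

    def rss(xs, ys):
        A = np.column_stack([np.ones_like(xs), xs])
        coef, *_ = np.linalg.lstsq(A, ys, rcond=None)
        r = ys - A @ coef
        out = float(r @ r)
        return 0.0 if out < 1e-12 * max(1.0, float(ys @ ys)) else out

    rss_p = rss(x, y)
    rss_1, rss_2 = rss(x[left], y[left]), rss(x[right], y[right])
    k, n = 2, len(x)
    if rss_1 + rss_2 == 0.0:
        return np.inf, 0.0
    f = ((rss_p - rss_1 - rss_2) / k) / ((rss_1 + rss_2) / (n - 2 * k))
    return f, stats.f.sf(f, k, n - 2 * k)


class TestChow:
    def test_matches_segmented_ols_oracle_on_hinge_fixture(self):
        # the hinge at x=4 lies on both segment lines: the two-segment fit
        # is exact and both routes agree the F statistic is infinite
        f, p = chow_f(SEVEN_X, SEVEN_Y, 4)
        f_o, p_o = _segmented_ols_f(SEVEN_X, SEVEN_Y, 4)
        assert f == f_o == np.inf
        assert p == pytest.approx(p_o, abs=1e-8)

    def test_matches_segmented_ols_oracle_with_noise(self):
        rng = np.random.default_rng(21)
        y = SEVEN_Y + rng.normal(0, 0.03, 7)
        for split in [3, 4]:
            f, p = chow_f(SEVEN_X, y, split)
            f_o, p_o = _segmented_ols_f(SEVEN_X, y, split)
            assert f == pytest.approx(f_o, abs=1e-8)
            assert p == pytest.approx(p_o, abs=1e-8)

    def test_perfect_line_has_zero_f(self):
        x = np.arange(1.0, 11.0)
        f, p = chow_f(x, 3 * x - 2, 5)
        assert f == 0.0
        assert p == 1.0

    def test_minimum_segment_size_enforced(self):
        with pytest.raises(DomainError):
            chow_f(SEVEN_X, SEVEN_Y, 5, min_segment=3)  # right segment = 2

    def test_invariance_under_shift_and_scale(self):
        rng = np.random.default_rng(9)
        x = np.arange(1.0, 31.0)
        y = np.where(x < 15, 0.1 * x, 1.5 + 0.0 * x) + rng.normal(0, 0.1, 30)
        f0, _ = chow_f(x, y, 14)
        f_shift, _ = chow_f(x, y + 11.0, 14)
        f_scale, _ = chow_f(x, 3.7 * y, 14)
        assert f_shift == pytest.approx(f0, rel=1e-9)
        assert f_scale == pytest.approx(f0, rel=1e-9)


class TestSupFScan:
    def test_recovers_fixture_breakpoint(self):
        series = lowess_smooth(SEVEN_X, SEVEN_Y, bandwidth=1.0, robustify_iterations=0)
        res = find_breakpoint(series, use="raw")
        assert res.break_x == 4.0
        assert res.f_statistic > 0
        assert not res.no_break

    def test_equals_exhaustive_recomputation(self):
        rng = np.random.default_rng(10)
        x = np.arange(1.0, 41.0)
        y = np.cumsum(rng.normal(size=40))
        series = lowess_smooth(x, y)
        res = find_breakpoint(series)
        scan = {c: chow_f(x, series.y_fit, c)[0] for c in x[2:-3]}
        best = min(scan, key=lambda c: (-scan[c], c))
        assert res.break_x == best
        assert res.f_statistic == pytest.approx(scan[best], rel=1e-12)
        assert res.candidate_scan.keys() == scan.keys()

    def test_strictly_linear_series_flags_no_break(self):
        x = np.arange(1.0, 21.0)
        series = lowess_smooth(x, 0.7 * x + 2)
        res = find_breakpoint(series)
        assert res.no_break
        assert res.f_statistic == 0.0
        assert all(f == 0.0 for f in res.candidate_scan.values())

    def test_short_series_rejected(self):
        x = np.arange(1.0, 6.0)
        series = lowess_smooth(x, x)
        with pytest.raises(DomainError):
            find_breakpoint(series, min_segment=3)

    def test_rss_additivity_invariant(self):
        rng = np.random.default_rng(11)
        x = np.arange(1.0, 31.0)
        y = rng.normal(size=30)
        series = lowess_smooth(x, y)
        res = find_breakpoint(series, use="raw")
        assert res.left_fit[2] + res.right_fit[2] <= res.pooled_fit[2] + 1e-9
        assert res.n_left + res.n_right == 30

    def test_white_noise_naive_p_inflation_is_bounded_but_present(self):
        """The naive sup-F p-value ignores that the split is estimated;
        on raw white noise the rejection rate exceeds the nominal 5% but
        stays far from certainty."""
        rng = np.random.default_rng(12)
        rejections = 0
        for _ in range(100):
            x = np.arange(1.0, 31.0)
            y = rng.normal(size=30)
            series = lowess_smooth(x, y, robustify_iterations=0)
            res = find_breakpoint(series, use="raw")
            rejections += res.p_value < 0.05
        assert 0.05 <= rejections / 100 <= 0.95

    def test_permutation_p_is_better_calibrated_than_naive(self):
        rng = np.random.default_rng(13)
        x = np.arange(1.0, 31.0)
        y = rng.normal(size=30)
        series = lowess_smooth(x, y, robustify_iterations=0)
        res = find_breakpoint(series, use="raw", permutations=199, rng=1)
        assert res.permutation_p >= res.p_value
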