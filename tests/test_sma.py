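"""Standardized major axis estimation and the slope/elevation test battery."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import allomorph as am
from allomorph.dataset import VariablePair
from allomorph.errors import DegenerateDataError, InsufficientDataError


def make_pair(x, y, label="pair"):
    x, y = np.asarray(x, float), np.asarray(y, float)
    return VariablePair("x", "y", x, y, tuple(f"s{i}" for i in range(len(x))), label)


def random_pair(rng, n=20, slope=1.2, intercept=-1.0, sd=0.2, label="pair"):
    x = rng.uniform(1, 4, n)
    y = intercept + slope * x + rng.normal(0, sd, n)
    return make_pair(x, y, label)


class TestFitSMA:
    def test_perfect_line_collapses_ci(self):
        x = np.arange(10.0)
        fit = am.fit_sma(make_pair(x, 3 * x + 1))
        assert fit.slope == pytest.approx(3.0, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.slope_ci[0] == pytest.approx(3.0, abs=1e-9)
        assert fit.slope_ci[1] == pytest.approx(3.0, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_geometric_mean_of_ols_slopes_oracle(self, seed):
        """SMA slope equals the geometric mean of the two OLS slopes.

        The oracle fits y|x and x|y by ordinary least squares independently of
        the SMA code path: b_sma = sign(r) * sqrt(b_yx / b_xy^-1)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        pair = random_pair(rng)
        b_yx = sm.OLS(pair.y, sm.add_constant(pair.x)).fit().params[1]
        b_xy = sm.OLS(pair.x, sm.add_constant(pair.y)).fit().params[1]
        r = np.corrcoef(pair.x, pair.y)[0, 1]
        oracle = np.sign(r) * np.sqrt(b_yx / b_xy * 1.0) if b_yx * b_xy > 0 else np.nan
        oracle = np.sign(r) * np.sqrt(abs(b_yx * (1.0 / b_xy)))
        assert am.fit_sma(pair).slope == pytest.approx(oracle, abs=1e-12)

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(
        logc=st.floats(-3, 3),
        seed=st.integers(0, 2**16),
    )
    def test_scale_equivariance(self, logc, seed):
        """Multiplying raw y by c shifts only the intercept by log10(c)."""
        rng = np.random.default_rng(seed)
        pair = random_pair(rng)
        shifted = make_pair(pair.x, pair.y + logc)  # log-scale shift = raw rescaling
        f0, f1 = am.fit_sma(pair), am.fit_sma(shifted)
        assert f1.slope == pytest.approx(f0.slope, abs=1e-12)
        assert f1.r2 == pytest.approx(f0.r2, abs=1e-12)
        assert f1.intercept - f0.intercept == pytest.approx(logc, abs=1e-9)
        t0, t1 = am.test_slope(pair, 1.0), am.test_slope(shifted, 1.0)
        assert t1.p == pytest.approx(t0.p, abs=1e-9)

    def test_swap_inverts_slope(self):
        rng = np.random.default_rng(7)
        pair = random_pair(rng)
        swapped = make_pair(pair.y, pair.x)
        assert am.fit_sma(swapped).slope == pytest.approx(
            1.0 / am.fit_sma(pair).slope, abs=1e-12
        )

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            am.fit_sma(make_pair(np.ones(5), np.arange(5.0)))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            am.fit_sma(make_pair([1, 2], [1, 2]))


class TestSlopeTest:
    def test_null_at_estimate_gives_p_one(self):
        rng = np.random.default_rng(3)
        pair = random_pair(rng)
        fit = am.fit_sma(pair)
        res = am.test_slope(pair, fit.slope)
        assert res.F == pytest.approx(0.0, abs=1e-18)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(seed=st.integers(0, 2**16), b0=st.floats(0.2, 5.0))
    def test_f_test_and_ci_exclusion_agree(self, seed, b0):
        """The slope CI is the inversion of the F test: verdicts always agree."""
        rng = np.random.default_rng(seed)
        pair = random_pair(rng)
        fit = am.fit_sma(pair)
        res = am.test_slope(pair, b0)
        assert am.ci_excludes(fit, b0) == res.reject

    def test_ci_boundary_not_excluded(self):
        rng = np.random.default_rng(5)
        fit = am.fit_sma(random_pair(rng))
        assert not am.ci_excludes(fit, fit.slope_ci[0])
        assert not am.ci_excludes(fit, fit.slope_ci[1])

    def test_nonpositive_null_warns(self):
        rng = np.random.default_rng(6)
        with pytest.warns(UserWarning, match="non-positive"):
            am.test_slope(random_pair(rng), -1.0)


class TestCommonSlope:
    def test_duplicated_group_statistic_zero(self):
        rng = np.random.default_rng(8)
        pair = random_pair(rng)
        res = am.test_common_slope([pair, pair])
        assert res.statistic == pytest.approx(0.0, abs=1e-8)
        assert res.p == pytest.approx(1.0, abs=1e-6)

    def test_pooled_slope_within_group_range(self):
        rng = np.random.default_rng(9)
        pairs = [random_pair(rng, slope=s) for s in (0.8, 1.0, 1.3)]
        res = am.test_common_slope(pairs)
        slopes = [f.slope for f in res.group_fits]
        assert min(slopes) <= res.b_common <= max(slopes)

    def test_type_one_error_rate(self):
        """Groups sharing a true slope are rejected ~5% of the time."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            g1 = random_pair(rng, n=30, slope=1.1, intercept=-1.8, sd=0.15)
            g2 = random_pair(rng, n=30, slope=1.1, intercept=-1.0, sd=0.15)
            rejections += am.test_common_slope([g1, g2]).p < 0.05
        assert abs(rejections / n_rep - 0.05) < 0.02

    def test_degenerate_group_identified(self):
        rng = np.random.default_rng(12)
        good = random_pair(rng)
        bad = VariablePair("x", "y", np.ones(5), np.arange(5.0), tuple("abcde"), "flat")
        with pytest.raises(DegenerateDataError, match="flat"):
            am.test_common_slope([good, bad])

    def test_needs_two_groups(self):
        rng = np.random.default_rng(13)
        with pytest.raises(InsufficientDataError):
            am.test_common_slope([random_pair(rng)])


class TestElevation:
    def test_type_one_error_rate(self):
        """One population split at random is rejected ~alpha of the time."""
        rng = np.random.default_rng(14)
        rejections = 0
        n_rep = 1000
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for _ in range(n_rep):
                x = rng.uniform(1, 4, 60)
                y = -1.8 + 1.1 * x + rng.normal(0, 0.15, 60)
                idx = rng.permutation(60)
                halves = [
                    make_pair(x[idx[:30]], y[idx[:30]]),
                    make_pair(x[idx[30:]], y[idx[30:]]),
                ]
                rejections += am.test_elevation(halves).p < 0.05
        assert abs(rejections / n_rep - 0.05) < 0.025

    def test_shifted_copy_is_detected(self):
        rng = np.random.default_rng(15)
        pair = random_pair(rng, n=40, sd=0.1)
        shifted = make_pair(pair.x, pair.y + 0.8)
        res = am.test_elevation([pair, shifted])
        assert res.p < 1e-6
        assert res.elevations[1] - res.elevations[0] == pytest.approx(0.8, abs=0.05)

    def test_warns_when_common_slope_rejected(self):
        rng = np.random.default_rng(16)
        g1 = random_pair(rng, n=60, slope=0.5, sd=0.05)
        g2 = random_pair(rng, n=60, slope=2.5, sd=0.05)
        with pytest.warns(UserWarning, match="common slope rejected"):
            am.test_elevation([g1, g2])

    def test_pairwise_matrix_is_symmetric_in_content(self):
        rng = np.random.default_rng(17)
        pairs = [random_pair(rng, intercept=c, label=f"g{i}") for i, c in enumerate((0, 0.05, 1.0))]
        res = am.pairwise_elevation(pairs)
        assert set(res) == {("g0", "g1"), ("g0", "g2"), ("g1", "g2")}
        assert res[("g0", "g2")].p < 0.001
        assert res[("g0", "g1")].df == 1
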