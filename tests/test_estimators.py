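"""Univariable estimators against hand values and a generic WLS oracle."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from mrscreen import bh_adjust, egger, ivw, wald_ratio, weighted_median
from mrscreen.estimators import EstimationError
from mrscreen.summstats import ValidationError

from conftest import make_hset, sim_hset


def wls_origin_oracle(bx, by, sy):
    """Weighted regression through the origin via statsmodels."""
    fit = sm.WLS(by, bx[:, None], weights=1 / np.asarray(sy) ** 2).fit()
    theta = fit.params[0]
    # fixed-effect SE: unscaled (X'WX)^{-1/2}
    se = float(np.sqrt(fit.normalized_cov_params[0, 0]))
    return float(theta), se


class TestWaldRatio:
    def test_null_outcome_effect_gives_zero_and_p_one(self):
        res = wald_ratio(0.1, 0.01, 0.0, 0.02)
        assert res.theta == 0.0
        assert res.pvalue == pytest.approx(1.0)

    def test_hand_division(self):
        res = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert res.theta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.2)

    def test_sign_through_bx_magnitude_through_abs(self):
        res = wald_ratio(-0.1, 0.01, 0.05, 0.02)
        assert res.theta == pytest.approx(-0.5)
        assert res.se == pytest.approx(0.2)

    def test_null_instrument_rejected(self):
        with pytest.raises(EstimationError, match="null_instrument"):
            wald_ratio(0.0, 0.01, 0.05, 0.02)


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        h = make_hset([0.1], [0.01], [0.05], [0.02])
        res = ivw(h)
        wald = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert res.theta == wald.theta
        assert res.se == wald.se
        assert res.method == "ivw"

    def test_collinear_data_recovers_exact_slope(self):
        h = make_hset(
            [0.1, 0.2, 0.1], [0.01] * 3, [0.05, 0.10, 0.05], [0.02] * 3
        )
        assert ivw(h).theta == pytest.approx(0.5, abs=1e-14)

    def test_matches_wls_through_origin_oracle(self, rng):
        for _ in range(200):
            j = rng.integers(2, 12)
            bx = rng.normal(0, 0.05, j)
            by = rng.normal(0, 0.01, j)
            sy = rng.uniform(0.005, 0.05, j)
            res = ivw(make_hset(bx, np.full(j, 0.01), by, sy))
            theta, se = wls_origin_oracle(bx, by, sy)
            assert res.theta == pytest.approx(theta, abs=1e-10)
            assert res.se == pytest.approx(se, abs=1e-10)

    def test_invariant_to_joint_sign_flips(self, rng):
        j = 8
        bx = rng.normal(0, 0.05, j)
        by = rng.normal(0, 0.01, j)
        sy = rng.uniform(0.005, 0.05, j)
        base = ivw(make_hset(bx, np.full(j, 0.01), by, sy))
        flip = rng.random(j) < 0.5
        s = np.where(flip, -1.0, 1.0)
        flipped = ivw(make_hset(bx * s, np.full(j, 0.01), by * s, sy))
        assert flipped.theta == pytest.approx(base.theta, abs=1e-14)
        assert flipped.se == pytest.approx(base.se, abs=1e-14)


class TestEgger:
    def test_exact_linear_data_recovers_intercept_and_slope(self):
        bx = np.array([0.02, 0.04, 0.05, 0.07, 0.1, 0.12])
        by = 0.01 + 0.5 * bx
        res = egger(make_hset(bx, np.full(6, 0.005), by, np.full(6, 0.01)))
        assert res.intercept == pytest.approx(0.01, abs=1e-12)
        assert res.theta == pytest.approx(0.5, abs=1e-10)
        assert res.meta["rss_w"] == pytest.approx(0.0, abs=1e-20)

    def test_matches_wls_oracle_with_inflation_rule(self, rng):
        for _ in range(50):
            j = int(rng.integers(4, 12))
            bx = np.abs(rng.normal(0, 0.05, j))
            by = rng.normal(0.01 + 0.4 * bx, 0.02)
            sy = rng.uniform(0.005, 0.05, j)
            res = egger(make_hset(bx, np.full(j, 0.01), by, sy))
            X = sm.add_constant(bx)
            fit = sm.WLS(by, X, weights=1 / sy**2).fit()
            rss = float(np.sum((1 / sy**2) * fit.resid**2))
            infl = max(1.0, np.sqrt(rss / (j - 2)))
            se_base = np.sqrt(np.diag(fit.normalized_cov_params))
            assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)
            assert res.theta == pytest.approx(fit.params[1], abs=1e-10)
            assert res.intercept_se == pytest.approx(se_base[0] * infl, abs=1e-10)
            assert res.se == pytest.approx(se_base[1] * infl, abs=1e-10)

    def test_orientation_flip_invariance(self, rng):
        j = 10
        bx = rng.normal(0, 0.05, j)
        by = rng.normal(0, 0.01, j)
        sy = rng.uniform(0.005, 0.05, j)
        base = egger(make_hset(bx, np.full(j, 0.01), by, sy))
        s = np.where(rng.random(j) < 0.5, -1.0, 1.0)
        flipped = egger(make_hset(bx * s, np.full(j, 0.01), by * s, sy))
        assert flipped.theta == pytest.approx(base.theta, abs=1e-12)
        assert flipped.intercept == pytest.approx(base.intercept, abs=1e-12)

    def test_too_few_instruments_rejected(self):
        h = make_hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(EstimationError, match="insufficient_instruments"):
            egger(h)


class TestWeightedMedian:
    def test_equal_weights_middle_element(self):
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.1, 0.5, 0.9])
        res = weighted_median(make_hset(bx, [0.01] * 3, by, [1.0] * 3), seed=1)
        assert res.theta == pytest.approx(0.5)

    def test_hand_interpolated_breakpoints(self):
        # ratios {0.1, 0.2, 0.8, 0.9} with weights {0.1, 0.4, 0.4, 0.1}:
        # cumulative midpoints {0.05, 0.3, 0.7, 0.95}; 0.5 interpolates to 0.5
        bx = np.ones(4)
        by = np.array([0.1, 0.2, 0.8, 0.9])
        sy = 1 / np.sqrt(np.array([0.1, 0.4, 0.4, 0.1]))
        res = weighted_median(make_hset(bx, [0.01] * 4, by, sy), seed=1)
        assert res.theta == pytest.approx(0.5, abs=1e-12)

    def test_point_estimate_invariant_to_bootstrap_seed(self, rng):
        h = sim_hset(11, J=20, theta_true=[0.1])
        r1 = weighted_median(h, n_boot=200, seed=1)
        r2 = weighted_median(h, n_boot=200, seed=99)
        assert r1.theta == r2.theta
        assert r1.se != r2.se  # bootstrap SEs differ within MC error

    def test_requires_three_instruments_and_a_seed(self):
        h = make_hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(EstimationError):
            weighted_median(h, seed=1)
        h3 = make_hset([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.15], [0.02] * 3)
        with pytest.raises(EstimationError, match="seed"):
            weighted_median(h3)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_brute_force_min_over_tails(self, rng):
        for _ in range(20):
            m = int(rng.integers(1, 30))
            p = rng.uniform(1e-6, 1, m)
            q = bh_adjust(p)
            order = np.argsort(p, kind="mergesort")
            # oracle: q_(i) = min_{k >= i} m p_(k) / k, mapped back
            q_oracle = np.empty(m)
            sorted_p = p[order]
            tail_min = np.minimum.accumulate(
                (m * sorted_p / np.arange(1, m + 1))[::-1]
            )[::-1]
            q_oracle[order] = np.minimum(tail_min, 1.0)
            np.testing.assert_allclose(q, q_oracle, atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, 0.0])


class TestOddsRatioScale:
    def test_null_effect_is_or_one(self):
        res = wald_ratio(0.1, 0.01, 0.0, 0.02)
        assert res.odds_ratio()["or"] == pytest.approx(1.0)

    def test_hand_exponentiation_matches_reported_rounding(self):
        h = make_hset([1.0], [0.01], [0.113], [0.0385])
        res = ivw(h)
        orr = res.odds_ratio()
        assert round(orr["or"], 2) == 1.12
        assert round(orr["ci_low"], 2) == 1.04
        assert round(orr["ci_high"], 2) == 1.21

    def test_or_interval_contains_or_point(self, rng):
        h = sim_hset(3, J=15, theta_true=[0.05])
        res = ivw(h)
        orr = res.odds_ratio()
        assert orr["ci_low"] <= orr["or"] <= orr["ci_high"]
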