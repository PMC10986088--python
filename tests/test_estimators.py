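"""Univariable MR estimators against independent oracles and invariants."""

import numpy as np
import pytest
from scipy import stats

from mrmediate import (
    HarmonizedSet,
    cochran_q,
    ivw,
    mode_estimate,
    mr_egger,
    wald_ratio,
    weighted_median,
)
from mrmediate.estimators import silverman_bandwidth, weighted_quantile
from mrmediate.simulate import UniSimConfig, simulate_univariable


def random_hset(seed, n=20):
    rng = np.random.default_rng(seed)
    return HarmonizedSet.from_arrays(
        beta_x=rng.normal(0.1, 0.05, n),
        se_x=rng.uniform(0.01, 0.03, n),
        beta_y=rng.normal(-0.05, 0.1, n),
        se_y=rng.uniform(0.02, 0.1, n),
    )


class TestWaldRatio:
    def test_ratio_and_first_order_se(self):
        est = wald_ratio(0.1, 0.01, -0.2, 0.05)
        assert est.beta == pytest.approx(-2.0)
        assert est.se == pytest.approx(0.5)

    def test_zero_outcome_effect(self):
        assert wald_ratio(1.0, 0.1, 0.0, 0.05).beta == 0.0

    def test_second_order_se(self):
        est = wald_ratio(0.1, 0.01, -0.2, 0.05, second_order=True)
        assert est.se == pytest.approx(0.5385164807134504, rel=1e-9)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ZeroDivisionError, match="zero_exposure_effect"):
            wald_ratio(0.0, 0.01, 0.1, 0.05)


def wls_oracle(x, y, w, intercept):
    """Generic weighted least squares via the normal equations."""
    X = np.column_stack([np.ones_like(x), x]) if intercept else x[:, None]
    W = np.diag(w)
    coef = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    cov = np.linalg.inv(X.T @ W @ X)
    return coef, cov


class TestIVW:
    def test_single_snp_equals_wald_ratio(self):
        h = HarmonizedSet.from_arrays([0.1], [0.01], [-0.2], [0.05])
        est = ivw(h)
        ref = wald_ratio(0.1, 0.01, -0.2, 0.05)
        assert est.beta == pytest.approx(ref.beta)
        assert est.se == pytest.approx(ref.se)

    def test_unit_exposure_equal_weights_gives_mean(self):
        h = HarmonizedSet.from_arrays([1, 1, 1], [0.01] * 3, [0.2, 0.4, 0.9], [0.05] * 3)
        assert ivw(h, model="fixed").beta == pytest.approx(np.mean([0.2, 0.4, 0.9]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_wls_oracle_through_origin(self, seed):
        h = random_hset(seed)
        est = ivw(h, model="fixed")
        coef, cov = wls_oracle(h.beta_x, h.beta_y, h.se_y**-2, intercept=False)
        assert est.beta == pytest.approx(coef[0], abs=1e-10)
        assert est.se == pytest.approx(np.sqrt(cov[0, 0]), abs=1e-10)

    def test_equals_inverse_variance_weighted_mean_of_ratios(self):
        h = random_hset(4)
        ratios = h.beta_y / h.beta_x
        w = h.beta_x**2 / h.se_y**2  # first-order inverse ratio variance
        assert ivw(h, model="fixed").beta == pytest.approx(np.sum(w * ratios) / np.sum(w), abs=1e-10)

    def test_random_effects_se_never_below_fixed(self):
        h = random_hset(5)
        assert ivw(h, model="multiplicative_random").se >= ivw(h, model="fixed").se


class TestEgger:
    def test_exact_line_recovered(self):
        x = np.linspace(0.05, 0.3, 10)
        y = 0.02 + (-0.5) * x
        h = HarmonizedSet.from_arrays(x, np.full(10, 0.01), y, np.full(10, 0.05))
        est, pleio = mr_egger(h)
        assert est.beta == pytest.approx(-0.5, abs=1e-12)
        assert pleio.intercept == pytest.approx(0.02, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_wls_oracle_with_intercept(self, seed):
        h = random_hset(seed)
        est, pleio = mr_egger(h, model="fixed")
        flip = np.where(h.beta_x < 0, -1.0, 1.0)
        coef, cov = wls_oracle(h.beta_x * flip, h.beta_y * flip, h.se_y**-2, intercept=True)
        assert est.beta == pytest.approx(coef[1], abs=1e-10)
        assert pleio.intercept == pytest.approx(coef[0], abs=1e-10)
        assert est.se == pytest.approx(np.sqrt(cov[1, 1]), abs=1e-10)

    def test_too_few_snps(self):
        h = HarmonizedSet.from_arrays([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.05] * 2)
        with pytest.raises(ValueError, match="too_few_snps"):
            mr_egger(h)


class TestWeightedMedian:
    def test_equal_weights_reduce_to_median(self):
        h = HarmonizedSet.from_arrays([1, 1, 1], [0.01] * 3, [1, 2, 9], [0.05] * 3)
        assert weighted_median(h, n_boot=10, seed=1).beta == pytest.approx(2.0)

    def test_interpolation_matches_quantile_function_oracle(self):
        # cumulative-weight oracle: p_j = cumsum(w) - w/2 evaluated at 0.5
        values = np.array([1.0, 2.0, 3.0, 4.0])
        weights = np.array([0.1, 0.1, 0.1, 0.7])
        assert weighted_quantile(values, weights, 0.5) == pytest.approx(3.625)
        # reconstruct through the estimator: choose se_y so the
        # first-order weights equal the target weights with beta_x = 1
        se_y = 1.0 / np.sqrt(weights)
        h = HarmonizedSet.from_arrays([1.0] * 4, [0.01] * 4, values, se_y)
        assert weighted_median(h, n_boot=10, seed=1).beta == pytest.approx(3.625)

    def test_seeded_bootstrap_is_deterministic(self):
        h = random_hset(6)
        a = weighted_median(h, n_boot=200, seed=42)
        b = weighted_median(h, n_boot=200, seed=42)
        assert a.se == b.se


class TestMode:
    def test_identical_ratios_return_common_value(self):
        h = HarmonizedSet.from_arrays([0.1, 0.2, 0.3], [0.01] * 3,
                                      [0.07, 0.14, 0.21], [0.05] * 3)
        assert mode_estimate(h, n_boot=10, seed=1).beta == pytest.approx(0.7)

    def test_mode_lands_in_tight_cluster_matching_grid_oracle(self):
        ratios = np.array([0.99, 1.00, 1.01, 5.0])
        h = HarmonizedSet.from_arrays([1.0] * 4, [0.01] * 4, ratios, [0.05] * 4)
        est = mode_estimate(h, n_boot=10, seed=1)
        # independent dense-grid argmax of the same kernel density
        hband = silverman_bandwidth(ratios)
        grid = np.linspace(ratios.min(), ratios.max(), 10_000)
        dens = np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / hband) ** 2).mean(axis=0)
        assert est.beta == pytest.approx(grid[np.argmax(dens)], abs=1e-12)
        assert 0.97 < est.beta < 1.03

    def test_weighted_mode_moves_toward_heavy_snp(self):
        # the outlying ratio carries ~90% of the inverse-variance weight
        beta_x = np.array([1.0, 1.0, 1.0, 3.0])
        se_y = np.array([0.3, 0.3, 0.3, 0.1])
        beta_y = np.array([0.99, 1.00, 1.01, 3 * 5.0])
        h = HarmonizedSet.from_arrays(beta_x, [0.01] * 4, beta_y, se_y)
        simple = mode_estimate(h, weighted=False, n_boot=10, seed=1).beta
        heavy = mode_estimate(h, weighted=True, n_boot=10, seed=1).beta
        assert simple == pytest.approx(1.0, abs=0.05)
        assert heavy > simple + 1.0


class TestCochranQ:
    def test_exact_fit_gives_zero_q(self):
        x = np.array([0.1, 0.2, 0.3])
        h = HarmonizedSet.from_arrays(x, [0.01] * 3, -0.5 * x, [0.05] * 3)
        res = cochran_q(h, "ivw")
        assert res.Q == pytest.approx(0.0, abs=1e-20)
        assert res.pval == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "q, df, expected",
        [(9.5282, 13, 0.7320), (9.4818, 12, 0.6613), (4.6105, 3, 0.2026)],
    )
    def test_upper_tail_probabilities_match_published_values(self, q, df, expected):
        assert stats.chi2.sf(q, df) == pytest.approx(expected, abs=5e-5)


class TestInvariants:
    def test_scale_equivariance(self):
        h = random_hset(9)
        c = 3.7
        scaled = HarmonizedSet.from_arrays(h.beta_x, h.se_x, c * h.beta_y, c * h.se_y)
        for method in (lambda s: ivw(s), lambda s: weighted_median(s, n_boot=50, seed=3)):
            a, b = method(h), method(scaled)
            assert b.beta == pytest.approx(c * a.beta, rel=1e-9)
            assert b.se == pytest.approx(c * a.se, rel=1e-9)

    def test_orientation_invariance(self):
        h = random_hset(10)
        flip = np.ones(len(h))
        flip[::2] = -1.0
        flipped = HarmonizedSet.from_arrays(
            flip * h.beta_x, h.se_x, flip * h.beta_y, h.se_y
        )
        assert ivw(flipped).beta == pytest.approx(ivw(h).beta, rel=1e-12)
        assert weighted_median(flipped, n_boot=10, seed=0).beta == pytest.approx(
            weighted_median(h, n_boot=10, seed=0).beta, rel=1e-12
        )
        assert mode_estimate(flipped, n_boot=10, seed=0).beta == pytest.approx(
            mode_estimate(h, n_boot=10, seed=0).beta, rel=1e-12
        )


class TestCalibration:
    """Small sampling studies on the synthetic univariable generator."""

    def test_ivw_unbiased_without_pleiotropy(self):
        ests = [
            ivw(simulate_univariable(UniSimConfig(n_snps=50, seed=s))[0]).beta
            for s in range(100)
        ]
        mc_se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert np.mean(ests) == pytest.approx(-0.5, abs=3 * mc_se + 0.02)

    def test_egger_intercept_centred_under_balanced_pleiotropy(self):
        intercepts = [
            mr_egger(simulate_univariable(
                UniSimConfig(n_snps=50, pleiotropy="balanced", seed=s))[0])[1].intercept
            for s in range(100)
        ]
        mc_se = np.std(intercepts, ddof=1) / np.sqrt(len(intercepts))
        assert np.mean(intercepts) == pytest.approx(0.0, abs=3 * mc_se)

    def test_weighted_median_beats_ivw_under_directional_pleiotropy(self):
        # 40% invalid instruments with directional pleiotropy: the
        # median stays consistent, IVW drifts
        rng = np.random.default_rng(12)
        err_ivw, err_med = [], []
        for _ in range(60):
            n, theta = 50, -0.5
            gamma = rng.normal(0.11, 0.03, n)
            alpha = np.zeros(n)
            alpha[: int(0.4 * n)] = rng.normal(0.08, 0.02, int(0.4 * n))
            bx = gamma + rng.normal(0, 0.02, n)
            by = theta * gamma + alpha + rng.normal(0, 0.05, n)
            h = HarmonizedSet.from_arrays(bx, np.full(n, 0.02), by, np.full(n, 0.05))
            err_ivw.append(abs(ivw(h).beta - theta))
            err_med.append(abs(weighted_median(h, n_boot=10, seed=0).beta - theta))
        assert np.mean(err_med) < np.mean(err_ivw)
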