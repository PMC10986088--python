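"""MR-BMA: enumeration, closed-form vs quadrature oracles, calibration."""

import numpy as np
import pytest
from scipy import integrate, stats

from mrmediate import (
    BmaConfig,
    MvmrDataset,
    bma_diagnostics,
    bma_fit,
    bma_permutation_p,
    enumerate_models,
)
from mrmediate.simulate import MvmrSimConfig, simulate_mvmr


@pytest.mark.parametrize("d, max_size, expected", [(2, 2, 3), (3, 2, 6), (1, 1, 1), (3, 3, 7)])
def test_enumerate_models_counts(d, max_size, expected):
    models = enumerate_models(d, max_size)
    assert len(models) == expected
    sizes = [len(m) for m in models]
    assert sizes == sorted(sizes)  # ordered by size then lexicographic


def small_dataset(seed=0, n=12, d=2):
    rng = np.random.default_rng(seed)
    G = 0.08 * rng.standard_normal((n, d))
    se_y = np.full(n, 0.05)
    y = 0.3 * G[:, 0] + rng.normal(0, se_y)
    return MvmrDataset(
        snp_ids=[f"s{i}" for i in range(n)],
        beta_x=G + rng.normal(0, 0.01, G.shape),
        se_x=np.full((n, d), 0.01),
        beta_y=y,
        se_y=se_y,
        factor_labels=[f"f{k}" for k in range(d)],
    )


def quadrature_log_ml(Xs, yt, sigma2):
    """Marginal likelihood from its integral definition (k <= 2)."""
    n, k = Xs.shape
    const = (2 * np.pi) ** (-n / 2)

    def integrand(*beta):
        b = np.array(beta)
        resid = yt - Xs @ b
        lik = const * np.exp(-0.5 * resid @ resid)
        prior = np.prod(stats.norm.pdf(b, 0, np.sqrt(sigma2)))
        return lik * prior

    lim = 8.0
    if k == 1:
        val, _ = integrate.quad(integrand, -lim, lim, epsabs=0, epsrel=1e-10)
    else:
        val, _ = integrate.dblquad(
            lambda b2, b1: integrand(b1, b2), -lim, lim, -lim, lim, epsabs=0, epsrel=1e-8
        )
    return np.log(val)


class TestPosteriorOracles:
    def test_single_factor_matches_two_model_bayes_factor(self):
        """d=1: MIP must equal p·BF / (p·BF + 1 - p) with the hand-derived
        Bayes factor of the one-factor model against the empty model."""
        data = small_dataset(seed=1, d=1)
        cfg = BmaConfig(prior_prob=0.1, prior_variance=0.5)
        res, est = bma_fit(data, cfg)
        xt = (data.beta_x[:, 0] / data.se_y)
        xt = xt / np.linalg.norm(xt)
        yt = data.beta_y / data.se_y
        z = xt @ yt
        s2 = 0.5
        log_bf = -0.5 * np.log1p(s2) + 0.5 * z**2 * s2 / (1 + s2)
        bf = np.exp(log_bf)
        expected_mip = 0.1 * bf / (0.1 * bf + 0.9)
        assert res.mip["f0"] == pytest.approx(expected_mip, abs=1e-12)

    @pytest.mark.parametrize("d", [2, 3, 4])
    def test_posteriors_match_quadrature_enumeration(self, d):
        """Brute-force enumeration: every model's marginal likelihood from
        its integral definition by quadrature (models of size <= 2)."""
        data = small_dataset(seed=2, d=d)
        cfg = BmaConfig(prior_prob=0.1, prior_variance=0.5, max_model_size=2)
        res, est = bma_fit(data, cfg)
        Xstd, yt = est._Xstd, est._yt
        yty = float(yt @ yt)
        logs = []
        for subset in est.model_subsets_:
            k = len(subset)
            lp = k * np.log(0.1) + (d - k) * np.log(0.9)
            logs.append(lp + quadrature_log_ml(Xstd[:, subset], yt, 0.5))
        logs.append(d * np.log(0.9) - 0.5 * len(yt) * np.log(2 * np.pi) - 0.5 * yty)
        logs = np.array(logs)
        expected = np.exp(logs - logs.max())
        expected /= expected.sum()
        np.testing.assert_allclose(est.model_posteriors_, expected[:-1], atol=1e-6)
        assert est.empty_model_posterior_ == pytest.approx(expected[-1], abs=1e-6)


class TestInvariants:
    def test_posteriors_sum_to_one_and_mip_bounded(self):
        data = small_dataset(seed=3, d=3)
        res, est = bma_fit(data, BmaConfig())
        total = est.model_posteriors_.sum() + est.empty_model_posterior_
        assert total == pytest.approx(1.0, abs=1e-12)
        assert np.all((est.mip_ >= 0) & (est.mip_ <= 1))

    def test_shrinkage_limit_prior_variance_to_zero(self):
        data = small_dataset(seed=4, d=2)
        res, est = bma_fit(data, BmaConfig(prior_variance=1e-10))
        for coefs in est.model_estimates_:
            np.testing.assert_allclose(coefs, 0.0, atol=1e-5)


class TestCalibration:
    def test_null_data_mean_mip_near_prior(self):
        """No signal: the prior should dominate every factor's MIP."""
        mips = []
        rng = np.random.default_rng(99)
        for rep in range(200):
            n, d = 100, 3
            G = 0.08 * rng.standard_normal((n, d))
            se_y = np.full(n, 0.05)
            data = MvmrDataset(
                snp_ids=[f"s{i}" for i in range(n)],
                beta_x=G,
                se_x=np.full((n, d), 0.01),
                beta_y=rng.normal(0, se_y),
                se_y=se_y,
                factor_labels=list("abc"),
            )
            _, est = bma_fit(data, BmaConfig(prior_prob=0.1))
            mips.append(est.mip_)
        assert np.mean(mips) == pytest.approx(0.1, abs=0.05)

    def test_causal_factor_ranks_top_among_correlated_candidates(self):
        wins = 0
        for rep in range(200):
            data, truth = simulate_mvmr(MvmrSimConfig(seed=rep))
            _, est = bma_fit(data, BmaConfig())
            wins += int(np.argmax(est.mip_)) == 0
        assert wins >= 180  # >= 90% of 200 replicates

    def test_permutation_p_small_for_causal_factor(self):
        data, _ = simulate_mvmr(MvmrSimConfig(seed=5))
        cfg = BmaConfig(n_perm=1000, seed=2)
        res = bma_permutation_p(data, cfg)
        assert res.empirical_p["factor_1"] <= 1 / 1001 + 1e-9
        # BH-adjusted values present and valid
        assert all(0 < q <= 1 for q in res.fdr_p.values())

    def test_permutation_p_uniform_under_null(self):
        """Null outcome: permutation p-values should be ~ Uniform(0,1)."""
        rng = np.random.default_rng(1234)
        pvals = []
        for rep in range(200):
            n, d = 60, 2
            G = 0.08 * rng.standard_normal((n, d))
            se_y = np.full(n, 0.05)
            data = MvmrDataset(
                snp_ids=[f"s{i}" for i in range(n)],
                beta_x=G,
                se_x=np.full((n, d), 0.01),
                beta_y=rng.normal(0, se_y),
                se_y=se_y,
                factor_labels=["u", "v"],
            )
            res = bma_permutation_p(data, BmaConfig(n_perm=200, seed=rep))
            pvals.extend(res.empirical_p.values())
        stat = stats.kstest(pvals, "uniform").pvalue
        assert stat > 0.01


class TestDiagnostics:
    def test_inflated_snp_flagged(self):
        data, _ = simulate_mvmr(MvmrSimConfig(seed=6))
        data.beta_y[3] *= 10.0
        _, est = bma_fit(data, BmaConfig())
        diag = bma_diagnostics(data, est)
        assert 3 in diag["flagged_indices"]

    def test_clean_data_rarely_flagged(self):
        clean = 0
        for rep in range(30):
            data, _ = simulate_mvmr(MvmrSimConfig(seed=1000 + rep))
            _, est = bma_fit(data, BmaConfig())
            diag = bma_diagnostics(data, est)
            clean += len(diag["flagged_indices"]) == 0
        assert clean >= 27  # >= 90%

    def test_excluding_flagged_snp_never_increases_q(self):
        data, _ = simulate_mvmr(MvmrSimConfig(seed=6))
        data.beta_y[3] *= 10.0
        _, est = bma_fit(data, BmaConfig())
        diag = bma_diagnostics(data, est)
        q_total = diag["q_contribution"].sum()
        kept = [i for i in range(data.n_snps) if i not in diag["flagged_indices"]]
        assert diag["q_contribution"][kept].sum() <= q_total
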