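"""Multivariable MR Bayesian model averaging (MR-BMA).

Candidate risk factors are prioritized by averaging over every
weighted-regression model formed from non-empty subsets of the factors.
Working on the inverse-variance-weighted scale (all associations
divided by the SNP-outcome standard error) the outcome residuals have
unit variance, so each model's marginal likelihood has the closed
conjugate form for a zero-mean normal prior of fixed variance on the
causal coefficients.  Per-factor evidence is summarized by the marginal
inclusion probability (MIP, the summed posterior of models containing
the factor) and the model-averaged causal effect (MACE); empirical
p-values come from permuting the outcome associations across SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

MAX_ENUM_FACTORS = 20


@dataclass
class MvmrDataset:
    """Per-SNP associations with d candidate factors and one outcome."""

    snp_ids: list[str]
    beta_x: np.ndarray  # (n_snps, d)
    se_x: np.ndarray
    beta_y: np.ndarray  # (n_snps,)
    se_y: np.ndarray
    factor_labels: list[str]

    def __post_init__(self) -> None:
        self.beta_x = np.atleast_2d(np.asarray(self.beta_x, float))
        self.se_x = np.atleast_2d(np.asarray(self.se_x, float))
        self.beta_y = np.asarray(self.beta_y, float).reshape(-1)
        self.se_y = np.asarray(self.se_y, float).reshape(-1)
        n, d = self.beta_x.shape
        if self.se_x.shape != (n, d) or self.beta_y.size != n or self.se_y.size != n:
            raise ValueError("inconsistent MvmrDataset dimensions")
        if len(self.factor_labels) != d or len(self.snp_ids) != n:
            raise ValueError("labels do not match matrix dimensions")
        if np.any(self.se_x <= 0) or np.any(self.se_y <= 0):
            raise ValueError("standard errors must be > 0")

    @property
    def n_snps(self) -> int:
        return self.beta_x.shape[0]

    @property
    def d(self) -> int:
        return self.beta_x.shape[1]


@dataclass
class BmaConfig:
    """MR-BMA settings (per-factor prior inclusion probability and the
    prior variance of standardized causal effects)."""

    prior_prob: float = 0.1
    prior_variance: float = 0.5
    max_model_size: int | None = None
    n_perm: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.prior_prob < 1):
            raise ValueError("prior_prob must be in (0,1)")
        if self.prior_variance <= 0:
            raise ValueError("prior_variance must be > 0")


@dataclass
class BmaResult:
    """Model posteriors plus per-factor MIP / MACE / empirical p (Table-3 shape)."""

    factor_labels: list[str]
    models: list[tuple[tuple[str, ...], float]]
    empty_model_posterior: float
    mip: dict[str, float]
    mace: dict[str, float]
    mace_standardized: dict[str, float]
    empirical_p: dict[str, float] = field(default_factory=dict)
    fdr_p: dict[str, float] = field(default_factory=dict)


def enumerate_models(d: int, max_model_size: int | None = None) -> list[tuple[int, ...]]:
    """All non-empty factor subsets of size <= max_model_size.

    Deterministic order: by size, then lexicographic.  The empty model
    is excluded from the model space.
    """
    if max_model_size is None:
        max_model_size = d
    if not (1 <= max_model_size <= d):
        raise ValueError("need 1 <= max_model_size <= d")
    models: list[tuple[int, ...]] = []
    for size in range(1, max_model_size + 1):
        models.extend(combinations(range(d), size))
    return models


class MRBMAEstimator(BaseEstimator):
    """Bayesian model averaging over subsets of candidate risk factors.

    fit(X, y, x_se=None, y_se=...) takes the (n_snps, d) matrix of
    SNP-factor associations and the SNP-outcome associations.  Columns
    are standardized to unit weighted second moment on the IVW scale so
    a single prior variance is meaningful for every factor; reported
    MACE values are rescaled back to the input effect scale
    (``mace_standardized_`` keeps the standardized-scale values).

    Attributes
    ----------
    model_subsets_ : list of index tuples, ordered by size then lexicographic
    model_posteriors_ : posterior probability per subset (sums to 1)
    model_estimates_ : per-model posterior-mean coefficients (standardized)
    mip_ : (d,) marginal inclusion probabilities
    mace_ : (d,) model-averaged causal effects, input scale
    mace_standardized_ : (d,) model-averaged causal effects, fitted scale
    """

    def __init__(
        self,
        prior_prob: float = 0.1,
        prior_variance: float = 0.5,
        max_model_size: int | None = None,
        standardize: bool = True,
    ):
        self.prior_prob = prior_prob
        self.prior_variance = prior_variance
        self.max_model_size = max_model_size
        self.standardize = standardize

    # -- internals ----------------------------------------------------

    def _design(self, X, y, y_se):
        """IVW-scale design: divide everything by se_y, standardize columns.

        Each factor column is scaled to unit weighted second moment
        (unit Euclidean norm on the IVW scale), so the fixed prior
        variance means the same thing for every factor and the Bayes
        factor of a null factor against the empty model is O(1).
        """
        Xt = X / y_se[:, None]
        yt = y / y_se
        if self.standardize:
            scale = np.linalg.norm(Xt, axis=0)
            if np.any(scale == 0):
                raise ValueError("a factor column is identically zero")
        else:
            scale = np.ones(X.shape[1])
        return Xt / scale, yt, scale

    @staticmethod
    def _log_marginal(Xs: np.ndarray, yty: float, Xty: np.ndarray, sigma2: float, n: int):
        """Closed-form log marginal likelihood and posterior-mean coefficients.

        y ~ N(0, I + sigma2 Xs Xs'); evaluated via the k x k Woodbury
        identity.  A = Xs'Xs + I/sigma2 is positive definite for any
        sigma2 > 0, so the Cholesky factorization cannot fail for
        rank-deficient designs.
        """
        k = Xs.shape[1]
        A = Xs.T @ Xs + np.eye(k) / sigma2
        c, low = cho_factor(A)
        beta_hat = cho_solve((c, low), Xty)
        logdet = 2.0 * np.sum(np.log(np.diag(c))) + k * np.log(sigma2)
        quad = yty - Xty @ beta_hat
        log_ml = -0.5 * n * np.log(2 * np.pi) - 0.5 * logdet - 0.5 * quad
        return log_ml, beta_hat

    def _fit_mips(self, Xstd: np.ndarray, Y: np.ndarray):
        """MIP matrix for one or many outcome vectors (columns of Y).

        The model space is the empty model plus every enumerated
        non-empty subset; the empty model (no causal factor, marginal
        likelihood N(y; 0, I)) occupies the last row of the returned
        posterior matrix.
        """
        n, d = Xstd.shape
        Y = np.atleast_2d(Y.T).T  # (n, B)
        B = Y.shape[1]
        yty = np.sum(Y**2, axis=0)
        log_prior = {}
        n_models = len(self.model_subsets_)
        log_post = np.empty((n_models + 1, B))
        for m, subset in enumerate(self.model_subsets_):
            k = len(subset)
            if k not in log_prior:
                log_prior[k] = k * np.log(self.prior_prob) + (d - k) * np.log(1 - self.prior_prob)
            Xs = Xstd[:, subset]
            A = Xs.T @ Xs + np.eye(k) / self.prior_variance
            c, low = cho_factor(A)
            XtY = Xs.T @ Y
            quad = yty - np.sum(XtY * cho_solve((c, low), XtY), axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(c))) + k * np.log(self.prior_variance)
            log_post[m] = log_prior[k] - 0.5 * (logdet + quad)
        log_post[n_models] = d * np.log(1 - self.prior_prob) - 0.5 * yty
        log_post -= log_post.max(axis=0, keepdims=True)
        post = np.exp(log_post)
        post /= post.sum(axis=0, keepdims=True)
        member = np.zeros((d, n_models + 1))
        for m, subset in enumerate(self.model_subsets_):
            member[list(subset), m] = 1.0
        return member @ post, post  # (d, B), (n_models + 1, B)

    # -- public API ---------------------------------------------------

    def fit(self, X, y, x_se=None, y_se=None):
        X = np.atleast_2d(np.asarray(X, float))
        y = np.asarray(y, float).reshape(-1)
        if y_se is None:
            raise ValueError("mr_bma: y_se is required")
        y_se = np.asarray(y_se, float).reshape(-1)
        n, d = X.shape
        if n < d + 2:
            raise ValueError(f"mr_bma needs >= d+2 SNPs (d={d}, n={n})")
        if d > MAX_ENUM_FACTORS and self.max_model_size is None:
            raise ValueError(
                f"full enumeration guarded at d <= {MAX_ENUM_FACTORS}; set max_model_size"
            )
        self.model_subsets_ = enumerate_models(d, self.max_model_size)
        Xstd, yt, scale = self._design(X, y, y_se)
        self._Xstd, self._scale, self._yse, self._yt = Xstd, scale, y_se, yt

        mips, post = self._fit_mips(Xstd, yt)
        self.model_posteriors_ = post[:-1, 0]
        self.empty_model_posterior_ = float(post[-1, 0])
        self.mip_ = mips[:, 0]
        # posterior-mean coefficients per model, for MACE
        yty = float(yt @ yt)
        self.model_estimates_ = []
        mace_std = np.zeros(d)
        for m, subset in enumerate(self.model_subsets_):
            Xs = Xstd[:, subset]
            _, beta_hat = self._log_marginal(Xs, yty, Xs.T @ yt, self.prior_variance, n)
            self.model_estimates_.append(beta_hat)
            mace_std[list(subset)] += self.model_posteriors_[m] * beta_hat
        self.mace_standardized_ = mace_std
        self.mace_ = mace_std / scale
        self.n_snps_ = n
        return self

    def permutation_pvalues(self, n_perm: int = 10_000, seed: int = 0) -> np.ndarray:
        """Empirical per-factor p-values by permuting the outcome across SNPs.

        p_k = (1 + #{null MIP_k >= observed MIP_k}) / (1 + n_perm).
        """
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        rng = np.random.default_rng(seed)
        return self._perm_impl(rng, n_perm)

    def _perm_impl(self, rng, n_perm):
        yt = self._yt
        perms = np.empty((yt.size, n_perm))
        for b in range(n_perm):
            perms[:, b] = yt[rng.permutation(yt.size)]
        null_mips, _ = self._fit_mips(self._Xstd, perms)
        exceed = np.sum(null_mips >= self.mip_[:, None], axis=1)
        return (1 + exceed) / (1 + n_perm)


def bma_fit(data: MvmrDataset, cfg: BmaConfig) -> tuple[BmaResult, MRBMAEstimator]:
    """Fit MR-BMA and package per-factor summaries (no permutation p)."""
    est = MRBMAEstimator(
        prior_prob=cfg.prior_prob,
        prior_variance=cfg.prior_variance,
        max_model_size=cfg.max_model_size,
    ).fit(data.beta_x, data.beta_y, y_se=data.se_y)
    labels = data.factor_labels
    models = [
        (tuple(labels[i] for i in subset), float(p))
        for subset, p in zip(est.model_subsets_, est.model_posteriors_)
    ]
    models.sort(key=lambda t: -t[1])
    result = BmaResult(
        factor_labels=list(labels),
        models=models,
        empty_model_posterior=est.empty_model_posterior_,
        mip={l: float(m) for l, m in zip(labels, est.mip_)},
        mace={l: float(m) for l, m in zip(labels, est.mace_)},
        mace_standardized={l: float(m) for l, m in zip(labels, est.mace_standardized_)},
    )
    return result, est


def bma_permutation_p(data: MvmrDataset, cfg: BmaConfig) -> BmaResult:
    """MR-BMA with permutation empirical p-values and BH adjustment."""
    from .mediation import bh_fdr

    result, est = bma_fit(data, cfg)
    rng = np.random.default_rng(cfg.seed)
    pvals = est._perm_impl(rng, cfg.n_perm)
    result.empirical_p = {l: float(p) for l, p in zip(data.factor_labels, pvals)}
    q = bh_fdr(list(pvals)).qvals
    result.fdr_p = {l: float(qv) for l, qv in zip(data.factor_labels, q)}
    return result


def bma_diagnostics(
    data: MvmrDataset,
    est: MRBMAEstimator,
    cooks_threshold: float | None = None,
    q_threshold: float | None = None,
) -> dict:
    """Influence/heterogeneity diagnostics on the highest-posterior model.

    Cook's distance is computed from the OLS fit of the best model on
    the IVW scale (default threshold: median of F(k, n-k)); the per-SNP
    heterogeneity contribution q_j is the squared standardized residual
    (default threshold: the upper 1% chi-square(1) point with a
    Bonferroni correction across the n SNPs, so clean data is flagged
    at a ~1% familywise rate rather than ~1% per SNP).
    """
    best = est.model_subsets_[int(np.argmax(est.model_posteriors_))]
    Xs = est._Xstd[:, best]
    yt = est._yt
    n, k = Xs.shape
    coef, *_ = np.linalg.lstsq(Xs, yt, rcond=None)
    fitted = Xs @ coef
    resid = yt - fitted
    hat = np.einsum("ij,jk,ik->i", Xs, np.linalg.pinv(Xs.T @ Xs), Xs)
    s2 = float(resid @ resid) / max(n - k, 1)
    cooks = resid**2 * hat / (k * s2 * (1 - hat) ** 2)
    q_contrib = resid**2
    if cooks_threshold is None:
        cooks_threshold = float(stats.f.ppf(0.5, k, max(n - k, 1)))
    if q_threshold is None:
        q_threshold = float(stats.chi2.ppf(1 - 0.01 / n, 1))
    flagged = sorted(
        set(np.flatnonzero(cooks > cooks_threshold)) | set(np.flatnonzero(q_contrib > q_threshold))
    )
    return {
        "best_model": best,
        "cooks_distance": cooks,
        "q_contribution": q_contrib,
        "cooks_threshold": cooks_threshold,
        "q_threshold": q_threshold,
        "flagged_indices": [int(i) for i in flagged],
        "flagged_snps": [data.snp_ids[i] for i in flagged],
    }


def bma_fit_with_diagnostics(data: MvmrDataset, cfg: BmaConfig, **thresholds) -> tuple[BmaResult, dict]:
    """Fit, flag outlying/influential SNPs, and refit after exclusion."""
    _, est = bma_fit(data, cfg)
    diag = bma_diagnostics(data, est, **thresholds)
    if diag["flagged_indices"]:
        keep = [i for i in range(data.n_snps) if i not in set(diag["flagged_indices"])]
        data = MvmrDataset(
            snp_ids=[data.snp_ids[i] for i in keep],
            beta_x=data.beta_x[keep],
            se_x=data.se_x[keep],
            beta_y=data.beta_y[keep],
            se_y=data.se_y[keep],
            factor_labels=data.factor_labels,
        )
    result = bma_permutation_p(data, cfg)
    return result, diag
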