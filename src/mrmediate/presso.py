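"""MR-PRESSO: pleiotropy residual sum of squares and outlier test.

The global test compares the observed leave-one-out residual sum of
squares against a null distribution obtained by parametric simulation
under the leave-one-out fitted model; the outlier test does the same
per SNP with Bonferroni adjustment; the corrected estimate is IVW after
removing flagged SNPs; the distortion test asks whether removing the
flagged SNPs changed the estimate more than removing random SNP subsets
of the same size would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import HarmonizedSet
from .estimators import IVWEstimator, MrEstimate, _check_xy, _normal_summary


def _loo_slopes(x, y, w):
    """Leave-one-out fixed-effect IVW slope for each SNP (vectorized)."""
    sxy = np.sum(w * x * y, axis=-1, keepdims=True)
    sxx = np.sum(w * x * x, axis=-1, keepdims=True)
    return (sxy - w * x * y) / (sxx - w * x * x)


class MRPressoEstimator(BaseEstimator):
    """MR-PRESSO global, outlier, and distortion tests with correction.

    Parameters
    ----------
    n_sim : number of parametric simulations for the null RSS distribution.
    outlier_alpha : flag threshold on the Bonferroni-adjusted per-SNP p.
    n_distortion : resamples for the distortion null.
    seed : seed for all resampling; results are bit-reproducible.

    Attributes
    ----------
    rss_obs_ : float
    global_pval_ : float  (add-one smoothed)
    outlier_snps_ : list[int]   indices of flagged SNPs
    outlier_pvals_ : ndarray    Bonferroni-adjusted per-SNP p-values
    estimate_, se_, ... : outlier-corrected IVW summary
    distortion_pval_ : float | None   (None when nothing was flagged)
    """

    def __init__(
        self,
        n_sim: int = 1000,
        outlier_alpha: float = 0.05,
        n_distortion: int = 1000,
        seed: int = 0,
    ):
        self.n_sim = n_sim
        self.outlier_alpha = outlier_alpha
        self.n_distortion = n_distortion
        self.seed = seed

    def fit(self, X, y, x_se=None, y_se=None):
        if self.n_sim < 100:
            raise ValueError("n_sim must be >= 100")
        x, y, x_se, y_se = _check_xy(X, y, x_se, y_se, 4, "mr_presso")
        if x_se is None:
            raise ValueError("mr_presso: x_se is required for the simulations")
        n = x.size
        w = y_se**-2
        rng = np.random.default_rng(self.seed)

        b_loo = _loo_slopes(x, y, w)
        obs_sq = w * (y - b_loo * x) ** 2
        self.rss_obs_ = float(np.sum(obs_sq))

        # parametric null: resample both arms about the LOO-predicted model
        xs = rng.normal(x, x_se, size=(self.n_sim, n))
        ys = rng.normal(b_loo * x, y_se, size=(self.n_sim, n))
        b_loo_sim = _loo_slopes(xs, ys, w)
        sim_sq = w * (ys - b_loo_sim * xs) ** 2
        rss_sim = sim_sq.sum(axis=1)
        self.global_pval_ = float((1 + np.sum(rss_sim >= self.rss_obs_)) / (1 + self.n_sim))

        p_snp = (1 + np.sum(sim_sq >= obs_sq[None, :], axis=0)) / (1 + self.n_sim)
        self.outlier_pvals_ = np.minimum(1.0, p_snp * n)
        flagged = np.flatnonzero(self.outlier_pvals_ < self.outlier_alpha)
        self.outlier_snps_ = flagged.tolist()

        keep = np.setdiff1d(np.arange(n), flagged)
        if keep.size == 0:
            raise ValueError("mr_presso: every SNP was flagged as an outlier")
        corrected = IVWEstimator().fit(x[keep], y[keep], y_se=y_se[keep])
        self.estimate_ = corrected.estimate_
        self.se_ = corrected.se_
        self.ci_low_, self.ci_high_, self.pval_ = _normal_summary(self.estimate_, self.se_)
        self.n_snps_ = int(keep.size)

        self.distortion_pval_ = None
        if flagged.size > 0 and keep.size >= 2:
            b_all = IVWEstimator(model="fixed").fit(x, y, y_se=y_se).estimate_
            d_obs = (b_all - self.estimate_) / abs(self.estimate_)
            null = np.empty(self.n_distortion)
            for i in range(self.n_distortion):
                drop = rng.choice(n, size=flagged.size, replace=False)
                sub = np.setdiff1d(np.arange(n), drop)
                b_sub = IVWEstimator().fit(x[sub], y[sub], y_se=y_se[sub]).estimate_
                null[i] = (b_all - b_sub) / abs(b_sub)
            self.distortion_pval_ = float(
                (1 + np.sum(np.abs(null) >= abs(d_obs))) / (1 + self.n_distortion)
            )
        return self


@dataclass
class PressoResult:
    """MR-PRESSO output: global test, per-SNP outliers, corrected IVW."""

    rss_obs: float
    global_pval: float
    outlier_snps: list[str]
    outlier_pvals: dict[str, float]
    corrected: MrEstimate
    distortion_pval: float | None = None
    flagged_indices: list[int] = field(default_factory=list)


def presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
) -> PressoResult:
    """Run MR-PRESSO on a harmonized SNP set (wrapper over the estimator)."""
    est = MRPressoEstimator(n_sim=n_sim, outlier_alpha=outlier_alpha, seed=seed).fit(
        h.beta_x, h.beta_y, x_se=h.se_x, y_se=h.se_y
    )
    ids = h.snp_ids
    corrected = MrEstimate(
        method="mr_presso",
        beta=est.estimate_,
        se=est.se_,
        ci_low=est.ci_low_,
        ci_high=est.ci_high_,
        pval=est.pval_,
        n_snps=est.n_snps_,
        or_scale=h.binary_outcome,
    )
    return PressoResult(
        rss_obs=est.rss_obs_,
        global_pval=est.global_pval_,
        outlier_snps=[ids[i] for i in est.outlier_snps_],
        outlier_pvals={ids[i]: float(p) for i, p in enumerate(est.outlier_pvals_)},
        corrected=corrected,
        distortion_pval=est.distortion_pval_,
        flagged_indices=est.outlier_snps_,
    )
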