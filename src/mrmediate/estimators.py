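"""Univariable two-sample MR estimators and their diagnostics.

All estimators consume per-SNP summary associations: the SNP-exposure
effects ``beta_x`` (standard errors ``se_x``) and the allele-aligned
SNP-outcome effects ``beta_y`` (``se_y``).  They are written as
scikit-learn style estimators — ``fit(X, y, x_se=..., y_se=...)`` with
trailing-underscore fitted attributes — so they compose with sklearn
tooling; the module-level functions (:func:`ivw`, :func:`mr_egger`,
:func:`weighted_median`, :func:`mode_estimate`) are thin wrappers that
accept a :class:`~mrmediate.datatypes.HarmonizedSet` and return a
:class:`MrEstimate` row.

Implemented methods
-------------------
wald_ratio
    Single-SNP causal estimate beta_y / beta_x with a first-order (or
    optional second-order) delta-method standard error.
IVW
    Inverse-variance-weighted estimate: weighted regression of beta_y on
    beta_x through the origin with weights se_y^-2; multiplicative
    random-effects scaling of the standard error by default.
MR-Egger
    The same weighted regression with an intercept; the intercept
    estimates average directional pleiotropy and the slope remains a
    consistent causal estimate under the InSIDE assumption.
Weighted median
    Weighted median of the per-SNP Wald ratios; consistent when at least
    half the weight comes from valid instruments.
Mode-based (simple / weighted)
    Argmax of a Gaussian kernel density over the per-SNP ratios;
    consistent when the largest cluster of ratios is formed by valid
    instruments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import HarmonizedSet

Z975 = float(stats.norm.ppf(0.975))


@dataclass
class MrEstimate:
    """One MR method's causal estimate (a Table-1 style row).

    ``beta`` is on the log-odds scale for a binary outcome; when
    ``or_scale`` is set, :meth:`as_odds_ratio` exponentiates estimate and
    confidence bounds consistently.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    or_scale: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError("confidence interval does not bracket the estimate")

    def as_odds_ratio(self) -> tuple[float, float, float]:
        """(OR, lower, upper) — exponentiated estimate and CI."""
        return (np.exp(self.beta), np.exp(self.ci_low), np.exp(self.ci_high))


@dataclass
class HeterogeneityResult:
    """Cochran's Q heterogeneity test for an MR model fit."""

    Q: float
    df: int
    pval: float


@dataclass
class PleiotropyResult:
    """MR-Egger intercept test for average directional pleiotropy."""

    intercept: float
    se: float
    pval: float


# ---------------------------------------------------------------------------
# input validation shared by the estimator classes


def _check_xy(X, y, x_se, y_se, min_snps: int, method: str):
    x = np.asarray(X, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.size != y.size:
        raise ValueError(f"{method}: X and y lengths differ")
    if x.size < min_snps:
        raise ValueError(f"too_few_snps: {method} needs >= {min_snps} SNPs, got {x.size}")
    if y_se is None:
        raise ValueError(f"{method}: y_se (outcome standard errors) is required")
    y_se = np.asarray(y_se, dtype=float).reshape(-1)
    if y_se.size != y.size or np.any(y_se <= 0):
        raise ValueError(f"{method}: y_se must be positive and match y")
    if x_se is not None:
        x_se = np.asarray(x_se, dtype=float).reshape(-1)
        if x_se.size != x.size or np.any(x_se <= 0):
            raise ValueError(f"{method}: x_se must be positive and match X")
    return x, y, x_se, y_se


def _normal_summary(beta: float, se: float) -> tuple[float, float, float]:
    """(ci_low, ci_high, pval) from normal theory."""
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    pval = float(min(1.0, 2.0 * stats.norm.sf(abs(z)))) if se > 0 else 0.0
    pval = max(pval, np.nextafter(0, 1))
    return beta - Z975 * se, beta + Z975 * se, pval


# ---------------------------------------------------------------------------
# Wald ratio


def wald_ratio(
    beta_x: float,
    se_x: float,
    beta_y: float,
    se_y: float,
    second_order: bool = False,
    or_scale: bool = False,
) -> MrEstimate:
    """Single-SNP causal estimate ``beta_y / beta_x``.

    The default standard error is the first-order delta approximation
    ``se_y / |beta_x|``; ``second_order`` adds the term propagating the
    exposure-side sampling error.
    """
    if beta_x == 0:
        raise ZeroDivisionError("zero_exposure_effect: beta_x = 0")
    if se_x <= 0 or se_y <= 0:
        raise ValueError("standard errors must be > 0")
    beta = beta_y / beta_x
    if second_order:
        se = float(np.sqrt(se_y**2 / beta_x**2 + beta_y**2 * se_x**2 / beta_x**4))
    else:
        se = se_y / abs(beta_x)
    lo, hi, p = _normal_summary(beta, se)
    return MrEstimate("wald_ratio", beta, se, lo, hi, p, 1, or_scale)


# ---------------------------------------------------------------------------
# IVW


class IVWEstimator(BaseEstimator):
    """Inverse-variance-weighted MR: origin regression of beta_y on beta_x.

    Parameters
    ----------
    model : {"multiplicative_random", "fixed"}
        Under the multiplicative random-effects model the fixed-effect
        standard error is inflated by ``max(1, sqrt(Q / df))``, which
        never shrinks it below the fixed-effect value.

    Attributes
    ----------
    estimate_, se_, ci_low_, ci_high_, pval_ : float
    n_snps_ : int
    heterogeneity_ : HeterogeneityResult
        Cochran's Q about the fixed-effect fit, df = n - 1.
    """

    def __init__(self, model: str = "multiplicative_random"):
        self.model = model

    def fit(self, X, y, x_se=None, y_se=None):
        if self.model not in ("multiplicative_random", "fixed"):
            raise ValueError(f"unknown IVW model {self.model!r}")
        x, y, _, y_se = _check_xy(X, y, x_se, y_se, 1, "ivw")
        w = y_se**-2
        sxx = float(np.sum(w * x * x))
        if sxx == 0:
            raise ValueError("ivw: all exposure effects are zero")
        beta = float(np.sum(w * x * y) / sxx)
        se_fixed = float(np.sqrt(1.0 / sxx))
        n = x.size
        Q = float(np.sum(w * (y - beta * x) ** 2))
        df = max(n - 1, 1)
        self.heterogeneity_ = HeterogeneityResult(Q, n - 1, float(stats.chi2.sf(Q, n - 1))) if n >= 2 else None
        scale = max(1.0, float(np.sqrt(Q / df))) if (self.model == "multiplicative_random" and n >= 2) else 1.0
        self.estimate_ = beta
        self.se_ = se_fixed * scale
        self.ci_low_, self.ci_high_, self.pval_ = _normal_summary(self.estimate_, self.se_)
        self.n_snps_ = n
        return self


# ---------------------------------------------------------------------------
# MR-Egger


class EggerEstimator(BaseEstimator):
    """MR-Egger: weighted regression of beta_y on beta_x with intercept.

    SNPs are oriented so every beta_x >= 0 before fitting (the intercept
    is only interpretable under a common orientation).  The slope is the
    causal estimate; a non-zero intercept indicates average directional
    pleiotropy.  Standard errors use multiplicative random-effects
    scaling with df = n - 2 by default.

    Attributes
    ----------
    estimate_, se_, ci_low_, ci_high_, pval_ : slope summary
    intercept_, intercept_se_, intercept_pval_ : pleiotropy test
    heterogeneity_ : HeterogeneityResult (Q about the Egger fit, df = n - 2)
    """

    def __init__(self, model: str = "multiplicative_random"):
        self.model = model

    def fit(self, X, y, x_se=None, y_se=None):
        x, y, _, y_se = _check_xy(X, y, x_se, y_se, 3, "mr_egger")
        flip = np.where(x < 0, -1.0, 1.0)
        x, y = x * flip, y * flip
        w = y_se**-2
        sw = np.sqrt(w)
        design = np.column_stack([np.ones_like(x), x]) * sw[:, None]
        coef, *_ = np.linalg.lstsq(design, y * sw, rcond=None)
        intercept, slope = float(coef[0]), float(coef[1])
        resid = y - (intercept + slope * x)
        n = x.size
        Q = float(np.sum(w * resid**2))
        df = n - 2
        self.heterogeneity_ = HeterogeneityResult(Q, df, float(stats.chi2.sf(Q, df)))
        xtwx_inv = np.linalg.inv(design.T @ design)
        scale = max(1.0, float(np.sqrt(Q / df))) if self.model == "multiplicative_random" else 1.0
        se_int = float(np.sqrt(xtwx_inv[0, 0])) * scale
        se_slope = float(np.sqrt(xtwx_inv[1, 1])) * scale
        self.estimate_, self.se_ = slope, se_slope
        self.ci_low_, self.ci_high_, self.pval_ = _normal_summary(slope, se_slope)
        self.intercept_, self.intercept_se_ = intercept, se_int
        _, _, self.intercept_pval_ = _normal_summary(intercept, se_int)
        self.n_snps_ = n
        return self


# ---------------------------------------------------------------------------
# ratio-based robust estimators


def _ratio_weights(x, y, y_se, method: str):
    """Per-SNP Wald ratios and first-order inverse-variance weights."""
    nonzero = x != 0
    if not np.all(nonzero):
        warnings.warn(f"{method}: dropping {np.sum(~nonzero)} SNP(s) with beta_x = 0")
    x, y, y_se = x[nonzero], y[nonzero], y_se[nonzero]
    if x.size == 0:
        raise ValueError(f"{method}: all SNPs have beta_x = 0")
    ratios = y / x
    weights = x**2 / y_se**2  # 1 / Var(ratio), first order
    return ratios, weights / weights.sum()


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float = 0.5) -> float:
    """Linear interpolation of the weighted empirical quantile function.

    With values sorted ascending and normalized weights w_j, the
    quantile function passes through (cumsum(w)_j - w_j/2, value_j).
    """
    order = np.argsort(values)
    v, w = values[order], weights[order]
    p = np.cumsum(w) - 0.5 * w
    return float(np.interp(q, p, v))


class WeightedMedianEstimator(BaseEstimator):
    """Weighted median of per-SNP Wald ratios.

    Consistent when instruments carrying >= 50% of the weight are valid.
    The standard error is a seeded parametric bootstrap: beta_x and
    beta_y are resampled from normal distributions centred on the
    observed values with the reported standard errors.
    """

    def __init__(self, n_boot: int = 1000, seed: int = 0):
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, X, y, x_se=None, y_se=None):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        x, y, x_se, y_se = _check_xy(X, y, x_se, y_se, 3, "weighted_median")
        if x_se is None:
            raise ValueError("weighted_median: x_se is required for the bootstrap")
        ratios, weights = _ratio_weights(x, y, y_se, "weighted_median")
        self.estimate_ = weighted_quantile(ratios, weights, 0.5)
        rng = np.random.default_rng(self.seed)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            xb = rng.normal(x, x_se)
            yb = rng.normal(y, y_se)
            ok = xb != 0
            rb = yb[ok] / xb[ok]
            wb = xb[ok] ** 2 / y_se[ok] ** 2
            boots[b] = weighted_quantile(rb, wb / wb.sum(), 0.5)
        self.se_ = float(np.std(boots, ddof=1))
        self.ci_low_, self.ci_high_, self.pval_ = _normal_summary(self.estimate_, self.se_)
        self.n_snps_ = x.size
        return self


def silverman_bandwidth(ratios: np.ndarray) -> float:
    """Modified Silverman rule: 0.9 min(sd, normalized MAD) n^(-1/5)."""
    n = ratios.size
    sd = float(np.std(ratios, ddof=1)) if n > 1 else 0.0
    mad = 1.4826 * float(np.median(np.abs(ratios - np.median(ratios))))
    spread = min(sd, mad) if mad > 0 else sd
    return 0.9 * spread * n ** (-0.2)


class ModeEstimator(BaseEstimator):
    """Mode-based estimate: argmax of a Gaussian KDE over Wald ratios.

    ``weighted=False`` gives the simple mode (uniform kernel weights);
    ``weighted=True`` weights each ratio by its first-order inverse
    variance, pulling the mode toward precisely estimated SNPs.  The
    density is evaluated on a fixed fine grid spanning the ratio range;
    the standard error comes from a seeded parametric bootstrap.
    """

    def __init__(
        self,
        weighted: bool = False,
        bandwidth_factor: float = 1.0,
        n_boot: int = 1000,
        seed: int = 0,
        grid_size: int = 10_000,
    ):
        self.weighted = weighted
        self.bandwidth_factor = bandwidth_factor
        self.n_boot = n_boot
        self.seed = seed
        self.grid_size = grid_size

    def _point(self, ratios: np.ndarray, weights: np.ndarray) -> float:
        h = self.bandwidth_factor * silverman_bandwidth(ratios)
        if h == 0 or ratios.min() == ratios.max():
            return float(ratios[0])  # degenerate: all ratios identical
        grid = np.linspace(ratios.min(), ratios.max(), self.grid_size)
        dens = weights @ np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2)
        return float(grid[np.argmax(dens)])

    def fit(self, X, y, x_se=None, y_se=None):
        x, y, x_se, y_se = _check_xy(X, y, x_se, y_se, 3, "mode_estimate")
        if x_se is None:
            raise ValueError("mode_estimate: x_se is required for the bootstrap")
        ratios, ivw_w = _ratio_weights(x, y, y_se, "mode_estimate")
        uniform = np.full(ratios.size, 1.0 / ratios.size)
        self.estimate_ = self._point(ratios, ivw_w if self.weighted else uniform)
        rng = np.random.default_rng(self.seed)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            xb = rng.normal(x, x_se)
            yb = rng.normal(y, y_se)
            ok = xb != 0
            rb = yb[ok] / xb[ok]
            if self.weighted:
                wb = xb[ok] ** 2 / y_se[ok] ** 2
                wb = wb / wb.sum()
            else:
                wb = np.full(rb.size, 1.0 / rb.size)
            boots[b] = self._point(rb, wb)
        self.se_ = float(np.std(boots, ddof=1))
        self.ci_low_, self.ci_high_, self.pval_ = _normal_summary(self.estimate_, self.se_)
        self.n_snps_ = x.size
        return self


# ---------------------------------------------------------------------------
# heterogeneity


def cochran_q(h: HarmonizedSet, about: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q about the fixed-effect IVW or the MR-Egger fit.

    Q = sum_j w_j (beta_y_j - fitted_j)^2 with w_j = se_y_j^-2;
    df = n - 1 for IVW, n - 2 for Egger; p is the upper chi-square tail.
    """
    if about == "ivw":
        if len(h) < 2:
            raise ValueError("too_few_snps: Q about IVW needs >= 2 SNPs")
        est = IVWEstimator(model="fixed").fit(h.beta_x, h.beta_y, y_se=h.se_y)
        return est.heterogeneity_
    if about == "egger":
        est = EggerEstimator().fit(h.beta_x, h.beta_y, y_se=h.se_y)
        return est.heterogeneity_
    raise ValueError(f"unknown heterogeneity reference {about!r}")


# ---------------------------------------------------------------------------
# HarmonizedSet-facing wrappers


def _wrap(est, method: str, h: HarmonizedSet) -> MrEstimate:
    return MrEstimate(
        method=method,
        beta=est.estimate_,
        se=est.se_,
        ci_low=est.ci_low_,
        ci_high=est.ci_high_,
        pval=est.pval_,
        n_snps=est.n_snps_,
        or_scale=h.binary_outcome,
    )


def ivw(h: HarmonizedSet, model: str = "multiplicative_random") -> MrEstimate:
    est = IVWEstimator(model=model).fit(h.beta_x, h.beta_y, y_se=h.se_y)
    return _wrap(est, "ivw", h)


def mr_egger(h: HarmonizedSet, model: str = "multiplicative_random") -> tuple[MrEstimate, PleiotropyResult]:
    est = EggerEstimator(model=model).fit(h.beta_x, h.beta_y, y_se=h.se_y)
    return (
        _wrap(est, "egger", h),
        PleiotropyResult(est.intercept_, est.intercept_se_, est.intercept_pval_),
    )


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MrEstimate:
    est = WeightedMedianEstimator(n_boot=n_boot, seed=seed).fit(
        h.beta_x, h.beta_y, x_se=h.se_x, y_se=h.se_y
    )
    return _wrap(est, "weighted_median", h)


def mode_estimate(
    h: HarmonizedSet,
    weighted: bool = False,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MrEstimate:
    est = ModeEstimator(
        weighted=weighted, bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seed
    ).fit(h.beta_x, h.beta_y, x_se=h.se_x, y_se=h.se_y)
    return _wrap(est, "weighted_mode" if weighted else "simple_mode", h)
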