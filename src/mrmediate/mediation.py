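"""Two-step MR mediation arithmetic and FDR utilities.

The indirect (mediated) effect is the product of the exposure→mediator
estimate β1 and the mediator→outcome estimate β2; the proportion
mediated divides it by the total exposure→outcome effect.  All
variances use first-order delta approximations assuming the three
estimates come from non-overlapping samples (zero covariances), which
is the design this package targets; the result carries an explicit
flag recording that assumption.

Effects are combined on the additive (log-odds for a binary outcome)
scale; odds ratios are presentation-layer transforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import Z975


@dataclass
class MediationResult:
    """Product-of-coefficients mediation summary (indirect, proportion, CIs)."""

    beta1: float
    se1: float
    beta2: float
    se2: float
    total: float
    se_total: float
    indirect: float
    indirect_se: float
    indirect_ci: tuple[float, float]
    indirect_pval: float
    proportion: float
    proportion_se: float
    proportion_ci: tuple[float, float]
    proportion_pval: float
    assumes_independent_samples: bool = True

    def indirect_odds_ratio(self) -> tuple[float, float, float]:
        """(OR, lower, upper) of the indirect effect on a binary outcome."""
        return tuple(np.exp([self.indirect, *self.indirect_ci]))


def mediate(
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    total: float,
    se_total: float,
) -> MediationResult:
    """Indirect effect β1·β2 and proportion mediated β1·β2 / total.

    Var(β1β2) = β1² se2² + β2² se1² (first-order delta); the proportion
    CI additionally propagates the sampling error of the total effect,
    with zero covariance between numerator and denominator.
    """
    for name, se in (("se1", se1), ("se2", se2), ("se_total", se_total)):
        if se <= 0:
            raise ValueError(f"{name} must be > 0")
    if total == 0:
        raise ZeroDivisionError("zero_total_effect: proportion undefined")

    indirect = beta1 * beta2
    var_ind = beta1**2 * se2**2 + beta2**2 * se1**2
    se_ind = float(np.sqrt(var_ind))
    p_ind = _two_sided_p(indirect, se_ind)

    proportion = indirect / total
    # gradient of b1*b2/T wrt (b1, b2, T)
    grad = np.array([beta2 / total, beta1 / total, -indirect / total**2])
    var_prop = float(grad @ (np.array([se1, se2, se_total]) ** 2 * grad))
    se_prop = float(np.sqrt(var_prop))
    p_prop = _two_sided_p(proportion, se_prop)

    return MediationResult(
        beta1=beta1,
        se1=se1,
        beta2=beta2,
        se2=se2,
        total=total,
        se_total=se_total,
        indirect=indirect,
        indirect_se=se_ind,
        indirect_ci=(indirect - Z975 * se_ind, indirect + Z975 * se_ind),
        indirect_pval=p_ind,
        proportion=proportion,
        proportion_se=se_prop,
        proportion_ci=(proportion - Z975 * se_prop, proportion + Z975 * se_prop),
        proportion_pval=p_prop,
    )


def _two_sided_p(est: float, se: float) -> float:
    if se == 0:
        return 1.0 if est == 0 else np.nextafter(0, 1)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(est) / se)))


@dataclass
class FdrTable:
    """Benjamini–Hochberg adjusted p-values with a q <= threshold flag."""

    pvals: np.ndarray
    qvals: np.ndarray
    significant: np.ndarray
    q_threshold: float
    m: int


def bh_fdr(pvals, m: int | None = None, q_threshold: float = 0.10) -> FdrTable:
    """Benjamini–Hochberg step-up q-values.

    ``m`` is the multiple-testing family size; it defaults to the number
    of p-values supplied but may be larger when only a subset of a wider
    screen is being adjusted.  q_i = min over j with p_j >= p_i of
    (p_j * m / rank_j), capped at 1; tests with q <= q_threshold are
    flagged significant.
    """
    p = np.asarray(pvals, float)
    if p.size and (np.any(p <= 0) or np.any(p > 1)):
        raise ValueError("p-values must be in (0,1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("family size m cannot be smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(p)
    q[order] = q_sorted
    return FdrTable(
        pvals=p,
        qvals=q,
        significant=q <= q_threshold,
        q_threshold=q_threshold,
        m=int(m),
    )
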