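"""Approximate-Bayes-factor colocalization between two traits in a region.

For each SNP and trait a Wakefield approximate Bayes factor compares the
single-SNP association model against the null; the five regional
hypotheses (no association; trait 1 only; trait 2 only; two distinct
causal variants; one shared causal variant) are assembled by summing
per-SNP and SNP-pair configurations with priors p1, p2, p12, all in
log space.  The shared-variant posterior PP4 is the evidence used to
gate instrument selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .datatypes import SummaryDataset


@dataclass
class ColocResult:
    """Posterior probabilities PP0..PP4 for the five regional hypotheses."""

    pp: np.ndarray  # length 5, sums to 1
    n_snps: int
    p1: float
    p2: float
    p12: float

    def __post_init__(self) -> None:
        self.pp = np.asarray(self.pp, float)
        if self.pp.shape != (5,) or np.any(self.pp < -1e-12):
            raise ValueError("pp must be five non-negative probabilities")
        if abs(self.pp.sum() - 1.0) > 1e-9:
            raise ValueError("posterior probabilities must sum to 1")

    @property
    def pp4(self) -> float:
        return float(self.pp[4])

    def colocalizes(self, threshold: float = 0.70) -> bool:
        """Shared-causal-variant gate: PP4 above the threshold."""
        return self.pp4 > threshold


def wakefield_log_abf(beta, se, prior_sd: float = 0.15) -> np.ndarray:
    """Log approximate Bayes factor (association vs null) per SNP.

    With z = beta/se and shrinkage r = prior_sd^2 / (prior_sd^2 + se^2):
    log ABF = 0.5 log(1 - r) + 0.5 z^2 r.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0) or prior_sd <= 0:
        raise ValueError("se and prior_sd must be > 0")
    z = beta / se
    r = prior_sd**2 / (prior_sd**2 + se**2)
    return 0.5 * np.log1p(-r) + 0.5 * z**2 * r


def coloc_pp_from_abf(
    labf1: np.ndarray,
    labf2: np.ndarray,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
) -> ColocResult:
    """Assemble the five hypothesis posteriors from per-SNP log ABFs."""
    labf1 = np.asarray(labf1, float)
    labf2 = np.asarray(labf2, float)
    if labf1.shape != labf2.shape or labf1.ndim != 1:
        raise ValueError("log ABF vectors must be 1-D and equal length")
    for name, p in (("p1", p1), ("p2", p2), ("p12", p12)):
        if not (0 < p < 1):
            raise ValueError(f"{name} must be in (0,1)")
    if p12 > min(p1, p2):
        raise ValueError("p12 must not exceed min(p1, p2)")

    l1 = logsumexp(labf1)
    l2 = logsumexp(labf2)
    l_both_same = logsumexp(labf1 + labf2)  # same causal SNP for both traits
    # sum over ordered pairs i != j : exp(l1 + l2) - exp(l_both_same)
    with np.errstate(divide="ignore"):
        l_both_diff = l1 + l2 + np.log1p(-np.exp(min(l_both_same - l1 - l2, 0.0)))

    logpost = np.array(
        [
            0.0,
            np.log(p1) + l1,
            np.log(p2) + l2,
            np.log(p1) + np.log(p2) + l_both_diff,
            np.log(p12) + l_both_same,
        ]
    )
    pp = np.exp(logpost - logsumexp(logpost))
    return ColocResult(pp=pp / pp.sum(), n_snps=labf1.size, p1=p1, p2=p2, p12=p12)


def coloc_pp(
    region_1: SummaryDataset,
    region_2: SummaryDataset,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd_1: float = 0.15,
    prior_sd_2: float = 0.15,
) -> ColocResult:
    """Colocalization posteriors for two traits over the same SNP region."""
    ids1, ids2 = region_1.snp_ids, region_2.snp_ids
    if set(ids1) != set(ids2):
        raise ValueError("region_mismatch: the two regions cover different SNP sets")
    rec2 = {r.snp_id: r for r in region_2.records}
    beta1 = np.array([r.beta for r in region_1.records])
    se1 = np.array([r.se for r in region_1.records])
    beta2 = np.array([rec2[s].beta for s in ids1])
    se2 = np.array([rec2[s].se for s in ids1])
    labf1 = wakefield_log_abf(beta1, se1, prior_sd_1)
    labf2 = wakefield_log_abf(beta2, se2, prior_sd_2)
    return coloc_pp_from_abf(labf1, labf2, p1=p1, p2=p2, p12=p12)
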