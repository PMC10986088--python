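"""Synthetic GWAS summary statistics with known causal structure.

The generators cover the designs the analysis stages need:

* a univariable exposure→outcome instrument set with optional balanced
  or directional pleiotropy;
* a three-arm exposure→mediator→outcome chain with non-overlapping
  instrument sets and a known mediated proportion;
* a pair of regional association profiles over an autoregressive LD
  block with a shared, distinct, single-trait or absent causal variant,
  for the colocalization gate;
* a correlated candidate-factor panel for multivariable MR;
* a full screening suite (exposure, biomarker panel, outcome) over a
  shared SNP panel for the end-to-end two-step pipeline.

Summary statistics are generated directly at the summary level (no
individual genotypes): observed effects are the true per-SNP effects
plus independent normal sampling noise at the stated standard errors,
and p-values are the matching two-sided normal tails.  Defaults put the
median per-SNP instrument F statistic near 30, a strong-instrument
regime.  Every generator is a pure function of its config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import AssocRecord, HarmonizedSet, LdMatrix, SummaryDataset

#: SNP-exposure effect distribution giving median per-SNP F ~ 30.  The
#: exposure-side standard error is small relative to the effect spread
#: (a large exposure GWAS), so the no-measurement-error assumption of
#: Egger regression holds to good approximation.
DEFAULT_GAMMA_MEAN = 0.055
DEFAULT_GAMMA_SD = 0.05
DEFAULT_SE_X = 0.01
DEFAULT_SE_Y = 0.05


@dataclass
class UniSimConfig:
    """One exposure→outcome instrument set."""

    n_snps: int = 50
    true_theta: float = -0.5
    gamma_mean: float = DEFAULT_GAMMA_MEAN
    gamma_sd: float = DEFAULT_GAMMA_SD
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_magnitude: float = 0.05
    se_x: float = DEFAULT_SE_X
    se_y: float = DEFAULT_SE_Y
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 2:
            raise ValueError("n_snps must be >= 2")
        if self.se_x <= 0 or self.se_y <= 0:
            raise ValueError("se scales must be > 0")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy mode {self.pleiotropy!r}")


def _pleiotropy(rng, mode: str, magnitude: float, n: int) -> np.ndarray:
    if mode == "none":
        return np.zeros(n)
    if mode == "balanced":
        return rng.normal(0.0, magnitude, n)
    return rng.normal(magnitude, magnitude / 2, n)  # directional: positive mean


def simulate_univariable(cfg: UniSimConfig) -> tuple[HarmonizedSet, dict]:
    """Draw one harmonized instrument set under the stated causal model."""
    rng = np.random.default_rng(cfg.seed)
    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, cfg.n_snps)
    alpha = _pleiotropy(rng, cfg.pleiotropy, cfg.pleiotropy_magnitude, cfg.n_snps)
    beta_x = gamma + rng.normal(0.0, cfg.se_x, cfg.n_snps)
    beta_y = cfg.true_theta * gamma + alpha + rng.normal(0.0, cfg.se_y, cfg.n_snps)
    h = HarmonizedSet.from_arrays(
        beta_x=beta_x,
        se_x=np.full(cfg.n_snps, cfg.se_x),
        beta_y=beta_y,
        se_y=np.full(cfg.n_snps, cfg.se_y),
        exposure_label="sim_exposure",
        outcome_label="sim_outcome",
    )
    truth = {
        "theta": cfg.true_theta,
        "gamma": gamma,
        "alpha": alpha,
        "config": cfg,
    }
    return h, truth


@dataclass
class ChainSimConfig:
    """Exposure→mediator→outcome chain with a known mediated proportion."""

    theta_xm: float = 0.4
    theta_my: float = 0.5
    theta_direct: float = 0.8
    n_snps_per_arm: int = 100
    gamma_mean: float = DEFAULT_GAMMA_MEAN
    gamma_sd: float = DEFAULT_GAMMA_SD
    se_x: float = DEFAULT_SE_X
    se_y: float = DEFAULT_SE_Y
    seed: int = 0

    @property
    def total_effect(self) -> float:
        return self.theta_direct + self.theta_xm * self.theta_my

    @property
    def true_proportion(self) -> float:
        if self.total_effect == 0:
            raise ZeroDivisionError("total effect is zero; proportion undefined")
        return self.theta_xm * self.theta_my / self.total_effect


def simulate_mediation_chain(cfg: ChainSimConfig) -> tuple[dict[str, HarmonizedSet], dict]:
    """Three non-overlapping instrument sets for the two-step design.

    Returns arms keyed ``exposure_mediator`` (slope theta_xm),
    ``mediator_outcome`` (slope theta_my) and ``exposure_outcome``
    (slope theta_direct + theta_xm * theta_my, the linear-scale total).
    """
    rng = np.random.default_rng(cfg.seed)
    arms: dict[str, HarmonizedSet] = {}
    for name, slope in (
        ("exposure_mediator", cfg.theta_xm),
        ("mediator_outcome", cfg.theta_my),
        ("exposure_outcome", cfg.total_effect),
    ):
        n = cfg.n_snps_per_arm
        gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, n)
        beta_x = gamma + rng.normal(0.0, cfg.se_x, n)
        beta_y = slope * gamma + rng.normal(0.0, cfg.se_y, n)
        arms[name] = HarmonizedSet.from_arrays(
            beta_x=beta_x,
            se_x=np.full(n, cfg.se_x),
            beta_y=beta_y,
            se_y=np.full(n, cfg.se_y),
            snp_ids=[f"{name}_snp{i+1}" for i in range(n)],
        )
    truth = {
        "theta_xm": cfg.theta_xm,
        "theta_my": cfg.theta_my,
        "theta_direct": cfg.theta_direct,
        "total": cfg.total_effect,
        "proportion": cfg.true_proportion,
        "config": cfg,
    }
    return arms, truth


@dataclass
class RegionSimConfig:
    """Paired regional association profiles over one LD block."""

    n_snps: int = 200
    rho: float = 0.9  # AR(1) LD decay
    configuration: str = "shared"  # shared | distinct | trait1_only | null
    noncentrality_1: float = 8.0
    noncentrality_2: float = 8.0
    n_samples_1: int = 10_000
    n_samples_2: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0,1)")
        if self.n_snps < 10:
            raise ValueError("n_snps must be >= 10")
        if self.configuration not in ("shared", "distinct", "trait1_only", "null"):
            raise ValueError(f"unknown configuration {self.configuration!r}")


def simulate_region_pair(
    cfg: RegionSimConfig,
) -> tuple[SummaryDataset, SummaryDataset, LdMatrix, dict]:
    """Two traits' marginal summary statistics over a shared LD block.

    True causal z-scores propagate through the AR(rho) LD matrix to
    marginal non-centralities; the observed z vector is one draw from
    MVN(Sigma z_true, Sigma).  Betas and standard errors are expressed
    for standardized traits at the stated sample sizes (se = n^-1/2).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    idx = np.arange(n)
    sigma = cfg.rho ** np.abs(idx[:, None] - idx[None, :])
    chol = np.linalg.cholesky(sigma + 1e-10 * np.eye(n))

    causal_1 = causal_2 = None
    if cfg.configuration == "shared":
        causal_1 = causal_2 = n // 2
    elif cfg.configuration == "distinct":
        causal_1, causal_2 = n // 5, (4 * n) // 5
    elif cfg.configuration == "trait1_only":
        causal_1 = n // 2

    snp_ids = [f"rs{i+1}" for i in range(n)]
    datasets = []
    for trait, causal, ncp, n_samp, role in (
        (1, causal_1, cfg.noncentrality_1, cfg.n_samples_1, "exposure"),
        (2, causal_2, cfg.noncentrality_2, cfg.n_samples_2, "outcome"),
    ):
        z_true = np.zeros(n)
        if causal is not None:
            z_true[causal] = ncp
        z_obs = sigma @ z_true + chol @ rng.standard_normal(n)
        se = np.full(n, 1.0 / np.sqrt(n_samp))
        beta = z_obs * se
        pvals = np.clip(2 * stats.norm.sf(np.abs(z_obs)), np.nextafter(0, 1), 1.0)
        records = [
            AssocRecord(
                snp_id=snp_ids[j],
                chrom="1",
                pos=(j + 1) * 1000,
                effect_allele="A",
                other_allele="G",
                eaf=0.3,
                beta=float(beta[j]),
                se=float(se[j]),
                pval=float(pvals[j]),
                n=n_samp,
            )
            for j in range(n)
        ]
        datasets.append(
            SummaryDataset(trait_label=f"region_trait{trait}", role=role, records=records)
        )
    ld = LdMatrix(snp_ids=snp_ids, r=sigma)
    truth = {
        "configuration": cfg.configuration,
        "causal_1": causal_1,
        "causal_2": causal_2,
        "config": cfg,
    }
    return datasets[0], datasets[1], ld, truth


@dataclass
class MvmrSimConfig:
    """Correlated candidate-factor panel for multivariable MR.

    SNP-factor effects are zero-mean multivariate normal with pairwise
    correlation ``factor_cor`` across factors, the regime in which
    model averaging must separate a causal factor from its correlated
    proxies; ``causal`` lists the factor indices with a real effect
    ``theta`` on the outcome.
    """

    n_snps: int = 150
    d: int = 3
    factor_cor: float = 0.6
    causal: tuple[int, ...] = (0,)
    theta: float = 0.3
    effect_sd: float = 0.09
    se_x: float = DEFAULT_SE_X
    se_y: float = DEFAULT_SE_Y
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.factor_cor < 1):
            raise ValueError("factor_cor must be in [0,1)")
        if any(not 0 <= c < self.d for c in self.causal):
            raise ValueError("causal indices out of range")


def simulate_mvmr(cfg: MvmrSimConfig):
    """Draw one MVMR dataset with known causal factors.

    Returns ``(MvmrDataset, truth)``; ``truth['theta']`` holds the
    per-factor causal effects (zero for non-causal factors).
    """
    from .bma import MvmrDataset

    rng = np.random.default_rng(cfg.seed)
    C = cfg.factor_cor * np.ones((cfg.d, cfg.d)) + (1 - cfg.factor_cor) * np.eye(cfg.d)
    G = cfg.effect_sd * rng.standard_normal((cfg.n_snps, cfg.d)) @ np.linalg.cholesky(C).T
    theta = np.zeros(cfg.d)
    theta[list(cfg.causal)] = cfg.theta
    beta_x = G + rng.normal(0.0, cfg.se_x, G.shape)
    beta_y = G @ theta + rng.normal(0.0, cfg.se_y, cfg.n_snps)
    data = MvmrDataset(
        snp_ids=[f"mv_snp{i+1}" for i in range(cfg.n_snps)],
        beta_x=beta_x,
        se_x=np.full(G.shape, cfg.se_x),
        beta_y=beta_y,
        se_y=np.full(cfg.n_snps, cfg.se_y),
        factor_labels=[f"factor_{k+1}" for k in range(cfg.d)],
    )
    return data, {"theta": theta, "true_effects": G, "config": cfg}


# ---------------------------------------------------------------------------
# full-screen suite for the two-step pipeline


@dataclass
class ScreenSimConfig:
    """A complete synthetic study: exposure, biomarker panel, outcome.

    One biomarker (``true_mediator_index``) sits on the causal chain
    with effects ``theta_xm`` and ``theta_my``; the rest are null in
    both steps.  Every dataset reports the full SNP panel so that
    harmonization, instrument selection and MR-BMA all have complete
    inputs.  Each instrument block lives on its own chromosome.
    """

    n_biomarkers: int = 10
    true_mediator_index: int = 0
    #: optional biomarker affected by the exposure but with no effect on
    #: the outcome (passes step 1, must not reach mediation)
    step1_only_index: int | None = None
    theta_xm: float = 0.4
    theta_my: float = 0.5
    theta_direct: float = 0.8
    n_instruments_exposure: int = 20
    n_instruments_biomarker: int = 10
    #: instrument effects emulate strong cis-acting eQTL/pQTL signals
    #: (per-SNP F around 100), not the weaker genome-wide regime
    gamma_mean: float = 0.15
    gamma_sd: float = 0.04
    se_scale: float = 0.015
    #: outcome GWAS noise; emulates a large case-control meta-analysis,
    #: where per-SNP log-odds standard errors sit near 0.02
    se_outcome: float = 0.02
    seed: int = 0

    @property
    def total_effect(self) -> float:
        return self.theta_direct + self.theta_xm * self.theta_my

    @property
    def true_proportion(self) -> float:
        return self.theta_xm * self.theta_my / self.total_effect


def _records_from_arrays(snp_ids, chroms, positions, beta, se, rng, n=50_000):
    pvals = np.clip(2 * stats.norm.sf(np.abs(beta / se)), np.nextafter(0, 1), 1.0)
    alleles = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    return [
        AssocRecord(
            snp_id=snp_ids[j],
            chrom=str(chroms[j]),
            pos=int(positions[j]),
            effect_allele=alleles[j % 4][0],
            other_allele=alleles[j % 4][1],
            eaf=float(np.round(0.1 + 0.8 * ((j * 37) % 100) / 100.0, 3)),
            beta=float(beta[j]),
            se=float(se[j]),
            pval=float(pvals[j]),
            n=n,
        )
        for j in range(len(snp_ids))
    ]


def simulate_screen_suite(cfg: ScreenSimConfig) -> tuple[dict, dict]:
    """Generate the datasets for a full two-step mediation screen.

    Returns ``(data, truth)`` where ``data`` holds the exposure
    SummaryDataset, the list of biomarker SummaryDatasets and the
    outcome SummaryDataset, all over one shared SNP panel.
    """
    rng = np.random.default_rng(cfg.seed)
    K = cfg.n_biomarkers
    n_x, n_m = cfg.n_instruments_exposure, cfg.n_instruments_biomarker
    n_panel = n_x + K * n_m

    # panel layout: exposure block on chrom 1, biomarker k block on chrom k+2
    chroms = ["1"] * n_x + [str(k + 2) for k in range(K) for _ in range(n_m)]
    positions = np.concatenate(
        [1_000_000 * (np.arange(n_x) + 1)]
        + [1_000_000 * (np.arange(n_m) + 1) for _ in range(K)]
    )
    snp_ids = [f"rs{j+1:05d}" for j in range(n_panel)]

    # true per-SNP effects on each trait
    gamma = rng.normal(cfg.gamma_mean, cfg.gamma_sd, n_x)  # SNP -> exposure
    delta = rng.normal(cfg.gamma_mean, cfg.gamma_sd, (K, n_m))  # SNP -> own biomarker

    true_x = np.zeros(n_panel)
    true_x[:n_x] = gamma
    true_m = np.zeros((K, n_panel))
    true_y = np.zeros(n_panel)
    true_y[:n_x] = cfg.total_effect * gamma
    for k in range(K):
        block = slice(n_x + k * n_m, n_x + (k + 1) * n_m)
        true_m[k, block] = delta[k]
        if k == cfg.true_mediator_index:
            true_m[k, :n_x] = cfg.theta_xm * gamma
            true_y[block] = cfg.theta_my * delta[k]
        elif k == cfg.step1_only_index:
            true_m[k, :n_x] = cfg.theta_xm * gamma  # exposure moves it, outcome ignores it

    se_x = np.full(n_panel, cfg.se_scale)
    se_m = np.full(n_panel, cfg.se_scale)
    se_y = np.full(n_panel, cfg.se_outcome)

    exposure = SummaryDataset(
        trait_label="exposure",
        role="exposure",
        records=_records_from_arrays(
            snp_ids, chroms, positions, true_x + rng.normal(0, se_x), se_x, rng
        ),
        scale_note="per 1-SD lowering of the intermediate trait",
    )
    biomarkers = [
        SummaryDataset(
            trait_label=f"biomarker_{k+1}",
            role="mediator",
            records=_records_from_arrays(
                snp_ids, chroms, positions, true_m[k] + rng.normal(0, se_m), se_m, rng
            ),
        )
        for k in range(K)
    ]
    outcome = SummaryDataset(
        trait_label="outcome",
        role="outcome",
        records=_records_from_arrays(
            snp_ids, chroms, positions, true_y + rng.normal(0, se_y), se_y, rng
        ),
        binary_outcome=True,
    )
    truth = {
        "true_mediator": f"biomarker_{cfg.true_mediator_index + 1}",
        "theta_xm": cfg.theta_xm,
        "theta_my": cfg.theta_my,
        "total": cfg.total_effect,
        "proportion": cfg.true_proportion,
        "config": cfg,
    }
    return {"exposure": exposure, "biomarkers": biomarkers, "outcome": outcome}, truth
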