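"""Two-step screening pipeline: exposure → biomarkers → outcome.

Step 1 estimates the exposure's effect on every candidate biomarker
with the exposure's instruments and applies Benjamini–Hochberg FDR
across the biomarker family.  Step 2 instruments each surviving
biomarker and estimates its effect on the outcome, with FDR over the
set actually tested.  Biomarkers significant in both steps enter
multivariable MR Bayesian model averaging; the top-ranked factor's
mediated effect and proportion are then computed by the product of
coefficients against the exposure's total effect on the outcome.

Every threshold is configuration; the defaults are the drug-target MR
conventions this package targets (genome-wide 5e-8 with 5e-7 fallback
at fewer than 3 SNPs, clumping r² 0.001 within 10,000 kb for biomarker
instruments and r² 0.8 within 250 kb for the drug-target instruments,
colocalization gate PP4 > 0.70, FDR q <= 0.10).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bma import BmaConfig, BmaResult, MvmrDataset, bma_fit_with_diagnostics
from .coloc import coloc_pp
from .datatypes import HarmonizedSet, InstrumentSet, LdMatrix, SummaryDataset
from .estimators import cochran_q, ivw, mode_estimate, mr_egger, weighted_median
from .harmonize import HarmonizationError, harmonize
from .instruments import InstrumentSelectionError, clump, f_statistics, select_instruments
from .mediation import MediationResult, bh_fdr, mediate
from .presso import presso


@dataclass
class RunConfig:
    """All thresholds and seeds for one end-to-end screen."""

    # biomarker instrument preset
    p_primary: float = 5e-8
    p_fallback: float = 5e-7
    min_snps: int = 3
    biomarker_clump_r2: float = 0.001
    biomarker_clump_kb: float = 10_000.0
    # exposure (drug-target) instrument preset
    exposure_p: float = 1e-4
    eqtl_p: float = 1e-3
    coloc_pp4_threshold: float = 0.70
    exposure_clump_r2: float = 0.8
    exposure_clump_kb: float = 250.0
    # testing rules
    fdr_q: float = 0.10
    alpha: float = 0.05
    fdr_family_step1: int | None = None
    # estimators
    methods: tuple[str, ...] = ("ivw", "egger", "wmedian", "smode", "wmode", "presso")
    palindrome_eaf_window: float = 0.08
    # MR-BMA
    prior_prob: float = 0.1
    prior_variance: float = 0.5
    n_perm: int = 10_000
    # misc
    exclude_snps: tuple[str, ...] = ()
    seed: int = 17

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("methods", "exclude_snps"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ScreenReport:
    """All tables and logs produced by one two-step screen."""

    total_effect: object  # MrEstimate for exposure -> outcome
    battery: pd.DataFrame  # Table-1 style sensitivity battery
    step1: pd.DataFrame
    step2: pd.DataFrame
    bma: BmaResult | None
    bma_diagnostics: dict | None
    mediation: dict[str, MediationResult]
    no_instruments: list[str]
    logs: list[str]
    seeds: dict[str, int]


def drug_target_instruments(
    eqtl: SummaryDataset,
    trait: SummaryDataset,
    cfg: RunConfig,
    ld: LdMatrix | None = None,
) -> InstrumentSet:
    """Expression-based instrument selection with a colocalization gate.

    SNPs associated with target gene expression (p < eqtl_p) are
    intersected with SNPs associated with the downstream trait
    (p < exposure_p); the region must colocalize (PP4 above threshold)
    for the instruments to be accepted, and survivors are LD-clumped.
    """
    eqtl_hits = [r for r in eqtl.records if r.pval < cfg.eqtl_p]
    if not eqtl_hits:
        raise InstrumentSelectionError("insufficient_instruments: no eQTL hits")
    res = coloc_pp(eqtl.subset([r.snp_id for r in eqtl.records if r.snp_id in trait]),
                   trait.subset([r.snp_id for r in eqtl.records if r.snp_id in trait]))
    if not res.colocalizes(cfg.coloc_pp4_threshold):
        raise InstrumentSelectionError(
            f"coloc_gate_failed: PP4={res.pp4:.3f} <= {cfg.coloc_pp4_threshold}"
        )
    trait_hits = [
        trait.get(r.snp_id)
        for r in eqtl_hits
        if r.snp_id in trait and trait.get(r.snp_id).pval < cfg.exposure_p
    ]
    if not trait_hits:
        raise InstrumentSelectionError("insufficient_instruments: no trait-associated eQTL SNPs")
    out = clump(trait_hits, ld, cfg.exposure_clump_r2, cfg.exposure_clump_kb)
    out.selection_log.insert(0, (f"eqtl p<{cfg.eqtl_p:g}", len(eqtl), len(eqtl_hits)))
    out.selection_log.insert(1, (f"trait p<{cfg.exposure_p:g} + coloc PP4>{cfg.coloc_pp4_threshold}",
                                 len(eqtl_hits), len(trait_hits)))
    return out


def univariable_battery(h: HarmonizedSet, methods, seeds: dict[str, int]) -> pd.DataFrame:
    """Table-1 style battery of univariable estimates and diagnostics."""
    rows = []
    for m in methods:
        row = {"method": m, "nsnp": len(h)}
        try:
            if m == "ivw":
                est = ivw(h)
                q = cochran_q(h, "ivw")
                row.update(_est_cols(est), Q=q.Q, p_het=q.pval)
            elif m == "egger":
                est, pleio = mr_egger(h)
                q = cochran_q(h, "egger")
                row.update(
                    _est_cols(est),
                    Q=q.Q,
                    p_het=q.pval,
                    egger_intercept=pleio.intercept,
                    p_intercept=pleio.pval,
                )
            elif m == "wmedian":
                row.update(_est_cols(weighted_median(h, seed=seeds["wmedian"])))
            elif m == "smode":
                row.update(_est_cols(mode_estimate(h, weighted=False, seed=seeds["smode"])))
            elif m == "wmode":
                row.update(_est_cols(mode_estimate(h, weighted=True, seed=seeds["wmode"])))
            elif m == "presso":
                res = presso(h, seed=seeds["presso"])
                row.update(
                    _est_cols(res.corrected),
                    nsnp=res.corrected.n_snps,
                    rss_obs=res.rss_obs,
                    global_p=res.global_pval,
                    n_outliers=len(res.outlier_snps),
                )
            else:
                raise ValueError(f"unknown method {m!r}")
        except (ValueError, ZeroDivisionError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def _est_cols(est) -> dict:
    cols = {
        "beta": est.beta,
        "se": est.se,
        "pval": est.pval,
    }
    if est.or_scale:
        o, lo, hi = est.as_odds_ratio()
        cols.update({"or": o, "or_ci_low": lo, "or_ci_high": hi})
    else:
        cols.update({"ci_low": est.ci_low, "ci_high": est.ci_high})
    return cols


def _stage_seeds(seed: int) -> dict[str, int]:
    """Expand one top-level seed into fixed per-stage seeds."""
    rng = np.random.default_rng(seed)
    names = ["wmedian", "smode", "wmode", "presso", "bma", "mediation"]
    return {name: int(rng.integers(0, 2**31 - 1)) for name in names}


def run_two_step_screen(
    exposure: SummaryDataset,
    biomarkers: list[SummaryDataset],
    outcome: SummaryDataset,
    cfg: RunConfig,
    ld: LdMatrix | None = None,
    out_dir: str | Path | None = None,
) -> ScreenReport:
    """Execute the full two-step mediation screen (see module docstring).

    Per-biomarker failures (no overlap, too few instruments) are logged
    and skipped; only unreadable inputs are fatal.
    """
    seeds = _stage_seeds(cfg.seed)
    logs = [f"top-level seed {cfg.seed}", f"stage seeds {seeds}"]

    # exposure instruments: p-threshold, optional exclusion list, clumping
    cand = [
        r
        for r in exposure.records
        if r.pval < cfg.exposure_p and r.snp_id not in set(cfg.exclude_snps)
    ]
    if not cand:
        raise InstrumentSelectionError("insufficient_instruments: no exposure instruments")
    x_instr = clump(cand, ld, cfg.exposure_clump_r2, cfg.exposure_clump_kb)
    logs.append(f"exposure instruments: {len(x_instr)} SNPs ({x_instr.selection_log})")
    x_ds = exposure.subset(x_instr.snp_ids)

    # total effect and sensitivity battery on the outcome
    h_total = harmonize(x_ds, outcome, cfg.palindrome_eaf_window)
    fstats = f_statistics(h_total)
    logs.append(f"mean instrument F = {fstats['mean_f']:.2f}")
    total_est = ivw(h_total)
    battery = univariable_battery(h_total, cfg.methods, seeds)

    # step 1: exposure -> each biomarker
    step1_rows = []
    for bm in biomarkers:
        try:
            h1 = harmonize(x_ds, bm, cfg.palindrome_eaf_window)
            est = ivw(h1)
            step1_rows.append(
                {
                    "biomarker": bm.trait_label,
                    "nsnp": est.n_snps,
                    "beta": est.beta,
                    "se": est.se,
                    "or": float(np.exp(est.beta)),
                    "or_ci_low": float(np.exp(est.ci_low)),
                    "or_ci_high": float(np.exp(est.ci_high)),
                    "pval": est.pval,
                }
            )
        except (HarmonizationError, ValueError) as exc:
            logs.append(f"step1 {bm.trait_label}: skipped ({exc})")
    step1 = pd.DataFrame(step1_rows)
    if len(step1):
        fam1 = cfg.fdr_family_step1 or len(biomarkers)
        fdr1 = bh_fdr(step1["pval"].tolist(), m=fam1, q_threshold=cfg.fdr_q)
        step1["qval"] = fdr1.qvals
        step1["significant"] = fdr1.significant
    else:
        step1 = pd.DataFrame(
            columns=["biomarker", "nsnp", "beta", "se", "or", "or_ci_low",
                     "or_ci_high", "pval", "qval", "significant"]
        )

    flagged1 = step1.loc[step1.get("significant", pd.Series(dtype=bool)).fillna(False), "biomarker"].tolist()
    logs.append(f"step1 significant at q<={cfg.fdr_q}: {flagged1}")

    # step 2: each flagged biomarker -> outcome
    by_label = {bm.trait_label: bm for bm in biomarkers}
    step2_rows, no_instruments, step2_instr = [], [], {}
    for label in flagged1:
        bm = by_label[label]
        try:
            sel = select_instruments(bm, cfg.p_primary, cfg.p_fallback, cfg.min_snps)
            cl = clump(sel.records, ld, cfg.biomarker_clump_r2, cfg.biomarker_clump_kb)
            if len(cl) < cfg.min_snps:
                raise InstrumentSelectionError(
                    f"insufficient_instruments: {len(cl)} after clumping"
                )
            h2 = harmonize(bm.subset(cl.snp_ids), outcome, cfg.palindrome_eaf_window)
            est = ivw(h2)
            step2_instr[label] = h2.snp_ids
            step2_rows.append(
                {
                    "biomarker": label,
                    "nsnp": est.n_snps,
                    "beta": est.beta,
                    "se": est.se,
                    "or": float(np.exp(est.beta)),
                    "or_ci_low": float(np.exp(est.ci_low)),
                    "or_ci_high": float(np.exp(est.ci_high)),
                    "pval": est.pval,
                }
            )
        except (InstrumentSelectionError, HarmonizationError, ValueError) as exc:
            no_instruments.append(label)
            logs.append(f"step2 {label}: no_instruments ({exc})")
    step2 = pd.DataFrame(step2_rows)
    if len(step2):
        fdr2 = bh_fdr(step2["pval"].tolist(), q_threshold=cfg.fdr_q)
        step2["qval"] = fdr2.qvals
        step2["significant"] = fdr2.significant
    else:
        step2 = pd.DataFrame(
            columns=["biomarker", "nsnp", "beta", "se", "or", "or_ci_low",
                     "or_ci_high", "pval", "qval", "significant"]
        )
    flagged2 = step2.loc[step2.get("significant", pd.Series(dtype=bool)).fillna(False), "biomarker"].tolist()
    logs.append(f"step2 significant at q<={cfg.fdr_q}: {flagged2}")

    # MR-BMA over biomarkers significant in both steps
    bma_result = bma_diag = None
    mediation_results: dict[str, MediationResult] = {}
    if flagged2:
        mv = _build_mvmr(outcome, [by_label[l] for l in flagged2],
                         sorted({s for l in flagged2 for s in step2_instr[l]}),
                         cfg.palindrome_eaf_window)
        if mv is not None and mv.n_snps >= mv.d + 2:
            bma_cfg = BmaConfig(
                prior_prob=cfg.prior_prob,
                prior_variance=cfg.prior_variance,
                n_perm=cfg.n_perm,
                seed=seeds["bma"],
            )
            bma_result, bma_diag = bma_fit_with_diagnostics(mv, bma_cfg)
            logs.append(f"MR-BMA MIP: {bma_result.mip}")
            top = max(bma_result.mip, key=bma_result.mip.get)
        else:
            logs.append("MR-BMA skipped: too few shared SNPs")
            top = flagged2[0]
        r1 = step1.set_index("biomarker").loc[top]
        r2 = step2.set_index("biomarker").loc[top]
        mediation_results[top] = mediate(
            beta1=float(r1["beta"]),
            se1=float(r1["se"]),
            beta2=float(r2["beta"]),
            se2=float(r2["se"]),
            total=total_est.beta,
            se_total=total_est.se,
        )

    report = ScreenReport(
        total_effect=total_est,
        battery=battery,
        step1=step1,
        step2=step2,
        bma=bma_result,
        bma_diagnostics=bma_diag,
        mediation=mediation_results,
        no_instruments=no_instruments,
        logs=logs,
        seeds=seeds,
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def _build_mvmr(outcome, biomarker_list, union_snps, window) -> MvmrDataset | None:
    """Align every factor's effects to the outcome's effect alleles."""
    out_sub = outcome.subset([s for s in union_snps if s in outcome])
    if len(out_sub) == 0:
        return None
    cols, keep_ids = [], None
    for bm in biomarker_list:
        try:
            h = harmonize(out_sub, bm, window)
        except HarmonizationError:
            return None
        ids = set(h.snp_ids)
        keep_ids = ids if keep_ids is None else keep_ids & ids
        cols.append(h)
    keep = sorted(keep_ids or set())
    if not keep:
        return None
    beta_x = np.column_stack(
        [h.table.set_index("snp_id").loc[keep, "beta_y"].to_numpy() for h in cols]
    )
    se_x = np.column_stack(
        [h.table.set_index("snp_id").loc[keep, "se_y"].to_numpy() for h in cols]
    )
    out_tab = cols[0].table.set_index("snp_id").loc[keep]
    return MvmrDataset(
        snp_ids=keep,
        beta_x=beta_x,
        se_x=se_x,
        beta_y=out_tab["beta_x"].to_numpy(),
        se_y=out_tab["se_x"].to_numpy(),
        factor_labels=[bm.trait_label for bm in biomarker_list],
    )


def write_report(report: ScreenReport, out_dir: str | Path) -> None:
    """Write table1/table2/table3 TSVs, mediation.json and run.log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = dict(sep="\t", index=False, float_format="%.6g")
    report.battery.to_csv(out / "table1.tsv", **fmt)
    report.step1.to_csv(out / "table2.tsv", **fmt)
    step2_path = out / "table2b.tsv"
    report.step2.to_csv(step2_path, **fmt)
    if report.bma is not None:
        rows = [
            {
                "factor": l,
                "MIP": report.bma.mip[l],
                "MACE": report.bma.mace[l],
                "empirical_p": report.bma.empirical_p.get(l),
                "fdr_p": report.bma.fdr_p.get(l),
            }
            for l in sorted(report.bma.mip, key=report.bma.mip.get, reverse=True)
        ]
        pd.DataFrame(rows).to_csv(out / "table3.tsv", **fmt)
        pd.DataFrame(
            [{"model": "+".join(m), "posterior": p} for m, p in report.bma.models]
        ).to_csv(out / "model_ranking.tsv", **fmt)
    med = {
        label: {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(res).items()
        }
        for label, res in report.mediation.items()
    }
    with open(out / "mediation.json", "w") as fh:
        json.dump(med, fh, indent=2, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(report.logs + [f"no_instruments: {report.no_instruments}"]) + "\n")
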