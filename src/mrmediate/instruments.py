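"""Instrument selection: p-value thresholding, LD clumping, F statistics.

The selection conventions mirror standard drug-target MR practice: a
primary genome-wide threshold with a suggestive fallback when too few
SNPs survive, greedy LD clumping within a physical window, and a per-SNP
F statistic with the conventional F > 10 strength rule.
"""

from __future__ import annotations

import numpy as np

from .datatypes import AssocRecord, HarmonizedSet, InstrumentSet, LdMatrix

WEAK_INSTRUMENT_F = 10.0


class InstrumentSelectionError(ValueError):
    pass


def select_instruments(
    ds,
    p_primary: float = 5e-8,
    p_fallback: float = 5e-7,
    min_snps: int = 3,
) -> InstrumentSet:
    """Select instruments at ``p_primary``, falling back to ``p_fallback``.

    If fewer than ``min_snps`` SNPs pass the primary threshold the looser
    fallback threshold is applied instead; failure to reach ``min_snps``
    even then raises :class:`InstrumentSelectionError`.
    """
    if not (0 < p_primary <= p_fallback < 1):
        raise ValueError("need 0 < p_primary <= p_fallback < 1")
    if min_snps < 1:
        raise ValueError("min_snps must be >= 1")
    records = list(ds.records)
    n0 = len(records)
    primary = [r for r in records if r.pval < p_primary]
    if len(primary) >= min_snps:
        return InstrumentSet(
            records=primary,
            selection_log=[(f"pval<{p_primary:g} (primary)", n0, len(primary))],
        )
    fallback = [r for r in records if r.pval < p_fallback]
    log = [
        (f"pval<{p_primary:g} (primary, insufficient)", n0, len(primary)),
        (f"pval<{p_fallback:g} (fallback)", n0, len(fallback)),
    ]
    if len(fallback) < min_snps:
        raise InstrumentSelectionError(
            f"insufficient_instruments: {len(fallback)} SNPs at p<{p_fallback:g}, "
            f"need {min_snps}"
        )
    return InstrumentSet(records=fallback, selection_log=log)


def clump(
    candidates: list[AssocRecord],
    ld: LdMatrix | None,
    r2_threshold: float = 0.001,
    kb_window: float = 10_000.0,
) -> InstrumentSet:
    """Greedy LD clumping of candidate SNPs.

    Candidates are visited in order of ascending p-value (ties broken by
    ascending position then snp_id); each kept SNP removes every
    remaining candidate on the same chromosome within ``kb_window``
    kilobases whose r² with it reaches ``r2_threshold``.  SNPs absent
    from the LD matrix are treated as independent of all others.
    """
    if not candidates:
        raise InstrumentSelectionError("no_candidates: empty candidate list")
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must be in (0,1]")
    if kb_window <= 0:
        raise ValueError("kb_window must be > 0")

    ordered = sorted(candidates, key=lambda r: (r.pval, r.pos, r.snp_id))
    kept: list[AssocRecord] = []
    removed: set[str] = set()
    for rec in ordered:
        if rec.snp_id in removed:
            continue
        kept.append(rec)
        for other in ordered:
            if other.snp_id == rec.snp_id or other.snp_id in removed:
                continue
            if other.chrom != rec.chrom:
                continue
            if abs(other.pos - rec.pos) / 1000.0 > kb_window:
                continue
            if ld is None or rec.snp_id not in ld or other.snp_id not in ld:
                continue  # unknown LD: treat as independent
            if ld.r2(rec.snp_id, other.snp_id) >= r2_threshold:
                removed.add(other.snp_id)
    return InstrumentSet(
        records=kept,
        selection_log=[
            (f"clump r2>={r2_threshold:g} within {kb_window:g} kb", len(candidates), len(kept))
        ],
    )


def f_statistics(h: HarmonizedSet) -> dict:
    """Per-SNP instrument-strength F statistics from the exposure arm.

    Uses the squared-z approximation F_j = (beta_x_j / se_x_j)^2, which
    needs neither allele frequencies nor sample sizes.  SNPs with
    F <= 10 are flagged as weak.
    """
    if len(h) == 0:
        raise ValueError("empty HarmonizedSet")
    f = (h.beta_x / h.se_x) ** 2
    return {
        "per_snp": dict(zip(h.snp_ids, f.tolist())),
        "mean_f": float(np.mean(f)),
        "weak": {s: bool(fj <= WEAK_INSTRUMENT_F) for s, fj in zip(h.snp_ids, f)},
    }
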