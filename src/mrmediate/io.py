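"""Readers and writers for the delimited-text exchange formats.

GWAS summary statistics travel as tab-delimited UTF-8 tables with the
canonical header ``snp_id chrom pos effect_allele other_allele eaf beta
se pval n`` ("NA" for missing); LD matrices as square tables whose first
row and column carry the SNP identifiers.  Round-trips are loss-free.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AssocRecord, LdMatrix, SummaryDataset

GWAS_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]


def read_gwas_tsv(
    path: str | Path,
    trait_label: str,
    role: str,
    column_map: dict[str, str] | None = None,
    scale_note: str = "",
    binary_outcome: bool = False,
) -> SummaryDataset:
    """Read a GWAS summary TSV into a :class:`SummaryDataset`.

    ``column_map`` renames source columns to the canonical names, e.g.
    ``{"rsid": "snp_id", "p": "pval"}``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA"])
    if column_map:
        df = df.rename(columns=column_map)
        if "chrom" in df.columns:
            df["chrom"] = df["chrom"].astype(str)
    missing = set(GWAS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            AssocRecord(
                snp_id=str(row.snp_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                eaf=None if _isna(row.eaf) else float(row.eaf),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                n=None if _isna(row.n) else int(row.n),
            )
        )
    return SummaryDataset(
        trait_label=trait_label,
        role=role,
        records=records,
        scale_note=scale_note,
        binary_outcome=binary_outcome,
    )


def write_gwas_tsv(ds: SummaryDataset, path: str | Path) -> None:
    df = ds.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_ld_tsv(path: str | Path) -> LdMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    snp_ids = [str(s) for s in df.index]
    if [str(c) for c in df.columns] != snp_ids:
        raise ValueError(f"{path}: LD row and column snp_ids disagree")
    return LdMatrix(snp_ids=snp_ids, r=df.to_numpy(dtype=float))


def write_ld_tsv(ld: LdMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r, index=ld.snp_ids, columns=ld.snp_ids).to_csv(path, sep="\t")


def _isna(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return pd.isna(value)
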