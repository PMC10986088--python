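"""Core data containers for GWAS summary statistics.

Every analysis stage consumes or produces one of the types defined here:
per-SNP association records grouped into trait-level datasets, a pairwise
LD matrix, the allele-aligned exposure/outcome pairs used by the MR
estimators, and the audited product of instrument selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_ROLES = ("exposure", "mediator", "outcome")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str:
    """Reverse-complement a (possibly multi-base) allele string."""
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(allele.upper()))
    except KeyError as exc:
        raise ValueError(f"non-ACGT base in allele {allele!r}") from exc


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G variants, whose strand is ambiguous."""
    return complement(a1.upper()) == a2.upper()


@dataclass(frozen=True)
class AssocRecord:
    """One SNP-trait association row from a GWAS summary file.

    ``beta`` is the additive per-effect-allele effect on the trait scale,
    ``eaf`` the effect-allele frequency.  ``eaf`` and ``n`` may be missing
    (None).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int | None = None

    def __post_init__(self) -> None:
        if self.effect_allele.upper() == self.other_allele.upper():
            raise ValueError(f"{self.snp_id}: effect and other allele identical")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.snp_id}: pval must be in (0,1], got {self.pval}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.snp_id}: eaf outside [0,1]: {self.eaf}")
        if self.n is not None and self.n <= 0:
            raise ValueError(f"{self.snp_id}: n must be positive")

    @property
    def palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)

    def flipped(self) -> "AssocRecord":
        """Same association expressed for the other allele."""
        return AssocRecord(
            snp_id=self.snp_id,
            chrom=self.chrom,
            pos=self.pos,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
            beta=-self.beta,
            se=self.se,
            pval=self.pval,
            n=self.n,
        )


@dataclass
class SummaryDataset:
    """All association records for one trait, unique by snp_id."""

    trait_label: str
    role: str
    records: list[AssocRecord]
    scale_note: str = ""
    binary_outcome: bool = False

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(f"role must be one of {VALID_ROLES}, got {self.role!r}")
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.trait_label}: duplicated snp_id values")
        self._index = {r.snp_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_id: str) -> AssocRecord:
        return self._index[snp_id]

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def subset(self, snp_ids) -> "SummaryDataset":
        keep = set(snp_ids)
        return SummaryDataset(
            trait_label=self.trait_label,
            role=self.role,
            records=[r for r in self.records if r.snp_id in keep],
            scale_note=self.scale_note,
            binary_outcome=self.binary_outcome,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": [r.snp_id for r in self.records],
                "chrom": [r.chrom for r in self.records],
                "pos": [r.pos for r in self.records],
                "effect_allele": [r.effect_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "eaf": [r.eaf for r in self.records],
                "beta": [r.beta for r in self.records],
                "se": [r.se for r in self.records],
                "pval": [r.pval for r in self.records],
                "n": [r.n for r in self.records],
            }
        )


@dataclass
class LdMatrix:
    """Square symmetric matrix of pairwise allelic correlations r."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise ValueError("LD matrix shape does not match snp_ids")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1 + 1e-8):
            raise ValueError("LD correlations outside [-1,1]")
        self._pos = {s: i for i, s in enumerate(self.snp_ids)}

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._pos

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self._pos[a], self._pos[b]] ** 2)


@dataclass
class HarmonizedSet:
    """Allele-aligned per-SNP (exposure, outcome) effect pairs.

    ``table`` columns: snp_id, beta_x, se_x, beta_y, se_y.  ``dropped``
    maps each discarded snp_id to a reason code.
    """

    table: pd.DataFrame
    dropped: dict[str, str] = field(default_factory=dict)
    exposure_label: str = ""
    outcome_label: str = ""
    binary_outcome: bool = False

    def __post_init__(self) -> None:
        required = {"snp_id", "beta_x", "se_x", "beta_y", "se_y"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"HarmonizedSet table missing columns {missing}")
        if self.table["snp_id"].duplicated().any():
            raise ValueError("duplicated snp_id in HarmonizedSet")
        if (self.table[["se_x", "se_y"]] <= 0).any().any():
            raise ValueError("non-positive se in HarmonizedSet")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def beta_x(self) -> np.ndarray:
        return self.table["beta_x"].to_numpy(float)

    @property
    def se_x(self) -> np.ndarray:
        return self.table["se_x"].to_numpy(float)

    @property
    def beta_y(self) -> np.ndarray:
        return self.table["beta_y"].to_numpy(float)

    @property
    def se_y(self) -> np.ndarray:
        return self.table["se_y"].to_numpy(float)

    @property
    def snp_ids(self) -> list[str]:
        return self.table["snp_id"].tolist()

    @classmethod
    def from_arrays(cls, beta_x, se_x, beta_y, se_y, snp_ids=None, **kw) -> "HarmonizedSet":
        beta_x = np.asarray(beta_x, float)
        if snp_ids is None:
            snp_ids = [f"snp{i+1}" for i in range(beta_x.size)]
        return cls(
            table=pd.DataFrame(
                {
                    "snp_id": list(snp_ids),
                    "beta_x": beta_x,
                    "se_x": np.asarray(se_x, float),
                    "beta_y": np.asarray(beta_y, float),
                    "se_y": np.asarray(se_y, float),
                }
            ),
            **kw,
        )

    def subset(self, snp_ids) -> "HarmonizedSet":
        keep = self.table["snp_id"].isin(set(snp_ids))
        return HarmonizedSet(
            table=self.table[keep].copy(),
            dropped=dict(self.dropped),
            exposure_label=self.exposure_label,
            outcome_label=self.outcome_label,
            binary_outcome=self.binary_outcome,
        )


@dataclass
class InstrumentSet:
    """SNPs surviving an instrument-selection step, with an audit trail.

    ``selection_log`` records (rule, n_before, n_after) for each filter
    applied; ``f_stats`` holds per-SNP instrument-strength F statistics
    once computed.
    """

    records: list[AssocRecord]
    selection_log: list[tuple[str, int, int]] = field(default_factory=list)
    f_stats: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rule, n_before, n_after in self.selection_log:
            if n_after > n_before:
                raise ValueError(f"selection step {rule!r} increased the SNP count")
        if any(f < 0 for f in self.f_stats.values()):
            raise ValueError("negative F statistic")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]
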