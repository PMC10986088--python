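"""Instrument selection: thresholds, clumping vs a brute-force oracle, F."""

import numpy as np
import pytest

from mrmediate import (
    AssocRecord,
    HarmonizedSet,
    LdMatrix,
    SummaryDataset,
    clump,
    f_statistics,
    select_instruments,
)
from mrmediate.instruments import InstrumentSelectionError


def rec(snp_id, pval, pos=1000, chrom="1"):
    return AssocRecord(snp_id, chrom, pos, "A", "G", 0.3, 0.1, 0.02, pval, 1000)


def dataset(pvals):
    return SummaryDataset(
        "t", "exposure", [rec(f"rs{i}", p, pos=1000 * (i + 1)) for i, p in enumerate(pvals)]
    )


class TestSelectInstruments:
    def test_primary_threshold_sufficient(self):
        ds = dataset([1e-9] * 5 + [0.5] * 95)
        sel = select_instruments(ds, 5e-8, 5e-7, 3)
        assert len(sel) == 5
        assert "primary" in sel.selection_log[0][0]

    def test_fallback_applied_when_primary_short(self):
        ds = dataset([1e-9, 1e-9, 1e-7, 2e-7])
        sel = select_instruments(ds, 5e-8, 5e-7, 3)
        assert len(sel) == 4
        assert any("fallback" in rule for rule, *_ in sel.selection_log)

    def test_insufficient_even_at_fallback(self):
        ds = dataset([1e-7, 0.5, 0.9])
        with pytest.raises(InstrumentSelectionError, match="insufficient_instruments"):
            select_instruments(ds, 5e-8, 5e-7, 3)

    def test_looser_primary_threshold_returns_superset(self):
        rng = np.random.default_rng(11)
        ds = dataset(rng.uniform(1e-12, 1e-4, 60))
        tight = select_instruments(ds, 1e-9, 1e-3, 1)
        loose = select_instruments(ds, 1e-6, 1e-3, 1)
        assert set(tight.snp_ids) <= set(loose.snp_ids)


def random_ld(snp_ids, seed):
    rng = np.random.default_rng(seed)
    a = rng.uniform(-1, 1, (len(snp_ids), len(snp_ids)))
    r = np.clip((a + a.T) / 2, -0.99, 0.99)
    np.fill_diagonal(r, 1.0)
    return LdMatrix(list(snp_ids), r)


def greedy_oracle(records, ld, r2_threshold, kb_window):
    """Independent exhaustive greedy re-implementation for small inputs."""
    remaining = sorted(records, key=lambda r: (r.pval, r.pos, r.snp_id))
    kept = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        survivors = []
        for other in remaining:
            same_chrom = other.chrom == best.chrom
            near = abs(other.pos - best.pos) / 1000.0 <= kb_window
            linked = (
                best.snp_id in ld and other.snp_id in ld
                and ld.r2(best.snp_id, other.snp_id) >= r2_threshold
            )
            if not (same_chrom and near and linked):
                survivors.append(other)
        remaining = survivors
    return [r.snp_id for r in kept]


class TestClump:
    def test_linked_pair_keeps_stronger_snp(self):
        a, b = rec("rs1", 1e-10, pos=10_000), rec("rs2", 1e-8, pos=20_000)
        ld = LdMatrix(["rs1", "rs2"], np.array([[1.0, np.sqrt(0.9)], [np.sqrt(0.9), 1.0]]))
        out = clump([a, b], ld, r2_threshold=0.8, kb_window=250)
        assert out.snp_ids == ["rs1"]

    def test_below_threshold_keeps_both(self):
        a, b = rec("rs1", 1e-10, pos=10_000), rec("rs2", 1e-8, pos=20_000)
        ld = LdMatrix(["rs1", "rs2"], np.array([[1.0, np.sqrt(0.5)], [np.sqrt(0.5), 1.0]]))
        out = clump([a, b], ld, r2_threshold=0.8, kb_window=250)
        assert out.snp_ids == ["rs1", "rs2"]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_greedy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        records = [
            rec(f"rs{i}", float(rng.uniform(1e-12, 1e-3)), pos=int(rng.integers(1, 400_000)))
            for i in range(5)
        ]
        ld = random_ld([r.snp_id for r in records], seed + 100)
        out = clump(records, ld, r2_threshold=0.8, kb_window=250)
        assert out.snp_ids == greedy_oracle(records, ld, 0.8, 250)

    def test_kept_snps_are_pairwise_independent(self):
        rng = np.random.default_rng(7)
        records = [
            rec(f"rs{i}", float(rng.uniform(1e-12, 1e-3)), pos=int(rng.integers(1, 100_000)))
            for i in range(12)
        ]
        ld = random_ld([r.snp_id for r in records], 8)
        out = clump(records, ld, r2_threshold=0.5, kb_window=250)
        for i, a in enumerate(out.records):
            for b in out.records[i + 1:]:
                within = abs(a.pos - b.pos) / 1000.0 <= 250
                assert not (within and ld.r2(a.snp_id, b.snp_id) >= 0.5)

    def test_snp_missing_from_ld_is_kept(self):
        a, b = rec("rs1", 1e-10, pos=10_000), rec("rs2", 1e-8, pos=11_000)
        ld = LdMatrix(["rs1"], np.array([[1.0]]))
        out = clump([a, b], ld, r2_threshold=0.8, kb_window=250)
        assert out.snp_ids == ["rs1", "rs2"]

    def test_empty_candidates_error(self):
        with pytest.raises(InstrumentSelectionError, match="no_candidates"):
            clump([], None, 0.8, 250)


class TestFStatistics:
    def test_squared_z_values_and_weak_flag(self):
        h = HarmonizedSet.from_arrays(
            beta_x=[0.1, 0.02, 0.0],
            se_x=[0.02, 0.02, 0.02],
            beta_y=[0.0, 0.0, 0.0],
            se_y=[0.05, 0.05, 0.05],
        )
        out = f_statistics(h)
        f = list(out["per_snp"].values())
        assert f == pytest.approx([25.0, 1.0, 0.0])
        assert list(out["weak"].values()) == [False, True, True]
        assert out["mean_f"] == pytest.approx(26.0 / 3)
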