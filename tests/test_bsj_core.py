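"""BSJ detection, table merging, gene annotation and normalisation."""

from __future__ import annotations

import random

import pytest

from bsjkit import bsj_core, formats, simulate
from bsjkit.bsj_core import BsjKey, BsjTable, detect_bsj, merge_tables


def chim(donor, acceptor, strand="+", read_id="r1", code=1, chrom="chr1",
         seg1=(650, "60M40S"), seg2=(700, "60S40M100p100M")):
    return formats.ChimericRecord(
        chrom, donor, strand, chrom, acceptor, strand, code, 0, 0, read_id,
        seg1[0], seg1[1], seg2[0], seg2[1],
    )


class TestBsjKey:
    def test_orientation_invariants(self):
        with pytest.raises(ValueError):
            BsjKey("chr1", 1000, 2000, "+")  # canonical order is not a BSJ
        with pytest.raises(ValueError):
            BsjKey("chr1", 2000, 1000, "-")
        key = BsjKey("chr1", 2000, 999, "+")
        assert key.circle_length == 1000
        assert BsjKey.from_id(key.to_id()) == key


class TestDetect:
    def test_tally_single_key(self):
        records = [chim(2000, 1000, read_id=f"r{i}") for i in range(10)]
        table, report = detect_bsj(records)
        assert len(table) == 1
        assert int(table.counts("sample").iloc[0]) == 10
        assert report.n_counted == 10 and not report.discards

    def test_canonical_order_discarded(self):
        table, report = detect_bsj([chim(1000, 2000)])
        assert len(table) == 0
        assert report.discards == {"not_backsplice": 1}

    def test_span_cutoff(self):
        table, report = detect_bsj([chim(2_000_000, 1)], max_span=1_000_000)
        assert len(table) == 0 and report.discards == {"span_exceeded": 1}

    def test_read_pair_deduplicated(self):
        records = [chim(2000, 1000, read_id="same")] * 3
        table, report = detect_bsj(records)
        assert int(table.counts("sample").iloc[0]) == 1
        assert report.discards == {"duplicate_read": 2}

    def test_total_is_type2_plus_type3(self):
        recs = [chim(2000, 1000, read_id=f"a{i}") for i in range(4)]
        recs += [
            chim(2000, 1000, read_id=f"b{i}",
                 seg1=(650, "100M50p35M65S"), seg2=(700, "35S65M"))
            for i in range(3)
        ]
        table, _ = detect_bsj(recs)
        row = table.df.iloc[0]
        assert row[("sample", "type2")] == 4
        assert row[("sample", "type3")] == 3
        assert row[("sample", "total")] == 7

    def test_encompassing_supports_but_never_counts(self):
        key_recs = [chim(2000, 999, read_id=f"r{i}") for i in range(3)]
        support = chim(2000, 999, read_id="pair", code=-1,
                       seg1=(1800, "100M"), seg2=(1100, "100M"))
        lone = chim(9000, 7999, read_id="orphan", code=-1,
                    seg1=(8800, "100M"), seg2=(8100, "100M"))
        table, report = detect_bsj(key_recs + [support, lone])
        row = table.df.iloc[0]
        assert row[("sample", "total")] == 3  # type IV never enters the total
        assert row[("sample", "type4")] == 1
        assert report.discards == {"unmatched_encompassing": 1}

    def test_order_independence(self):
        records = [
            chim(2000 + 100 * (i % 5), 1000, read_id=f"r{i}") for i in range(40)
        ]
        shuffled = records[:]
        random.Random(3).shuffle(shuffled)
        t1, _ = detect_bsj(records)
        t2, _ = detect_bsj(shuffled)
        assert t1.df.equals(t2.df)

    def test_conservation(self):
        records = [chim(2000, 1000, read_id=f"r{i}") for i in range(5)]
        records += [chim(1000, 2000, read_id="bad")]  # not a backsplice
        table, report = detect_bsj(records)
        counted = int(table.df.xs("total", axis=1, level="metric").sum().sum())
        assert counted + report.n_type4 + report.n_discarded == len(records)

    def test_io_idempotence(self, tmp_path):
        records = [chim(2000, 1000, read_id=f"r{i}") for i in range(6)]
        table, _ = detect_bsj(records)
        p = tmp_path / "table.tsv"
        table.to_tsv(p)
        again = BsjTable.from_tsv(p)
        assert again.df.equals(table.df)

    def test_simulated_counts_recovered(self):
        keys = [BsjKey("chr1", 5000 + i * 3000, 5000 + i * 3000 - 1201, "+")
                for i in range(20)]
        truths = []
        for k in keys:
            for j in range(12):
                atype = "II" if j % 2 == 0 else "III"
                rid = f"{k.to_id()}|{atype}|50|{j}"
                truths.append(simulate.SimTruth(rid, k, atype, 50))
        records = simulate.simulate_chimeric_records(truths)
        table, _ = detect_bsj(records)
        assert len(table) == 20
        assert (table.counts("sample") == 12).all()


class TestMerge:
    def t(self, sample, key, n):
        return BsjTable.from_counts(
            sample, {key: {"total": n, "type2": n, "type3": 0}}
        )

    def test_union_with_zero_fill(self):
        k1 = BsjKey("chr1", 2000, 999, "+")
        k2 = BsjKey("chr1", 9000, 7999, "+")
        merged = merge_tables([self.t("A", k1, 5), self.t("B", k2, 7)])
        assert len(merged) == 2
        assert merged.df.loc[k1.as_tuple(), ("B", "total")] == 0
        assert merged.df.loc[k2.as_tuple(), ("B", "total")] == 7

    def test_shared_key_columns(self):
        k = BsjKey("chr1", 2000, 999, "+")
        merged = merge_tables([self.t("A", k, 5), self.t("B", k, 7)])
        assert list(merged.df.loc[k.as_tuple(), [("A", "total"), ("B", "total")]]) == [5, 7]

    def test_group_sum_conserves_counts(self):
        k1 = BsjKey("chr1", 2000, 999, "+")
        k2 = BsjKey("chr2", 5000, 3999, "+")
        tables = [self.t("A", k1, 3), self.t("B", k1, 4), self.t("C", k2, 9)]
        merged = merge_tables(tables)
        totals = merged.df.xs("total", axis=1, level="metric")
        assert totals.to_numpy().sum() == 3 + 4 + 9

    def test_duplicate_sample_id_rejected(self):
        k = BsjKey("chr1", 2000, 999, "+")
        with pytest.raises(ValueError, match="duplicate"):
            merge_tables([self.t("A", k, 1), self.t("A", k, 2)])


class TestAnnotate:
    def test_gene_overlap_and_unassigned(self, gene_model):
        gene = sorted(gene_model.genes.values(), key=lambda g: g.name)[0]
        strand = gene.strand
        inside = (
            BsjKey(gene.chrom, gene.end, gene.start + 1, "+")
            if strand == "+" else BsjKey(gene.chrom, gene.start + 1, gene.end, "-")
        )
        nowhere = BsjKey("chr1", 59_999, 59_000, "+")
        table = merge_tables([
            BsjTable.from_counts("S", {inside: {"total": 1}, nowhere: {"total": 1}})
        ])
        annotated = bsj_core.annotate_genes(table, gene_model)
        assert annotated.gene.loc[inside.as_tuple()] == gene.name
        assert annotated.gene.loc[nowhere.as_tuple()] == "unassigned"

    def test_two_overlapping_genes_alphabetical(self):
        from bsjkit.seq_assembly import GeneModel, Transcript

        model = GeneModel([
            Transcript("tB", "B", "chr1", "+", ((100, 200), (900, 1000))),
            Transcript("tA", "A", "chr1", "+", ((150, 250), (950, 1050))),
        ])
        key = BsjKey("chr1", 980, 160, "+")
        table = BsjTable.from_counts("S", {key: {"total": 1}})
        annotated = bsj_core.annotate_genes(table, model)
        assert annotated.gene.loc[key.as_tuple()] == "A,B"


class TestNormalize:
    def test_total_bsj_per_million(self):
        keys = [BsjKey("chr1", 2000, 999, "+"), BsjKey("chr1", 9000, 7999, "+")]
        table = BsjTable.from_counts(
            "S", {keys[0]: {"total": 10}, keys[1]: {"total": 990}}
        )
        out, flagged = bsj_core.normalize(table, "total_bsj")
        assert out.df.loc[keys[0].as_tuple(), ("S", "norm")] == 10 / 1000 * 1e6
        assert not flagged["S"]

    def test_gene_counts_library_size_ratio(self):
        k = BsjKey("chr1", 2000, 999, "+")
        a = BsjTable.from_counts("A", {k: {"total": 10}})
        b = BsjTable.from_counts("B", {k: {"total": 10}})
        merged = merge_tables([a, b])
        out, _ = bsj_core.normalize(
            merged, "gene_counts", {"A": 1_000_000, "B": 2_000_000}
        )
        row = out.df.loc[k.as_tuple()]
        assert row[("A", "norm")] == pytest.approx(2 * row[("B", "norm")])

    def test_rank_order_preserved(self):
        keys = [BsjKey("chr1", 2000 + i * 10, 999, "+") for i in range(5)]
        counts = {k: {"total": (i + 1) * 3} for i, k in enumerate(keys)}
        table = BsjTable.from_counts("S", counts)
        out, _ = bsj_core.normalize(table, "total_bsj")
        raw = table.df[("S", "total")]
        norm = out.df[("S", "norm")]
        assert list(raw.rank()) == list(norm.rank())

    def test_zero_denominator_flagged(self):
        k = BsjKey("chr1", 2000, 999, "+")
        table = BsjTable.from_counts("S", {k: {"total": 0}})
        out, flagged = bsj_core.normalize(table, "total_bsj")
        assert flagged["S"]
        assert out.df[("S", "norm")].isna().all()
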