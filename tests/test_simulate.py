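"""Simulator: determinism, geometry of generated reads/records, truth recovery."""

from __future__ import annotations

import numpy as np
import pytest

from bsjkit import bsj_core, formats, qc_scores, simulate
from bsjkit.bsj_core import BsjKey
from bsjkit.seq_assembly import GeneModel, assemble_circ_sequence, revcomp
from bsjkit.simulate import (
    SimTruth,
    bsj_fastq_generate,
    exon_bounded_key,
    make_fixture_genome,
    make_fsj_table,
    mid_exon_key,
    simulate_chimeric_records,
)


class TestFixtureGenome:
    def test_deterministic(self, tmp_path):
        fa1, gtf1 = make_fixture_genome(tmp_path / "a", seed=1, n_genes=4)
        fa2, gtf2 = make_fixture_genome(tmp_path / "b", seed=1, n_genes=4)
        assert fa1.read_bytes() == fa2.read_bytes()
        assert gtf1.read_bytes() == gtf2.read_bytes()

    def test_gene_count(self, tmp_path):
        _, gtf = make_fixture_genome(tmp_path, seed=2, n_genes=10,
                                     n_chroms=2, chrom_len=200_000)
        genes = [l for l in gtf.read_text().splitlines() if "\tgene\t" in l]
        assert len(genes) == 10

    def test_exons_within_fasta_bounds(self, tmp_path):
        import pyfaidx

        fa, gtf = make_fixture_genome(tmp_path, seed=3, n_genes=6)
        fasta = pyfaidx.Fasta(str(fa))
        for line in gtf.read_text().splitlines():
            f = line.split("\t")
            if f[2] != "exon":
                continue
            assert 1 <= int(f[3]) <= int(f[4]) <= len(fasta[f[0]])

    def test_infeasible_packing_raises(self, tmp_path):
        with pytest.raises(ValueError, match="pack"):
            make_fixture_genome(tmp_path, seed=1, n_genes=50, n_chroms=1,
                                chrom_len=5000)


class TestFastqGenerate:
    def keys_and_seqs(self, n=3, C=1000):
        keys = [
            BsjKey("chr1", 5000 + i * 3000, 5000 + i * 3000 - C - 1, "+")
            for i in range(n)
        ]
        rng = np.random.default_rng(1)
        seqs = {
            k: "".join(rng.choice(list("ACGT"), size=C)) for k in keys
        }
        return keys, seqs

    def test_bookkeeping(self):
        keys, seqs = self.keys_and_seqs(n=20)
        r1, r2, truths = bsj_fastq_generate(
            keys, sequences=seqs, n_pairs_per_key=12, seed=0
        )
        assert len(truths) == 240
        assert len(r1) == len(r2) == 240  # 480 FASTQ records across both files

    def test_type_ii_read1_crosses_junction(self):
        keys, seqs = self.keys_and_seqs(n=1)
        key, seq = keys[0], seqs[keys[0]]
        r1, r2, truths = bsj_fastq_generate(
            [key], sequences=seqs, n_pairs_per_key=5, seed=3,
            type_mix={"II": 1.0}, offsets=[50],
        )
        for (rid, read), t in zip(r1, truths):
            assert t.alignment_type == "II" and t.offset == 50
            # first 50 bases from the donor side (circle end), rest wraps
            assert read[:50] == seq[-50:]
            assert read[50:] == seq[: len(read) - 50]

    def test_read2_is_reverse_complement_of_fragment_end(self):
        keys, seqs = self.keys_and_seqs(n=1)
        key, seq = keys[0], seqs[keys[0]]
        r1, r2, truths = bsj_fastq_generate(
            [key], sequences=seqs, n_pairs_per_key=1, seed=4,
            type_mix={"III": 1.0}, offsets=[40], frag_len=300, read_len=100,
        )
        (rid, read2) = r2[0]
        # junction 40 nt into read 2: its 5' end holds the acceptor side
        assert revcomp(read2)[-40:] == seq[:40]

    def test_truth_round_trips_through_read_id(self):
        keys, seqs = self.keys_and_seqs()
        _, _, truths = bsj_fastq_generate(keys, sequences=seqs, seed=5,
                                          n_pairs_per_key=3)
        for t in truths:
            assert SimTruth.from_read_id(t.read_id) == t

    def test_type_i_impossible_on_small_circle(self):
        keys, seqs = self.keys_and_seqs(n=1, C=299)
        with pytest.raises(ValueError, match="circle"):
            bsj_fastq_generate(keys, sequences=seqs, type_mix={"I": 1.0}, seed=1)
        keys2, seqs2 = self.keys_and_seqs(n=1, C=300)
        with pytest.raises(ValueError, match="type I"):
            bsj_fastq_generate(keys2, sequences=seqs2, type_mix={"I": 1.0}, seed=1)

    def test_fastq_files_written(self, tmp_path):
        keys, seqs = self.keys_and_seqs(n=2)
        prefix = tmp_path / "sim"
        bsj_fastq_generate(keys, sequences=seqs, n_pairs_per_key=2, seed=6,
                           out_prefix=prefix)
        fq1 = (tmp_path / "sim_1.fastq").read_text().splitlines()
        assert len(fq1) == 2 * 2 * 4
        assert fq1[0].startswith("@chr1:")
        truths = simulate.read_truth_table(tmp_path / "sim_truth.tsv")
        assert len(truths) == 4


class TestChimericRecords:
    def truth(self, key, atype, offset, serial=0):
        rid = f"{key.to_id()}|{atype}|{offset}|{serial}"
        return SimTruth(rid, key, atype, offset)

    def test_type_ii_cigar_pattern(self):
        key = BsjKey("chr1", 2102, 1000, "+")  # circle [1001, 2101], C=1101
        (rec,) = simulate_chimeric_records([self.truth(key, "II", 60)])
        assert rec.seg1_cigar == "60M40S"
        assert rec.seg2_cigar == "60S40M100p100M"
        assert rec.junction_code >= 0
        assert rec.pos_donor == 2102 and rec.pos_acceptor == 1000
        # read 1 head sits 60 bases before the donor boundary
        assert rec.seg1_start == 2101 - 60 + 1
        assert rec.seg2_start == 1001

    def test_type_iii_cigar_pattern(self):
        key = BsjKey("chr1", 2102, 1000, "+")
        (rec,) = simulate_chimeric_records([self.truth(key, "III", 65)])
        assert rec.seg1_cigar == "100M100p35M65S"
        assert rec.seg2_cigar == "35S65M"

    def test_type_iv_is_encompassing(self):
        key = BsjKey("chr1", 2102, 1000, "+")
        (rec,) = simulate_chimeric_records([self.truth(key, "IV", 150)])
        assert rec.junction_code == -1
        assert "p" not in rec.seg1_cigar and "p" not in rec.seg2_cigar

    def test_type_i_raises(self):
        key = BsjKey("chr1", 2102, 1000, "+")
        with pytest.raises(ValueError, match="type I"):
            simulate_chimeric_records([self.truth(key, "I", 500)])

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_classifier_on_both_strands(self, strand):
        if strand == "+":
            key = BsjKey("chr1", 3000, 1499, "+")
        else:
            key = BsjKey("chr1", 1499, 3000, "-")
        truths = [self.truth(key, "II", o, i) for i, o in enumerate((20, 50, 80))]
        truths += [self.truth(key, "III", o, 10 + i) for i, o in enumerate((20, 50, 80))]
        records = simulate_chimeric_records(truths)
        preds = {t.read_id: qc_scores.classify_mate(r)
                 for t, r in zip(truths, records)}
        assert qc_scores.evaluate_classifier(truths, preds) == 1.0

    def test_detection_round_trip_with_type4(self):
        key = BsjKey("chr1", 3000, 1499, "+")
        truths = [self.truth(key, "II", 30 + i, i) for i in range(4)]
        truths += [self.truth(key, "III", 30 + i, 10 + i) for i in range(4)]
        truths += [self.truth(key, "IV", 120 + i, 20 + i) for i in range(3)]
        table, report = bsj_core.detect_bsj(
            simulate_chimeric_records(truths), "S"
        )
        row = table.df.iloc[0]
        assert row[("S", "total")] == 8
        assert row[("S", "type2")] == 4
        assert row[("S", "type3")] == 4
        assert row[("S", "type4")] == 3
        assert not report.discards


class TestFsjTable:
    def test_one_junction_per_adjacent_exon_pair(self, gene_model):
        rows = make_fsj_table(gene_model, mean_count=20, seed=1)
        n_expected = sum(
            len(t.exons) - 1 for t in gene_model.transcripts.values()
        )
        assert len(rows) == n_expected
        assert all(r.unique_count >= 0 for r in rows)

    def test_coordinates_match_gtf_introns(self, gene_model):
        rows = {(r.chrom, r.intron_start, r.intron_end)
                for r in make_fsj_table(gene_model, seed=2)}
        for tr in gene_model.transcripts.values():
            for (s1, e1), (s2, e2) in zip(tr.exons, tr.exons[1:]):
                assert (tr.chrom, e1 + 1, s2 - 1) in rows

    def test_zeroed_junction_absent(self, gene_model):
        tr = next(iter(gene_model.transcripts.values()))
        drop = (tr.chrom, tr.exons[0][1] + 1, tr.exons[1][0] - 1)
        rows = make_fsj_table(gene_model, seed=3, zero_junctions=[drop])
        assert drop not in {(r.chrom, r.intron_start, r.intron_end) for r in rows}

    def test_boundary_keys_get_full_support_mid_exon_none(self, gene_model):
        fsj = make_fsj_table(gene_model, seed=4)
        for tid in sorted(gene_model.transcripts)[:2]:
            tr = gene_model.transcripts[tid]
            inner = exon_bounded_key(tr, 1, 2)  # internal exon block
            assert qc_scores.fsj_support(inner, fsj).value == 2
            mid = mid_exon_key(tr, 1)
            assert qc_scores.fsj_support(mid, fsj).value == 0


class TestEndToEnd:
    def test_fastq_and_records_share_truth_geometry(self, gene_model, fasta_path):
        """The FASTQ reads and the chimeric records describe the same pairs."""
        tr = gene_model.transcripts[sorted(gene_model.transcripts)[0]]
        key = exon_bounded_key(tr)
        circ = assemble_circ_sequence(key, gene_model, str(fasta_path))
        reads1, _, truths = bsj_fastq_generate(
            [key], gene_model, str(fasta_path), n_pairs_per_key=6, seed=8
        )
        records = simulate_chimeric_records(truths)
        assert len(records) == len(reads1)
        for t, rec in zip(truths, records):
            assert rec.read_id == t.read_id
            assert rec.pos_donor == key.donor_pos
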