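"""Synthetic-data generation with exact ground truth.

Everything the pipeline consumes can be fabricated here without an
aligner or any external download: a random genome with a multi-exon gene
model (FASTA + GTF), paired-end FASTQ reads drawn from circularised
sequences with the backsplice junction placed at controlled offsets, the
chimeric-junction records an aligner would emit for those reads, and
Poisson-count forward-splice-junction tables.

Geometry convention used throughout: a fragment of length ``F`` is cut
from the circle (of size ``C``) so that the junction sits at fragment
offset ``d`` (``d`` bases of fragment precede the junction).  ``d`` in
``[m, R-m]`` puts the junction inside read 1 (type II), ``d`` in
``[F-R+m, F-m]`` inside read 2 (type III, read-2 offset ``o = F-d``),
``d`` in the inter-mate gap gives type IV, and ``d >= F`` means the
fragment misses the junction entirely (type I — impossible when the
circle is smaller than a fragment).  Every read id encodes the BSJ id,
alignment type and offset, so truth is recoverable after any downstream
step.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .bsj_core import BsjKey
from .formats import ChimericRecord, ForwardJunction
from .seq_assembly import (
    GeneModel,
    NoCompatibleModel,
    Transcript,
    assemble_circ_sequence,
    revcomp,
)

__all__ = [
    "SimTruth",
    "make_fixture_genome",
    "exon_bounded_key",
    "mid_exon_key",
    "bsj_fastq_generate",
    "simulate_chimeric_records",
    "make_fsj_table",
    "write_truth_table",
    "read_truth_table",
]


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated read pair.

    ``offset`` is the junction offset from the 5' end of the junction-
    bearing read for types II/III; for type IV it is the fragment offset
    of the junction (inside the inter-mate gap), and for type I the
    fragment offset at which the junction was *avoided* (>= fragment
    length).  ``read_id`` round-trips all fields.
    """

    read_id: str
    bsj: BsjKey
    alignment_type: str  # "I" | "II" | "III" | "IV"
    offset: int

    @classmethod
    def from_read_id(cls, read_id: str) -> "SimTruth":
        key_id, atype, offset, _serial = read_id.rsplit("|", 3)
        return cls(read_id, BsjKey.from_id(key_id), atype, int(offset))


def _format_read_id(key: BsjKey, atype: str, offset: int, serial: int) -> str:
    return f"{key.to_id()}|{atype}|{offset}|{serial}"


# ---------------------------------------------------------------------------
# Fixture genome + gene model
# ---------------------------------------------------------------------------


def make_fixture_genome(
    out_dir,
    seed: int = 0,
    n_chroms: int = 2,
    chrom_len: int = 100_000,
    n_genes: int = 8,
    exons_per_gene: int = 4,
    exon_len_range: tuple[int, int] = (90, 260),
    intron_len_range: tuple[int, int] = (120, 420),
    intergenic_range: tuple[int, int] = (400, 1200),
) -> tuple[Path, Path]:
    """Write a deterministic random genome (FASTA) and gene model (GTF).

    Genes are packed left to right with random intergenic gaps, assigned
    to chromosomes round-robin, on random strands, one transcript each.
    Raises if the requested genes cannot fit on the chromosomes.
    """
    if min(n_chroms, chrom_len, n_genes, exons_per_gene) < 1:
        raise ValueError("all sizes must be >= 1")
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    seqs = {
        c: "".join(rng.choice(list("ACGT"), size=chrom_len)) for c in chroms
    }
    cursors = {c: 1 for c in chroms}
    gtf_lines: list[str] = []
    for gi in range(n_genes):
        chrom = chroms[gi % n_chroms]
        gene = f"G{gi + 1}"
        tid = f"{gene}.T1"
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursors[chrom] + int(rng.integers(*intergenic_range))
        exons: list[tuple[int, int]] = []
        pos = start
        for ei in range(exons_per_gene):
            elen = int(rng.integers(*exon_len_range))
            exons.append((pos, pos + elen - 1))
            pos += elen
            if ei < exons_per_gene - 1:
                pos += int(rng.integers(*intron_len_range))
        end = exons[-1][1]
        if end > chrom_len:
            raise ValueError(
                f"cannot pack {n_genes} genes of this size into "
                f"{n_chroms} x {chrom_len} bp"
            )
        cursors[chrom] = end + 1
        attrs = f'gene_id "{gene}"; transcript_id "{tid}"; gene_name "{gene}";'
        src = "bsjkit_sim"
        gtf_lines.append(
            f"{chrom}\t{src}\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
            f'gene_id "{gene}"; gene_name "{gene}";'
        )
        gtf_lines.append(
            f"{chrom}\t{src}\ttranscript\t{start}\t{end}\t.\t{strand}\t.\t{attrs}"
        )
        for s, e in exons:
            gtf_lines.append(
                f"{chrom}\t{src}\texon\t{s}\t{e}\t.\t{strand}\t.\t{attrs}"
            )
    fasta_path = out_dir / "genome.fa"
    with open(fasta_path, "w") as fh:
        for c in chroms:
            fh.write(f">{c}\n")
            seq = seqs[c]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    gtf_path = out_dir / "genes.gtf"
    with open(gtf_path, "w") as fh:
        fh.write("\n".join(gtf_lines) + "\n")
    return fasta_path, gtf_path


def exon_bounded_key(tr: Transcript, first_exon: int = 0, last_exon: int | None = None) -> BsjKey:
    """The BSJ whose boundaries coincide with a transcript's exon block.

    The circle covers exons ``first_exon..last_exon`` (genomic order), so
    its backsplice donor and acceptor land exactly on splice sites of the
    model — the fully model-compatible, FSJ-supported case.
    """
    if last_exon is None:
        last_exon = len(tr.exons) - 1
    lo = tr.exons[first_exon][0]
    hi = tr.exons[last_exon][1]
    if tr.strand == "-":
        return BsjKey(tr.chrom, lo - 1, hi + 1, "-")
    return BsjKey(tr.chrom, hi + 1, lo - 1, "+")


def non_canonical_key(tr: Transcript, trim: int = 7) -> BsjKey:
    """A BSJ whose boundaries sit inside the first and last exons.

    Emulates circles spliced from positions within coding exons rather
    than annotated donor/acceptor sites: the genomic span stays large
    enough for standard fragment geometry, but neither coordinate matches
    a forward-splice boundary, so the FSJ support score is 0 and no
    transcript model is compatible.
    """
    lo = tr.exons[0][0] + trim
    hi = tr.exons[-1][1] - trim
    if hi - lo < 2:
        raise ValueError("gene too short for the requested trim")
    if tr.strand == "-":
        return BsjKey(tr.chrom, lo, hi, "-")
    return BsjKey(tr.chrom, hi, lo, "+")


def mid_exon_key(tr: Transcript, exon: int, trim: int = 10) -> BsjKey:
    """A BSJ placed strictly inside one exon (no model boundary matches).

    Emulates non-canonical circles formed within coding exons: the RAD
    score can still be balanced, but the FSJ support score is 0 and no
    transcript model is compatible.
    """
    s, e = tr.exons[exon]
    lo, hi = s + trim, e - trim
    if hi - lo < 2:
        raise ValueError("exon too short for the requested trim")
    if tr.strand == "-":
        return BsjKey(tr.chrom, lo, hi, "-")
    return BsjKey(tr.chrom, hi, lo, "+")


# ---------------------------------------------------------------------------
# Paired-end FASTQ with positioned BSJs
# ---------------------------------------------------------------------------


def _circle_sequence(key: BsjKey, model, genome, sequences) -> str:
    if sequences is not None and key in sequences:
        return sequences[key]
    if model is None or genome is None:
        raise ValueError(f"no sequence for {key.to_id()} and no model/genome given")
    result = assemble_circ_sequence(key, model, genome)
    if isinstance(result, NoCompatibleModel):
        raise ValueError(f"cannot resolve {key.to_id()}: {result.reason}")
    return result.sequence


def _draw_fragment_offset(
    rng, atype: str, C: int, F: int, R: int, m: int
) -> tuple[int, int]:
    """Return (d, offset) for one pair of the requested alignment type."""
    lo_ov = max(m, 1)
    if atype == "II":
        o = int(rng.integers(lo_ov, R - lo_ov + 1))
        return o, o
    if atype == "III":
        o = int(rng.integers(lo_ov, R - lo_ov + 1))
        return F - o, o
    if atype == "IV":
        if F < 2 * R + 2:
            raise ValueError("type IV needs a gap: fragment_len >= 2*read_len + 2")
        d = int(rng.integers(R + 1, F - R))
        return d, d
    if atype == "I":
        if C <= F:
            raise ValueError(
                "type I is impossible for a circle not larger than a fragment"
            )
        d = int(rng.integers(F, C))
        return d, d
    raise ValueError(f"unknown alignment type {atype!r}")


def bsj_fastq_generate(
    keys: Sequence[BsjKey],
    model: GeneModel | None = None,
    genome=None,
    sequences: Mapping[BsjKey, str] | None = None,
    read_len: int = 100,
    frag_len: int = 300,
    n_pairs_per_key: int = 12,
    type_mix: Mapping[str, float] | None = None,
    offsets: Sequence[int] | None = None,
    min_overhang: int = 15,
    seed: int = 0,
    out_prefix=None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], list[SimTruth]]:
    """Generate paired-end reads from circularised sequences with truth.

    Each key resolves to a circular sequence (via the gene model, or
    directly through ``sequences``).  For every pair an alignment type is
    drawn from ``type_mix`` (default 50/50 type II/III) and the junction
    is positioned accordingly — uniformly within ``[min_overhang,
    read_len - min_overhang]`` of the junction-bearing read, or at the
    explicit ``offsets`` if given (cycled).  Read 2 is the reverse
    complement of the fragment end (FR orientation).  Base qualities are
    constant high; reads are error-free.

    Returns ``(reads1, reads2, truths)`` as (id, sequence) pairs; with
    ``out_prefix`` also writes ``<prefix>_1.fastq``, ``<prefix>_2.fastq``
    and ``<prefix>_truth.tsv``.
    """
    if read_len > frag_len:
        raise ValueError("read_len cannot exceed frag_len")
    if not 0 <= min_overhang < read_len / 2:
        raise ValueError("min_overhang must satisfy 0 <= m < read_len/2")
    type_mix = dict(type_mix or {"II": 0.5, "III": 0.5})
    types = sorted(type_mix)
    weights = np.array([type_mix[t] for t in types], dtype=float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)

    reads1: list[tuple[str, str]] = []
    reads2: list[tuple[str, str]] = []
    truths: list[SimTruth] = []
    serial = 0
    offset_i = 0
    for key in keys:
        seq = _circle_sequence(key, model, genome, sequences)
        C = len(seq)
        if C < frag_len:
            raise ValueError(
                f"{key.to_id()}: circle ({C} nt) shorter than a fragment "
                f"({frag_len} nt); wrap-around fragments of small circles "
                "are not modelled"
            )
        doubled = seq + seq
        for _ in range(n_pairs_per_key):
            atype = types[int(rng.choice(len(types), p=weights))]
            if offsets is not None and atype in ("II", "III"):
                o = offsets[offset_i % len(offsets)]
                offset_i += 1
                d = o if atype == "II" else frag_len - o
                offset = o
            else:
                d, offset = _draw_fragment_offset(
                    rng, atype, C, frag_len, read_len, min_overhang
                )
            frag_start = (C - d) % C
            frag = doubled[frag_start : frag_start + frag_len]
            read_id = _format_read_id(key, atype, offset, serial)
            serial += 1
            reads1.append((read_id, frag[:read_len]))
            reads2.append((read_id, revcomp(frag[frag_len - read_len :])))
            truths.append(SimTruth(read_id, key, atype, offset))
    if out_prefix is not None:
        out_prefix = str(out_prefix)
        qual = "I" * read_len
        for suffix, reads in (("_1.fastq", reads1), ("_2.fastq", reads2)):
            with open(out_prefix + suffix, "w") as fh:
                for rid, rseq in reads:
                    fh.write(f"@{rid}\n{rseq}\n+\n{qual}\n")
        write_truth_table(truths, out_prefix + "_truth.tsv")
    return reads1, reads2, truths


def write_truth_table(truths: Iterable[SimTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tdonor_pos\tacceptor_pos\tstrand\ttype\toffset\n")
        for t in truths:
            fh.write(
                f"{t.read_id}\t{t.bsj.chrom}\t{t.bsj.donor_pos}\t"
                f"{t.bsj.acceptor_pos}\t{t.bsj.strand}\t{t.alignment_type}\t{t.offset}\n"
            )


def read_truth_table(path) -> list[SimTruth]:
    truths = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("read_id")
        for line in fh:
            rid, chrom, donor, acceptor, strand, atype, offset = line.rstrip("\n").split("\t")
            truths.append(
                SimTruth(rid, BsjKey(chrom, int(donor), int(acceptor), strand), atype, int(offset))
            )
    return truths


# ---------------------------------------------------------------------------
# Chimeric records exactly as an aligner would emit them
# ---------------------------------------------------------------------------


def _piece_start(key: BsjKey, a: int, b: int) -> int:
    """Genomic (leftmost, 1-based) start of circle-index piece [a, b).

    Circle index 0 is the first base after the acceptor in transcript
    orientation: genomic ``low+1`` upward on '+', ``high-1`` downward
    on '-'.
    """
    if key.strand == "-":
        return (key.high - 1) - b + 1
    return (key.low + 1) + a


def simulate_chimeric_records(
    truths: Sequence[SimTruth],
    read_len: int = 100,
    frag_len: int = 300,
) -> list[ChimericRecord]:
    """Emit the chimeric-junction records an aligner would produce.

    Bypasses alignment entirely: positions and CIGARs (including the
    mate-gap ``p`` operator separating mate portions) are constructed from
    the truth geometry, so the mate classifier and the BSJ detector can be
    tested hermetically.  CIGAR operations are written in read order;
    soft-clip sidedness for '-'-strand alignments follows the read, not
    the genome.  Type I truths raise — they produce no chimeric record.
    """
    R, F = read_len, frag_len
    if F < 2 * R:
        raise ValueError("record simulation requires frag_len >= 2*read_len")
    records: list[ChimericRecord] = []
    for t in truths:
        if t.alignment_type == "I":
            raise ValueError(f"type I truth {t.read_id!r} produces no chimeric record")
        key = t.bsj
        C = key.circle_length
        if C < F:
            raise ValueError(f"{key.to_id()}: circle shorter than a fragment")
        gap = F - 2 * R
        strand = key.strand if key.strand in "+-" else "+"
        common = dict(
            chrom_donor=key.chrom,
            strand_donor=strand,
            chrom_acceptor=key.chrom,
            strand_acceptor=strand,
            repeat_left=0,
            repeat_right=0,
            read_id=t.read_id,
        )
        if t.alignment_type == "II":
            o = t.offset
            if not 0 < o < R:
                raise ValueError(f"bad type II offset {o} for {t.read_id}")
            d = o
            records.append(
                ChimericRecord(
                    pos_donor=key.donor_pos,
                    pos_acceptor=key.acceptor_pos,
                    junction_code=1,
                    seg1_start=_piece_start(key, C - d, C),
                    seg1_cigar=f"{d}M{R - d}S",
                    seg2_start=min(
                        _piece_start(key, 0, R - d),
                        _piece_start(key, F - R - d, F - d),
                    ),
                    seg2_cigar=f"{d}S{R - d}M{gap}p{R}M",
                    **common,
                )
            )
        elif t.alignment_type == "III":
            o = t.offset
            if not 0 < o < R:
                raise ValueError(f"bad type III offset {o} for {t.read_id}")
            d = F - o
            records.append(
                ChimericRecord(
                    pos_donor=key.donor_pos,
                    pos_acceptor=key.acceptor_pos,
                    junction_code=1,
                    seg1_start=min(
                        _piece_start(key, C - d, C - d + R),
                        _piece_start(key, C - d + F - R, C),
                    ),
                    seg1_cigar=f"{R}M{gap}p{R - o}M{o}S",
                    seg2_start=_piece_start(key, 0, o),
                    seg2_cigar=f"{R - o}S{o}M",
                    **common,
                )
            )
        elif t.alignment_type == "IV":
            d = t.offset
            if not R < d < F - R:
                raise ValueError(f"bad type IV gap offset {d} for {t.read_id}")
            m1 = (C - d, C - d + R)
            m2 = (F - R - d, F - d)
            m1_start = _piece_start(key, *m1)
            m2_start = _piece_start(key, *m2)
            records.append(
                ChimericRecord(
                    pos_donor=key.donor_pos,
                    pos_acceptor=key.acceptor_pos,
                    junction_code=-1,
                    seg1_start=m1_start,
                    seg1_cigar=f"{R}M",
                    seg2_start=m2_start,
                    seg2_cigar=f"{R}M",
                    **common,
                )
            )
        else:
            raise ValueError(f"unknown alignment type {t.alignment_type!r}")
    return records


# ---------------------------------------------------------------------------
# Forward-splice-junction tables
# ---------------------------------------------------------------------------


def make_fsj_table(
    model: GeneModel,
    mean_count: float = 20.0,
    seed: int = 0,
    zero_junctions: Iterable[tuple[str, int, int]] = (),
) -> list[ForwardJunction]:
    """One forward junction per adjacent exon pair, Poisson unique counts.

    ``zero_junctions`` (chrom, intron_start, intron_end) triples are
    omitted entirely, emulating junctions with no linear evidence (e.g.
    after RNase R depletion).  Junctions shared between transcripts are
    emitted once.
    """
    rng = np.random.default_rng(seed)
    zeroed = set(zero_junctions)
    seen: dict[tuple[str, int, int], ForwardJunction] = {}
    for tid in sorted(model.transcripts):
        tr = model.transcripts[tid]
        for (s1, e1), (s2, e2) in zip(tr.exons, tr.exons[1:]):
            coords = (tr.chrom, e1 + 1, s2 - 1)
            if coords in zeroed or coords in seen:
                continue
            seen[coords] = ForwardJunction(
                chrom=tr.chrom,
                intron_start=e1 + 1,
                intron_end=s2 - 1,
                strand_code=1 if tr.strand == "+" else 2,
                motif_code=1 if tr.strand == "+" else 2,
                annotated_flag=1,
                unique_count=int(rng.poisson(mean_count)),
                multi_count=0,
                max_overhang=50,
            )
    return sorted(seen.values(), key=lambda j: (j.chrom, j.intron_start, j.intron_end))
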