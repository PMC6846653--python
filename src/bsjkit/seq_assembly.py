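"""Assembly of predicted circRNA sequences from gene-model exons.

A BSJ delimits a circularised genomic span (the coordinates strictly
between the donor and acceptor intron bases).  The predicted circRNA
sequence is the longest combination of exons from a *single* transcript
that (a) all fall within that span and (b) whose outermost boundaries
coincide exactly with the span edges — i.e. the backsplice donor and
acceptor must align to a splice donor and acceptor of the concatenated
exons.  BSJs that match no transcript under both conditions yield an
explicit "no compatible model" result rather than an error: non-canonical
circles formed inside coding exons are a real phenomenon and simply have
no model-derived sequence.

Gene models are read from GTF via :mod:`gffutils`; genome sequence comes
from an indexed FASTA via :mod:`pyfaidx`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pyfaidx

from .bsj_core import BsjKey

__all__ = [
    "Transcript",
    "Gene",
    "GeneModel",
    "CircSequence",
    "NoCompatibleModel",
    "assemble_circ_sequence",
    "backsplice_window",
    "window_from_sequence",
    "bsj_to_circRNA_sequence",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Transcript:
    id: str
    gene: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive, sorted

    def __post_init__(self):
        prev_end = 0
        for s, e in self.exons:
            if s > e or s <= prev_end:
                raise ValueError(f"exons must be sorted and non-overlapping: {self.id}")
            prev_end = e


@dataclass(frozen=True)
class Gene:
    name: str
    chrom: str
    strand: str
    start: int
    end: int


class GeneModel:
    """Transcripts with exons, indexed by id, plus per-gene extents."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts: dict[str, Transcript] = {t.id: t for t in transcripts}
        genes: dict[str, Gene] = {}
        for t in self.transcripts.values():
            lo, hi = t.exons[0][0], t.exons[-1][1]
            g = genes.get(t.gene)
            if g is None:
                genes[t.gene] = Gene(t.gene, t.chrom, t.strand, lo, hi)
            else:
                genes[t.gene] = Gene(
                    t.gene, g.chrom, g.strand, min(g.start, lo), max(g.end, hi)
                )
        self.genes = genes

    @classmethod
    def from_gtf(cls, path) -> "GeneModel":
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
        transcripts = []
        for tr in db.features_of_type("transcript"):
            exons = sorted(
                (ex.start, ex.end) for ex in db.children(tr, featuretype="exon")
            )
            if not exons:
                continue
            gene = tr.attributes.get("gene_name", tr.attributes.get("gene_id", ["?"]))[0]
            transcripts.append(
                Transcript(
                    id=tr.attributes["transcript_id"][0],
                    gene=gene,
                    chrom=tr.seqid,
                    strand=tr.strand,
                    exons=tuple(exons),
                )
            )
        return cls(transcripts)

    def on_chrom(self, chrom: str) -> list[Transcript]:
        return [t for t in self.transcripts.values() if t.chrom == chrom]


@dataclass(frozen=True)
class CircSequence:
    """Assembled circRNA sequence: exon blocks plus the 5'->3' sequence.

    ``blocks`` are genomic 1-based inclusive intervals in genomic order;
    ``sequence`` is in the transcript-strand orientation (reverse
    complemented for '-' transcripts), linearised from the backsplice
    acceptor to the donor so the junction sits between the last and first
    base.
    """

    key: BsjKey
    transcript_id: str
    blocks: tuple[tuple[int, int], ...]
    sequence: str

    def __post_init__(self):
        if len(self.sequence) != sum(e - s + 1 for s, e in self.blocks):
            raise ValueError("sequence length != sum of block lengths")


@dataclass(frozen=True)
class NoCompatibleModel:
    """Marker result: no transcript's exons satisfy the BSJ boundaries."""

    key: BsjKey
    reason: str = "no transcript with matching exon boundaries"


def _fasta(genome) -> pyfaidx.Fasta:
    if isinstance(genome, (str, Path)):
        return pyfaidx.Fasta(str(genome))
    return genome


def _fetch(fasta, chrom: str, start: int, end: int) -> str:
    # pyfaidx slices are 0-based half-open
    return str(fasta[chrom][start - 1 : end]).upper()


def assemble_circ_sequence(
    key: BsjKey, model: GeneModel, genome
) -> CircSequence | NoCompatibleModel:
    """Assemble the predicted circRNA sequence bounded by ``key``.

    Among transcripts whose exons inside the BSJ span start exactly at the
    acceptor-side boundary and end exactly at the donor-side boundary, the
    one maximising total selected-exon length wins (ties broken by
    lexicographically smallest transcript id).
    """
    fasta = _fasta(genome)
    lo_bound, hi_bound = key.low + 1, key.high - 1  # circularised genomic span
    if hi_bound < lo_bound:
        return NoCompatibleModel(key, "empty genomic span")
    best: tuple[int, str, tuple[tuple[int, int], ...], Transcript] | None = None
    for tr in model.on_chrom(key.chrom):
        if key.strand in "+-" and tr.strand != key.strand:
            continue
        selected = tuple(
            (s, e) for s, e in tr.exons if s >= lo_bound and e <= hi_bound
        )
        if not selected:
            continue
        if selected[0][0] != lo_bound or selected[-1][1] != hi_bound:
            continue  # BSJ must land on splice boundaries of the selection
        length = sum(e - s + 1 for s, e in selected)
        cand = (-length, tr.id, selected, tr)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        return NoCompatibleModel(key)
    _, _, blocks, tr = best
    seq = "".join(_fetch(fasta, key.chrom, s, e) for s, e in blocks)
    if tr.strand == "-":
        seq = revcomp(seq)
    return CircSequence(key, tr.id, blocks, seq)


def window_from_sequence(sequence: str, flank: int = 50) -> str:
    """Backsplice window of a circular sequence: flank + '.' + flank.

    The sequence is taken as linearised acceptor->donor, so the junction
    lies between its last and first base.  For circles shorter than the
    flank the window wraps and repeats are permitted.
    """
    if not sequence:
        raise ValueError("empty sequence")
    reps = math.ceil(flank / len(sequence)) + 1
    tiled = sequence * reps
    return tiled[-flank:] + "." + tiled[:flank]


def backsplice_window(
    key: BsjKey, model: GeneModel, genome, flank: int = 50
) -> str | NoCompatibleModel:
    """Render the junction-centred sequence window for a BSJ.

    Returns a string of ``flank`` nt, the ``'.'`` junction marker, then
    ``flank`` nt (length ``2*flank + 1``), cut from the circularised
    sequence so it wraps across the BSJ.
    """
    circ = assemble_circ_sequence(key, model, genome)
    if isinstance(circ, NoCompatibleModel):
        return circ
    return window_from_sequence(circ.sequence, flank)


def bsj_to_circRNA_sequence(
    keys: Sequence[BsjKey],
    model: GeneModel,
    genome,
    out_fasta,
    report_path=None,
) -> tuple[list[CircSequence], list[NoCompatibleModel]]:
    """Write predicted circRNA sequences for ``keys`` to a FASTA file.

    One record per resolvable key (id ``chrom:donor-acceptor:strand``);
    unresolvable keys go to a sidecar TSV report (if a path is given) and
    are returned alongside the assembled sequences.
    """
    fasta = _fasta(genome)
    resolved: list[CircSequence] = []
    failed: list[NoCompatibleModel] = []
    with open(out_fasta, "w") as fh:
        for key in keys:
            result = assemble_circ_sequence(key, model, fasta)
            if isinstance(result, NoCompatibleModel):
                failed.append(result)
                continue
            resolved.append(result)
            fh.write(f">{key.to_id()} transcript={result.transcript_id}\n")
            for i in range(0, len(result.sequence), 60):
                fh.write(result.sequence[i : i + 60] + "\n")
    if report_path is not None:
        with open(report_path, "w") as fh:
            fh.write("key\treason\n")
            for f in failed:
                fh.write(f"{f.key.to_id()}\t{f.reason}\n")
    return resolved, failed
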