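"""Readers and writers for the text formats the toolkit consumes and produces.

Supported dialects:

* STAR ``Chimeric.out.junction`` — the classic 14-column layout, plus a
  tolerant mode for newer header-bearing files that append extra columns
  and a trailing ``# Nreads`` comment line.
* STAR ``SJ.out.tab`` — 9-column canonical (forward) splice junction table.
* STAR ``ReadsPerGene.out.tab`` — per-gene counts with four leading ``N_*``
  summary rows.
* CIRI2 tables (``.ciri``, 1-based inclusive coordinates, header line).
* circExplorer2 tables (``.ce``, BED-derived: 0-based half-open start).

All coordinates are normalised to 1-based inclusive at parse time so that
internal code never has to reason about dialect origin.  Gzip-compressed
inputs are accepted transparently (``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

__all__ = [
    "ChimericRecord",
    "ForwardJunction",
    "GeneCountRow",
    "GeneCountSummary",
    "ExternalBsjRow",
    "SampleGroup",
    "ParseError",
    "parse_chimeric",
    "write_chimeric",
    "parse_sj",
    "write_sj",
    "parse_reads_per_gene",
    "write_reads_per_gene",
    "parse_external",
    "write_external",
    "group_samples",
    "SUFFIX_KINDS",
]

CIGAR_RE = re.compile(r"^(?:[0-9]+[MIDNSHp])+$")

CIRI_HEADER = (
    "circRNA_ID\tchr\tcircRNA_start\tcircRNA_end\t#junction_reads\t"
    "SM_MS_SMS\t#non_junction_reads\tjunction_reads_ratio\tcircRNA_type\t"
    "gene_id\tstrand\tjunction_reads_ID"
)


class ParseError(ValueError):
    """Malformed input line; carries the path and 1-based line number."""

    def __init__(self, path, lineno: int, message: str):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


def _open(path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Domain rows
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChimericRecord:
    """One line of an aligner chimeric-junction file.

    ``pos_donor`` is the 1-based first intron base on the donor side of the
    junction and ``pos_acceptor`` the 1-based last intron base on the
    acceptor side, exactly as STAR reports them.  ``junction_code`` is -1
    for pair-encompassing records (the mates flank, but do not contain, the
    junction) and >= 0 for junctions captured within a read.  Segment CIGARs
    may contain the mate-gap operator ``p`` separating the two mates of a
    paired-end alignment.
    """

    chrom_donor: str
    pos_donor: int
    strand_donor: str
    chrom_acceptor: str
    pos_acceptor: int
    strand_acceptor: str
    junction_code: int
    repeat_left: int
    repeat_right: int
    read_id: str
    seg1_start: int
    seg1_cigar: str
    seg2_start: int
    seg2_cigar: str

    def __post_init__(self):
        if self.pos_donor < 1 or self.pos_acceptor < 1:
            raise ValueError(f"positions must be >= 1: {self}")
        for cig in (self.seg1_cigar, self.seg2_cigar):
            if not CIGAR_RE.match(cig):
                raise ValueError(f"invalid CIGAR {cig!r} in record {self.read_id}")

    def to_line(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.chrom_donor,
                self.pos_donor,
                self.strand_donor,
                self.chrom_acceptor,
                self.pos_acceptor,
                self.strand_acceptor,
                self.junction_code,
                self.repeat_left,
                self.repeat_right,
                self.read_id,
                self.seg1_start,
                self.seg1_cigar,
                self.seg2_start,
                self.seg2_cigar,
            )
        )


@dataclass(frozen=True)
class ForwardJunction:
    """One canonical splice junction (one row of ``SJ.out.tab``).

    ``intron_start``/``intron_end`` are the 1-based first and last intron
    bases; ``strand_code`` follows the aligner convention 0=undefined,
    1=+, 2=-.  ``unique_count`` is the uniquely-mapping read support used
    throughout for FSJ evidence.
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand_code: int
    motif_code: int
    annotated_flag: int
    unique_count: int
    multi_count: int
    max_overhang: int

    def __post_init__(self):
        if self.intron_start > self.intron_end:
            raise ValueError(f"intron_start > intron_end: {self}")
        if min(self.unique_count, self.multi_count) < 0:
            raise ValueError(f"negative counts: {self}")

    def to_line(self) -> str:
        return "\t".join(
            str(x)
            for x in (
                self.chrom,
                self.intron_start,
                self.intron_end,
                self.strand_code,
                self.motif_code,
                self.annotated_flag,
                self.unique_count,
                self.multi_count,
                self.max_overhang,
            )
        )


@dataclass(frozen=True)
class GeneCountRow:
    gene_id: str
    unstranded_count: int
    stranded_fwd_count: int
    stranded_rev_count: int


@dataclass(frozen=True)
class GeneCountSummary:
    """The four leading ``N_*`` rows of a ReadsPerGene file."""

    n_unmapped: tuple[int, int, int]
    n_multimapping: tuple[int, int, int]
    n_no_feature: tuple[int, int, int]
    n_ambiguous: tuple[int, int, int]


@dataclass(frozen=True)
class ExternalBsjRow:
    """A BSJ row imported from an external caller, coordinate-normalised.

    ``start`` is the 1-based first circRNA base and ``end`` the 1-based last
    base regardless of the source dialect (circExplorer2 starts are shifted
    +1 on import).
    """

    source: str  # "CIRI2" or "CIRCEXPLORER2"
    chrom: str
    start: int
    end: int
    strand: str
    count: int
    gene_name: str | None = None
    extra: tuple[str, ...] = ()

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start > end: {self}")
        if self.count < 0:
            raise ValueError(f"negative count: {self}")


@dataclass
class SampleGroup:
    """Files belonging to one sample, grouped by filename prefix."""

    sample_id: str
    files: dict[str, Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Chimeric.out.junction
# ---------------------------------------------------------------------------


def parse_chimeric(path, dialect: str = "auto") -> list[ChimericRecord]:
    """Parse a ``Chimeric.out.junction`` file.

    ``dialect`` is ``"14-column"`` (classic layout), ``"21-column"``
    (newer header-bearing files; the 14 leading columns are read and the
    rest ignored) or ``"auto"``.  Comment lines (``#``) and the column
    header line of newer files are skipped.
    """
    if dialect not in ("auto", "14-column", "21-column"):
        raise ValueError(f"unknown dialect {dialect!r}")
    records: list[ChimericRecord] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] in ("chr_donorA", "chr_donor"):  # column header
                continue
            if len(fields) < 14:
                raise ParseError(path, lineno, f"expected >=14 columns, got {len(fields)}")
            if dialect == "14-column" and len(fields) != 14:
                raise ParseError(path, lineno, f"expected 14 columns, got {len(fields)}")
            try:
                rec = ChimericRecord(
                    chrom_donor=fields[0],
                    pos_donor=int(fields[1]),
                    strand_donor=fields[2],
                    chrom_acceptor=fields[3],
                    pos_acceptor=int(fields[4]),
                    strand_acceptor=fields[5],
                    junction_code=int(fields[6]),
                    repeat_left=int(fields[7]),
                    repeat_right=int(fields[8]),
                    read_id=fields[9],
                    seg1_start=int(fields[10]),
                    seg1_cigar=fields[11],
                    seg2_start=int(fields[12]),
                    seg2_cigar=fields[13],
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            records.append(rec)
    return records


def write_chimeric(records: Iterable[ChimericRecord], path) -> None:
    with _open(path, "wt") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")


# ---------------------------------------------------------------------------
# SJ.out.tab
# ---------------------------------------------------------------------------


def parse_sj(path) -> list[ForwardJunction]:
    """Parse a 9-column ``SJ.out.tab`` splice junction table."""
    rows: list[ForwardJunction] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(path, lineno, f"expected 9 columns, got {len(fields)}")
            try:
                rows.append(
                    ForwardJunction(
                        chrom=fields[0],
                        intron_start=int(fields[1]),
                        intron_end=int(fields[2]),
                        strand_code=int(fields[3]),
                        motif_code=int(fields[4]),
                        annotated_flag=int(fields[5]),
                        unique_count=int(fields[6]),
                        multi_count=int(fields[7]),
                        max_overhang=int(fields[8]),
                    )
                )
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
    return rows


def write_sj(rows: Iterable[ForwardJunction], path) -> None:
    with _open(path, "wt") as fh:
        for row in rows:
            fh.write(row.to_line() + "\n")


# ---------------------------------------------------------------------------
# ReadsPerGene.out.tab
# ---------------------------------------------------------------------------

_SUMMARY_KEYS = ("N_unmapped", "N_multimapping", "N_noFeature", "N_ambiguous")


def parse_reads_per_gene(path) -> tuple[GeneCountSummary, list[GeneCountRow]]:
    """Parse a ``ReadsPerGene.out.tab`` file.

    The four leading ``N_*`` summary rows are returned as a separate
    :class:`GeneCountSummary`, never as genes.
    """
    summary: dict[str, tuple[int, int, int]] = {}
    rows: list[GeneCountRow] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(path, lineno, f"expected 4 columns, got {len(fields)}")
            try:
                counts = (int(fields[1]), int(fields[2]), int(fields[3]))
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from exc
            if fields[0] in _SUMMARY_KEYS:
                summary[fields[0]] = counts
            else:
                if min(counts) < 0:
                    raise ParseError(path, lineno, "negative count")
                rows.append(GeneCountRow(fields[0], *counts))
    zero = (0, 0, 0)
    return (
        GeneCountSummary(
            n_unmapped=summary.get("N_unmapped", zero),
            n_multimapping=summary.get("N_multimapping", zero),
            n_no_feature=summary.get("N_noFeature", zero),
            n_ambiguous=summary.get("N_ambiguous", zero),
        ),
        rows,
    )


def write_reads_per_gene(summary: GeneCountSummary, rows: Iterable[GeneCountRow], path) -> None:
    with _open(path, "wt") as fh:
        for key, counts in zip(
            _SUMMARY_KEYS,
            (summary.n_unmapped, summary.n_multimapping, summary.n_no_feature, summary.n_ambiguous),
        ):
            fh.write(key + "\t" + "\t".join(str(c) for c in counts) + "\n")
        for row in rows:
            fh.write(
                f"{row.gene_id}\t{row.unstranded_count}\t"
                f"{row.stranded_fwd_count}\t{row.stranded_rev_count}\n"
            )


# ---------------------------------------------------------------------------
# External callers: CIRI2 (.ciri) and circExplorer2 (.ce)
# ---------------------------------------------------------------------------


def _infer_source(path) -> str:
    name = str(path)
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith(".ciri"):
        return "CIRI2"
    if name.endswith(".ce"):
        return "CIRCEXPLORER2"
    raise ValueError(f"cannot infer source from extension of {path!r}")


def parse_external(path, source: str | None = None) -> list[ExternalBsjRow]:
    """Parse a CIRI2 (``.ciri``) or circExplorer2 (``.ce``) BSJ table.

    CIRI2 coordinates are already 1-based inclusive; circExplorer2 starts
    are 0-based (BED heritage) and are incremented by 1 on import, so the
    same circRNA read from either dialect yields the same internal
    coordinates.
    """
    source = source or _infer_source(path)
    rows: list[ExternalBsjRow] = []
    with _open(path) as fh:
        if source == "CIRI2":
            header = fh.readline().rstrip("\n")
            if header.split("\t")[:5] != CIRI_HEADER.split("\t")[:5]:
                raise ParseError(path, 1, "unexpected CIRI2 header")
            for lineno, line in enumerate(fh, start=2):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 11:
                    raise ParseError(path, lineno, f"expected >=11 columns, got {len(fields)}")
                try:
                    rows.append(
                        ExternalBsjRow(
                            source="CIRI2",
                            chrom=fields[1],
                            start=int(fields[2]),
                            end=int(fields[3]),
                            strand=fields[10],
                            count=int(fields[4]),
                            gene_name=fields[9] if fields[9] not in ("n/a", "") else None,
                            extra=(fields[0], *fields[5:9], *fields[11:]),
                        )
                    )
                except ValueError as exc:
                    raise ParseError(path, lineno, str(exc)) from exc
        elif source == "CIRCEXPLORER2":
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 18:
                    raise ParseError(path, lineno, f"expected 18 columns, got {len(fields)}")
                try:
                    rows.append(
                        ExternalBsjRow(
                            source="CIRCEXPLORER2",
                            chrom=fields[0],
                            start=int(fields[1]) + 1,  # 0-based -> 1-based
                            end=int(fields[2]),
                            strand=fields[5],
                            count=int(fields[12]),
                            gene_name=fields[14] or None,
                            extra=(fields[3], fields[4], *fields[6:12], fields[13], *fields[15:]),
                        )
                    )
                except ValueError as exc:
                    raise ParseError(path, lineno, str(exc)) from exc
        else:
            raise ValueError(f"unknown source {source!r}")
    return rows


def write_external(rows: Sequence[ExternalBsjRow], path, source: str | None = None) -> None:
    """Write rows back out in the requested dialect (coordinates round-trip)."""
    source = source or _infer_source(path)
    with _open(path, "wt") as fh:
        if source == "CIRI2":
            fh.write(CIRI_HEADER + "\n")
            for r in rows:
                circ_id = r.extra[0] if r.extra else f"{r.chrom}:{r.start}|{r.end}"
                mid = r.extra[1:5] if len(r.extra) >= 5 else ("0,0,0", "0", "0", "exon")
                tail = r.extra[5:] if len(r.extra) > 5 else ("",)
                fh.write(
                    "\t".join(
                        (
                            circ_id,
                            r.chrom,
                            str(r.start),
                            str(r.end),
                            str(r.count),
                            *mid,
                            r.gene_name or "n/a",
                            r.strand,
                            *tail,
                        )
                    )
                    + "\n"
                )
        elif source == "CIRCEXPLORER2":
            for r in rows:
                extra = list(r.extra) if len(r.extra) >= 9 else [
                    "circRNA/unknown", "0", *["0"] * 6, "circRNA",
                ]
                fh.write(
                    "\t".join(
                        (
                            r.chrom,
                            str(r.start - 1),  # back to 0-based
                            str(r.end),
                            extra[0],
                            extra[1],
                            r.strand,
                            *extra[2:8],
                            str(r.count),
                            extra[8],
                            r.gene_name or "",
                            *extra[9:],
                        )
                    )
                    + "\n"
                )
        else:
            raise ValueError(f"unknown source {source!r}")


# ---------------------------------------------------------------------------
# Sample grouping
# ---------------------------------------------------------------------------

#: recognised filename suffixes, longest first so stripping is longest-match
SUFFIX_KINDS: tuple[tuple[str, str], ...] = (
    (".ReadsPerGene.out.tab", "gene_counts"),
    (".Chimeric.out.junction", "chimeric"),
    (".SJ.out.tab", "sj"),
    (".ciri", "ciri"),
    (".ce", "ce"),
)


def group_samples(paths: Iterable) -> tuple[list[SampleGroup], list[Path]]:
    """Group files into samples by filename prefix.

    The sample id is the basename with the longest recognised suffix
    stripped (so prefixes containing dots survive).  Files with an
    unrecognised suffix are returned in the second element rather than
    raising.  Two files of the same kind under one prefix is an error.
    """
    groups: dict[str, SampleGroup] = {}
    unassigned: list[Path] = []
    for path in paths:
        path = Path(path)
        name = path.name
        if name.endswith(".gz"):
            name = name[:-3]
        for suffix, kind in SUFFIX_KINDS:
            if name.endswith(suffix):
                sample_id = name[: -len(suffix)]
                grp = groups.setdefault(sample_id, SampleGroup(sample_id))
                if kind in grp.files:
                    raise ValueError(
                        f"sample {sample_id!r} has more than one {kind} file"
                    )
                grp.files[kind] = path
                break
        else:
            unassigned.append(path)
    return sorted(groups.values(), key=lambda g: g.sample_id), unassigned
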