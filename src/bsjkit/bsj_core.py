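"""BSJ detection from chimeric records and the multi-sample count table.

A backsplice junction joins a splice donor to an *upstream* splice
acceptor, so on the '+' strand the acceptor coordinate is smaller than the
donor coordinate (and the reverse on '-').  Chimeric records satisfying
that inversion on one chromosome and strand, within a configurable genomic
span, are tallied under their :class:`BsjKey`.  Pair-encompassing records
(junction code -1) never create a junction on their own; they are matched
to already-detected keys within a fragment-length tolerance and tallied as
type-IV supporting evidence only.

The count table is a thin wrapper over a pandas DataFrame with a
(sample, metric) column MultiIndex, so multi-sample merging, annotation,
normalisation and TSV/BED export are ordinary frame operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import qc_scores
from .formats import ChimericRecord

__all__ = [
    "BsjKey",
    "BsjTable",
    "DetectionReport",
    "detect_bsj",
    "merge_tables",
    "annotate_genes",
    "normalize",
    "COUNT_METRICS",
]

COUNT_METRICS = ("total", "type2", "type3", "type4", "ambiguous")
KEY_NAMES = ("chrom", "donor_pos", "acceptor_pos", "strand")


@dataclass(frozen=True, order=True)
class BsjKey:
    """Canonical identity of a backsplice junction.

    ``donor_pos`` is the 1-based first intron base on the donor side,
    ``acceptor_pos`` the 1-based last intron base on the acceptor side.
    The backsplice inversion means ``acceptor_pos < donor_pos`` on '+' and
    ``acceptor_pos > donor_pos`` on '-'.  The circularised sequence spans
    the coordinates strictly between the two.
    """

    chrom: str
    donor_pos: int
    acceptor_pos: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")
        if self.strand == "+" and not self.acceptor_pos < self.donor_pos:
            raise ValueError(f"'+' strand BSJ requires acceptor < donor: {self}")
        if self.strand == "-" and not self.acceptor_pos > self.donor_pos:
            raise ValueError(f"'-' strand BSJ requires acceptor > donor: {self}")

    @property
    def span(self) -> int:
        """Genomic span |donor - acceptor| of the junction."""
        return abs(self.donor_pos - self.acceptor_pos)

    @property
    def circle_length(self) -> int:
        """Length of the circularised sequence between the intron bases."""
        return self.span - 1

    @property
    def low(self) -> int:
        return min(self.donor_pos, self.acceptor_pos)

    @property
    def high(self) -> int:
        return max(self.donor_pos, self.acceptor_pos)

    def to_id(self) -> str:
        return f"{self.chrom}:{self.donor_pos}-{self.acceptor_pos}:{self.strand}"

    @classmethod
    def from_id(cls, text: str) -> "BsjKey":
        chrom, coords, strand = text.rsplit(":", 2)
        donor, acceptor = coords.split("-")
        return cls(chrom, int(donor), int(acceptor), strand)

    def as_tuple(self) -> tuple:
        return (self.chrom, self.donor_pos, self.acceptor_pos, self.strand)


@dataclass
class DetectionReport:
    """Bookkeeping for one detect_bsj run (conservation accounting)."""

    n_records: int = 0
    n_counted: int = 0
    n_type4: int = 0
    discards: dict[str, int] = field(default_factory=dict)

    def discard(self, reason: str):
        self.discards[reason] = self.discards.get(reason, 0) + 1

    @property
    def n_discarded(self) -> int:
        return sum(self.discards.values())


class BsjTable:
    """Per-sample BSJ count matrix with optional scores and annotation.

    ``df`` is indexed by (chrom, donor_pos, acceptor_pos, strand) with a
    (sample, metric) column MultiIndex.  Count metrics are ``total``,
    ``type2``, ``type3``, ``type4`` and ``ambiguous`` (total = type2 +
    type3 + ambiguous); score metrics (``rad``, ``fsj``, ``norm``) are
    attached by :mod:`bsjkit.qc_scores` / :func:`normalize`.  Gene
    annotation lives in the ``gene`` attribute (a Series aligned with the
    index, or None).
    """

    def __init__(self, df: pd.DataFrame, gene: pd.Series | None = None):
        if not isinstance(df.columns, pd.MultiIndex):
            raise ValueError("BsjTable frame needs (sample, metric) columns")
        self.df = df.sort_index()
        self.gene = gene if gene is None else gene.reindex(self.df.index)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_counts(
        cls,
        sample_id: str,
        counts: Mapping[BsjKey, Mapping[str, int]],
    ) -> "BsjTable":
        index = pd.MultiIndex.from_tuples(
            [k.as_tuple() for k in counts], names=KEY_NAMES
        ) if counts else pd.MultiIndex.from_arrays([[], [], [], []], names=KEY_NAMES)
        data = {
            (sample_id, m): [counts[k].get(m, 0) for k in counts] for m in COUNT_METRICS
        }
        df = pd.DataFrame(data, index=index, dtype="int64")
        df.columns = pd.MultiIndex.from_tuples(df.columns, names=("sample", "metric"))
        return cls(df)

    # -- basic views ------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.df.columns.get_level_values("sample")))

    def keys(self) -> list[BsjKey]:
        return [BsjKey(*idx) for idx in self.df.index]

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, index_keys) -> "BsjTable":
        sub = self.df.loc[list(index_keys)] if len(index_keys) else self.df.iloc[0:0]
        gene = None if self.gene is None else self.gene.reindex(sub.index)
        return BsjTable(sub, gene)

    def copy(self) -> "BsjTable":
        return BsjTable(self.df.copy(), None if self.gene is None else self.gene.copy())

    def set_metric(self, sample: str, metric: str, values: pd.Series):
        self.df[(sample, metric)] = values.reindex(self.df.index)
        self.df = self.df.sort_index(axis=1)

    def counts(self, sample: str, metric: str = "total") -> pd.Series:
        return self.df[(sample, metric)]

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path):
        """Write a flat TSV: key columns then ``sample:metric`` columns."""
        flat = self.df.copy()
        flat.columns = [f"{s}:{m}" for s, m in flat.columns]
        if self.gene is not None:
            flat["gene"] = self.gene
        flat.reset_index().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BsjTable":
        flat = pd.read_csv(path, sep="\t")
        flat = flat.set_index(list(KEY_NAMES))
        gene = None
        if "gene" in flat.columns:
            gene = flat.pop("gene")
        cols = pd.MultiIndex.from_tuples(
            [tuple(c.split(":", 1)) for c in flat.columns], names=("sample", "metric")
        )
        flat.columns = cols
        return cls(flat, gene)

    def to_bed(self, path, sample: str | None = None):
        """Export BSJ spans as 0-based half-open BED for genome browsers."""
        sample = sample or self.samples[0]
        with open(path, "w") as fh:
            for idx, row in self.df.iterrows():
                key = BsjKey(*idx)
                fh.write(
                    f"{key.chrom}\t{key.low - 1}\t{key.high}\t{key.to_id()}\t"
                    f"{int(row[(sample, 'total')])}\t{key.strand}\n"
                )


def _canonical_key(rec: ChimericRecord, same_strand_required: bool) -> BsjKey | None:
    """Map a within-read chimeric record to a BSJ key, or None if not a BSJ."""
    if rec.chrom_donor != rec.chrom_acceptor:
        return None
    if rec.strand_donor != rec.strand_acceptor:
        if same_strand_required:
            return None
        strand = "."  # strand-agnostic mode: fold onto an unstranded key
    else:
        strand = rec.strand_donor
    if strand == "+" and rec.pos_acceptor < rec.pos_donor:
        return BsjKey(rec.chrom_donor, rec.pos_donor, rec.pos_acceptor, "+")
    if strand == "-" and rec.pos_acceptor > rec.pos_donor:
        return BsjKey(rec.chrom_donor, rec.pos_donor, rec.pos_acceptor, "-")
    if strand == ".":
        # unstranded: canonicalise with the '+' convention so the same
        # physical junction maps to one key from either representation
        donor, acceptor = rec.pos_donor, rec.pos_acceptor
        if acceptor == donor:
            return None
        if acceptor > donor:
            donor, acceptor = acceptor, donor
        return BsjKey(rec.chrom_donor, donor, acceptor, ".")
    return None


def _type4_matches(key: BsjKey, rec: ChimericRecord, tolerance: int) -> bool:
    """Does an encompassing record support ``key``?

    Both mates must start inside the circular span, each within
    ``tolerance`` of its respective junction coordinate, on the correct
    side (donor-side mate adjacent to the donor, acceptor-side mate
    adjacent to the acceptor).
    """
    if rec.chrom_donor != key.chrom or rec.chrom_acceptor != key.chrom:
        return False
    if key.strand in "+-" and rec.strand_donor not in (key.strand,):
        return False
    lo, hi = key.low, key.high
    p_lo, p_hi = sorted((rec.seg1_start, rec.seg2_start))
    return lo <= p_lo <= lo + tolerance and hi - tolerance <= p_hi <= hi


def detect_bsj(
    records: Sequence[ChimericRecord],
    sample_id: str = "sample",
    max_span: int = 1_000_000,
    same_strand_required: bool = True,
    type4_tolerance: int = 300,
) -> tuple[BsjTable, DetectionReport]:
    """Detect backsplice junctions in one sample's chimeric records.

    Within-read records (junction code >= 0) with same chromosome, same
    strand, inverted donor/acceptor order and span <= ``max_span`` are
    deduplicated by (read id, key) and tallied; each counted record is
    mate-classified into type II/III (or ambiguous).  Encompassing records
    (code -1) matching a detected key within ``type4_tolerance`` of both
    coordinates are tallied as type-IV support only — they never create a
    key and never enter the total.  Everything else is discarded with a
    reason, so counts + discards = input records.
    """
    report = DetectionReport(n_records=len(records))
    counts: dict[BsjKey, dict[str, int]] = {}
    seen: set[tuple[str, tuple]] = set()
    encompassing: list[ChimericRecord] = []

    for rec in records:
        if rec.junction_code < 0:
            encompassing.append(rec)
            continue
        key = _canonical_key(rec, same_strand_required)
        if key is None:
            if rec.chrom_donor != rec.chrom_acceptor:
                report.discard("different_chromosome")
            elif rec.strand_donor != rec.strand_acceptor:
                report.discard("different_strand")
            else:
                report.discard("not_backsplice")
            continue
        if key.span > max_span:
            report.discard("span_exceeded")
            continue
        dedupe = (rec.read_id, key.as_tuple())
        if dedupe in seen:
            report.discard("duplicate_read")
            continue
        seen.add(dedupe)
        tally = counts.setdefault(
            key, {m: 0 for m in COUNT_METRICS}
        )
        cls = qc_scores.classify_mate(rec)
        tally["total"] += 1
        if cls.label == qc_scores.TYPE_II:
            tally["type2"] += 1
        elif cls.label == qc_scores.TYPE_III:
            tally["type3"] += 1
        else:
            tally["ambiguous"] += 1
        report.n_counted += 1

    for rec in encompassing:
        matched = None
        for key in counts:
            if _type4_matches(key, rec, type4_tolerance):
                matched = key
                break
        if matched is None:
            report.discard("unmatched_encompassing")
            continue
        dedupe = (rec.read_id, matched.as_tuple())
        if dedupe in seen:
            report.discard("duplicate_read")
            continue
        seen.add(dedupe)
        counts[matched]["type4"] += 1
        report.n_type4 += 1

    return BsjTable.from_counts(sample_id, counts), report


def merge_tables(
    tables: Sequence[BsjTable], sample_ids: Sequence[str] | None = None
) -> BsjTable:
    """Union-merge single-sample tables into one multi-sample table.

    Missing counts are filled with 0 (a junction absent from a sample was
    simply not observed there); missing scores stay NaN.  Duplicate sample
    ids are an error.
    """
    if not tables:
        raise ValueError("need at least one table")
    frames = [t.df for t in tables]
    if sample_ids is not None:
        if len(sample_ids) != len(tables):
            raise ValueError("sample_ids length mismatch")
        frames = []
        for t, sid in zip(tables, sample_ids):
            if len(t.samples) != 1:
                raise ValueError("sample_ids renaming requires single-sample tables")
            df = t.df.copy()
            df.columns = pd.MultiIndex.from_tuples(
                [(sid, m) for _, m in df.columns], names=("sample", "metric")
            )
            frames.append(df)
    all_samples: list[str] = []
    for f in frames:
        all_samples.extend(dict.fromkeys(f.columns.get_level_values("sample")))
    if len(set(all_samples)) != len(all_samples):
        raise ValueError(f"duplicate sample ids in merge: {all_samples}")
    merged = pd.concat(frames, axis=1)
    count_cols = [c for c in merged.columns if c[1] in COUNT_METRICS]
    merged[count_cols] = merged[count_cols].fillna(0).astype("int64")
    genes = [t.gene for t in tables if t.gene is not None]
    gene = None
    if genes:
        gene = pd.concat(genes)
        gene = gene[~gene.index.duplicated()]
    return BsjTable(merged, gene)


def annotate_genes(table: BsjTable, gene_model) -> BsjTable:
    """Annotate each BSJ with overlapping gene names.

    Overlap is by interval intersection of the BSJ span with the genomic
    extent of each gene on the same chromosome — a BSJ need not touch any
    exon boundary to be assigned.  Multiple overlapping genes are reported
    alphabetically, comma-separated; intergenic keys are ``unassigned``.
    """
    names = []
    for idx in table.df.index:
        key = BsjKey(*idx)
        hits = sorted(
            g.name
            for g in gene_model.genes.values()
            if g.chrom == key.chrom and g.start <= key.high and g.end >= key.low
        )
        names.append(",".join(hits) if hits else "unassigned")
    out = table.copy()
    out.gene = pd.Series(names, index=table.df.index, name="gene")
    return out


def normalize(
    table: BsjTable,
    method: str = "total_bsj",
    gene_count_totals: Mapping[str, int] | None = None,
) -> tuple[BsjTable, dict[str, bool]]:
    """Attach library-size normalised counts as the ``norm`` metric.

    ``total_bsj``: counts per million of the sample's summed BSJ counts.
    ``gene_counts``: counts per billion of the sample's total mapped gene
    counts (the spliced-reads-per-billion-mapped scale), which requires
    per-sample totals from the gene-count files.  Samples with a zero
    denominator get NaN and are flagged in the returned mapping.
    """
    out = table.copy()
    flagged: dict[str, bool] = {}
    for s in table.samples:
        raw = table.df[(s, "total")].astype(float)
        if method == "total_bsj":
            denom = raw.sum()
            scale = 1e6
        elif method == "gene_counts":
            if gene_count_totals is None or s not in gene_count_totals:
                raise ValueError(f"gene_counts normalisation needs totals for {s!r}")
            denom = float(gene_count_totals[s])
            scale = 1e9
        else:
            raise ValueError(f"unknown normalisation method {method!r}")
        if denom == 0:
            flagged[s] = True
            out.set_metric(s, "norm", pd.Series(np.nan, index=table.df.index))
        else:
            flagged[s] = False
            out.set_metric(s, "norm", raw / denom * scale)
    return out, flagged


def attach_scores(
    table: BsjTable,
    fsj_by_sample: Mapping[str, Sequence] | None = None,
    rad_threshold: int = 10,
    strand_aware: bool = False,
) -> BsjTable:
    """Compute and attach RAD (and optionally FSJ-support) per sample.

    RAD uses the type II/III tallies already in the table; ambiguous reads
    count toward the total but not toward the ratio.  ``fsj_by_sample``
    maps sample ids to ForwardJunction sequences; samples without an entry
    get no ``fsj`` column.
    """
    out = table.copy()
    keys = [BsjKey(*idx) for idx in table.df.index]
    for s in table.samples:
        t2 = table.df[(s, "type2")]
        t3 = table.df[(s, "type3")]
        rad = [
            qc_scores.rad_score(int(a), int(b), rad_threshold).value
            for a, b in zip(t2, t3)
        ]
        out.set_metric(
            s, "rad", pd.Series([np.nan if v is None else v for v in rad], index=table.df.index)
        )
        if fsj_by_sample is not None and s in fsj_by_sample:
            fsj_rows = list(fsj_by_sample[s])
            # index FSJ boundaries per chromosome for fast lookup
            scores = [
                float(qc_scores.fsj_support(k, fsj_rows, strand_aware).value)
                for k in keys
            ]
            out.set_metric(s, "fsj", pd.Series(scores, index=table.df.index))
    return out
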