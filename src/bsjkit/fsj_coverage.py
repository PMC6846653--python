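"""Forward-splice-junction coverage around a BSJ and biogenesis calls.

Canonical splicing around a circRNA discriminates two biogenesis models:
a circle spliced out of its parental transcript by exon skipping leaves
behind forward junctions that *span* the whole backsplice span, while a
circle produced alongside the linear transcript shows forward junctions
*internal* to the span (and the parental gene's other, *canonical*,
junctions elsewhere).  Junction read counts are binned into those three
disjoint categories; spanning support is normalised against the BSJ
count so the comparison is abundance-aware.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .formats import ForwardJunction

__all__ = [
    "FsjCoverage",
    "TRANSCRIPT_DERIVED",
    "TRANSCRIPT_BYPRODUCT",
    "INDETERMINATE",
    "annotate_fsj_coverage",
    "classify_biogenesis",
]

TRANSCRIPT_DERIVED = "transcript_derived"
TRANSCRIPT_BYPRODUCT = "transcript_byproduct"
INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class FsjCoverage:
    """FSJ read support around one BSJ, split into disjoint categories.

    ``internal_avg``: mean unique-read count over junctions with both
    intron ends strictly inside the BSJ span.  ``canonical_avg``: mean
    over the gene's remaining junctions (straddlers with one end inside
    are classed canonical).  ``spanning_count``: total unique reads on
    junctions whose intron encloses the whole span;
    ``spanning_normalized`` divides that by the BSJ count.
    """

    internal_avg: float
    canonical_avg: float
    spanning_count: int
    spanning_normalized: float
    n_internal: int = 0
    n_canonical: int = 0
    n_spanning: int = 0


def annotate_fsj_coverage(
    key,
    bsj_count: int,
    fsj: Iterable[ForwardJunction],
    gene_span: tuple[int, int] | None = None,
) -> FsjCoverage:
    """Bin a gene's forward junctions relative to a BSJ span.

    ``fsj`` should already be restricted to the parental gene's
    chromosome; ``gene_span`` optionally restricts further to junctions
    intersecting the gene extent.  Categories partition the junction set:
    *internal* (both intron ends strictly inside the span), *spanning*
    (intron encloses the span) and *canonical* (everything else,
    including straddlers).
    """
    lo, hi = key.low, key.high
    internal: list[int] = []
    canonical: list[int] = []
    spanning: list[int] = []
    for j in fsj:
        if j.chrom != key.chrom:
            continue
        if gene_span is not None and (j.intron_end < gene_span[0] or j.intron_start > gene_span[1]):
            continue
        if j.intron_start > lo and j.intron_end < hi:
            internal.append(j.unique_count)
        elif j.intron_start <= lo and j.intron_end >= hi:
            spanning.append(j.unique_count)
        else:
            canonical.append(j.unique_count)
    spanning_count = sum(spanning)
    if bsj_count > 0:
        spanning_normalized = spanning_count / bsj_count
    else:
        spanning_normalized = 0.0 if spanning_count == 0 else float("inf")
    return FsjCoverage(
        internal_avg=sum(internal) / len(internal) if internal else 0.0,
        canonical_avg=sum(canonical) / len(canonical) if canonical else 0.0,
        spanning_count=spanning_count,
        spanning_normalized=spanning_normalized,
        n_internal=len(internal),
        n_canonical=len(canonical),
        n_spanning=len(spanning),
    )


def classify_biogenesis(cov: FsjCoverage, spanning_threshold: float = 0.05) -> str:
    """Call the biogenesis mode from FSJ coverage.

    Spanning junctions at or above ``spanning_threshold`` (relative to the
    BSJ count) indicate exon skipping, i.e. a transcript by-product;
    internal forward splicing without spanning evidence indicates a
    transcript-derived circle; no junction evidence at all is
    indeterminate.
    """
    if cov.n_internal + cov.n_canonical + cov.n_spanning == 0:
        return INDETERMINATE
    if cov.spanning_normalized >= spanning_threshold and cov.spanning_count > 0:
        return TRANSCRIPT_BYPRODUCT
    if cov.n_internal > 0:
        return TRANSCRIPT_DERIVED
    return INDETERMINATE
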