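"""Longest-ORF detection on circular sequences and miRNA seed scanning.

A circular transcript has no end, so an open reading frame can run past
its own start codon ("rolling-circle" translation).  The scan concatenates
the sequence three times — enough for every frame to traverse the circle
at least once past any start in the first copy — and reports the longest
ATG-to-stop frame whose start lies in the first copy.  An ORF longer than
``floor(L/3)`` amino acids exceeds what a linear transcript of the same
length could encode (the "super-ORF" criterion); an ORF that exhausts all
three copies without a stop is flagged ``rolling`` and truncated there.

miRNA target sites are located by exact matching of the reverse
complement of the miRNA seed (positions 2-8 of the mature sequence by
default, length 6-8 nt) against the circular sequence; the search string
is extended by ``seed_len - 1`` bases so sites straddling the backsplice
junction are found.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Data import CodonTable

__all__ = [
    "OrfResult",
    "SeedHit",
    "longest_orf",
    "linear_orf_capacity",
    "scan_seeds",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrfResult:
    """Longest open reading frame found on a (possibly circular) sequence.

    ``start_offset`` is the 0-based position of the ATG on the circle;
    ``crosses_bsj`` flags ORFs extending past the backsplice junction;
    ``exceeds_linear`` flags ORFs longer than the linear coding capacity
    ``floor(L/3)``; ``rolling`` flags ORFs truncated because no stop codon
    appeared within three traversals.
    """

    start_offset: int | None
    length_aa: int
    peptide: str
    crosses_bsj: bool
    exceeds_linear: bool
    rolling: bool


@dataclass(frozen=True)
class SeedHit:
    mirna_id: str
    seed: str
    match_positions: tuple[int, ...]
    count: int


def linear_orf_capacity(length_nt: int) -> int:
    """Maximum amino acids a linear transcript of this length can encode."""
    return length_nt // 3


def _translate_codon(codon: str) -> str | None:
    """Amino acid for a codon; 'X' for N-containing, None past sequence end."""
    if len(codon) < 3:
        return None
    if codon in _STOPS:
        return "*"
    aa = _FORWARD.get(codon)
    return aa if aa is not None else "X"


def longest_orf(
    circ_seq: str, circular: bool = True, require_atg: bool = True
) -> OrfResult:
    """Find the longest ORF, with rolling-circle semantics when circular.

    The circular scan translates the tripled sequence in all three frames
    and reports the longest ATG-initiated ORF whose start codon lies in
    the first copy.  Codons containing ambiguity codes translate to ``X``
    and never act as start or stop.  With ``require_atg=False`` the
    longest stop-to-stop stretch is reported instead (start at the first
    codon after the previous stop).
    """
    s = circ_seq.upper().replace("U", "T")
    L = len(s)
    if L < 3:
        raise ValueError("sequence shorter than one codon")
    scan = s * 3 if circular else s
    limit = L if circular else max(L - 2, 0)

    best: tuple[int, int, str, bool] | None = None  # (length, start, peptide, rolling)

    starts: list[int] = []
    if require_atg:
        pos = scan.find("ATG")
        while pos != -1 and pos < limit:
            starts.append(pos)
            pos = scan.find("ATG", pos + 1)
    else:
        # stop-to-stop mode: candidate starts are frame starts and the
        # codon following each stop, restricted to the first copy
        for frame in range(3):
            prev_stop = frame
            for i in range(frame, len(scan) - 2, 3):
                if scan[i : i + 3] in _STOPS:
                    if prev_stop < limit:
                        starts.append(prev_stop)
                    prev_stop = i + 3
            if prev_stop < limit:
                starts.append(prev_stop)

    for start in starts:
        n_aa = 0
        peptide_chars: list[str] = []
        rolling = True
        for i in range(start, len(scan) - 2, 3):
            codon = scan[i : i + 3]
            if codon in _STOPS:
                rolling = False
                break
            peptide_chars.append(_translate_codon(codon))
            n_aa += 1
        if not circular:
            rolling = False
        if best is None or (n_aa, -start) > (best[0], -best[1]):
            best = (n_aa, start, "".join(peptide_chars), rolling)

    if best is None or best[0] == 0:
        return OrfResult(None, 0, "", False, False, False)
    n_aa, start, peptide, rolling = best
    crosses = circular and (start + 3 * n_aa) > L
    exceeds = circular and n_aa > linear_orf_capacity(L)
    return OrfResult(start, n_aa, peptide, crosses, exceeds, rolling)


def scan_seeds(
    circ_seq: str,
    seeds: Mapping[str, str],
    seed_start: int = 2,
    seed_len: int = 7,
    min_hits: int = 1,
) -> list[SeedHit]:
    """Scan a circular sequence for miRNA seed matches.

    ``seeds`` maps miRNA ids to *mature* miRNA sequences (RNA or DNA
    alphabet).  The seed is the ``seed_len``-nt window starting at 1-based
    position ``seed_start`` of the mature sequence; its reverse complement
    is matched (overlapping matches allowed) against the circularised
    sequence, including sites straddling the backsplice junction.  Only
    miRNAs with at least ``min_hits`` sites are reported.
    """
    if not 6 <= seed_len <= 8:
        raise ValueError("seed_len must be within [6, 8]")
    if seed_start < 1:
        raise ValueError("seed_start is 1-based")
    circ = circ_seq.upper().replace("U", "T")
    search = circ + circ[: seed_len - 1]
    hits: list[SeedHit] = []
    for mirna_id in sorted(seeds):
        mature = seeds[mirna_id].upper().replace("U", "T")
        if seed_start - 1 + seed_len > len(mature):
            raise ValueError(
                f"{mirna_id}: mature sequence too short for seed "
                f"{seed_start}..{seed_start + seed_len - 1}"
            )
        seed = mature[seed_start - 1 : seed_start - 1 + seed_len]
        target = _revcomp(seed)
        positions = []
        pos = search.find(target)
        while pos != -1:
            positions.append(pos)
            pos = search.find(target, pos + 1)
        if len(positions) >= min_hits:
            hits.append(SeedHit(mirna_id, seed, tuple(positions), len(positions)))
    return hits
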