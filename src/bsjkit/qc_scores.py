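"""Quality metrics that separate true from false circRNA without a gene model.

Two metrics are computed for every backsplice junction (BSJ):

* **RAD score** (read alignment distribution): the fraction of junction
  reads in which the BSJ falls in mate 1 (type II) rather than mate 2
  (type III), ``RAD = typeII / (typeII + typeIII)``.  Genuine circles are
  sampled from both mates and sit near 0.5; homology artefacts are
  systematically one-sided and sit near 0 or 1.  Below a count threshold
  (default 10) the ratio is too noisy to be meaningful and no score is
  assigned.
* **FSJ support score** (0, 1 or 2): whether the BSJ donor and acceptor
  coordinates are each also observed in canonical forward splicing.  This
  replaces gene-model filtering: splice sites evidenced in the data itself
  vouch for the junction.

Mate classification works directly from the chimeric CIGAR strings: the
mate-gap operator ``p`` splits each segment CIGAR into a mate-1 and a
mate-2 portion, and the longest contiguous match run locates the *intact*
mate — the one that does **not** contain the BSJ.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .formats import ChimericRecord, ForwardJunction

__all__ = [
    "TYPE_II",
    "TYPE_III",
    "AMBIGUOUS",
    "MateClassification",
    "RadScore",
    "FsjSupportScore",
    "classify_mate",
    "rad_score",
    "fsj_support",
    "apply_filters",
    "evaluate_classifier",
]

TYPE_II = "TYPE_II"
TYPE_III = "TYPE_III"
AMBIGUOUS = "AMBIGUOUS"

_CIGAR_OP = re.compile(r"([0-9]+)([MIDNSHp])")


@dataclass(frozen=True)
class MateClassification:
    """Which mate of a read pair contains the BSJ.

    ``TYPE_II`` means the BSJ was inferred to lie in mate 1, ``TYPE_III``
    in mate 2.  ``longest_match_mate`` is the mate holding the longest
    contiguous match run, i.e. the *intact* mate.
    """

    label: str
    longest_match_len: int
    longest_match_mate: int | None


@dataclass(frozen=True)
class RadScore:
    value: float | None
    typeII_count: int
    typeIII_count: int
    threshold_used: int


@dataclass(frozen=True)
class FsjSupportScore:
    value: int
    donor_supported: bool
    acceptor_supported: bool


def _split_cigar(cigar: str, where: str) -> list[tuple[int, str]]:
    ops = [(int(n), op) for n, op in _CIGAR_OP.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"invalid CIGAR {cigar!r} in record {where}")
    return ops


def _longest_m_run(ops: Sequence[tuple[int, str]]) -> int:
    best = run = 0
    for n, op in ops:
        if op == "M":
            run += n
            best = max(best, run)
        else:
            run = 0
    return best


def classify_mate(record: ChimericRecord) -> MateClassification:
    """Classify a chimeric record as type II or type III from its CIGARs.

    Each segment CIGAR containing the mate-gap operator ``p`` is split at
    ``p`` into a mate-1 portion (before) and a mate-2 portion (after).
    The longest contiguous M run across the attributed portions identifies
    the intact mate; the BSJ is assigned to the other mate.  Records with
    no ``p`` in either segment (single-end) and exact ties are AMBIGUOUS.
    """
    if record.junction_code < 0:
        raise ValueError(
            f"record {record.read_id} is pair-encompassing (junction_code -1); "
            "only within-read junctions can be mate-classified"
        )
    best = {1: 0, 2: 0}
    paired = False
    for cigar in (record.seg1_cigar, record.seg2_cigar):
        ops = _split_cigar(cigar, record.read_id)
        p_idx = [i for i, (_, op) in enumerate(ops) if op == "p"]
        if not p_idx:
            continue  # cannot attribute this segment's runs to a mate
        paired = True
        cut = p_idx[0]
        best[1] = max(best[1], _longest_m_run(ops[:cut]))
        best[2] = max(best[2], _longest_m_run(ops[cut + 1 :]))
    if not paired:
        longest = max(
            _longest_m_run(_split_cigar(record.seg1_cigar, record.read_id)),
            _longest_m_run(_split_cigar(record.seg2_cigar, record.read_id)),
        )
        return MateClassification(AMBIGUOUS, longest, None)
    if best[1] == best[2]:
        return MateClassification(AMBIGUOUS, best[1], None)
    intact = 1 if best[1] > best[2] else 2
    # the intact mate does NOT hold the BSJ: intact mate 1 -> BSJ in mate 2
    label = TYPE_III if intact == 1 else TYPE_II
    return MateClassification(label, best[intact], intact)


def rad_score(typeII: int, typeIII: int, threshold: int = 10) -> RadScore:
    """RAD = typeII / (typeII + typeIII), undefined below ``threshold`` reads."""
    if typeII < 0 or typeIII < 0:
        raise ValueError("counts must be non-negative")
    total = typeII + typeIII
    value = None if total < threshold else typeII / total
    return RadScore(value, typeII, typeIII, threshold)


def fsj_support(
    key,
    fsj: Iterable[ForwardJunction],
    strand_aware: bool = False,
) -> FsjSupportScore:
    """Count how many of a BSJ's splice sites are reused in forward splicing.

    The donor contributes 1 when its coordinate appears as a forward-intron
    boundary on the matching chromosome, likewise the acceptor; the score
    is their sum (0, 1 or 2).  With ``strand_aware`` the boundary role is
    fixed by strand (on '+' a donor matches an intron start, an acceptor an
    intron end; mirrored on '-'); by default, suitable for unstranded
    libraries, either boundary counts.
    """
    donor = acceptor = False
    for j in fsj:
        if j.chrom != key.chrom:
            continue
        if strand_aware and key.strand in "+-":
            if key.strand == "+":
                donor = donor or j.intron_start == key.donor_pos
                acceptor = acceptor or j.intron_end == key.acceptor_pos
            else:
                donor = donor or j.intron_end == key.donor_pos
                acceptor = acceptor or j.intron_start == key.acceptor_pos
        else:
            donor = donor or key.donor_pos in (j.intron_start, j.intron_end)
            acceptor = acceptor or key.acceptor_pos in (j.intron_start, j.intron_end)
        if donor and acceptor:
            break
    return FsjSupportScore(int(donor) + int(acceptor), donor, acceptor)


def apply_filters(
    table,
    rad_min: float = 0.1,
    rad_max: float = 0.9,
    fsj_min: int | None = 1,
    min_count: int | None = None,
    mode: str = "per_sample",
):
    """Filter a BSJ table on RAD, FSJ-support and count thresholds.

    A row passes the RAD filter when ``rad_min < RAD < rad_max``; rows with
    *undefined* RAD (below the reporting threshold) are never removed by
    the RAD filter itself — removing low-count junctions is ``min_count``'s
    job.  ``fsj_min`` removes rows whose FSJ support is below the floor
    (``None`` disables).  In ``per_sample`` mode a row is kept if it passes
    in at least one sample; in ``mean`` mode the RAD values are averaged
    across samples (where defined) before filtering.

    Returns ``(filtered_table, audit)`` where ``audit`` is a DataFrame of
    removed keys and the reasons tabulated per key.
    """
    if mode not in ("per_sample", "mean"):
        raise ValueError(f"unknown filter mode {mode!r}")
    df = table.df
    samples = table.samples
    keep = []
    audit_rows = []
    mean_rad = None
    if mode == "mean":
        rad_cols = [(s, "rad") for s in samples if (s, "rad") in df.columns]
        if rad_cols:
            mean_rad = df[rad_cols].mean(axis=1, skipna=True)
    for idx, row in df.iterrows():
        reasons: set[str] = set()
        passed_any = False
        for s in samples:
            reasons_s = set()
            total = row.get((s, "total"), 0)
            if min_count is not None and total < min_count:
                reasons_s.add("min_count")
            if mode == "mean":
                rad = None if mean_rad is None else mean_rad.loc[idx]
            else:
                rad = row.get((s, "rad"))
            if rad is not None and pd.notna(rad) and not (rad_min < rad < rad_max):
                reasons_s.add("rad")
            if fsj_min is not None and (s, "fsj") in df.columns:
                fsj_val = row.get((s, "fsj"))
                if pd.notna(fsj_val) and fsj_val < fsj_min:
                    reasons_s.add("fsj")
            if not reasons_s:
                passed_any = True
                break
            reasons |= reasons_s
        if passed_any:
            keep.append(idx)
        else:
            audit_rows.append({"key": idx, "reasons": ",".join(sorted(reasons))})
    filtered = table.subset(keep)
    audit = pd.DataFrame(audit_rows, columns=["key", "reasons"])
    return filtered, audit


def evaluate_classifier(
    truth: Sequence,
    predicted: Mapping[str, MateClassification] | Sequence[MateClassification],
) -> float:
    """Fraction of type II/III ground-truth records correctly labelled.

    ``truth`` is a sequence of simulator truth records (read_id +
    alignment_type); ``predicted`` maps read ids to classifications (or is
    a sequence aligned with ``truth``).  Truth records of other types are
    ignored.  Missing predictions raise.
    """
    if not isinstance(predicted, Mapping):
        if len(predicted) != len(truth):
            raise ValueError("truth and prediction lengths differ")
        predicted = {t.read_id: p for t, p in zip(truth, predicted)}
    expected_label = {"II": TYPE_II, "III": TYPE_III}
    n = correct = 0
    for t in truth:
        if t.alignment_type not in expected_label:
            continue
        if t.read_id not in predicted:
            raise KeyError(f"no prediction for read {t.read_id!r}")
        n += 1
        if predicted[t.read_id].label == expected_label[t.alignment_type]:
            correct += 1
    if n == 0:
        raise ValueError("no type II/III truth records to evaluate")
    return correct / n
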