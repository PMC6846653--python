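"""Closed-form model of alignment-type proportions for circular RNA.

A sequencing fragment of length ``F`` is drawn from a circle of size
``C``; paired reads of length ``R`` are taken from its two ends, and the
backsplice junction falls at a position uniform on the circle.  Relative
to the junction, a read pair is

* **type I** — the fragment does not contain the junction at all; its
  alignments are indistinguishable from linear RNA;
* **type II / III** — the junction falls inside read 1 / read 2, with at
  least ``m`` (minimum overhang) bases on each side, giving direct BSJ
  evidence;
* **type IV** — the fragment contains the junction but neither read
  captures it with sufficient overhang (the unsequenced gap between
  mates, plus the overhang slack at the fragment edges).

For ``C >= F`` this reduces to the continuous fractions ``p1 = (C-F)/C``,
``p2 = p3 = (R-2m)/C`` and ``p4 = (F-2R+4m)/C`` (gap clamped at 0 for
overlapping reads).  For circles smaller than a fragment the fragment
wraps, every fragment contains the junction (``p1 = 0``) and the read
regions are mapped onto the circle as interval unions; positions captured
by both reads are split evenly between types II and III, preserving the
II/III symmetry.  The continuous (length-fraction) approximation is used
throughout; the discrepancy against discrete base counting is O(1/C).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "LibraryGeometry",
    "TypeProportions",
    "type_proportions",
    "expected_type1_count",
    "proportions_curve",
]

Interval = tuple[float, float]


@dataclass(frozen=True)
class LibraryGeometry:
    """Circle size, fragment length, read length and minimum overhang (nt)."""

    circ_size: float
    fragment_len: float = 300.0
    read_len: float = 100.0
    min_overhang: float = 0.0

    def __post_init__(self):
        if min(self.circ_size, self.fragment_len, self.read_len) <= 0:
            raise ValueError(f"sizes must be positive: {self}")
        if self.read_len > self.fragment_len:
            raise ValueError("read length cannot exceed fragment length")
        if self.min_overhang < 0 or self.min_overhang >= self.read_len / 2:
            raise ValueError("min_overhang must satisfy 0 <= m < R/2")


@dataclass(frozen=True)
class TypeProportions:
    p1: float
    p2: float
    p3: float
    p4: float

    @property
    def total(self) -> float:
        return self.p1 + self.p2 + self.p3 + self.p4


# -- interval-union helpers (unions kept as sorted disjoint half-open tuples)


def _normalise(ivs: list[Interval]) -> list[Interval]:
    ivs = sorted((a, b) for a, b in ivs if b > a)
    out: list[Interval] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _measure(ivs: list[Interval]) -> float:
    return sum(b - a for a, b in ivs)


def _intersect(xs: list[Interval], ys: list[Interval]) -> list[Interval]:
    out = []
    for a, b in xs:
        for c, d in ys:
            lo, hi = max(a, c), min(b, d)
            if hi > lo:
                out.append((lo, hi))
    return _normalise(out)


def _circle_preimage(region: Interval, C: float, F: float) -> list[Interval]:
    """Positions x in [0, C) whose capture offsets x + kC hit ``region``."""
    a, b = region
    out: list[Interval] = []
    k = 0
    while k * C < F:
        lo, hi = a - k * C, b - k * C
        lo, hi = max(lo, 0.0), min(hi, C)
        if hi > lo:
            out.append((lo, hi))
        k += 1
    return _normalise(out)


def type_proportions(g: LibraryGeometry) -> TypeProportions:
    """Proportions of type I-IV read pairs for a given library geometry."""
    C, F, R, m = g.circ_size, g.fragment_len, g.read_len, g.min_overhang
    # read regions in fragment coordinates (offset of the junction from the
    # fragment start); detection needs >= m bases of overhang on each side
    region2: Interval = (m, R - m)
    region3: Interval = (F - R + m, F - m)
    u2 = _circle_preimage(region2, C, F)
    u3 = _circle_preimage(region3, C, F)
    covered = _circle_preimage((0.0, F), C, F)
    both = _intersect(u2, u3)
    p2 = (_measure(u2) - _measure(both) / 2.0) / C
    p3 = (_measure(u3) - _measure(both) / 2.0) / C
    p4 = (_measure(covered) - _measure(_normalise(u2 + u3))) / C
    p1 = 1.0 - _measure(covered) / C
    return TypeProportions(p1, p2, p3, p4)


def expected_type1_count(g: LibraryGeometry, bsj_count: float) -> float:
    """Expected number of type I alignments given an observed BSJ count.

    Observed BSJ evidence comes from types II and III, so the inferred
    linear-indistinguishable read load is ``bsj_count * p1 / (p2 + p3)``.
    """
    p = type_proportions(g)
    if p.p2 + p.p3 <= 0:
        raise ValueError("degenerate geometry: no type II/III alignments possible")
    return bsj_count * p.p1 / (p.p2 + p.p3)


def proportions_curve(
    sizes,
    fragment_len: float = 300.0,
    read_len: float = 100.0,
    min_overhang: float = 0.0,
    bsj_count: float | None = None,
) -> pd.DataFrame:
    """Tabulate the model over a grid of circle sizes (for plotting/export)."""
    rows = []
    for c in sizes:
        g = LibraryGeometry(c, fragment_len, read_len, min_overhang)
        p = type_proportions(g)
        row = {"circ_size": c, "p1": p.p1, "p2": p.p2, "p3": p.p3, "p4": p.p4}
        if bsj_count is not None and p.p2 + p.p3 > 0:
            row["expected_type1"] = expected_type1_count(g, bsj_count)
        rows.append(row)
    return pd.DataFrame(rows)
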