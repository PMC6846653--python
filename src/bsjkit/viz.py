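"""Junction arc ("loop") plot geometry and optional rendering.

Junction counts are drawn as arcs whose feet sit on the genomic
coordinates of the junction and whose height is proportional to the read
count, over a gene-model track of exon rectangles.  Arc geometry is
computed separately from any graphics backend so it is unit-testable
headlessly; rendering is a thin matplotlib layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .bsj_core import BsjKey, BsjTable
from .formats import ForwardJunction

__all__ = ["ArcSpec", "build_arcs", "render_arcs"]


@dataclass(frozen=True)
class ArcSpec:
    """One junction arc: feet at x1 < x2, height proportional to count."""

    x1: int
    x2: int
    height: float
    kind: str  # "FSJ" | "BSJ"
    label: str

    def __post_init__(self):
        if self.x1 >= self.x2:
            raise ValueError("arc requires x1 < x2")


def build_arcs(
    fsj: Iterable[ForwardJunction],
    bsj_table: BsjTable | None,
    region: tuple[str, int, int],
    scale: float = 1.0,
    sample: str | None = None,
) -> list[ArcSpec]:
    """Arc specs for every junction intersecting ``region``.

    FSJ arcs span the intron; BSJ arcs span donor to acceptor.  Heights
    are ``count * scale``; zero-count junctions are dropped.  Ordering is
    deterministic: BSJ before FSJ, then by coordinates.
    """
    chrom, start, end = region
    if end < start:
        raise ValueError("empty region")
    arcs: list[ArcSpec] = []
    for j in fsj:
        if j.chrom != chrom or j.intron_end < start or j.intron_start > end:
            continue
        if j.unique_count <= 0:
            continue
        arcs.append(
            ArcSpec(
                j.intron_start,
                j.intron_end,
                j.unique_count * scale,
                "FSJ",
                f"{chrom}:{j.intron_start}-{j.intron_end}",
            )
        )
    if bsj_table is not None and len(bsj_table):
        use_sample = sample or bsj_table.samples[0]
        for idx, row in bsj_table.df.iterrows():
            key = BsjKey(*idx)
            if key.chrom != chrom or key.high < start or key.low > end:
                continue
            count = int(row[(use_sample, "total")])
            if count <= 0:
                continue
            arcs.append(
                ArcSpec(key.low, key.high, count * scale, "BSJ", key.to_id())
            )
    return sorted(arcs, key=lambda a: (a.kind, a.x1, a.x2, a.label))


def render_arcs(
    arcs: Sequence[ArcSpec],
    path,
    gene_model=None,
    region: tuple[str, int, int] | None = None,
):
    """Render arcs (and optionally a gene-model exon track) to an image.

    BSJ arcs are drawn below the axis, FSJ arcs above, mirroring how back
    and forward splicing are usually displayed together.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(10, 4))
    theta = np.linspace(0.0, np.pi, 64)
    for arc in arcs:
        mid = (arc.x1 + arc.x2) / 2.0
        half = (arc.x2 - arc.x1) / 2.0
        sign = 1.0 if arc.kind == "FSJ" else -1.0
        ax.plot(
            mid + half * np.cos(theta),
            sign * arc.height * np.sin(theta),
            color="tab:blue" if arc.kind == "FSJ" else "tab:red",
            lw=1.2,
        )
    if gene_model is not None and region is not None:
        chrom, start, end = region
        for tr in gene_model.on_chrom(chrom):
            for s, e in tr.exons:
                if e < start or s > end:
                    continue
                ax.add_patch(
                    plt.Rectangle((s, -0.02), e - s + 1, 0.04, color="0.3", zorder=3)
                )
    ax.axhline(0, color="0.6", lw=0.8)
    ax.set_xlabel("genomic position")
    ax.set_ylabel("junction count (FSJ up / BSJ down)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
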