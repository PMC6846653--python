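"""Shared fixtures: a deterministic toy genome + gene model and helpers.

Everything is generated programmatically at test time; no data files ship
with the package.
"""

from __future__ import annotations

import pytest

from bsjkit import seq_assembly, simulate
from bsjkit.bsj_core import BsjKey


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("fixture")


@pytest.fixture(scope="session")
def genome_paths(fixture_dir):
    """Deterministic random genome (FASTA) + gene model (GTF)."""
    return simulate.make_fixture_genome(
        fixture_dir, seed=7, n_chroms=2, chrom_len=60_000, n_genes=6,
        exons_per_gene=6,
    )


@pytest.fixture(scope="session")
def fasta_path(genome_paths):
    return genome_paths[0]


@pytest.fixture(scope="session")
def gene_model(genome_paths):
    return seq_assembly.GeneModel.from_gtf(genome_paths[1])


@pytest.fixture(scope="session")
def boundary_keys(gene_model):
    """BSJs on internal exon blocks (one per gene): both splice sites are
    reused by flanking forward junctions, and the circles fit a fragment."""
    return [
        simulate.exon_bounded_key(gene_model.transcripts[tid], 1, 4)
        for tid in sorted(gene_model.transcripts)
    ]


@pytest.fixture
def toy_key():
    return BsjKey("chr1", 2000, 999, "+")
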