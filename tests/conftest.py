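import pytest

from polygenespace.io_formats import SequenceRecord
from polygenespace.simdata import (
    SimConfig,
    generate_gene_space,
    make_polyploid_catalogue,
    simulate_reads,
    transcripts_from_gene_space,
)


@pytest.fixture(scope="session")
def small_gene_space():
    """12 single-copy genes with repeats, shared across tests."""
    return generate_gene_space(12, repeat_fraction=0.3, seed=42)


@pytest.fixture(scope="session")
def small_catalogue(small_gene_space):
    """Triplicated catalogue + transcripts + gene models for 12 families."""
    chromosome, genes, _ = small_gene_space
    transcripts = transcripts_from_gene_space(chromosome, genes)
    cfg = SimConfig(seed=7)
    catalogue, truth = make_polyploid_catalogue(transcripts, cfg)
    return catalogue, truth, transcripts, genes


@pytest.fixture(scope="session")
def small_reads(small_catalogue):
    catalogue, _, _, _ = small_catalogue
    return simulate_reads(catalogue, SimConfig(seed=8))


@pytest.fixture(scope="session")
def ogr_proteins(small_catalogue):
    _, _, _, genes = small_catalogue
    return [SequenceRecord(g.family_id, g.protein) for g in genes]
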