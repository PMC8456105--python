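"""Shared fixtures: tiny hand-built genomes and a scaled-down benchmark."""

import pytest

from cuproscan import synthetic_data as sd
from cuproscan.genome_model import DomainHit, Gene, GenomeSet


def make_contig(n_genes: int, genome_id: str = "G1", contig: str = "c1",
                protein: str = "MKTAYIAKQR", strand: str = "+",
                gap: int = 80) -> GenomeSet:
    """A single contig of identical genes with regular spacing."""
    gs = GenomeSet()
    pos = 0
    for rank in range(n_genes):
        start = pos + gap
        end = start + 3 * len(protein) + 3
        pos = end
        gs.add_gene(Gene(
            gene_id=f"{genome_id}_{rank:03d}", genome_id=genome_id,
            contig_id=contig, start=start, end=end, strand=strand,
            rank=rank, protein=protein,
        ))
    gs.taxonomy[genome_id] = "alpha"
    gs.proteome_counts = {"alpha": 1}
    return gs


@pytest.fixture
def contig30() -> GenomeSet:
    return make_contig(30)


@pytest.fixture
def domain_genome() -> GenomeSet:
    """Four genes with assorted cupredoxin-domain annotations."""
    gs = make_contig(4, genome_id="GX")
    hits = [
        DomainHit("GX_000", "PF00394", 1e-30),
        DomainHit("GX_001", "PF00394", 1e-30),
        DomainHit("GX_001", "PF07731", 1e-25),
        DomainHit("GX_001", "PF07732", 1e-20),
        DomainHit("GX_002", "PF07732", 1e-30),
    ]
    for h in hits:
        gs.add_domain_hit(h)
    return gs


SMALL_SYNTH = sd.SynthConfig(
    n_genomes=8,
    genes_per_genome=250,
    n_cuto_anchors=5,
    n_cueo_anchors=1,
    n_ftsp_anchors=1,
    n_family=10,
    n_decoys_per_type=10,
    seed=7,
)


@pytest.fixture(scope="session")
def synth_small():
    """A small planted dataset shared across tests (seeded, deterministic)."""
    return sd.generate(SMALL_SYNTH)
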