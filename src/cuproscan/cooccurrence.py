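"""Genomic co-occurrence statistics for gene families.

The counting procedures behind the headline comparative-genomics fractions:
how often multicopper-oxidase cluster genes have a CutF-like neighbor in
their 10-gene window, how often their genomes encode a CutF-like protein at
all, how often both the CutF-like and CutG-like families co-occur, the
per-taxonomy-class rates normalized by proteome counts, and the fraction
of family neighborhoods containing an annotated (e.g. Cu-binding) gene.

Denominators are gene-level; all counting is deterministic, so on
generator output every fraction equals its planted count ratio exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_model import GenomeSet
from .neighborhood import extract_window


@dataclass
class ClassRate:
    count: int
    share_pct: float
    proteomes: int
    per_proteome: float


@dataclass
class CooccurrenceReport:
    neighbor_fraction: float
    neighbor_fraction_operon: float | None
    genome_fraction: float
    both_families_fraction: float
    family_gene_assoc_fraction: float
    neighborhood_annotation_fraction: float
    per_class: dict[str, ClassRate] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "neighbor_fraction": self.neighbor_fraction,
            "neighbor_fraction_operon": self.neighbor_fraction_operon,
            "genome_fraction": self.genome_fraction,
            "both_families_fraction": self.both_families_fraction,
            "family_gene_assoc_fraction": self.family_gene_assoc_fraction,
            "neighborhood_annotation_fraction":
                self.neighborhood_annotation_fraction,
            "per_class": {
                cls: vars(r) for cls, r in sorted(self.per_class.items())
            },
        }
        return d


def _window_contains(genomes: GenomeSet, gene_id: str, targets: set[str],
                     radius: int) -> bool:
    w = extract_window(genomes, gene_id, radius=radius)
    return any(m in targets for m in w.member_ids if m != gene_id)


def neighbor_fraction(cluster_genes, family_genes, genomes: GenomeSet,
                      radius: int = 10) -> float:
    """Fraction of cluster genes with >= 1 family gene in their window."""
    cluster = sorted(set(cluster_genes))
    if not cluster:
        return 0.0
    fam = set(family_genes)
    n = sum(
        1 for gid in cluster if _window_contains(genomes, gid, fam, radius)
    )
    return n / len(cluster)


def genome_cooccurrence(cluster_genes, family_genes, genomes: GenomeSet) -> float:
    """Fraction of cluster genes whose genome also hosts >= 1 family gene."""
    cluster = sorted(set(cluster_genes))
    if not cluster:
        return 0.0
    fam_genomes = {genomes.genes[g].genome_id for g in family_genes}
    n = sum(1 for gid in cluster if genomes.genes[gid].genome_id in fam_genomes)
    return n / len(cluster)


def multi_family_cooccurrence(cluster_genes, family_a, family_b,
                              genomes: GenomeSet) -> float:
    """Fraction of cluster genes whose genome hosts members of BOTH families."""
    cluster = sorted(set(cluster_genes))
    if not cluster:
        return 0.0
    ga = {genomes.genes[g].genome_id for g in family_a}
    gb = {genomes.genes[g].genome_id for g in family_b}
    both = ga & gb
    n = sum(1 for gid in cluster if genomes.genes[gid].genome_id in both)
    return n / len(cluster)


def family_gene_assoc_fraction(family_genes, target_genes, genomes: GenomeSet,
                               radius: int = 10) -> float:
    """Fraction of family genes with >= 1 target gene in their window.

    The reversed direction of ``neighbor_fraction``: per family gene, not
    per cluster gene.
    """
    fam = sorted(set(family_genes))
    if not fam:
        return 0.0
    targets = set(target_genes)
    n = sum(1 for gid in fam if _window_contains(genomes, gid, targets, radius))
    return n / len(fam)


def per_class_rates(family_genes, genomes: GenomeSet) -> dict[str, ClassRate]:
    """Per taxonomy class: raw count, share of total, count per proteome."""
    fam = sorted(set(family_genes))
    counts: dict[str, int] = {cls: 0 for cls in genomes.proteome_counts}
    for gid in fam:
        cls = genomes.taxonomy[genomes.genes[gid].genome_id]
        counts[cls] = counts.get(cls, 0) + 1
    total = sum(counts.values())
    out = {}
    for cls, count in sorted(counts.items()):
        proteomes = genomes.proteome_counts.get(cls, 0)
        out[cls] = ClassRate(
            count=count,
            share_pct=100.0 * count / total if total else 0.0,
            proteomes=proteomes,
            per_proteome=count / proteomes if proteomes else 0.0,
        )
    return out


def neighborhood_annotation_fraction(family_genes, annotation, genomes: GenomeSet,
                                     radius: int = 10) -> float:
    """Fraction of family-gene windows containing >= 1 annotated gene."""
    fam = sorted(set(family_genes))
    if not fam:
        return 0.0
    ann = set(annotation)
    n = sum(1 for gid in fam if _window_contains(genomes, gid, ann, radius))
    return n / len(fam)


def build_report(
    cluster_genes,
    family_genes,
    second_family_genes,
    annotation,
    genomes: GenomeSet,
    radius: int = 10,
    operon_neighbor_fn=None,
) -> CooccurrenceReport:
    """Assemble the full co-occurrence report for one oxidase cluster."""
    return CooccurrenceReport(
        neighbor_fraction=neighbor_fraction(
            cluster_genes, family_genes, genomes, radius),
        neighbor_fraction_operon=(
            operon_neighbor_fn(cluster_genes, family_genes)
            if operon_neighbor_fn else None
        ),
        genome_fraction=genome_cooccurrence(cluster_genes, family_genes, genomes),
        both_families_fraction=multi_family_cooccurrence(
            cluster_genes, family_genes, second_family_genes, genomes),
        family_gene_assoc_fraction=family_gene_assoc_fraction(
            family_genes, cluster_genes, genomes, radius),
        neighborhood_annotation_fraction=neighborhood_annotation_fraction(
            family_genes, annotation, genomes, radius),
        per_class=per_class_rates(family_genes, genomes),
    )
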