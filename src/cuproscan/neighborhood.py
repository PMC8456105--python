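"""Anchor-gene detection and gene-window / operon-context extraction.

Anchors are genes whose domain content marks them as multicopper-oxidase
homologs (any of a set of cupredoxin accessions).  The genomic context of
an anchor is the positional window of up to ``radius`` genes on each side
along the contig (strand-agnostic); the operon context is the contiguous
same-strand, small-gap subset of that window.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_model import Gene, GenomeSet


class ConfigurationError(ValueError):
    pass


class LookupError_(KeyError):
    pass


@dataclass(frozen=True)
class Window:
    """Positional gene window around an anchor (anchor included)."""

    anchor_id: str
    member_ids: tuple[str, ...]
    radius: int


@dataclass(frozen=True)
class OperonContext:
    """Contiguous same-strand, small-gap subset of a window, incl. anchor."""

    anchor_id: str
    operon_member_ids: tuple[str, ...]


def find_anchors(
    genomes: GenomeSet, required_any: set[str], evalue_max: float = 1e-5
) -> list[str]:
    """Gene ids with at least one hit in ``required_any`` at E <= evalue_max.

    This is the anchor rule for neighborhood mining: a multicopper-oxidase
    homolog carries either of the first two cupredoxin domains (or both).
    """
    if not required_any:
        raise ConfigurationError("required_any must name at least one domain")
    found = set()
    for hit in genomes.domain_hits:
        if hit.domain_acc in required_any and hit.evalue <= evalue_max:
            found.add(hit.gene_id)
    return sorted(found)


def find_cu_oxidases(
    genomes: GenomeSet, required_all: set[str], evalue_max: float = 1e-5
) -> list[str]:
    """Gene ids carrying ALL listed domains (the full Cu-oxidase set)."""
    if not required_all:
        raise ConfigurationError("required_all must name at least one domain")
    per_gene: dict[str, set[str]] = {}
    for hit in genomes.domain_hits:
        if hit.domain_acc in required_all and hit.evalue <= evalue_max:
            per_gene.setdefault(hit.gene_id, set()).add(hit.domain_acc)
    return sorted(g for g, accs in per_gene.items() if accs == set(required_all))


def extract_window(genomes: GenomeSet, anchor_id: str, radius: int = 10) -> Window:
    """Up to ``radius`` genes on each side of the anchor by rank.

    Truncated at contig ends; never crosses contig boundaries.
    """
    if anchor_id not in genomes.genes:
        raise LookupError_(f"unknown anchor {anchor_id}")
    anchor = genomes.genes[anchor_id]
    contig = genomes.contig_genes(anchor.genome_id, anchor.contig_id)
    lo = max(0, anchor.rank - radius)
    hi = min(len(contig), anchor.rank + radius + 1)
    return Window(
        anchor_id=anchor_id,
        member_ids=tuple(g.gene_id for g in contig[lo:hi]),
        radius=radius,
    )


def _gap_bp(a: Gene, b: Gene) -> int:
    """Intergenic distance between rank-adjacent genes (may be negative)."""
    first, second = (a, b) if a.start <= b.start else (b, a)
    return second.start - first.end


def infer_operon(
    window: Window,
    genomes: GenomeSet,
    max_gap_bp: int = 150,
    require_same_strand: bool = True,
) -> OperonContext:
    """Maximal run of window genes contiguous with the anchor that satisfy
    the strand/gap rule between consecutive genes.

    Standard prokaryotic operon heuristic: consecutive genes on the same
    strand (optional) separated by at most ``max_gap_bp``.
    """
    genes = [genomes.genes[gid] for gid in window.member_ids]
    anchor_pos = next(
        i for i, g in enumerate(genes) if g.gene_id == window.anchor_id
    )

    def compatible(a: Gene, b: Gene) -> bool:
        if require_same_strand and a.strand != b.strand:
            return False
        return _gap_bp(a, b) <= max_gap_bp

    lo = anchor_pos
    while lo > 0 and compatible(genes[lo - 1], genes[lo]):
        lo -= 1
    hi = anchor_pos
    while hi < len(genes) - 1 and compatible(genes[hi], genes[hi + 1]):
        hi += 1
    return OperonContext(
        anchor_id=window.anchor_id,
        operon_member_ids=tuple(g.gene_id for g in genes[lo : hi + 1]),
    )


def window_report_rows(
    window: Window, operon: OperonContext, genomes: GenomeSet
) -> list[dict]:
    """Rows for the window/operon report TSV (anchor, member, offset, flag)."""
    anchor_rank = genomes.genes[window.anchor_id].rank
    in_operon = set(operon.operon_member_ids)
    return [
        {
            "anchor_id": window.anchor_id,
            "member_id": gid,
            "offset": genomes.genes[gid].rank - anchor_rank,
            "in_operon": gid in in_operon,
        }
        for gid in window.member_ids
    ]
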