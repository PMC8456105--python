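"""Data model and I/O for multi-genome gene tables and domain annotations.

Genomes are represented as flat collections of coding genes with contig
coordinates, strand, rank along the contig, and the encoded protein
sequence.  Domain annotations (Pfam-style accessions with E-values) are an
external input consumed here, never computed: the workflow treats "matches
a known Pfam domain" as evidence delivered by an upstream hmmscan-like
step, so the package stays free of bundled domain databases.

Coordinates are stored 0-based half-open internally.  All file formats
(gene-table TSV, GFF3) are 1-based inclusive and converted at the boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

AA20 = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AA20 + "X")

GENE_TABLE_COLUMNS = [
    "genome_id",
    "contig",
    "start",
    "end",
    "strand",
    "locus_tag",
    "protein",
    "class",
]


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


class RecordError(ValueError):
    """A single record violates an invariant (reported with its line)."""


@dataclass(frozen=True)
class Gene:
    """A coding gene: coordinates, strand, rank, and its protein product."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    rank: int
    protein: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise RecordError(
                f"gene {self.gene_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise RecordError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.protein:
            raise RecordError(f"gene {self.gene_id}: empty protein")
        bad = set(self.protein) - VALID_RESIDUES
        if bad:
            raise RecordError(
                f"gene {self.gene_id}: non-amino-acid characters {sorted(bad)}"
            )

    @property
    def length_aa(self) -> int:
        return len(self.protein)


@dataclass(frozen=True)
class DomainHit:
    """A Pfam-style domain annotation on a gene."""

    gene_id: str
    domain_acc: str
    evalue: float

    def __post_init__(self) -> None:
        if not self.domain_acc:
            raise RecordError(f"domain hit on {self.gene_id}: empty accession")
        if self.evalue < 0:
            raise RecordError(
                f"domain hit {self.domain_acc} on {self.gene_id}: "
                f"negative E-value {self.evalue}"
            )


@dataclass
class GenomeSet:
    """Genes, domain hits and taxonomy for a collection of genomes."""

    genes: dict[str, Gene] = field(default_factory=dict)
    domain_hits: list[DomainHit] = field(default_factory=list)
    taxonomy: dict[str, str] = field(default_factory=dict)
    proteome_counts: dict[str, int] = field(default_factory=dict)

    # Lazy per-contig index, invalidated on add_gene.
    _contig_index: dict[tuple[str, str], list[Gene]] | None = None
    _hits_index: dict[str, list[DomainHit]] | None = None

    def add_gene(self, gene: Gene) -> None:
        if gene.gene_id in self.genes:
            raise RecordError(f"duplicate gene_id {gene.gene_id}")
        self.genes[gene.gene_id] = gene
        self._contig_index = None

    def add_domain_hit(self, hit: DomainHit, strict: bool = True) -> bool:
        """Attach a hit; unknown gene_id either raises or is skipped."""
        if hit.gene_id not in self.genes:
            if strict:
                raise RecordError(f"domain hit for unknown gene {hit.gene_id}")
            return False
        self.domain_hits.append(hit)
        self._hits_index = None
        return True

    def contig_genes(self, genome_id: str, contig_id: str) -> list[Gene]:
        """Genes on one contig, ordered by rank."""
        if self._contig_index is None:
            idx: dict[tuple[str, str], list[Gene]] = {}
            for g in self.genes.values():
                idx.setdefault((g.genome_id, g.contig_id), []).append(g)
            for genes in idx.values():
                genes.sort(key=lambda g: g.rank)
            self._contig_index = idx
        return self._contig_index.get((genome_id, contig_id), [])

    def hits_for(self, gene_id: str) -> list[DomainHit]:
        if self._hits_index is None:
            idx: dict[str, list[DomainHit]] = {}
            for h in self.domain_hits:
                idx.setdefault(h.gene_id, []).append(h)
            self._hits_index = idx
        return self._hits_index.get(gene_id, [])

    def contigs(self) -> list[tuple[str, str]]:
        return sorted({(g.genome_id, g.contig_id) for g in self.genes.values()})

    def validate(self) -> None:
        for h in self.domain_hits:
            if h.gene_id not in self.genes:
                raise RecordError(f"domain hit for unknown gene {h.gene_id}")
        missing = {g.genome_id for g in self.genes.values()} - set(self.taxonomy)
        if missing:
            raise RecordError(f"taxonomy missing for genomes {sorted(missing)}")
        for key in self.contigs():
            ranks = [g.rank for g in self.contig_genes(*key)]
            if ranks != list(range(len(ranks))):
                raise RecordError(f"ranks on contig {key} not consecutive: {ranks}")


def _assign_ranks(rows: list[dict]) -> None:
    """Set 'rank' in-place: 0-based order of start coordinate per contig."""
    by_contig: dict[tuple[str, str], list[dict]] = {}
    for r in rows:
        by_contig.setdefault((r["genome_id"], r["contig"]), []).append(r)
    for group in by_contig.values():
        group.sort(key=lambda r: (r["start"], r["end"], r["locus_tag"]))
        for i, r in enumerate(group):
            r["rank"] = i


def read_gene_table(path) -> GenomeSet:
    """Read a gene-table TSV (1-based inclusive coordinates) into a GenomeSet.

    Required columns: genome_id, contig, start, end, strand, locus_tag,
    protein, class.  Ranks are assigned by sorted start per contig.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in GENE_TABLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"gene table {path}: missing column {col!r}")
    rows = []
    # note: itertuples would mangle the "class" column (Python keyword)
    for lineno, rec in enumerate(df.to_dict(orient="records"), start=2):
        try:
            start, end = int(rec["start"]), int(rec["end"])
        except ValueError as exc:
            raise RecordError(f"line {lineno}: non-integer coordinate") from exc
        if start >= end:
            raise RecordError(
                f"line {lineno}: start {start} >= end {end} (1-based inclusive)"
            )
        rows.append(
            {
                "genome_id": rec["genome_id"],
                "contig": rec["contig"],
                "start": start - 1,  # to 0-based half-open
                "end": end,
                "strand": rec["strand"],
                "locus_tag": rec["locus_tag"],
                "protein": rec["protein"].upper(),
                "class": rec["class"],
                "lineno": lineno,
            }
        )
    _assign_ranks(rows)
    gs = GenomeSet()
    for r in rows:
        try:
            gs.add_gene(
                Gene(
                    gene_id=r["locus_tag"],
                    genome_id=r["genome_id"],
                    contig_id=r["contig"],
                    start=r["start"],
                    end=r["end"],
                    strand=r["strand"],
                    rank=r["rank"],
                    protein=r["protein"],
                )
            )
        except RecordError as exc:
            raise RecordError(f"line {r['lineno']}: {exc}") from exc
        gs.taxonomy[r["genome_id"]] = r["class"]
    counts: dict[str, int] = {}
    for genome_id, cls in gs.taxonomy.items():
        counts[cls] = counts.get(cls, 0) + 1
    gs.proteome_counts = counts
    return gs


def write_gene_table(gs: GenomeSet, path) -> None:
    """Write a GenomeSet as a gene-table TSV (1-based inclusive)."""
    recs = []
    for key in gs.contigs():
        for g in gs.contig_genes(*key):
            recs.append(
                {
                    "genome_id": g.genome_id,
                    "contig": g.contig_id,
                    "start": g.start + 1,
                    "end": g.end,
                    "strand": g.strand,
                    "locus_tag": g.gene_id,
                    "protein": g.protein,
                    "class": gs.taxonomy.get(g.genome_id, ""),
                }
            )
    pd.DataFrame(recs, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


@dataclass
class LoadReport:
    n_genes: int = 0
    n_skipped: int = 0
    skipped_ids: list[str] = field(default_factory=list)


def read_gff3_fasta(
    gff_path,
    protein_fasta_path,
    genome_id: str = "genome1",
    taxonomy_class: str = "unknown",
) -> tuple[GenomeSet, LoadReport]:
    """Read CDS features from GFF3 plus their proteins from FASTA.

    CDS features are matched to FASTA records by ID, then locus_tag.  A CDS
    without a protein partner is skipped and counted in the LoadReport.
    """
    import gffutils

    proteins = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(protein_fasta_path), "fasta")
    }
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows = []
    report = LoadReport()
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        key = None
        for attr in ("ID", "locus_tag"):
            for val in feat.attributes.get(attr, []):
                if val in proteins:
                    key = val
                    break
            if key:
                break
        if key is None:
            report.n_skipped += 1
            report.skipped_ids.append(feat.attributes.get("ID", ["?"])[0])
            continue
        rows.append(
            {
                "genome_id": genome_id,
                "contig": feat.seqid,
                "start": feat.start - 1,  # gffutils keeps 1-based inclusive
                "end": feat.end,
                "strand": feat.strand,
                "locus_tag": key,
                "protein": proteins[key],
            }
        )
    _assign_ranks(rows)
    gs = GenomeSet()
    for r in rows:
        gs.add_gene(
            Gene(
                gene_id=r["locus_tag"],
                genome_id=r["genome_id"],
                contig_id=r["contig"],
                start=r["start"],
                end=r["end"],
                strand=r["strand"],
                rank=r["rank"],
                protein=r["protein"],
            )
        )
    if rows:
        gs.taxonomy[genome_id] = taxonomy_class
        gs.proteome_counts = {taxonomy_class: 1}
    report.n_genes = len(rows)
    return gs, report


def read_domain_table(path, genome_set: GenomeSet | None = None, strict: bool = True
                      ) -> list[DomainHit]:
    """Read a domain-annotation TSV (gene_id, domain_acc, evalue).

    With a GenomeSet given, hits are validated against known gene_ids:
    unknown ids raise (strict) or are skipped with a warning (non-strict).
    Duplicate rows are kept — multi-domain proteins are expected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene_id", "domain_acc", "evalue"):
        if col not in df.columns:
            raise FormatError(f"domain table {path}: missing column {col!r}")
    hits: list[DomainHit] = []
    for lineno, rec in enumerate(df.itertuples(index=False), start=2):
        try:
            hit = DomainHit(rec.gene_id, rec.domain_acc, float(rec.evalue))
        except (ValueError, RecordError) as exc:
            raise RecordError(f"line {lineno}: {exc}") from exc
        if genome_set is not None:
            if genome_set.add_domain_hit(hit, strict=strict):
                pass
            else:
                import warnings

                warnings.warn(f"line {lineno}: unknown gene {hit.gene_id}, skipped")
                continue
        hits.append(hit)
    return hits


def write_domain_table(hits: list[DomainHit], path) -> None:
    pd.DataFrame(
        [{"gene_id": h.gene_id, "domain_acc": h.domain_acc, "evalue": h.evalue}
         for h in hits],
        columns=["gene_id", "domain_acc", "evalue"],
    ).to_csv(path, sep="\t", index=False)


def write_protein_fasta(gs: GenomeSet, path, gene_ids=None) -> None:
    """Write protein sequences (all genes, or a subset) as FASTA."""
    ids = sorted(gs.genes) if gene_ids is None else list(gene_ids)
    buf = io.StringIO()
    for gid in ids:
        buf.write(f">{gid}\n{gs.genes[gid].protein}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
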