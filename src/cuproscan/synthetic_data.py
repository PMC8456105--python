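"""Synthetic multi-genome benchmark with planted ground truth.

The generator emulates the statistical structure the discovery workflow
assumes: multiple bacterial genomes (one contig each) carrying planted
multicopper-oxidase anchor genes (three cupredoxin-domain annotations), a
planted CutF-like family derived from a common seed protein (signal
peptide, central CXXXC-type motif, C-terminal PP tail) at a configurable
divergence, a CutG-like second family, annotated Cu-binding neighbor
genes, and four decoy types.  Planted neighbor/genome co-occurrence rates
are realized by exact counts (round(p*n)), not Bernoulli draws, so the
co-occurrence statistics of a run equal the planted ratios exactly.

Every quantity is derived deterministically from ``SynthConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .candidate_rules import MotifSpec, apply_rules
from .genome_model import DomainHit, Gene, GenomeSet

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_NO_C = AA20.replace("C", "")

SIGNAL_BLOCK = "MKKLLLALLALLAVSAQA"  # tripartite Sec signal, cleavage at 18
PP_TAIL = "PEPEGPPPRL"  # proline-rich C-terminus with the PP motif

ANCHOR_DOMAINS = ("PF00394", "PF07731", "PF07732")
DECOY_DOMAIN = "PF99999"
BACKGROUND_DOMAINS = tuple(f"PF1{i:04d}" for i in range(20))


def _round_count(p: float, n: int) -> int:
    """Exact-count realization of a planted rate (round half up)."""
    return int(np.floor(p * n + 0.5))


@dataclass
class SynthConfig:
    """Study conditions for the synthetic benchmark."""

    n_genomes: int = 30
    genes_per_genome: int = 300
    class_distribution: dict[str, float] = field(
        default_factory=lambda: {
            "alpha": 0.5, "beta": 1 / 6, "gamma": 7 / 30, "delta": 0.1,
        }
    )
    # anchor clusters (distinct genomes each; rest of genomes anchor-free)
    n_cuto_anchors: int = 20
    n_cueo_anchors: int = 3
    n_ftsp_anchors: int = 2
    frac_three_domains: float = 1.0
    anchor_len: int = 450
    anchor_divergence: float = 0.15
    # CutF-like family
    n_family: int = 40
    family_len: int = 118
    motif_offset: int = 68  # 0-based start of the CXXHC motif (residue 69)
    divergence: float = 0.30
    # planted co-occurrence rates (exact-count realization)
    p_neighbor: float = 0.40
    p_genome: float = 0.71
    p_both: float = 0.55
    p_cueo_genome: float = 0.08
    p_ftsp_genome: float = 0.02
    p_annotation: float = 0.88
    # CutG-like family
    cutg_len: int = 130
    cutg_divergence: float = 0.20
    # decoys
    n_decoys_per_type: int = 100
    # background genes
    background_len_range: tuple[int, int] = (60, 350)
    p_background_domain: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_neighbor", "p_genome", "p_both", "p_cueo_genome",
                     "p_ftsp_genome", "p_annotation", "frac_three_domains"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 25 < self.family_len < 170:
            raise ValueError("family_len must lie in (25, 170)")
        n_anchor_genomes = (
            self.n_cuto_anchors + self.n_cueo_anchors + self.n_ftsp_anchors
        )
        if n_anchor_genomes > self.n_genomes:
            raise ValueError("more anchors than genomes")
        if self.genes_per_genome < 250:
            raise ValueError(
                "genes_per_genome < 250 cannot hold the planted layout "
                "(anchor window would overflow the contig)"
            )


@dataclass
class SyntheticTruth:
    """Planted structure of one generated dataset."""

    family_member_ids: set[str]
    cuto_anchor_ids: list[str]
    cueo_anchor_ids: list[str]
    ftsp_anchor_ids: list[str]
    ssn_anchor_ids: list[str]  # anchors carrying all three domains
    cutg_ids: list[str]
    neighbor_pairs: list[tuple[str, str]]  # (anchor_id, family_id)
    hosting_genomes: set[str]  # genomes with >= 1 family gene
    both_genomes: set[str]  # genomes with both families
    annotation_ids: set[str]  # planted Cu-binding neighbor genes
    annotated_family_ids: set[str]
    decoys: dict[str, list[str]]  # decoy type -> gene ids
    seed_protein: str
    counts: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        d = asdict(self)
        for k in ("family_member_ids", "hosting_genomes", "both_genomes",
                  "annotation_ids", "annotated_family_ids"):
            d[k] = sorted(d[k])
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=list)


def random_protein(rng: np.random.Generator, length: int,
                   alphabet: str = AA20) -> str:
    letters = np.array(list(alphabet))
    return "".join(rng.choice(letters, size=length))


def random_signal_block(rng: np.random.Generator) -> str:
    """A random 18-residue tripartite Sec signal (cleavage after 18).

    Same architecture as the family's block — positively charged n-region,
    hydrophobic h-region, A-X-A c-region — but independent residues, the
    way unrelated secreted proteins share signal structure without sharing
    signal sequence.
    """
    n_region = "".join(rng.choice(list("KR"), size=2))
    h_region = "".join(rng.choice(list("LAVIF"), size=10))
    c_late = rng.choice(list("DENQH"))
    return "M" + n_region + h_region + "VSA" + c_late + "A"


def mutate_member(seed_protein: str, divergence: float,
                  protected_positions: set[int],
                  rng: np.random.Generator) -> str:
    """Per-site substitution at rate ``divergence``, never at protected sites.

    Substitutions are uniform over the 19 alternative residues.
    """
    out = list(seed_protein)
    for i, res in enumerate(out):
        if i in protected_positions:
            continue
        if rng.random() < divergence:
            alternatives = AA20.replace(res, "") if res in AA20 else AA20
            out[i] = alternatives[rng.integers(len(alternatives))]
    mutant = "".join(out)
    assert all(mutant[i] == seed_protein[i] for i in protected_positions)
    return mutant


def make_family_seed(rng: np.random.Generator, cfg: SynthConfig) -> str:
    """Seed protein: signal block + random core with CXXHC motif + PP tail."""
    core_len = cfg.family_len - len(SIGNAL_BLOCK) - len(PP_TAIL)
    core = list(random_protein(rng, core_len, AA_NO_C))
    motif_core_start = cfg.motif_offset - len(SIGNAL_BLOCK)
    if not 0 <= motif_core_start <= core_len - 5:
        raise ValueError("motif_offset outside the mutable core")
    motif = "C" + "".join(rng.choice(list(AA_NO_C), size=2)) + "HC"
    core[motif_core_start : motif_core_start + 5] = motif
    return SIGNAL_BLOCK + "".join(core) + PP_TAIL


def family_protected_positions(cfg: SynthConfig) -> set[int]:
    """Signal block, motif cysteines/histidine, and PP tail are invariant."""
    protected = set(range(len(SIGNAL_BLOCK)))
    protected |= set(range(cfg.motif_offset, cfg.motif_offset + 5))
    protected |= set(range(cfg.family_len - len(PP_TAIL), cfg.family_len))
    return protected


def _largest_remainder(probs: dict[str, float], n: int) -> dict[str, int]:
    items = sorted(probs.items())
    raw = {k: v * n for k, v in items}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k, _ in sorted(raw.items(), key=lambda kv: -(kv[1] - np.floor(kv[1])))[:short]:
        counts[k] += 1
    return counts


class _GenomeLayout:
    """Rank bookkeeping for one genome while planting genes."""

    def __init__(self, genome_id: str, n_genes: int):
        self.genome_id = genome_id
        self.n_genes = n_genes
        self.proteins: dict[int, str] = {}
        self.strands: dict[int, str] = {}
        self.tight_gap: set[int] = set()  # rank has a small gap to predecessor
        self.special: set[int] = set()

    def place(self, rank: int, protein: str, strand: str = "+",
              tight: bool = False) -> None:
        if rank in self.special:
            raise ValueError(f"rank {rank} already used in {self.genome_id}")
        if not 0 <= rank < self.n_genes:
            raise ValueError(f"rank {rank} outside genome {self.genome_id}")
        self.special.add(rank)
        self.proteins[rank] = protein
        self.strands[rank] = strand
        if tight:
            self.tight_gap.add(rank)


def generate(cfg: SynthConfig) -> tuple[GenomeSet, SyntheticTruth]:
    """Generate the benchmark dataset and its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    gpg = cfg.genes_per_genome
    anchor_rank = gpg // 2
    radius_guard = 12  # family-elsewhere and decoys stay this far from anchors

    genome_ids = [f"G{i:02d}" for i in range(cfg.n_genomes)]
    class_counts = _largest_remainder(cfg.class_distribution, cfg.n_genomes)
    classes = []
    for cls in sorted(class_counts):
        classes.extend([cls] * class_counts[cls])
    rng.shuffle(classes)
    taxonomy = dict(zip(genome_ids, classes))

    layouts = {gid: _GenomeLayout(gid, gpg) for gid in genome_ids}
    domain_hits: list[tuple[str, str, float]] = []  # (gene_key, acc, evalue)

    def gene_id(gid: str, rank: int) -> str:
        return f"{gid}_{rank:04d}"

    # --- anchors -----------------------------------------------------------
    cuto_genomes = genome_ids[: cfg.n_cuto_anchors]
    cueo_genomes = genome_ids[cfg.n_cuto_anchors :
                              cfg.n_cuto_anchors + cfg.n_cueo_anchors]
    ftsp_genomes = genome_ids[
        cfg.n_cuto_anchors + cfg.n_cueo_anchors :
        cfg.n_cuto_anchors + cfg.n_cueo_anchors + cfg.n_ftsp_anchors
    ]
    free_genomes = genome_ids[
        cfg.n_cuto_anchors + cfg.n_cueo_anchors + cfg.n_ftsp_anchors :
    ]

    seeds = {
        "cuto": random_protein(rng, cfg.anchor_len),
        "cueo": random_protein(rng, cfg.anchor_len),
        "ftsp": random_protein(rng, cfg.anchor_len),
    }
    anchor_ids = {"cuto": [], "cueo": [], "ftsp": []}
    ssn_anchor_ids: list[str] = []
    all_anchor_lists = [
        ("cuto", cuto_genomes), ("cueo", cueo_genomes), ("ftsp", ftsp_genomes)
    ]
    n_anchors_total = sum(len(g) for _c, g in all_anchor_lists)
    n_three = _round_count(cfg.frac_three_domains, n_anchors_total)
    anchor_counter = 0
    for cluster, genomes_of in all_anchor_lists:
        for gid in genomes_of:
            prot = mutate_member(
                seeds[cluster], cfg.anchor_divergence, set(), rng
            )
            layouts[gid].place(anchor_rank, prot, strand="+")
            aid = gene_id(gid, anchor_rank)
            anchor_ids[cluster].append(aid)
            domain_hits.append((aid, "PF00394", 1e-50))
            domain_hits.append((aid, "PF07731", 1e-45))
            if anchor_counter < n_three:
                domain_hits.append((aid, "PF07732", 1e-40))
                ssn_anchor_ids.append(aid)
            anchor_counter += 1

    # --- CutF-like family --------------------------------------------------
    family_seed = make_family_seed(rng, cfg)
    protected = family_protected_positions(cfg)

    n_neighbor = _round_count(cfg.p_neighbor, cfg.n_cuto_anchors)
    n_host = _round_count(cfg.p_genome, cfg.n_cuto_anchors)
    n_cueo_host = _round_count(cfg.p_cueo_genome, cfg.n_cueo_anchors)
    n_ftsp_host = _round_count(cfg.p_ftsp_genome, cfg.n_ftsp_anchors)
    if n_neighbor > n_host:
        raise ValueError("p_neighbor may not exceed p_genome")
    base_hosts = (
        cuto_genomes[:n_host] + cueo_genomes[:n_cueo_host]
        + ftsp_genomes[:n_ftsp_host]
    )
    if cfg.n_family < len(base_hosts):
        raise ValueError("n_family too small for the planted host genomes")

    family_slots: list[tuple[str, int, bool]] = []  # (genome, rank, neighbor?)
    for k, gid in enumerate(base_hosts):
        if k < n_neighbor:
            family_slots.append((gid, anchor_rank + 1, True))
        else:
            family_slots.append((gid, 20, False))
    # extra members round-robin over hosting + anchor-free genomes, away
    # from every anchor window; spacing > window diameter keeps each family
    # window free of another member's planted annotation gene
    extra = cfg.n_family - len(base_hosts)
    spread = list(base_hosts) + list(free_genomes)
    rank_cursor: dict[str, int] = {g: 45 for g in spread}
    for k in range(extra):
        gid = spread[k % len(spread)]
        rank = rank_cursor[gid]
        rank_cursor[gid] += 25
        if rank >= anchor_rank - radius_guard:
            raise ValueError("family members overflow the pre-anchor region")
        family_slots.append((gid, rank, False))

    family_ids: list[str] = []
    neighbor_pairs: list[tuple[str, str]] = []
    for gid, rank, is_neighbor in family_slots:
        prot = mutate_member(family_seed, cfg.divergence, protected, rng)
        layouts[gid].place(rank, prot, strand="+", tight=is_neighbor)
        fid = gene_id(gid, rank)
        family_ids.append(fid)
        if is_neighbor:
            neighbor_pairs.append((gene_id(gid, anchor_rank), fid))
    hosting_genomes = {g for g, _r, _n in family_slots}

    # --- CutG-like family (genomes with both) ------------------------------
    n_both = _round_count(cfg.p_both, cfg.n_cuto_anchors)
    both_candidates = [g for g in cuto_genomes[:n_host]]
    if n_both > len(both_candidates):
        raise ValueError("p_both exceeds the family-hosting cutO genomes")
    both_genomes = set(both_candidates[:n_both])
    cutg_seed = random_protein(rng, cfg.cutg_len)
    cutg_ids = []
    for gid in sorted(both_genomes):
        prot = mutate_member(cutg_seed, cfg.cutg_divergence, set(), rng)
        rank = gpg - 50
        layouts[gid].place(rank, prot, strand="-")
        cutg_ids.append(gene_id(gid, rank))

    # --- Cu-binding annotation next to family genes ------------------------
    n_annot = _round_count(cfg.p_annotation, cfg.n_family)
    annotation_ids: set[str] = set()
    annotated_family: set[str] = set()
    for gid, rank, _n in family_slots[:n_annot]:
        ann_rank = rank + 1
        if ann_rank in layouts[gid].special:
            ann_rank = rank - 1
        prot = random_protein(rng, int(rng.integers(150, 300)))
        layouts[gid].place(ann_rank, prot, strand="+")
        annotation_ids.add(gene_id(gid, ann_rank))
        annotated_family.add(gene_id(gid, rank))

    # --- decoys -------------------------------------------------------------
    decoys: dict[str, list[str]] = {k: [] for k in
                                    ("small_no_motif", "motif_with_domain",
                                     "motif_outside_window", "large_motif")}
    decoy_base = {"small_no_motif": gpg - 100, "motif_with_domain": gpg - 90,
                  "motif_outside_window": gpg - 80, "large_motif": gpg - 70}

    def decoy_protein(kind: str) -> str:
        if kind == "small_no_motif":
            return random_protein(rng, int(rng.integers(90, 165)), AA_NO_C)
        if kind == "motif_with_domain":
            return mutate_member(family_seed, cfg.divergence, protected, rng)
        if kind == "motif_outside_window":
            length = int(rng.integers(100, 165))
            body = list(random_protein(rng, length, AA_NO_C))
            mid = length // 2
            body[mid : mid + 5] = "C" + "".join(
                rng.choice(list(AA_NO_C), size=3)) + "C"
            body[-6:-4] = "PP"
            return random_signal_block(rng) + "".join(body)
        # large_motif
        length = int(rng.integers(200, 300))
        body = list(random_protein(rng, length, AA_NO_C))
        mid = length // 2
        body[mid : mid + 5] = "C" + "".join(rng.choice(list(AA_NO_C), size=3)) + "C"
        body[-6:-4] = "PP"
        return random_signal_block(rng) + "".join(body)

    for kind in sorted(decoys):
        base = decoy_base[kind]
        for k in range(cfg.n_decoys_per_type):
            gid = genome_ids[k % cfg.n_genomes]
            rank = base + (k // cfg.n_genomes)
            layout = layouts[gid]
            while rank in layout.special:
                rank += 1
            layout.place(rank, decoy_protein(kind))
            did = gene_id(gid, rank)
            decoys[kind].append(did)
            if kind == "motif_with_domain":
                domain_hits.append((did, DECOY_DOMAIN, 1e-20))

    # --- background genes + assembly ---------------------------------------
    gs = GenomeSet()
    lo, hi = cfg.background_len_range
    for gid in genome_ids:
        layout = layouts[gid]
        pos = 1000
        for rank in range(gpg):
            if rank in layout.special:
                prot = layout.proteins[rank]
                strand = layout.strands[rank]
            else:
                prot = random_protein(rng, int(rng.integers(lo, hi + 1)))
                strand = "+" if rng.random() < 0.5 else "-"
                if rng.random() < cfg.p_background_domain:
                    acc = BACKGROUND_DOMAINS[
                        rng.integers(len(BACKGROUND_DOMAINS))
                    ]
                    domain_hits.append(
                        (gene_id(gid, rank), acc, float(10.0 ** -rng.integers(6, 40)))
                    )
            gap = 30 if rank in layout.tight_gap else 80
            start = pos + gap
            end = start + 3 * len(prot) + 3
            pos = end
            gs.add_gene(
                Gene(
                    gene_id=gene_id(gid, rank),
                    genome_id=gid,
                    contig_id="c0",
                    start=start,
                    end=end,
                    strand=strand,
                    rank=rank,
                    protein=prot,
                )
            )
        gs.taxonomy[gid] = taxonomy[gid]
    for key, acc, ev in domain_hits:
        gs.add_domain_hit(DomainHit(key, acc, ev))
    counts: dict[str, int] = {}
    for cls in gs.taxonomy.values():
        counts[cls] = counts.get(cls, 0) + 1
    gs.proteome_counts = counts
    gs.validate()

    # generator self-check: every planted family member passes the rules
    spec = MotifSpec()
    for fid in family_ids:
        decision = apply_rules(gs.genes[fid], gs.hits_for(fid), spec=spec)
        assert decision.passed, f"planted member {fid} fails the rule filter"

    truth = SyntheticTruth(
        family_member_ids=set(family_ids),
        cuto_anchor_ids=anchor_ids["cuto"],
        cueo_anchor_ids=anchor_ids["cueo"],
        ftsp_anchor_ids=anchor_ids["ftsp"],
        ssn_anchor_ids=ssn_anchor_ids,
        cutg_ids=cutg_ids,
        neighbor_pairs=neighbor_pairs,
        hosting_genomes=hosting_genomes,
        both_genomes=both_genomes,
        annotation_ids=annotation_ids,
        annotated_family_ids=annotated_family,
        decoys=decoys,
        seed_protein=family_seed,
        counts={
            "n_neighbor": n_neighbor,
            "n_host": n_host,
            "n_both": n_both,
            "n_annotated": n_annot,
            "n_family": cfg.n_family,
            "n_cuto_anchors": cfg.n_cuto_anchors,
        },
    )
    return gs, truth


def evaluate_recovery(predicted, truth: SyntheticTruth
                      ) -> tuple[float, float, float]:
    """Precision, recall and F1 of predicted family members versus truth."""
    if hasattr(predicted, "final_members"):
        predicted = predicted.final_members
    pred = set(predicted)
    true = set(truth.family_member_ids)
    tp = len(pred & true)
    precision = tp / len(pred) if pred else 0.0
    recall = tp / len(true) if true else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1
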