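"""Orchestration of the full discovery workflow.

Stage order mirrors the discovery procedure: anchor detection -> gene
windows -> candidate rule filter -> seed alignment with motif-column
curation -> iterative profile-HMM search with Pfam removal -> sequence
similarity network of the Cu oxidases (collapse, threshold network,
components, exemplar labels) -> co-occurrence statistics -> NJ tree with
bootstrap supports and low-support pruning.  Outputs are plain-text
per-stage files plus a JSON report; given a fixed seed the bundle is
reproducible byte-for-byte (the run log carries the timings).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import (
    alignment,
    candidate_rules,
    cooccurrence,
    genome_model,
    neighborhood,
    phylogeny,
    profile_hmm,
    ssn as ssn_mod,
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class PipelineConfig:
    """All stage parameters; defaults mirror the published thresholds."""

    window_radius: int = 10  # genes per side around an anchor
    anchor_domains: tuple[str, ...] = ("PF00394", "PF07731")  # any-of
    oxidase_domains: tuple[str, ...] = ("PF00394", "PF07731", "PF07732")  # all-of
    domain_evalue_max: float = 1e-5
    max_len: int = 170  # strict: candidates are < 170 aa
    motif_patterns: tuple[str, ...] = candidate_rules.DEFAULT_MOTIF_PATTERNS
    motif_region: tuple[float, float] | None = (0.20, 0.80)
    max_iter: int = 11  # iterative-search bound
    evalue_include: float = 0.01
    calibrate_n: int = 1000
    collapse_identity: float = 90.0  # % identity for node collapsing
    ssn_score_min: float = 100.0  # alignment-score edge threshold
    bootstrap_reps: int = 100
    support_min: float = 0.5  # strict < collapses
    operon_max_gap_bp: int = 150
    operon_same_strand: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise StageError(f"config: unknown keys {sorted(unknown)}")
        for key in ("anchor_domains", "oxidase_domains", "motif_patterns",
                    "motif_region"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DiscoveryResult:
    anchors: list[str]
    windows: list[neighborhood.Window]
    operons: list[neighborhood.OperonContext]
    decisions: list[candidate_rules.FilterDecision]
    seed_ids: list[str]
    curated_seed_ids: list[str]
    family: profile_hmm.FamilySet
    family_msa: alignment.MSA | None
    ssn: ssn_mod.SSNGraph | None
    cluster_genes: list[str]
    cooccurrence: cooccurrence.CooccurrenceReport | None
    tree: object | None
    pruned_tree: object | None
    timings: dict[str, float] = field(default_factory=dict)


def _operon_neighbor_fraction(result_windows, operons, family, genomes):
    fam = set(family)
    by_anchor = {o.anchor_id: set(o.operon_member_ids) for o in operons}
    anchors = sorted(by_anchor)
    if not anchors:
        return 0.0
    n = sum(
        1 for a in anchors if (by_anchor[a] - {a}) & fam
    )
    return n / len(anchors)


def run_discovery(
    genomes: genome_model.GenomeSet,
    config: PipelineConfig = PipelineConfig(),
    out_dir=None,
    signal_calls: dict[str, candidate_rules.SignalCall] | None = None,
    exemplars: dict[str, str] | None = None,
    second_family_genes: list[str] | None = None,
    annotation_ids: set[str] | None = None,
    skip_tree: bool = False,
) -> DiscoveryResult:
    """Run the full discovery workflow on a loaded GenomeSet."""
    timings: dict[str, float] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        timings[name] = time.perf_counter()
        return name

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    # -- anchors ------------------------------------------------------------
    stage("anchors")
    if not genomes.domain_hits:
        raise StageError(
            "anchors: no domain annotations loaded — supply a domain table "
            "(gene_id, domain_acc, evalue)"
        )
    anchors = neighborhood.find_anchors(
        genomes, set(config.anchor_domains), config.domain_evalue_max
    )
    done("anchors")
    if out is not None:
        pd.DataFrame({"anchor_id": anchors}).to_csv(
            out / "anchors.tsv", sep="\t", index=False)

    # -- windows + operons --------------------------------------------------
    stage("windows")
    windows = [
        neighborhood.extract_window(genomes, a, config.window_radius)
        for a in anchors
    ]
    operons = [
        neighborhood.infer_operon(
            w, genomes, config.operon_max_gap_bp, config.operon_same_strand)
        for w in windows
    ]
    done("windows")
    if out is not None:
        rows = []
        for w, o in zip(windows, operons):
            rows.extend(neighborhood.window_report_rows(w, o, genomes))
        pd.DataFrame(rows).to_csv(out / "windows.tsv", sep="\t", index=False)

    # -- candidate rule filter ---------------------------------------------
    stage("filter")
    spec = candidate_rules.MotifSpec(
        patterns=tuple(config.motif_patterns), region=config.motif_region
    )
    anchor_set = set(anchors)
    candidate_ids = sorted(
        {m for w in windows for m in w.member_ids} - anchor_set
    )
    decisions = [
        candidate_rules.apply_rules(
            genomes.genes[gid],
            genomes.hits_for(gid),
            signal_calls=signal_calls,
            spec=spec,
            max_len=config.max_len,
            domain_evalue_max=config.domain_evalue_max,
        )
        for gid in candidate_ids
    ]
    seed_ids = [d.gene_id for d in decisions if d.passed]
    done("filter")
    if out is not None:
        candidate_rules.decisions_to_frame(decisions).to_csv(
            out / "filter_decisions.tsv", sep="\t", index=False)
    if len(seed_ids) < 2:
        raise StageError(
            f"filter: only {len(seed_ids)} candidate(s) passed the rule "
            "filter; need >= 2 to seed the family search"
        )

    # -- seed MSA + motif-column curation ------------------------------------
    stage("msa")
    seed_msa = alignment.progressive_msa(
        {gid: genomes.genes[gid].protein for gid in seed_ids}
    )
    curated_msa, removed = alignment.curate_by_motif_columns(seed_msa)
    if curated_msa.n_rows < 2:
        curated_msa, removed = seed_msa, []
    done("msa")
    if out is not None:
        alignment.write_fasta_msa(curated_msa, out / "seed_msa.fasta")

    # -- iterative profile-HMM search ----------------------------------------
    stage("hmmsearch")
    family = profile_hmm.iterative_search(
        curated_msa,
        genomes,
        genomes.domain_hits,
        max_iter=config.max_iter,
        evalue_include=config.evalue_include,
        domain_evalue_max=config.domain_evalue_max,
        calibrate_n=config.calibrate_n,
        seed=config.seed,
    )
    family_msa = None
    if len(family.final_members) >= 2:
        family_msa = alignment.progressive_msa(
            {m: genomes.genes[m].protein for m in family.final_members}
        )
    done("hmmsearch")
    if out is not None:
        genome_model.write_protein_fasta(
            genomes, out / "family.fasta", sorted(family.final_members))
        pd.DataFrame(profile_hmm.hits_to_rows(family.hits)).to_csv(
            out / "family_hits.tsv", sep="\t", index=False)
        if family_msa is not None:
            alignment.write_fasta_msa(family_msa, out / "family_msa.fasta")
            pd.DataFrame({
                "column": range(1, family_msa.n_cols + 1),
                "bits": alignment.column_information(family_msa),
            }).to_csv(out / "family_logo.tsv", sep="\t", index=False)

    # -- SSN ------------------------------------------------------------------
    stage("ssn")
    oxidase_ids = neighborhood.find_cu_oxidases(
        genomes, set(config.oxidase_domains), config.domain_evalue_max
    )
    net = None
    cluster_genes: list[str] = []
    if len(oxidase_ids) >= 2:
        seqs = {gid: genomes.genes[gid].protein for gid in oxidase_ids}
        members = ssn_mod.collapse_nodes(seqs, config.collapse_identity)
        reps = {rep: seqs[rep] for rep in members}
        net = ssn_mod.build_network(reps, config.ssn_score_min, members)
        ssn_mod.connected_components(net)
        if exemplars:
            ssn_mod.label_clusters(net, exemplars)
            cuto_clusters = [
                cid for cid, labels in net.labels.items() if "CutO" in labels
            ]
            if cuto_clusters:
                cluster_genes = ssn_mod.cluster_members(net, cuto_clusters[0])
        if not cluster_genes and net.clusters:
            # default: the largest cluster (ties -> smallest id)
            sizes: dict[int, int] = {}
            for rep, cid in net.clusters.items():
                sizes[cid] = sizes.get(cid, 0) + len(net.members[rep])
            best = min(sizes, key=lambda c: (-sizes[c], c))
            cluster_genes = ssn_mod.cluster_members(net, best)
    done("ssn")
    if out is not None and net is not None:
        ssn_mod.write_edge_list(net, out / "ssn_edges.tsv")
        ssn_mod.write_graphml(net, out / "ssn.graphml")

    # -- co-occurrence --------------------------------------------------------
    stage("cooccur")
    report = None
    if cluster_genes:
        fam_members = sorted(family.final_members)
        report = cooccurrence.build_report(
            cluster_genes,
            fam_members,
            second_family_genes or [],
            annotation_ids or set(),
            genomes,
            radius=config.window_radius,
            operon_neighbor_fn=lambda cg, fg: _operon_neighbor_fraction(
                windows, [o for o in operons if o.anchor_id in set(cg)],
                fg, genomes),
        )
    done("cooccur")
    if out is not None and report is not None:
        with open(out / "cooccurrence.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)

    # -- phylogeny ------------------------------------------------------------
    stage("tree")
    tree = pruned = None
    if not skip_tree and net is not None and len(net.members) >= 4:
        rep_msa = alignment.progressive_msa(
            {rep: genomes.genes[rep].protein for rep in net.members}
        )
        tree = phylogeny.bootstrap_support(
            rep_msa, n_reps=config.bootstrap_reps, seed=config.seed
        )
        pruned = phylogeny.prune_low_support(tree, config.support_min)
    done("tree")
    if out is not None and tree is not None:
        phylogeny.write_newick(tree, out / "tree.nwk")
        phylogeny.write_newick(pruned, out / "tree_pruned.nwk")

    result = DiscoveryResult(
        anchors=anchors,
        windows=windows,
        operons=operons,
        decisions=decisions,
        seed_ids=seed_ids,
        curated_seed_ids=list(curated_msa.ids),
        family=family,
        family_msa=family_msa,
        ssn=net,
        cluster_genes=cluster_genes,
        cooccurrence=report,
        tree=tree,
        pruned_tree=pruned,
        timings=timings,
    )
    if out is not None:
        with open(out / "run_log.txt", "w") as fh:
            fh.write("config:\n")
            for k, v in sorted(config.to_dict().items()):
                fh.write(f"  {k}: {v}\n")
            fh.write("stages:\n")
            for name, t in timings.items():
                fh.write(f"  {name}: {t:.2f} s\n")
            fh.write(
                f"anchors: {len(anchors)}\nseeds: {len(seed_ids)}\n"
                f"family: {len(family.final_members)} members, "
                f"{family.iterations_run} iterations, "
                f"converged={family.converged}\n"
            )
    return result


def run_discovery_from_paths(
    genes_tsv,
    domains_tsv=None,
    signal_tsv=None,
    config: PipelineConfig = PipelineConfig(),
    out_dir=None,
    **kwargs,
) -> DiscoveryResult:
    """Load inputs from TSV files and run the workflow."""
    gs = genome_model.read_gene_table(genes_tsv)
    if domains_tsv is None:
        raise StageError(
            "filter: a domain table is required (the no-known-domain rule "
            "and anchor detection depend on it)"
        )
    genome_model.read_domain_table(domains_tsv, gs, strict=False)
    signal_calls = (
        candidate_rules.read_signal_table(signal_tsv) if signal_tsv else None
    )
    return run_discovery(
        gs, config=config, out_dir=out_dir, signal_calls=signal_calls, **kwargs
    )
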