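"""Sequence similarity networks for multicopper-oxidase sequences.

Sequences are first collapsed into representative nodes by greedy
single-linkage grouping at a percent-identity threshold (default 90%,
global alignment, gaps in the denominator).  Representatives are then
connected by an undirected edge wherever their Smith-Waterman score meets
the score threshold (default 100), and clusters are the connected
components.  Exemplar sequences (e.g. known CutO/CueO/FtsP proteins)
label the cluster that contains them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx

from .alignment import global_identity, smith_waterman


@dataclass
class SSNGraph:
    """Similarity network over collapsed representatives."""

    graph: nx.Graph
    members: dict[str, list[str]]  # representative -> collapsed member ids
    clusters: dict[str, int] = field(default_factory=dict)
    labels: dict[int, list[str]] = field(default_factory=dict)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def collapse_nodes(seqs: dict[str, str], identity_min: float = 90.0
                   ) -> dict[str, list[str]]:
    """Greedy single-linkage grouping at percent identity >= identity_min.

    Returns representative -> members (representative included); the
    representative is the longest member, ties broken lexicographically.
    Every input sequence belongs to exactly one representative.
    """
    if not seqs:
        raise ValueError("collapse_nodes needs >= 1 sequence")
    ids = sorted(seqs)
    uf = _UnionFind(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if uf.find(a) == uf.find(b):
                continue
            if global_identity(seqs[a], seqs[b]) >= identity_min:
                uf.union(a, b)
    groups: dict[str, list[str]] = {}
    for sid in ids:
        groups.setdefault(uf.find(sid), []).append(sid)
    out = {}
    for members in groups.values():
        rep = min(members, key=lambda m: (-len(seqs[m]), m))
        out[rep] = sorted(members)
    return out


def build_network(representatives: dict[str, str], score_min: float = 100.0,
                  members: dict[str, list[str]] | None = None) -> SSNGraph:
    """All-vs-all local alignment; edge iff score >= score_min."""
    if len(representatives) < 2:
        raise ValueError("build_network needs >= 2 representatives")
    g = nx.Graph()
    ids = sorted(representatives)
    for rid in ids:
        g.add_node(rid, length=len(representatives[rid]))
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            s_ab = smith_waterman(representatives[a], representatives[b]).score
            if s_ab >= score_min:
                g.add_edge(a, b, score=s_ab)
    return SSNGraph(
        graph=g,
        members=members or {rid: [rid] for rid in ids},
    )


def connected_components(ssn: SSNGraph) -> dict[str, int]:
    """Cluster labels by connected component, ids ordered by smallest member."""
    comps = sorted(
        (sorted(c) for c in nx.connected_components(ssn.graph)),
        key=lambda c: c[0],
    )
    clusters = {}
    for cid, comp in enumerate(comps):
        for node in comp:
            clusters[node] = cid
    ssn.clusters = clusters
    return clusters


def cluster_members(ssn: SSNGraph, cluster_id: int,
                    expand: bool = True) -> list[str]:
    """All representatives (or, expanded, all collapsed sequences) of a cluster."""
    reps = [n for n, c in ssn.clusters.items() if c == cluster_id]
    if not expand:
        return sorted(reps)
    out: list[str] = []
    for rep in reps:
        out.extend(ssn.members.get(rep, [rep]))
    return sorted(out)


def label_clusters(ssn: SSNGraph, exemplars: dict[str, str]) -> dict[int, list[str]]:
    """Assign label L to the cluster containing exemplar sequence id.

    Exemplar ids may name either a representative or a collapsed member.
    Multiple labels landing in one cluster are kept, with a warning.
    """
    if not ssn.clusters:
        connected_components(ssn)
    member_to_rep = {}
    for rep, mems in ssn.members.items():
        for m in mems:
            member_to_rep[m] = rep
    labels: dict[int, list[str]] = {}
    for label, sid in sorted(exemplars.items()):
        rep = member_to_rep.get(sid)
        if rep is None or rep not in ssn.clusters:
            raise KeyError(f"exemplar {sid!r} (label {label!r}) not in network")
        cid = ssn.clusters[rep]
        labels.setdefault(cid, []).append(label)
    for cid, ls in labels.items():
        if len(ls) > 1:
            warnings.warn(
                f"cluster {cid} contains exemplars for multiple labels: {ls}"
            )
    ssn.labels = labels
    return labels


def write_graphml(ssn: SSNGraph, path) -> None:
    g = ssn.graph.copy()
    for node in g.nodes:
        g.nodes[node]["cluster"] = ssn.clusters.get(node, -1)
        g.nodes[node]["members"] = ",".join(ssn.members.get(node, [node]))
        cid = ssn.clusters.get(node)
        g.nodes[node]["label"] = ";".join(ssn.labels.get(cid, []))
    nx.write_graphml(g, path)


def write_edge_list(ssn: SSNGraph, path) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tscore\n")
        for a, b, data in sorted(ssn.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data['score']}\n")
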