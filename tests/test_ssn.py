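"""Node collapsing, threshold networks, components and cluster labels."""

import numpy as np
import pytest

from cuproscan import ssn
from cuproscan.alignment import ALPHABET, global_identity, smith_waterman


def random_seqs(rng, n, lo=20, hi=60):
    letters = list(ALPHABET[:20])
    return {
        f"s{i:02d}": "".join(rng.choice(letters, size=rng.integers(lo, hi)))
        for i in range(n)
    }


class TestCollapse:
    def test_identical_pair_plus_unrelated(self):
        seqs = {"a": "MKTAYIAKQRMKTAYIAKQR", "b": "MKTAYIAKQRMKTAYIAKQR",
                "c": "WWFFHHGGPPCCWWFFHHGG"}
        groups = ssn.collapse_nodes(seqs, 90.0)
        assert len(groups) == 2
        assert groups["a"] == ["a", "b"]

    def test_all_distinct_at_full_identity(self):
        rng = np.random.default_rng(0)
        seqs = random_seqs(rng, 6)
        groups = ssn.collapse_nodes(seqs, 100.0)
        assert len(groups) == 6

    def test_partition_property(self, synth_small):
        gs, truth = synth_small
        seqs = {a: gs.genes[a].protein for a in truth.ssn_anchor_ids}
        groups = ssn.collapse_nodes(seqs, 90.0)
        seen = [m for mem in groups.values() for m in mem]
        assert sorted(seen) == sorted(seqs)

    def test_single_linkage_connectivity(self):
        # each member is >= threshold identical to at least one group mate
        base = "MKTAYIAKQRWLVNNACDEF" * 3
        variant = base[:-2] + "GG"  # ~96.7% identical to base
        far = "W" * 60
        groups = ssn.collapse_nodes(
            {"a": base, "b": variant, "c": far}, 90.0)
        for rep, members in groups.items():
            for m in members:
                if len(members) == 1:
                    continue
                assert any(
                    global_identity(
                        {"a": base, "b": variant, "c": far}[m],
                        {"a": base, "b": variant, "c": far}[o]) >= 90.0
                    for o in members if o != m
                )


class TestNetwork:
    def test_high_threshold_gives_no_edges(self):
        net = ssn.build_network({"a": "MKTA", "b": "WWFF"}, score_min=500.0)
        assert net.graph.number_of_edges() == 0

    def test_zero_threshold_gives_complete_graph(self):
        rng = np.random.default_rng(1)
        seqs = random_seqs(rng, 6)
        net = ssn.build_network(seqs, score_min=0.0)
        n = len(seqs)
        assert net.graph.number_of_edges() == n * (n - 1) // 2

    def test_edge_set_matches_threshold_oracle(self):
        rng = np.random.default_rng(2)
        seqs = random_seqs(rng, 12)
        threshold = 40.0
        net = ssn.build_network(seqs, score_min=threshold)
        ids = sorted(seqs)
        expected = set()
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if smith_waterman(seqs[a], seqs[b]).score >= threshold:
                    expected.add((a, b))
        got = {tuple(sorted(e)) for e in net.graph.edges}
        assert got == expected


def union_find_components(nodes, edges):
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return sorted(sorted(g) for g in groups.values())


class TestComponents:
    def test_two_planted_families_two_components(self, synth_small):
        gs, truth = synth_small
        seqs = {a: gs.genes[a].protein for a in truth.ssn_anchor_ids}
        members = ssn.collapse_nodes(seqs, 90.0)
        reps = {r: seqs[r] for r in members}
        net = ssn.build_network(reps, 100.0, members)
        clusters = ssn.connected_components(net)
        # three planted oxidase clusters (CutO-, CueO-, FtsP-like seeds)
        assert len(set(clusters.values())) == 3

    def test_empty_edge_set_gives_singletons(self):
        net = ssn.build_network({"a": "MKTA", "b": "WWFF"}, score_min=500.0)
        clusters = ssn.connected_components(net)
        assert len(set(clusters.values())) == 2

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(3)
        seqs = random_seqs(rng, 10)
        net = ssn.build_network(seqs, score_min=35.0)
        clusters = ssn.connected_components(net)
        got = {}
        for node, cid in clusters.items():
            got.setdefault(cid, set()).add(node)
        got_groups = sorted(sorted(g) for g in got.values())
        expected = union_find_components(
            sorted(seqs), [tuple(sorted(e)) for e in net.graph.edges])
        assert got_groups == expected


class TestLabels:
    def _net(self):
        seqs = {"a": "MKTAYIAKQRMKTAYIAKQR", "b": "MKTAYIAKQRMKTAYIAKQL",
                "c": "WWFFHHGGPPCCWWFFHHGG"}
        net = ssn.build_network(seqs, score_min=50.0)
        ssn.connected_components(net)
        return net

    def test_exemplar_labels_its_cluster(self):
        net = self._net()
        labels = ssn.label_clusters(net, {"CutO": "a"})
        assert labels[net.clusters["a"]] == ["CutO"]

    def test_conflicting_exemplars_warn_and_keep_both(self):
        net = self._net()
        with pytest.warns(UserWarning):
            labels = ssn.label_clusters(net, {"CutO": "a", "CueO": "b"})
        assert sorted(labels[net.clusters["a"]]) == ["CueO", "CutO"]

    def test_missing_exemplar_is_error(self):
        net = self._net()
        with pytest.raises(KeyError, match="nope"):
            ssn.label_clusters(net, {"CutO": "nope"})


def test_graphml_and_edge_list_export(tmp_path, synth_small):
    import networkx as nx
    gs, truth = synth_small
    seqs = {a: gs.genes[a].protein for a in truth.ssn_anchor_ids}
    members = ssn.collapse_nodes(seqs, 90.0)
    net = ssn.build_network({r: seqs[r] for r in members}, 100.0, members)
    ssn.connected_components(net)
    ssn.write_graphml(net, tmp_path / "net.graphml")
    back = nx.read_graphml(tmp_path / "net.graphml")
    assert set(back.nodes) == set(net.graph.nodes)
    ssn.write_edge_list(net, tmp_path / "edges.tsv")
    n_lines = len((tmp_path / "edges.tsv").read_text().splitlines())
    assert n_lines == net.graph.number_of_edges() + 1
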