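"""Distances, neighbor joining, bootstrap supports, pruning, Newick I/O."""

import numpy as np
import pytest

from cuproscan import phylogeny as phy
from cuproscan.alignment import MSA


def random_additive_tree(rng, n_taxa):
    """Random unrooted binary tree with positive lengths; returns (edges, D).

    Built by attaching each new leaf to a uniformly random existing edge.
    Distances are path sums, hence exactly additive.
    """
    import networkx as nx

    g = nx.Graph()
    g.add_edge("T0", "T1", length=float(rng.uniform(0.5, 2.0)))
    internal = 0
    for k in range(2, n_taxa):
        edges = list(g.edges)
        a, b = edges[rng.integers(len(edges))]
        w = g.edges[a, b]["length"]
        g.remove_edge(a, b)
        node = f"I{internal}"
        internal += 1
        split = float(rng.uniform(0.2, 0.8)) * w
        g.add_edge(a, node, length=split)
        g.add_edge(node, b, length=w - split)
        g.add_edge(node, f"T{k}", length=float(rng.uniform(0.5, 2.0)))
    names = [f"T{i}" for i in range(n_taxa)]
    D = np.zeros((n_taxa, n_taxa))
    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            D[i, j] = paths[a][b]
    # true bipartitions via edge removal
    bps = set()
    anchor = "T0"
    for a, b in list(g.edges):
        g.remove_edge(a, b)
        comp = set(nx.node_connected_component(g, a))
        g.add_edge(a, b, length=1.0)
        side = frozenset(n for n in comp if n.startswith("T"))
        if anchor in side:
            side = frozenset(set(names) - side)
        if 2 <= len(side) <= n_taxa - 2:
            bps.add(side)
    return names, D, bps


class TestDistances:
    def test_identical_rows_zero(self):
        msa = MSA(ids=["a", "b"], rows={"a": "MKTAY", "b": "MKTAY"})
        assert phy.distance_matrix(msa)[0, 1] == 0.0

    def test_poisson_correction_closed_form(self):
        rows = {"a": "A" * 10, "b": "A" * 9 + "C"}
        msa = MSA(ids=["a", "b"], rows=rows)
        assert phy.distance_matrix(msa)[0, 1] == pytest.approx(-np.log(0.9))

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(0)
        letters = list("ACDE-")
        rows = {}
        for i in range(5):
            row = "".join(rng.choice(letters, size=30))
            rows[f"s{i}"] = row.replace("-", "A", 1)
        msa = MSA(ids=sorted(rows), rows=rows)
        D = phy.distance_matrix(msa)
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_no_shared_columns_is_error(self):
        msa = MSA(ids=["a", "b"], rows={"a": "AA--", "b": "--CC"})
        with pytest.raises(phy.DistanceError, match="a and b"):
            phy.distance_matrix(msa)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = phy.neighbor_joining(D, ["A", "B", "C"])
        lengths = {t.name: t.branch_length for t in tree.get_terminals()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_exact_recovery_of_random_additive_trees(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            names, D, true_bps = random_additive_tree(rng, 6)
            tree = phy.neighbor_joining(D, names)
            assert phy.bipartitions(tree) == true_bps

    def test_path_lengths_reproduce_additive_distances(self):
        rng = np.random.default_rng(2)
        names, D, _ = random_additive_tree(rng, 6)
        tree = phy.neighbor_joining(D, names)
        for i, a in enumerate(names):
            for j in range(i + 1, len(names)):
                assert tree.distance(a, names[j]) == pytest.approx(
                    D[i, j], abs=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            phy.neighbor_joining(np.zeros((2, 2)), ["A", "B"])


SIGNAL_MSA = MSA(
    ids=["a", "b", "c", "d"],
    rows={
        "a": "AAAACCCC" * 25,
        "b": "AAAACCCG" * 25,
        "c": "AATTCCCC" * 25,
        "d": "AATTCCGG" * 25,
    },
)


class TestBootstrap:
    def test_replicated_signal_gives_full_support(self):
        tree = phy.bootstrap_support(SIGNAL_MSA, n_reps=50, seed=0)
        confs = [c.confidence for c in tree.get_nonterminals()
                 if c.confidence is not None]
        assert confs and all(c == 1.0 for c in confs)

    def test_same_seed_same_supports(self):
        t1 = phy.bootstrap_support(SIGNAL_MSA, n_reps=30, seed=5)
        t2 = phy.bootstrap_support(SIGNAL_MSA, n_reps=30, seed=5)
        c1 = sorted(c.confidence for c in t1.get_nonterminals()
                    if c.confidence is not None)
        c2 = sorted(c.confidence for c in t2.get_nonterminals()
                    if c.confidence is not None)
        assert c1 == c2

    def test_supports_within_unit_interval(self):
        rng = np.random.default_rng(3)
        rows = {f"s{i}": "".join(rng.choice(list("ACDEFG"), size=60))
                for i in range(5)}
        msa = MSA(ids=sorted(rows), rows=rows)
        tree = phy.bootstrap_support(msa, n_reps=20, seed=1)
        for c in tree.get_nonterminals():
            if c.confidence is not None:
                assert 0.0 <= c.confidence <= 1.0

    def test_too_few_replicates_refused(self):
        with pytest.raises(ValueError):
            phy.bootstrap_support(SIGNAL_MSA, n_reps=5, seed=0)


class TestPruning:
    def test_high_support_tree_unchanged(self):
        tree = phy.bootstrap_support(SIGNAL_MSA, n_reps=50, seed=0)
        pruned = phy.prune_low_support(tree, 0.5)
        assert phy.bipartitions(pruned) == phy.bipartitions(tree)

    def test_all_low_support_collapses_to_star(self):
        tree = phy.bootstrap_support(SIGNAL_MSA, n_reps=50, seed=0)
        for c in tree.get_nonterminals():
            if c.confidence is not None:
                c.confidence = 0.1
        star = phy.prune_low_support(tree, 0.5)
        assert phy.bipartitions(star) == set()
        assert phy.leaf_names(star) == phy.leaf_names(tree)

    def test_exactly_at_threshold_survives(self):
        tree = phy.bootstrap_support(SIGNAL_MSA, n_reps=50, seed=0)
        for c in tree.get_nonterminals():
            if c.confidence is not None:
                c.confidence = 0.5
        kept = phy.prune_low_support(tree, 0.5)
        assert phy.bipartitions(kept) == phy.bipartitions(tree)

    def test_pruned_bipartitions_are_subset(self):
        rng = np.random.default_rng(4)
        rows = {f"s{i}": "".join(rng.choice(list("ACDEFG"), size=40))
                for i in range(6)}
        msa = MSA(ids=sorted(rows), rows=rows)
        tree = phy.bootstrap_support(msa, n_reps=20, seed=2)
        pruned = phy.prune_low_support(tree, 0.5)
        assert phy.bipartitions(pruned) <= phy.bipartitions(tree)


class TestNewick:
    def test_three_leaf_string(self, tmp_path):
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = phy.neighbor_joining(D, ["A", "B", "C"])
        path = tmp_path / "t.nwk"
        phy.write_newick(tree, path)
        text = path.read_text().strip().replace(":0.00000", ":0")
        assert text.startswith("(A:1")
        back = phy.read_newick(path)
        assert phy.leaf_names(back) == ["A", "B", "C"]
        assert {t.name: t.branch_length for t in back.get_terminals()} == {
            "A": 1.0, "B": 1.0, "C": 3.0}

    def test_round_trip_preserves_structure(self, tmp_path):
        rng = np.random.default_rng(5)
        for k in range(20):
            names, D, _ = random_additive_tree(rng, int(rng.integers(4, 8)))
            tree = phy.neighbor_joining(D, names)
            for i, c in enumerate(tree.get_nonterminals()):
                if c is not tree.root:
                    c.confidence = round(float(rng.uniform()), 4)
            path = tmp_path / f"t{k}.nwk"
            phy.write_newick(tree, path)
            back = phy.read_newick(path)
            assert phy.bipartitions(back) == phy.bipartitions(tree)
            d1 = {t.name: t.branch_length for t in tree.get_terminals()}
            d2 = {t.name: t.branch_length for t in back.get_terminals()}
            for name in d1:
                assert d2[name] == pytest.approx(d1[name], abs=1e-4)
            s1 = sorted(c.confidence for c in tree.get_nonterminals()
                        if c.confidence is not None)
            s2 = sorted(c.confidence for c in back.get_nonterminals()
                        if c.confidence is not None)
            assert s2 == pytest.approx(s1)

    def test_malformed_string_raises(self, tmp_path):
        path = tmp_path / "bad.nwk"
        path.write_text("((A:1,B:2;")
        with pytest.raises(Exception):
            phy.read_newick(path)
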