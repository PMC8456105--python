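"""Distance-based phylogeny: NJ trees, bootstrap support, support pruning.

Neighbor joining with Poisson-corrected p-distances stands in for
approximate-ML tree inference: it is deterministic, exact on additive
distance matrices, and oracle-testable.  Bootstrap support is the fraction
of column-resampled replicate trees containing each internal bipartition
of the full-data tree; branches below the support threshold are collapsed
into polytomies (the threshold is strict: exactly 50% survives a 0.5
cutoff).  Trees are Bio.Phylo objects; Newick is the on-disk format, with
supports as internal node labels.
"""

from __future__ import annotations

import numpy as np
from Bio import Phylo
from Bio.Phylo.BaseTree import Clade, Tree

from .alignment import GAP, MSA


class DistanceError(ValueError):
    pass


def _encode_msa(msa: MSA) -> np.ndarray:
    """Rows as a (n, L) byte matrix for vectorized column comparisons."""
    return np.frombuffer(
        "".join(msa.rows[i] for i in msa.ids).encode("ascii"), dtype=np.uint8
    ).reshape(len(msa.ids), msa.n_cols)


def _pdist(arr: np.ndarray, ids: list[str], model: str) -> np.ndarray:
    gap = ord(GAP)
    n = arr.shape[0]
    D = np.zeros((n, n))
    nongap = arr != gap
    for i in range(n):
        both = nongap[i] & nongap[i + 1 :]
        shared = both.sum(axis=1)
        mism = ((arr[i] != arr[i + 1 :]) & both).sum(axis=1)
        if (shared == 0).any():
            j = int(np.argmax(shared == 0)) + i + 1
            raise DistanceError(
                f"sequences {ids[i]} and {ids[j]} share no aligned columns"
            )
        p = mism / shared
        if model == "poisson":
            d = -np.log1p(-np.minimum(p, 1.0 - 1e-9))
        elif model == "p":
            d = p
        else:
            raise ValueError(f"unknown distance model {model!r}")
        D[i, i + 1 :] = d
        D[i + 1 :, i] = d
    return D


def distance_matrix(msa: MSA, model: str = "poisson") -> np.ndarray:
    """Pairwise distances over shared non-gap columns.

    p-distance = mismatches / shared columns; the Poisson correction is
    d = -ln(1 - p).  Saturated pairs (p -> 1) are capped just below 1
    before correction.  A pair with zero shared columns is an error.
    """
    return _pdist(_encode_msa(msa), list(msa.ids), model)


def neighbor_joining(D: np.ndarray, names: list[str]) -> Tree:
    """Standard neighbor joining on a symmetric distance matrix.

    Negative branch lengths are clamped to 0 with the deficit moved to the
    sister edge.  The result is unrooted, represented with a trifurcating
    root; deterministic (ties resolved by smallest row-major index).
    """
    n = len(names)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("D must be a symmetric n x n matrix")
    D = D.astype(float).copy()
    nodes = [Clade(name=nm) for nm in names]
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        nodes[i].branch_length = float(li)
        nodes[j].branch_length = float(lj)
        parent = Clade(clades=[nodes[i], nodes[j]])
        dk = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        newD = np.zeros((m - 1, m - 1))
        newD[:-1, :-1] = D[np.ix_(keep, keep)]
        newD[-1, :-1] = dk[keep]
        newD[:-1, -1] = dk[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        D = newD
    # final three-way join (three-point formulas)
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lens = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    for node, ln in zip(nodes, lens):
        node.branch_length = float(max(ln, 0.0))
    root = Clade(clades=list(nodes))
    return Tree(root=root, rooted=False)


def nj_from_msa(msa: MSA, model: str = "poisson") -> Tree:
    return neighbor_joining(distance_matrix(msa, model), list(msa.ids))


def leaf_names(tree: Tree) -> list[str]:
    return sorted(t.name for t in tree.get_terminals())


def bipartitions(tree: Tree) -> set[frozenset]:
    """Non-trivial bipartitions as canonical leaf-name frozensets.

    Canonical side = the side NOT containing the lexicographically
    smallest leaf, so the representation is rooting-invariant.
    """
    leaves = set(leaf_names(tree))
    anchor = min(leaves)
    out = set()
    for clade in tree.get_nonterminals():
        side = frozenset(t.name for t in clade.get_terminals())
        if anchor in side:
            side = frozenset(leaves - side)
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def bootstrap_support(msa: MSA, n_reps: int = 100, seed: int = 0,
                      model: str = "poisson") -> Tree:
    """NJ tree with supports from column-resampled bootstrap replicates.

    Support on each internal edge of the full-data tree is the fraction of
    replicate trees containing the same bipartition.  Deterministic given
    the seed.
    """
    if n_reps < 10:
        raise ValueError("n_reps < 10 is not a meaningful bootstrap")
    tree = nj_from_msa(msa, model)
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(tree)}
    n_cols = msa.n_cols
    arr = _encode_msa(msa)
    ids = list(msa.ids)
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_tree = neighbor_joining(_pdist(arr[:, cols], ids, model), ids)
        rep_bps = bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    leaves = set(leaf_names(tree))
    anchor = min(leaves)
    for clade in tree.get_nonterminals():
        side = frozenset(t.name for t in clade.get_terminals())
        if anchor in side:
            side = frozenset(leaves - side)
        if 2 <= len(side) <= len(leaves) - 2:
            clade.confidence = counts[side] / n_reps
    return tree


def prune_low_support(tree: Tree, min_support: float = 0.5) -> Tree:
    """Collapse internal edges with support < min_support into polytomies.

    Strict threshold: an edge at exactly ``min_support`` survives.  The
    leaf set is unchanged; the collapsed edge's length is absorbed into
    its children's branches.
    """
    import copy

    pruned = copy.deepcopy(tree)
    changed = True
    while changed:
        changed = False
        for clade in pruned.get_nonterminals():
            if clade is pruned.root:
                continue
            if clade.confidence is not None and clade.confidence < min_support:
                pruned.collapse(clade)
                changed = True
                break
    return pruned


def write_newick(tree: Tree, path) -> None:
    Phylo.write(tree, str(path), "newick", format_confidence="%1.6g")


def read_newick(path) -> Tree:
    return Phylo.read(str(path), "newick")
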