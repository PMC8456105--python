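"""Pairwise and progressive multiple alignment, identity, and conservation.

Local/global affine-gap alignment uses BLOSUM62 with BLASTp-default gap
penalties (open 11, extend 1; a gap of length k costs 11 + k).  The
progressive aligner builds a UPGMA guide tree on k-mer distances and
merges profiles by global affine alignment of expected-score columns.  It
is an explicit in-repo stand-in for MUSCLE/MAFFT-class aligners: adequate
for the family sizes handled here, with aligned-FASTA import offered so an
external alignment can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage

from ._kernels import gotoh_fill

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
# Dense lookup over our 21-letter alphabet (includes X).
BLOSUM62 = np.zeros((21, 21))
for _a, _i in _AA_INDEX.items():
    for _b, _j in _AA_INDEX.items():
        BLOSUM62[_i, _j] = _BLOSUM62[_a][_b]

GAP = "-"


class AlignmentError(ValueError):
    pass


def encode(seq: str) -> np.ndarray:
    """Encode an uppercase protein string as alphabet indices."""
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise AlignmentError(f"unknown residue {exc.args[0]!r}") from None


@dataclass(frozen=True)
class Alignment:
    """A pairwise alignment: two gap-extended rows plus the DP score."""

    rows: tuple[str, str]
    score: float
    kind: str  # "local" | "global"

    def __post_init__(self) -> None:
        if len(self.rows[0]) != len(self.rows[1]):
            raise AlignmentError("alignment rows differ in length")


def _traceback(a, b, S, H, E, F, gap_open, gap_extend, local):
    """Recover one optimal path; ties prefer diagonal > up > left."""
    n, m = len(a), len(b)
    if local:
        # End at the maximal H cell (first by row, then column on ties).
        best, bi, bj = 0.0, 0, 0
        for i in range(n + 1):
            for j in range(m + 1):
                if H[i, j] > best + 1e-12:
                    best, bi, bj = H[i, j], i, j
        i, j = bi, bj
    else:
        i, j = n, m
    ra: list[str] = []
    rb: list[str] = []
    state = "H"
    while True:
        if local and (H[i, j] <= 1e-12 and state == "H"):
            break
        if not local and i == 0 and j == 0:
            break
        if state == "H":
            if i > 0 and j > 0 and abs(
                H[i, j] - (H[i - 1, j - 1] + S[i - 1, j - 1])
            ) < 1e-9:
                ra.append(a[i - 1])
                rb.append(b[j - 1])
                i -= 1
                j -= 1
                continue
            if abs(H[i, j] - F[i, j]) < 1e-9 and i > 0:
                state = "F"
                continue
            if abs(H[i, j] - E[i, j]) < 1e-9 and j > 0:
                state = "E"
                continue
            raise AssertionError("traceback dead end")
        if state == "F":  # gap in b, consume a_i ("up")
            ra.append(a[i - 1])
            rb.append(GAP)
            opened = abs(F[i, j] - (H[i - 1, j] - gap_open - gap_extend)) < 1e-9
            i -= 1
            state = "H" if opened else "F"
            continue
        # state == "E": gap in a, consume b_j ("left")
        ra.append(GAP)
        rb.append(b[j - 1])
        opened = abs(E[i, j] - (H[i, j - 1] - gap_open - gap_extend)) < 1e-9
        j -= 1
        state = "H" if opened else "E"
    return "".join(reversed(ra)), "".join(reversed(rb))


def _pair_align(a: str, b: str, gap_open: float, gap_extend: float, local: bool
                ) -> Alignment:
    if not a or not b:
        raise AlignmentError("empty sequence")
    ea, eb = encode(a), encode(b)
    S = BLOSUM62[np.ix_(ea, eb)]
    H, E, F = gotoh_fill(S, gap_open, gap_extend, local)
    if local:
        score = float(H.max())
        if score <= 0.0:
            return Alignment(rows=("", ""), score=0.0, kind="local")
    else:
        score = float(H[len(a), len(b)])
    ra, rb = _traceback(a, b, S, H, E, F, gap_open, gap_extend, local)
    return Alignment(rows=(ra, rb), score=score, kind="local" if local else "global")


def smith_waterman(a: str, b: str, gap_open: float = 11.0,
                   gap_extend: float = 1.0) -> Alignment:
    """Optimal local alignment under affine gaps (score >= 0)."""
    return _pair_align(a, b, gap_open, gap_extend, local=True)


def needleman_wunsch(a: str, b: str, gap_open: float = 11.0,
                     gap_extend: float = 1.0) -> Alignment:
    """Optimal global alignment under affine gaps."""
    return _pair_align(a, b, gap_open, gap_extend, local=False)


def percent_identity(aln: Alignment) -> float:
    """100 x identical columns / alignment length (gaps in denominator)."""
    length = len(aln.rows[0])
    if length == 0:
        raise AlignmentError("percent identity undefined for empty alignment")
    ident = sum(
        1 for x, y in zip(*aln.rows) if x == y and x != GAP
    )
    return 100.0 * ident / length


def global_identity(a: str, b: str) -> float:
    """Percent identity of the global alignment of two sequences."""
    return percent_identity(needleman_wunsch(a, b))


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - |shared k-mers| / |smaller k-mer set|; identical sequences -> 0."""
    if a == b:
        return 0.0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


@dataclass
class MSA:
    """A multiple sequence alignment: ordered ids and equal-length rows."""

    ids: list[str]
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(self.rows[i]) for i in self.ids}
        if len(lengths) > 1:
            raise AlignmentError("MSA rows differ in length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[self.ids[0]]) if self.ids else 0

    @property
    def n_rows(self) -> int:
        return len(self.ids)

    def degapped(self, seq_id: str) -> str:
        return self.rows[seq_id].replace(GAP, "")

    def column(self, j: int) -> str:
        return "".join(self.rows[i][j] for i in self.ids)

    def subset(self, keep_ids) -> "MSA":
        keep = [i for i in self.ids if i in set(keep_ids)]
        return MSA(ids=keep, rows={i: self.rows[i] for i in keep})


def read_fasta_msa(path) -> MSA:
    ids, rows = [], {}
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows[rec.id] = str(rec.seq).upper()
    return MSA(ids=ids, rows=rows)


def write_fasta_msa(msa: MSA, path) -> None:
    with open(path, "w") as fh:
        for sid in msa.ids:
            fh.write(f">{sid}\n{msa.rows[sid]}\n")


def _profile(block_ids: list[str], rows: dict[str, str]) -> np.ndarray:
    """Column frequency profile over the 21-letter alphabet (gaps drop mass)."""
    n_cols = len(rows[block_ids[0]])
    prof = np.zeros((n_cols, 21))
    for sid in block_ids:
        row = rows[sid]
        for j, c in enumerate(row):
            if c != GAP:
                prof[j, _AA_INDEX[c]] += 1.0
    return prof / len(block_ids)


def _merge_blocks(ids_a, ids_b, rows, gap_open, gap_extend):
    """Align two aligned blocks by global affine profile-profile DP."""
    pa = _profile(ids_a, rows)
    pb = _profile(ids_b, rows)
    S = pa @ BLOSUM62 @ pb.T
    H, E, F = gotoh_fill(S, gap_open, gap_extend, False)
    # Reuse the sequence traceback with dummy strings of matching lengths.
    a_key = "".join("A" for _ in range(pa.shape[0]))
    b_key = "".join("A" for _ in range(pb.shape[0]))
    ra, rb = _traceback(a_key, b_key, S, H, E, F, gap_open, gap_extend, False)
    new_rows = {}
    for sid in ids_a:
        old = rows[sid]
        it = iter(old)
        new_rows[sid] = "".join(next(it) if c != GAP else GAP for c in ra)
    for sid in ids_b:
        old = rows[sid]
        it = iter(old)
        new_rows[sid] = "".join(next(it) if c != GAP else GAP for c in rb)
    return ids_a + ids_b, new_rows


def progressive_msa(seqs: dict[str, str], k: int = 3, gap_open: float = 11.0,
                    gap_extend: float = 1.0) -> MSA:
    """Progressive multiple alignment along a UPGMA k-mer guide tree.

    Deterministic given input order: ids are sorted internally, distance
    ties broken by scipy's stable agglomeration order, DP ties by the
    diagonal > up > left rule.
    """
    ids = sorted(seqs)
    if len(ids) < 2:
        raise AlignmentError("progressive_msa needs >= 2 sequences")
    for sid in ids:
        if not seqs[sid]:
            raise AlignmentError(f"empty sequence {sid}")
    n = len(ids)
    cond = []
    for i in range(n):
        for j in range(i + 1, n):
            cond.append(kmer_distance(seqs[ids[i]], seqs[ids[j]], k))
    Z = linkage(np.array(cond), method="average")
    blocks: dict[int, list[str]] = {i: [ids[i]] for i in range(n)}
    rows: dict[str, str] = {sid: seqs[sid] for sid in ids}
    for step, (ia, ib, _d, _cnt) in enumerate(Z):
        ids_a = blocks.pop(int(ia))
        ids_b = blocks.pop(int(ib))
        merged_ids, merged_rows = _merge_blocks(
            ids_a, ids_b, rows, gap_open, gap_extend
        )
        rows.update(merged_rows)
        blocks[n + step] = merged_ids
    (final_ids,) = blocks.values()
    msa = MSA(ids=sorted(final_ids), rows={i: rows[i] for i in final_ids})
    # Invariant: every row degaps back to its input sequence.
    for sid in msa.ids:
        assert msa.degapped(sid) == seqs[sid]
    return msa


def curate_by_motif_columns(msa: MSA, residue: str = "C", n_cols: int = 2
                            ) -> tuple[MSA, list[str]]:
    """Automated motif-column curation of an alignment.

    Finds the ``n_cols`` columns with the highest frequency of ``residue``
    (ties -> leftmost) and removes rows lacking the residue in any of them.
    This automates the by-eye pruning of a cysteine-motif alignment: a row
    whose motif cysteines do not align with the family's conserved
    cysteine columns is dropped.
    """
    if msa.n_rows == 0 or msa.n_cols == 0:
        return msa, []
    freqs = []
    for j in range(msa.n_cols):
        col = msa.column(j)
        freqs.append(sum(1 for c in col if c == residue) / msa.n_rows)
    order = sorted(range(msa.n_cols), key=lambda j: (-freqs[j], j))
    top = order[:n_cols]
    removed = [
        sid for sid in msa.ids if any(msa.rows[sid][j] != residue for j in top)
    ]
    kept = msa.subset([sid for sid in msa.ids if sid not in set(removed)])
    return kept, removed


def column_information(msa: MSA) -> list[float]:
    """Per-column information content in bits (gaps excluded from counts).

    IC = log2(20) - H(column); an all-gap column scores 0.
    """
    out = []
    max_bits = np.log2(20.0)
    for j in range(msa.n_cols):
        col = [c for c in msa.column(j) if c != GAP]
        if not col:
            out.append(0.0)
            continue
        _vals, counts = np.unique(np.array(col), return_counts=True)
        p = counts / counts.sum()
        entropy = float(-(p * np.log2(p)).sum())
        out.append(float(max_bits - entropy))
    return out
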