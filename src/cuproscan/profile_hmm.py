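"""Profile HMMs: construction, scoring, E-value calibration, iterative search.

The model is a standard match/insert/delete profile HMM built from a
multiple alignment (match columns = columns with gap fraction below a
threshold; Laplace pseudocounts).  Scoring is glocal — global in the
profile, local in the sequence, with flanking residues emitted free at
background — and reported as log-odds bits against the background model.
E-values come from a Gumbel null fitted to scores of random background
sequences.  ``iterative_search`` is the jackhmmer-style loop: build,
calibrate, search, admit new members, re-align, repeat to convergence,
then remove every member annotated with any known Pfam-style domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gumbel_r

from ._kernels import NEG_INF, hmm_score
from .alignment import ALPHABET, GAP, MSA, encode, progressive_msa
from .genome_model import DomainHit, GenomeSet

N_AA = 20
# transition column order in the (M+1, 7) table
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)


class CalibrationError(RuntimeError):
    pass


@dataclass
class ProfileHMM:
    """Profile HMM parameters plus optional Gumbel calibration (mu, lambda)."""

    M: int
    match_emissions: np.ndarray  # (M+1, 20) probabilities; row 0 unused
    insert_emissions: np.ndarray  # (M+1, 20); row j = I_j
    transitions: np.ndarray  # (M+1, 7) probabilities; row j = out of node j
    background: np.ndarray  # (20,)
    calibration: tuple[float, float] | None = None

    # cached log-odds tables for the scoring kernel
    _lm: np.ndarray | None = field(default=None, repr=False)
    _li: np.ndarray | None = field(default=None, repr=False)
    _lt: np.ndarray | None = field(default=None, repr=False)

    def validate(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        for j in range(1, self.M + 1):
            if abs(self.match_emissions[j].sum() - 1.0) > 1e-9:
                raise ValueError(f"match emissions of node {j} not normalized")
        for j in range(self.M + 1):
            if abs(self.insert_emissions[j].sum() - 1.0) > 1e-9:
                raise ValueError(f"insert emissions of node {j} not normalized")
        for j in range(self.M + 1):
            for group in ((T_MM, T_MI, T_MD), (T_IM, T_II), (T_DM, T_DD)):
                s = self.transitions[j, list(group)].sum()
                if s > 0 and abs(s - 1.0) > 1e-9:
                    raise ValueError(f"transition group {group} of node {j}: {s}")
        if self.calibration is not None and self.calibration[1] <= 0:
            raise ValueError("calibrated lambda must be > 0")

    def _tables(self):
        if self._lm is None:
            with np.errstate(divide="ignore"):
                lm = np.full((self.M + 1, 21), 0.0)
                lm[:, :N_AA] = np.log2(
                    np.where(self.match_emissions > 0, self.match_emissions, 1e-300)
                ) - np.log2(self.background)[None, :]
                lm[0, :] = NEG_INF
                lm[:, 20] = 0.0  # X scores as background
                li = np.zeros((self.M + 1, 21))
                li[:, :N_AA] = np.log2(
                    np.where(self.insert_emissions > 0, self.insert_emissions, 1e-300)
                ) - np.log2(self.background)[None, :]
                li[:, 20] = 0.0
                lt = np.where(
                    self.transitions > 0, np.log2(
                        np.where(self.transitions > 0, self.transitions, 1.0)
                    ), NEG_INF,
                )
            self._lm, self._li, self._lt = lm, li, lt
        return self._lm, self._li, self._lt


def _match_columns(msa: MSA, match_gap_frac: float) -> list[int]:
    cols = []
    for j in range(msa.n_cols):
        col = msa.column(j)
        if col.count(GAP) / len(col) < match_gap_frac:
            cols.append(j)
    return cols


def build_hmm(msa: MSA, match_gap_frac: float = 0.5, pseudocount: float = 1.0,
              background: np.ndarray | None = None) -> ProfileHMM:
    """Build a profile HMM from an alignment.

    Match states are the columns whose gap fraction is below
    ``match_gap_frac``; Laplace pseudocounts are added to every emission
    and transition count before normalization.
    """
    if msa.n_rows < 2:
        raise ValueError("build_hmm needs an MSA with >= 2 rows")
    match_cols = _match_columns(msa, match_gap_frac)
    if not match_cols:
        raise ValueError("no column qualifies as a match state")
    M = len(match_cols)
    node_of_col = {c: k + 1 for k, c in enumerate(match_cols)}
    bg = (np.full(N_AA, 1.0 / N_AA) if background is None
          else np.asarray(background, dtype=float))

    me = np.full((M + 1, N_AA), pseudocount)
    ie = np.full((M + 1, N_AA), pseudocount)
    tc = np.full((M + 1, 7), pseudocount)
    me[0, :] = 0.0

    aa_index = {aa: i for i, aa in enumerate(ALPHABET[:N_AA])}
    for sid in msa.ids:
        row = msa.rows[sid]
        prev_state, prev_node = "M", 0  # begin acts as M_0
        for j, c in enumerate(row):
            if j in node_of_col:
                node = node_of_col[j]
                if c == GAP:
                    state = "D"
                else:
                    state = "M"
                    if c in aa_index:
                        me[node, aa_index[c]] += 1.0
                if prev_state == "M" and state == "M":
                    tc[prev_node, T_MM] += 1.0
                elif prev_state == "M" and state == "D":
                    tc[prev_node, T_MD] += 1.0
                elif prev_state == "I" and state == "M":
                    tc[prev_node, T_IM] += 1.0
                elif prev_state == "I" and state == "D":
                    # I->D is not modelled; count as I->M (textbook collapse)
                    tc[prev_node, T_IM] += 1.0
                elif prev_state == "D" and state == "M":
                    tc[prev_node, T_DM] += 1.0
                elif prev_state == "D" and state == "D":
                    tc[prev_node, T_DD] += 1.0
                prev_state, prev_node = state, node
            else:
                if c == GAP:
                    continue
                if c in aa_index:
                    ie[prev_node, aa_index[c]] += 1.0
                if prev_state == "M":
                    tc[prev_node, T_MI] += 1.0
                elif prev_state == "I":
                    tc[prev_node, T_II] += 1.0
                else:  # D -> I not modelled; treat as D->M->I approximation
                    tc[prev_node, T_MI] += 1.0
                prev_state = "I"
        # exit to End; every row finishes at node M (as M, I_M or D)
        if prev_state == "M":
            tc[M, T_MM] += 1.0
        elif prev_state == "I":
            tc[M, T_IM] += 1.0
        else:
            tc[M, T_DM] += 1.0

    me[1:] /= me[1:].sum(axis=1, keepdims=True)
    ie /= ie.sum(axis=1, keepdims=True)
    tr = np.zeros_like(tc)
    for j in range(M + 1):
        groups = [(T_MM, T_MI, T_MD), (T_IM, T_II), (T_DM, T_DD)]
        if j == M:
            groups = [(T_MM, T_MI), (T_IM, T_II), (T_DM,)]
        if j == 0:
            groups = [(T_MM, T_MI, T_MD), (T_IM, T_II)]
        for group in groups:
            idx = list(group)
            s = tc[j, idx].sum()
            tr[j, idx] = tc[j, idx] / s
    hmm = ProfileHMM(
        M=M, match_emissions=me, insert_emissions=ie, transitions=tr,
        background=bg,
    )
    hmm.validate()
    return hmm


def viterbi_score(hmm: ProfileHMM, seq: str) -> float:
    """Best-path log-odds score in bits."""
    if not seq:
        raise ValueError("empty sequence")
    lm, li, lt = hmm._tables()
    return float(hmm_score(lm, li, lt, encode(seq), True))


def forward_score(hmm: ProfileHMM, seq: str) -> float:
    """All-paths log-odds score in bits (>= Viterbi for every input)."""
    if not seq:
        raise ValueError("empty sequence")
    lm, li, lt = hmm._tables()
    return float(hmm_score(lm, li, lt, encode(seq), False))


def sample_background(rng: np.random.Generator, length: int,
                      background: np.ndarray) -> str:
    letters = np.array(list(ALPHABET[:N_AA]))
    return "".join(rng.choice(letters, size=length, p=background))


def calibrate(
    hmm: ProfileHMM,
    n_random: int = 1000,
    length_model: int | tuple[int, int] = (50, 400),
    seed: int = 0,
) -> tuple[float, float]:
    """Fit a Gumbel null (mu, lambda) to Viterbi scores of random sequences.

    ``length_model`` is a fixed length or an inclusive uniform range for
    the background sequences.  The fit is the scipy maximum-likelihood
    Gumbel fit; lambda is the inverse scale.  Stored on the model.
    """
    if n_random < 100:
        raise CalibrationError("n_random < 100 gives an unstable Gumbel fit")
    rng = np.random.default_rng(seed)
    if isinstance(length_model, int):
        lengths = np.full(n_random, length_model)
    else:
        lo, hi = length_model
        lengths = rng.integers(lo, hi + 1, size=n_random)
    scores = np.array([
        viterbi_score(hmm, sample_background(rng, int(ln), hmm.background))
        for ln in lengths
    ])
    loc, scale = gumbel_r.fit(scores)
    hmm.calibration = (float(loc), 1.0 / float(scale))
    return hmm.calibration


def score_pvalue(hmm: ProfileHMM, score: float) -> float:
    """P(S >= score) under the fitted Gumbel null."""
    if hmm.calibration is None:
        raise CalibrationError("model is not calibrated; run calibrate() first")
    mu, lam = hmm.calibration
    return float(-math.expm1(-math.exp(-lam * (score - mu))))


def evalue(hmm: ProfileHMM, score: float, n_database: int) -> float:
    """Expected number of scores >= ``score`` in a database of given size."""
    return n_database * score_pvalue(hmm, score)


@dataclass(frozen=True)
class SearchHit:
    target_id: str
    bit_score: float
    evalue: float
    iteration_found: int = 0


@dataclass
class FamilySet:
    """Cumulative family membership across search iterations."""

    members_by_iteration: list[set[str]]
    converged: bool
    iterations_run: int
    final_members: set[str]
    removed_by_domain: set[str] = field(default_factory=set)
    hits: list[SearchHit] = field(default_factory=list)


def _database_dict(database) -> dict[str, str]:
    if isinstance(database, GenomeSet):
        return {gid: g.protein for gid, g in database.genes.items()}
    return dict(database)


def search(hmm: ProfileHMM, database, evalue_include: float = 0.01,
           iteration: int = 0) -> list[SearchHit]:
    """Score every database protein; keep hits with E <= evalue_include."""
    seqs = _database_dict(database)
    n = len(seqs)
    hits = []
    for tid in sorted(seqs):
        s = viterbi_score(hmm, seqs[tid])
        e = evalue(hmm, s, n)
        if e <= evalue_include:
            hits.append(SearchHit(tid, s, e, iteration))
    hits.sort(key=lambda h: (h.evalue, h.target_id))
    return hits


def iterative_search(
    seed_msa: MSA,
    database,
    domain_hits: list[DomainHit],
    max_iter: int = 11,
    evalue_include: float = 0.01,
    domain_evalue_max: float = 1e-5,
    calibrate_n: int = 1000,
    seed: int = 0,
) -> FamilySet:
    """Jackhmmer-style iterative family expansion with final Pfam removal.

    Each iteration builds a profile HMM from the current member alignment,
    calibrates it on random background sequences, searches the database,
    and admits hits at E <= ``evalue_include``; members are then re-aligned
    and the loop repeats until an iteration adds nothing (converged) or
    ``max_iter`` is reached.  Afterwards, every member carrying any domain
    annotation at E <= ``domain_evalue_max`` is removed.
    """
    seqs = _database_dict(database)
    # membership is defined by search hits: the first iteration re-finds
    # the seeds, the second confirms convergence on a seeds-only database
    family: set[str] = set()
    msa = seed_msa
    members_by_iteration: list[set[str]] = []
    all_hits: list[SearchHit] = []
    converged = False
    iterations = 0
    for it in range(1, max_iter + 1):
        iterations = it
        hmm = build_hmm(msa)
        calibrate(hmm, n_random=calibrate_n, seed=seed * 1000 + it)
        hits = search(hmm, seqs, evalue_include=evalue_include, iteration=it)
        all_hits.extend(h for h in hits if h.target_id not in family)
        new = {h.target_id for h in hits} - family
        family |= new
        members_by_iteration.append(set(family))
        if not new:
            converged = True
            break
        member_seqs = {
            mid: (seqs[mid] if mid in seqs else msa.degapped(mid))
            for mid in family
        }
        msa = progressive_msa(member_seqs)
    annotated = {
        h.gene_id for h in domain_hits if h.evalue <= domain_evalue_max
    }
    removed = family & annotated
    return FamilySet(
        members_by_iteration=members_by_iteration,
        converged=converged,
        iterations_run=iterations,
        final_members=family - removed,
        removed_by_domain=removed,
        hits=all_hits,
    )


def write_hmm(hmm: ProfileHMM, path) -> None:
    """Serialize the model as a documented plain-text table."""
    with open(path, "w") as fh:
        fh.write(f"# cuproscan profile HMM, M={hmm.M}\n")
        if hmm.calibration:
            fh.write(f"CALIBRATION\t{float(hmm.calibration[0])!r}\t{float(hmm.calibration[1])!r}\n")
        fh.write("BACKGROUND\t" + "\t".join(repr(float(x)) for x in hmm.background) + "\n")
        for j in range(hmm.M + 1):
            fh.write(f"MATCH\t{j}\t" + "\t".join(
                repr(float(x)) for x in hmm.match_emissions[j]) + "\n")
            fh.write(f"INSERT\t{j}\t" + "\t".join(
                repr(float(x)) for x in hmm.insert_emissions[j]) + "\n")
            fh.write(f"TRANS\t{j}\t" + "\t".join(
                repr(float(x)) for x in hmm.transitions[j]) + "\n")


def read_hmm(path) -> ProfileHMM:
    match_rows, insert_rows, trans_rows = {}, {}, {}
    background = None
    calibration = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "CALIBRATION":
                calibration = (float(parts[1]), float(parts[2]))
            elif parts[0] == "BACKGROUND":
                background = np.array([float(x) for x in parts[1:]])
            else:
                j = int(parts[1])
                vals = np.array([float(x) for x in parts[2:]])
                {"MATCH": match_rows, "INSERT": insert_rows,
                 "TRANS": trans_rows}[parts[0]][j] = vals
    M = max(match_rows)
    hmm = ProfileHMM(
        M=M,
        match_emissions=np.vstack([match_rows[j] for j in range(M + 1)]),
        insert_emissions=np.vstack([insert_rows[j] for j in range(M + 1)]),
        transitions=np.vstack([trans_rows[j] for j in range(M + 1)]),
        background=background,
        calibration=calibration,
    )
    return hmm


def hits_to_rows(hits: list[SearchHit]) -> list[dict]:
    return [
        {"target_id": h.target_id, "bit_score": h.bit_score,
         "evalue": h.evalue, "iteration_found": h.iteration_found}
        for h in hits
    ]
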