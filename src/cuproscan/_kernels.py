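"""Numba dynamic-programming kernels shared by alignment and profile-HMM scoring.

All kernels operate on pre-encoded integer sequences / pre-computed score
matrices so the same affine-gap Gotoh recursion serves sequence-sequence
and profile-profile alignment.  Log-space is base 2 throughout (bits).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -1e30


@njit(cache=True)
def gotoh_fill(S, gap_open, gap_extend, local):
    """Affine-gap DP fill over a position score matrix S (n x m).

    Returns (H, E, F) matrices of shape (n+1, m+1).  Gap of length k costs
    gap_open + k * gap_extend.  ``local`` floors H at zero (Smith-Waterman);
    otherwise the recursion is global (Needleman-Wunsch/Gotoh).
    """
    n, m = S.shape
    H = np.full((n + 1, m + 1), NEG_INF)
    E = np.full((n + 1, m + 1), NEG_INF)  # gap in first sequence (horizontal)
    F = np.full((n + 1, m + 1), NEG_INF)  # gap in second sequence (vertical)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        if local:
            H[0, j] = 0.0
        else:
            E[0, j] = -(gap_open + j * gap_extend)
            H[0, j] = E[0, j]
    for i in range(1, n + 1):
        if local:
            H[i, 0] = 0.0
        else:
            F[i, 0] = -(gap_open + i * gap_extend)
            H[i, 0] = F[i, 0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = max(H[i, j - 1] - (gap_open + gap_extend),
                    E[i, j - 1] - gap_extend)
            f = max(H[i - 1, j] - (gap_open + gap_extend),
                    F[i - 1, j] - gap_extend)
            h = H[i - 1, j - 1] + S[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            if local and h < 0.0:
                h = 0.0
            E[i, j] = e
            F[i, j] = f
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def hmm_score(lm, li, tr, seq, viterbi):
    """Glocal profile-HMM score of ``seq`` in bits.

    lm: (M+1, A) match log-odds emissions (row 0 unused);
    li: (M+1, A) insert log-odds emissions (row j = insert state I_j);
    tr: (M+1, 7) log2 transitions [MM, MI, MD, IM, II, DM, DD], where row j
    holds transitions out of node j (node 0 = begin; row M's MM/IM/DM lead
    to the end state).  The model is global in the profile and local in the
    sequence: flanking residues are emitted by free N/C states at 0 bits.

    viterbi=True -> max over paths; False -> log-sum (forward).
    """
    M = lm.shape[0] - 1
    L = seq.shape[0]
    # v[j] for states at current sequence position; row 0 of vm acts as B.
    vm_prev = np.full(M + 1, NEG_INF)
    vi_prev = np.full(M + 1, NEG_INF)
    vd_prev = np.full(M + 1, NEG_INF)
    vm = np.full(M + 1, NEG_INF)
    vi = np.full(M + 1, NEG_INF)
    vd = np.full(M + 1, NEG_INF)

    # position i = 0 (no residues consumed): B plus silent D-chain.
    vm_prev[0] = 0.0  # begin state, flank free
    for j in range(1, M + 1):
        prev = j - 1
        best = vm_prev[prev] + tr[prev, 2]  # M/B -> D
        alt = vd_prev[prev] + tr[prev, 6]  # D -> D
        if viterbi:
            if alt > best:
                best = alt
        else:
            best = np.logaddexp2(best, alt)
        vd_prev[j] = best

    total = NEG_INF
    # exit at position 0 (empty-sequence path through deletes)
    e0 = max(vm_prev[M] + tr[M, 0], vd_prev[M] + tr[M, 5])
    if not viterbi:
        e0 = np.logaddexp2(vm_prev[M] + tr[M, 0], vd_prev[M] + tr[M, 5])
    e0_i = np.logaddexp2(e0, vi_prev[M] + tr[M, 3]) if not viterbi else max(
        e0, vi_prev[M] + tr[M, 3])
    total = e0_i

    for i in range(1, L + 1):
        x = seq[i - 1]
        vm[0] = 0.0  # begin reachable after i flank residues, free
        vi[0] = NEG_INF
        vd[0] = NEG_INF
        # I_0 .. I_M first need M row; compute in node order.
        for j in range(1, M + 1):
            p = j - 1
            a = vm_prev[p] + tr[p, 0]
            b = vi_prev[p] + tr[p, 3]
            c = vd_prev[p] + tr[p, 5]
            if viterbi:
                best = a
                if b > best:
                    best = b
                if c > best:
                    best = c
            else:
                best = np.logaddexp2(np.logaddexp2(a, b), c)
            vm[j] = best + lm[j, x]
            # delete (silent, same position i)
            a = vm[p] + tr[p, 2]
            b = vd[p] + tr[p, 6]
            if viterbi:
                best = a if a > b else b
            else:
                best = np.logaddexp2(a, b)
            vd[j] = best
        for j in range(0, M + 1):
            a = vm_prev[j] + tr[j, 1]
            b = vi_prev[j] + tr[j, 4]
            if viterbi:
                best = a if a > b else b
            else:
                best = np.logaddexp2(a, b)
            vi[j] = best + li[j, x]
        # exit after consuming i residues (C flank free for the rest)
        a = vm[M] + tr[M, 0]
        b = vd[M] + tr[M, 5]
        c = vi[M] + tr[M, 3]
        if viterbi:
            e = a
            if b > e:
                e = b
            if c > e:
                e = c
            if e > total:
                total = e
        else:
            e = np.logaddexp2(np.logaddexp2(a, b), c)
            total = np.logaddexp2(total, e)
        vm_prev, vm = vm, vm_prev
        vi_prev, vi = vi, vi_prev
        vd_prev, vd = vd, vd_prev
    return total
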