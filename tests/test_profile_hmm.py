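"""Profile-HMM construction, scoring oracles, calibration, iterative search."""

import numpy as np
import pytest

from cuproscan import profile_hmm as ph
from cuproscan.alignment import MSA
from cuproscan.genome_model import DomainHit

BITS = np.log2


def single_state_hmm(emit_letter="A"):
    """One match state emitting a single residue with probability 1."""
    idx = "ACDEFGHIKLMNPQRSTVWY".index(emit_letter)
    me = np.zeros((2, 20))
    me[1, idx] = 1.0
    ie = np.full((2, 20), 1 / 20)
    tr = np.zeros((2, 7))
    tr[0, ph.T_MM] = 1.0
    tr[0, ph.T_IM] = 1.0
    tr[1, ph.T_MM] = 1.0
    tr[1, ph.T_IM] = 1.0
    tr[1, ph.T_DM] = 1.0
    return ph.ProfileHMM(M=1, match_emissions=me, insert_emissions=ie,
                         transitions=tr, background=np.full(20, 1 / 20))


def random_hmm(rng, M):
    """A random, fully normalized model with all transitions possible."""
    me = rng.dirichlet(np.ones(20), size=M + 1)
    ie = rng.dirichlet(np.ones(20), size=M + 1)
    tr = np.zeros((M + 1, 7))
    for j in range(M + 1):
        tr[j, [ph.T_MM, ph.T_MI, ph.T_MD]] = rng.dirichlet(np.ones(3))
        tr[j, [ph.T_IM, ph.T_II]] = rng.dirichlet(np.ones(2))
        tr[j, [ph.T_DM, ph.T_DD]] = rng.dirichlet(np.ones(2))
    if M >= 1:
        tr[M, [ph.T_MM, ph.T_MI]] = rng.dirichlet(np.ones(2))
        tr[M, ph.T_MD] = 0.0
        tr[M, ph.T_DM] = 1.0
        tr[M, ph.T_DD] = 0.0
    hmm = ph.ProfileHMM(M=M, match_emissions=me, insert_emissions=ie,
                        transitions=tr, background=np.full(20, 1 / 20))
    hmm.validate()
    return hmm


def enumerate_path_scores(hmm, seq):
    """Explicit enumeration of every glocal state path (log-odds bits).

    Independent of the DP kernel: recursion over node/state/position with
    flanking residues split off explicitly.
    """
    lm, li, tr = hmm._tables()
    encoded = [("ACDEFGHIKLMNPQRSTVWYX").index(c) for c in seq]
    M = hmm.M
    out = []

    def rec(node, state, pos, acc, mid):
        if node == M and pos == len(mid):
            t_exit = {"M": tr[M, ph.T_MM], "I": tr[M, ph.T_IM],
                      "D": tr[M, ph.T_DM]}[state]
            if t_exit > -1e29:
                out.append(acc + t_exit)
        if pos < len(mid):
            t_ins = {"M": tr[node, ph.T_MI], "I": tr[node, ph.T_II]}.get(state)
            if t_ins is not None and t_ins > -1e29:
                rec(node, "I", pos + 1, acc + t_ins + li[node, mid[pos]], mid)
        if node < M:
            t_m = {"M": tr[node, ph.T_MM], "I": tr[node, ph.T_IM],
                   "D": tr[node, ph.T_DM]}[state]
            if pos < len(mid) and t_m > -1e29:
                rec(node + 1, "M", pos + 1,
                    acc + t_m + lm[node + 1, mid[pos]], mid)
            t_d = {"M": tr[node, ph.T_MD], "D": tr[node, ph.T_DD]}.get(state)
            if t_d is not None and t_d > -1e29:
                rec(node + 1, "D", pos, acc + t_d, mid)

    L = len(encoded)
    for s in range(L + 1):
        for e in range(L - s + 1):
            rec(0, "M", 0, 0.0, encoded[s : L - e])
    return out


class TestScoringOracles:
    def test_single_state_closed_form(self):
        hmm = single_state_hmm("A")
        assert ph.viterbi_score(hmm, "A") == pytest.approx(BITS(20))
        assert ph.forward_score(hmm, "A") == pytest.approx(BITS(20))

    def test_viterbi_and_forward_match_path_enumeration(self):
        rng = np.random.default_rng(3)
        letters = list("ACDEFGHIKL")
        for M in (1, 2, 3):
            for _ in range(8):
                hmm = random_hmm(rng, M)
                for L in (1, 2, 3, 4):
                    seq = "".join(rng.choice(letters, size=L))
                    scores = enumerate_path_scores(hmm, seq)
                    assert ph.viterbi_score(hmm, seq) == pytest.approx(
                        max(scores), abs=1e-9)
                    forward = BITS(np.sum(np.exp2(scores)))
                    assert ph.forward_score(hmm, seq) == pytest.approx(
                        forward, abs=1e-9)

    def test_forward_dominates_viterbi(self):
        rng = np.random.default_rng(4)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(60):
            hmm = random_hmm(rng, int(rng.integers(1, 6)))
            seq = "".join(rng.choice(letters, size=rng.integers(1, 15)))
            assert ph.forward_score(hmm, seq) >= ph.viterbi_score(hmm, seq) - 1e-9


class TestBuildHMM:
    def test_gapless_two_row_msa(self):
        msa = MSA(ids=["a", "b"], rows={"a": "MKACD", "b": "MKACD"})
        assert ph.build_hmm(msa).M == 5

    def test_gappy_column_becomes_insert(self):
        rows = {"a": "M-KAC", "b": "M-KAC", "c": "MWKAC", "d": "M-KAC",
                "e": "M-KAC"}
        msa = MSA(ids=list(rows), rows=rows)
        assert ph.build_hmm(msa, match_gap_frac=0.5).M == 4

    def test_normalization_invariant_on_random_msas(self):
        rng = np.random.default_rng(5)
        letters = list("ACDEFG-")
        for _ in range(10):
            n, L = int(rng.integers(2, 6)), int(rng.integers(3, 12))
            rows = {}
            for i in range(n):
                row = "".join(rng.choice(letters, size=L))
                if set(row) == {"-"}:
                    row = "A" * L
                rows[f"s{i}"] = row
            msa = MSA(ids=sorted(rows), rows=rows)
            try:
                hmm = ph.build_hmm(msa)
            except ValueError:
                continue  # all columns gappy: no match state, by contract
            hmm.validate()  # sums to 1 within 1e-9

    def test_no_match_column_is_error(self):
        msa = MSA(ids=["a", "b", "c"], rows={"a": "A-", "b": "--", "c": "--"})
        with pytest.raises(ValueError):
            ph.build_hmm(msa, match_gap_frac=0.3)


class TestCalibration:
    def test_gumbel_parameter_recovery(self):
        from scipy.stats import gumbel_r
        rng = np.random.default_rng(6)
        scores = gumbel_r.rvs(loc=3.0, scale=1 / 0.7, size=5000,
                              random_state=rng)
        loc, scale = gumbel_r.fit(scores)
        assert abs(loc - 3.0) / 3.0 < 0.05
        assert abs(1 / scale - 0.7) / 0.7 < 0.05

    def test_evalue_at_mu_is_gumbel_closed_form(self):
        hmm = single_state_hmm()
        ph.calibrate(hmm, n_random=200, length_model=(10, 30), seed=0)
        mu, _lam = hmm.calibration
        assert ph.evalue(hmm, mu, 1) == pytest.approx(1 - np.exp(-1))

    def test_evalues_monotone_decreasing_in_score(self):
        hmm = single_state_hmm()
        ph.calibrate(hmm, n_random=200, length_model=(10, 30), seed=0)
        es = [ph.evalue(hmm, s, 100) for s in np.linspace(-5, 20, 30)]
        assert all(a > b for a, b in zip(es, es[1:]))

    def test_too_few_samples_refused(self):
        with pytest.raises(ph.CalibrationError):
            ph.calibrate(single_state_hmm(), n_random=50)

    def test_uncalibrated_search_is_instructive_error(self):
        msa = MSA(ids=["a", "b"], rows={"a": "MKACD", "b": "MKACD"})
        hmm = ph.build_hmm(msa)
        with pytest.raises(ph.CalibrationError, match="calibrate"):
            ph.search(hmm, {"x": "MKACD"})


SEEDS = {
    "s1": "MKKLLLALLALLAVSAQADDEECAAHCEEDDAAEEDDPEPEGPPPRL",
    "s2": "MKKLLLALLALLAVSAQADDEECAAHCEEDDAAEEDDPEPEGPPPRL",
    "s3": "MKKLLLALLALLAVSAQADDEVCAAHCEEDDWAEEDDPEPEGPPPRL",
}


def seed_msa():
    return MSA(ids=sorted(SEEDS), rows=dict(SEEDS))


class TestSearch:
    def test_seeds_recover_themselves(self):
        msa = seed_msa()
        hmm = ph.build_hmm(msa)
        ph.calibrate(hmm, n_random=200, length_model=(30, 60), seed=0)
        hits = {h.target_id for h in ph.search(hmm, SEEDS)}
        assert hits == set(SEEDS)

    def test_empty_database(self):
        hmm = single_state_hmm()
        ph.calibrate(hmm, n_random=200, length_model=(10, 30), seed=0)
        assert ph.search(hmm, {}) == []


class TestIterativeSearch:
    def test_seeds_only_database_converges_in_two_iterations(self):
        fam = ph.iterative_search(seed_msa(), SEEDS, [], calibrate_n=200,
                                  seed=0)
        assert fam.converged
        assert fam.iterations_run == 2
        assert fam.final_members == set(SEEDS)

    def test_membership_monotone_and_bounded(self):
        fam = ph.iterative_search(seed_msa(), SEEDS, [], calibrate_n=200,
                                  seed=0)
        for a, b in zip(fam.members_by_iteration, fam.members_by_iteration[1:]):
            assert a <= b
        assert fam.iterations_run <= 11

    def test_domain_annotated_member_removed(self):
        database = dict(SEEDS)
        database["bad"] = SEEDS["s1"]  # scores as well as any seed
        hits = [DomainHit("bad", "PF00001", 1e-30)]
        fam = ph.iterative_search(seed_msa(), database, hits, calibrate_n=200,
                                  seed=0)
        assert "bad" in fam.removed_by_domain
        assert "bad" not in fam.final_members
        assert any("bad" in s for s in fam.members_by_iteration)

    def test_deterministic_given_seed(self):
        a = ph.iterative_search(seed_msa(), SEEDS, [], calibrate_n=200, seed=3)
        b = ph.iterative_search(seed_msa(), SEEDS, [], calibrate_n=200, seed=3)
        assert a.final_members == b.final_members
        assert a.members_by_iteration == b.members_by_iteration
        assert [h.bit_score for h in a.hits] == [h.bit_score for h in b.hits]


def test_hmm_serialization_round_trip(tmp_path):
    msa = seed_msa()
    hmm = ph.build_hmm(msa)
    ph.calibrate(hmm, n_random=200, length_model=(30, 60), seed=0)
    path = tmp_path / "model.hmm"
    ph.write_hmm(hmm, path)
    back = ph.read_hmm(path)
    back.validate()
    assert back.M == hmm.M
    np.testing.assert_array_equal(back.match_emissions, hmm.match_emissions)
    np.testing.assert_array_equal(back.transitions, hmm.transitions)
    assert back.calibration == hmm.calibration
    seq = "MKKLLLALLALLAVSAQA"
    assert ph.viterbi_score(back, seq) == ph.viterbi_score(hmm, seq)
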