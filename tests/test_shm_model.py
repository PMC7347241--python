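"""Pairwise SHM classification, T/H/M/S matrices, and the targeting model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectclone.grouping import VJLGroup, effective_germline
from spectclone.shm_model import (
    TargetingModel,
    TargetingModelError,
    classify_pair_mutations,
    damping_matrix,
    load_targeting_model,
    motif_mutability,
    mutation_matrices,
    shm_similarity,
)

from oracles import brute_group_matrices, brute_shm_similarity


def make_group(seqs, junction_span=(0, 0), alleles=None, germline=None):
    germline = germline or effective_germline(alleles or [seqs[0]])
    return VJLGroup(
        group_id="g0",
        member_ids=[f"s{i}" for i in range(len(seqs))],
        v_genes=frozenset({"V"}),
        j_genes=frozenset({"J"}),
        junction_length=junction_span[1] - junction_span[0],
        effective_germline=germline,
        germline_alleles=alleles or [germline],
        junction_span=junction_span,
    )


class TestTargetingModel:
    def test_uniform_covers_all_motifs(self):
        tm = TargetingModel.uniform(0.1)
        assert len(tm.mutability) == 4**5
        assert tm["AACGT"] == 0.1

    def test_missing_motif_is_zero(self):
        tm = TargetingModel({"AACGT": 0.2})
        assert tm["TTTTT"] == 0.0

    def test_out_of_range_rejected(self, tmp_path):
        path = tmp_path / "tm.tsv"
        path.write_text("motif\tmutability\nAACGT\t1.3\n")
        with pytest.raises(TargetingModelError):
            load_targeting_model(path)

    def test_file_load(self, tmp_path):
        path = tmp_path / "tm.tsv"
        path.write_text("motif\tmutability\nAACGT\t0.2\nTTTTT\t0.9\n")
        tm = load_targeting_model(path)
        assert tm["AACGT"] == 0.2 and tm["TTTTT"] == 0.9 and tm["ACGTA"] == 0.0


class TestMotifMutability:
    def test_uniform_center(self):
        assert motif_mutability(TargetingModel.uniform(0.1), "AAAAA", 2) == 0.1

    def test_iupac_ambiguity_averages(self):
        tm = TargetingModel({"AACAA": 0.2, "AATAA": 0.4})
        assert motif_mutability(tm, "AAYAA", 2) == pytest.approx(0.3)

    def test_window_off_edge_is_zero(self):
        assert motif_mutability(TargetingModel.uniform(0.5), "AAAAA", 0) == 0.0

    def test_n_in_window_is_zero(self):
        assert motif_mutability(TargetingModel.uniform(0.5), "AANAA", 2) == 0.0

    def test_gapped_germline_uses_stripped_coordinates(self):
        tm = TargetingModel({"ACGTA": 0.7})
        assert motif_mutability(tm, "AC..GTA", 2) == 0.7


class TestClassifyPair:
    def test_shared_and_single_mutation(self):
        prof = classify_pair_mutations("ACCTA", "ACCTG", "ACGTA")
        assert (prof.n_alpha, prof.n_beta, prof.n_gamma) == (1, 0, 1)
        assert prof.nu == 5.0
        assert prof.shared_positions == [2]

    def test_identical_to_germline_no_flags(self):
        prof = classify_pair_mutations("ACGTA", "ACGTA", "ACGTA")
        assert prof.n_alpha == prof.n_beta == prof.n_gamma == 0

    def test_two_unique_mutations_same_position(self):
        prof = classify_pair_mutations("AAGTA", "ATGTA", "ACGTA")
        assert (prof.n_alpha, prof.n_beta, prof.n_gamma) == (0, 1, 0)

    def test_iupac_germline_not_a_mutation(self):
        # Y covers C and T: neither sequence is mutated at position 1
        prof = classify_pair_mutations("ACGTA", "ATGTA", "AYGTA")
        assert prof.n_alpha == prof.n_beta == prof.n_gamma == 0

    def test_masked_positions_excluded(self):
        prof = classify_pair_mutations("ACCTA", "ACCTG", "ACGTA", mask={2, 4})
        assert (prof.n_alpha, prof.n_beta, prof.n_gamma) == (0, 0, 0)
        assert prof.nu == 3.0

    def test_non_acgt_position_carries_no_flags(self):
        prof = classify_pair_mutations("ACCTA", "ACNTA", "ACGTA")
        assert prof.n_gamma == 0 and prof.n_alpha == 0
        assert prof.nu == 4.5  # 5 and 4 informative positions

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classify_pair_mutations("ACG", "ACGT", "ACGT")


class TestMatrices:
    def test_t_and_h_from_known_profile(self):
        # alpha=1, gamma=1, nu=5 -> T = (1+2)/5 = 0.6, H = 2/5 = 0.4
        group = make_group(["ACCTA", "ACCTG"], germline="ACGTA")
        T, H = mutation_matrices(group, {"s0": "ACCTA", "s1": "ACCTG"})
        assert T[0, 1] == pytest.approx(0.6)
        assert H[0, 1] == pytest.approx(0.4)

    def test_identical_pair_zero(self):
        group = make_group(["ACGTA", "ACGTA"], germline="ACGTA")
        T, H = mutation_matrices(group, {"s0": "ACGTA", "s1": "ACGTA"})
        assert T[0, 1] == 0 and H[0, 1] == 0

    def test_alpha_only(self):
        # 2 alpha mutations, nu = 10 -> T = 0.2, H = 0
        germ = "ACGTACGTAC"
        seq_i = "AAGTACGTAA"  # mutated at 1 and 9
        group = make_group([seq_i, germ], germline=germ)
        T, H = mutation_matrices(group, {"s0": seq_i, "s1": germ})
        assert T[0, 1] == pytest.approx(0.2)
        assert H[0, 1] == 0.0

    def test_h_never_exceeds_t(self):
        rng = np.random.default_rng(0)
        germ = "".join(rng.choice(list("ACGT"), 40))
        seqs = []
        for _ in range(6):
            s = list(germ)
            for pos in rng.choice(40, size=5, replace=False):
                s[pos] = rng.choice([b for b in "ACGT" if b != germ[pos]])
            seqs.append("".join(s))
        group = make_group(seqs, germline=germ)
        T, H = mutation_matrices(group, dict(zip(group.member_ids, seqs)))
        assert np.all(H <= T + 1e-12)


class TestDamping:
    def test_no_shared_mutations_m_is_one(self):
        group = make_group(["ACGTA", "ACGTA"], germline="ACGTA")
        M = damping_matrix(group, TargetingModel.uniform(0.3), {"s0": "ACGTA", "s1": "ACGTA"})
        assert M[0, 1] == 1.0

    def test_two_shared_positions_uniform(self):
        germ = "AACGTACGTAA"
        mutated = "AATGTACTTAA"  # shared mutations at positions 2 and 7
        group = make_group([mutated, mutated + ""], germline=germ, alleles=[germ])
        # distinct ids but identical sequences: both carry the same two mutations
        M = damping_matrix(
            group, TargetingModel.uniform(0.1), {"s0": mutated, "s1": mutated}
        )
        assert M[0, 1] == pytest.approx(0.81)

    def test_allele_averaged_mutability(self):
        # two alleles whose 5-mers at the shared position have mutabilities 0.2, 0.4
        a1 = "AACAAAA"
        a2 = "AATAAAA"
        tm = TargetingModel({"AACAA": 0.2, "AATAA": 0.4})
        egl = effective_germline([a1, a2])
        mutated = "AAGAAAA"  # G at centre: mutation relative to Y={C,T}
        group = make_group([mutated, mutated], germline=egl, alleles=[a1, a2])
        M = damping_matrix(group, tm, {"s0": mutated, "s1": mutated})
        assert M[0, 1] == pytest.approx(0.7)

    def test_zero_mutability_disables_damping(self):
        germ = "AACGTACGTAA"
        mutated = "AATGTACTTAA"
        group = make_group([mutated, mutated], germline=germ, alleles=[germ])
        M = damping_matrix(group, TargetingModel.uniform(0.0), {"s0": mutated, "s1": mutated})
        assert M[0, 1] == 1.0


class TestSimilarity:
    def test_zero_shared_forces_zero_similarity(self):
        T = np.array([[0.0, 0.5], [0.5, 0.0]])
        H = np.zeros((2, 2))
        S = shm_similarity(T, H, np.ones((2, 2)), sigma_T=0.2, sigma_H=0.2)
        assert np.all(S == 0)

    def test_known_value(self):
        T = np.array([[0.0, 0.6], [0.6, 0.0]])
        H = np.array([[0.0, 0.4], [0.4, 0.0]])
        S = shm_similarity(T, H, np.ones((2, 2)), sigma_T=0.2, sigma_H=0.2)
        expected = math.exp(-0.5) * (1 - math.exp(-2.0))
        assert S[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_more_sharing_raises_similarity_at_fixed_total(self):
        T = np.full((3, 3), 0.6)
        np.fill_diagonal(T, 0)
        H = np.array([[0, 0.4, 0.2], [0.4, 0, 0.2], [0.2, 0.2, 0]], dtype=float)
        S = shm_similarity(T, H, np.ones((3, 3)), sigma_T=0.2, sigma_H=0.2)
        assert S[0, 1] > S[0, 2]

    def test_fewer_unshared_raises_similarity_at_fixed_shared(self):
        H = np.full((3, 3), 0.2)
        np.fill_diagonal(H, 0)
        T = np.array([[0, 0.3, 0.6], [0.3, 0, 0.6], [0.6, 0.6, 0]], dtype=float)
        S = shm_similarity(T, H, np.ones((3, 3)), sigma_T=0.2, sigma_H=0.2)
        assert S[0, 1] > S[0, 2]

    def test_degenerate_sigma_zero(self):
        # all pairs identical: sigma = 0 must not divide by zero
        T = np.zeros((3, 3))
        H = np.zeros((3, 3))
        S = shm_similarity(T, H, np.ones((3, 3)))
        assert np.all(S == 0)

    def test_range(self):
        rng = np.random.default_rng(1)
        H = np.abs(rng.normal(0.1, 0.05, (5, 5)))
        H = (H + H.T) / 2
        T = H + np.abs(rng.normal(0.1, 0.05, (5, 5)))
        T = (T + T.T) / 2
        np.fill_diagonal(T, 0)
        np.fill_diagonal(H, 0)
        S = shm_similarity(T, H, np.ones((5, 5)))
        assert np.all(S >= 0) and np.all(S < 1)


@settings(deadline=None, max_examples=30)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_vectorised_matches_brute_force(seed):
    """Vectorised T/H/M/S equals position-enumeration oracle to 1e-12."""
    rng = np.random.default_rng(seed)
    L = int(rng.integers(12, 40))
    m = int(rng.integers(2, 7))
    germ = "".join(rng.choice(list("ACGT"), L))
    allele = list(germ)
    allele[int(rng.integers(0, L))] = rng.choice(list("ACGT"))
    alleles = [germ, "".join(allele)]
    egl = effective_germline(alleles)
    seqs = []
    for _ in range(m):
        s = list(germ)
        for pos in rng.choice(L, size=int(rng.integers(0, 6)), replace=False):
            s[pos] = rng.choice(list("ACGTN"))
        seqs.append("".join(s))
    mask = frozenset(int(x) for x in rng.choice(L, size=3, replace=False))
    tm_table = {
        "".join(rng.choice(list("ACGT"), 5)): float(rng.uniform(0, 0.5)) for _ in range(30)
    }
    tm = TargetingModel(tm_table)
    group = make_group(seqs, germline=egl, alleles=alleles)
    seq_map = dict(zip(group.member_ids, seqs))
    T, H = mutation_matrices(group, seq_map, mask)
    M = damping_matrix(group, tm, seq_map, mask)
    S = shm_similarity(T, H, M)
    bT, bH, bM = brute_group_matrices(seqs, egl, alleles, tm_table, mask)
    bS = brute_shm_similarity(bT, bH, bM)
    np.testing.assert_allclose(T, np.array(bT), atol=1e-12)
    np.testing.assert_allclose(H, np.array(bH), atol=1e-12)
    np.testing.assert_allclose(M, np.array(bM), atol=1e-12)
    np.testing.assert_allclose(S, np.array(bS), atol=1e-12)
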