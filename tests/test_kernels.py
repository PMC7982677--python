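"""Kernel algebra: marker coding, GRMs, SCA, expansions, Hadamard products."""

import numpy as np
import pandas as pd
import pytest

from hybridnorm.kernels import (
    HybridSet,
    Kernel,
    MarkerMatrix,
    code_major_allele,
    expand_to_observations,
    grm,
    incidence_matrix,
    interaction_kernel,
    sca_kernel,
)


def brute_major_counts(calls):
    """Independent re-coding of string calls by exhaustive counting."""
    freq = {}
    for c in calls:
        for a in c:
            freq[a] = freq.get(a, 0) + 1
    major = sorted(freq, key=lambda a: (-freq[a], a))[0]
    return [sum(1 for a in c if a == major) for c in calls]


class TestCodeMajorAllele:
    def test_monomorphic_locus_is_column_of_twos(self):
        df = pd.DataFrame({"L1": ["AA", "AA", "AA"]}, index=["i1", "i2", "i3"])
        mm = code_major_allele(df)
        assert np.all(mm.values == 2)

    def test_heterozygote_codes_one(self):
        df = pd.DataFrame({"L1": ["AA", "AC", "CC", "AA"]}, index=list("wxyz"))
        mm = code_major_allele(df)
        assert mm.values[1, 0] == 1

    def test_matches_brute_force_enumeration(self):
        # 3 inbreds x 2 loci, allele frequencies 0.75 / 0.25
        df = pd.DataFrame(
            {"L1": ["AA", "AA", "AC"], "L2": ["GG", "GT", "TT"]},
            index=["i1", "i2", "i3"],
        )
        mm = code_major_allele(df)
        for j, locus in enumerate(df.columns):
            assert list(mm.values[:, j]) == brute_major_counts(df[locus])

    def test_tie_takes_lexicographically_smaller_allele(self):
        df = pd.DataFrame({"L1": ["AA", "CC"]}, index=["i1", "i2"])
        mm = code_major_allele(df)
        # A and C both at frequency 0.5 -> A is major
        assert list(mm.values[:, 0]) == [2, 0]

    def test_multiallelic_locus_dropped_with_warning(self):
        df = pd.DataFrame(
            {"L1": ["AA", "CC", "GG"], "L2": ["AA", "AA", "AC"]},
            index=["i1", "i2", "i3"],
        )
        with pytest.warns(UserWarning, match="dropped 1 loci"):
            mm = code_major_allele(df)
        assert mm.loci == ["L2"]

    def test_missing_imputed_to_rounded_locus_mean(self):
        df = pd.DataFrame({"L1": ["AA", "AA", "AC", "NA"]}, index=list("wxyz"))
        mm = code_major_allele(df)
        # counts 2,2,1 -> mean 5/3 -> rounds to 2
        assert mm.values[3, 0] == 2

    def test_numeric_input_passthrough(self):
        df = pd.DataFrame({"L1": ["0", "1", "2"], "L2": ["2", "NA", "0"]},
                          index=["a", "b", "c"])
        mm = code_major_allele(df)
        assert list(mm.values[:, 0]) == [0, 1, 2]
        assert mm.values[1, 1] == 1  # mean of 2,0 -> 1


class TestGrm:
    def test_zero_markers_give_zero_kernel(self):
        X = MarkerMatrix(np.zeros((3, 4), dtype=int), list("abc"), list("wxyz"))
        assert np.all(grm(X).matrix == 0)

    def test_known_product(self):
        X = MarkerMatrix(np.array([[1, 2], [0, 1]]), ["a", "b"], ["l1", "l2"])
        expected = np.array([[2.5, 1.0], [1.0, 0.5]])
        np.testing.assert_allclose(grm(X).matrix, expected)

    def test_gram_matrix_properties(self):
        rng = np.random.default_rng(0)
        X = MarkerMatrix(rng.integers(0, 3, (10, 30)), [f"i{k}" for k in range(10)],
                         [f"l{k}" for k in range(30)])
        G = grm(X)
        G.validate()
        assert np.all(np.diag(G.matrix) >= 0)

    def test_center_flag_equals_grm_of_precentered(self):
        rng = np.random.default_rng(1)
        vals = rng.integers(0, 3, (8, 20))
        X = MarkerMatrix(vals, [f"i{k}" for k in range(8)], [f"l{k}" for k in range(20)])
        Gc = grm(X, center=True)
        M = vals - vals.mean(axis=0)
        np.testing.assert_array_equal(Gc.matrix, (M @ M.T) / 20)

    def test_zero_loci_error(self):
        X = MarkerMatrix(np.zeros((2, 0), dtype=int), ["a", "b"], [])
        with pytest.raises(ValueError):
            grm(X)


@pytest.fixture
def toy_parents():
    G1 = Kernel("G_P1", "parent1", np.array([[1.0, 0.4], [0.4, 1.2]]), ["A", "B"])
    G2 = Kernel("G_P2", "parent2", np.array([[0.9, 0.2], [0.2, 1.1]]), ["T1", "T2"])
    hybrids = HybridSet([("H1", "A", "T1"), ("H2", "B", "T1"), ("H3", "B", "T2")])
    return G1, G2, hybrids


class TestScaKernel:
    def test_ones_second_factor_reduces_to_first(self, toy_parents):
        G1, _, hybrids = toy_parents
        ones = Kernel("ones", "parent2", np.ones((2, 2)), ["T1", "T2"])
        K = sca_kernel(G1, ones, hybrids)
        p1 = {"H1": "A", "H2": "B", "H3": "B"}
        idx = {"A": 0, "B": 1}
        for i, hi in enumerate(hybrids.ids):
            for j, hj in enumerate(hybrids.ids):
                assert K.matrix[i, j] == G1.matrix[idx[p1[hi]], idx[p1[hj]]]

    def test_identity_second_factor_zeroes_cross_tester_pairs(self, toy_parents):
        G1, _, hybrids = toy_parents
        eye = Kernel("I", "parent2", np.eye(2), ["T1", "T2"])
        K = sca_kernel(G1, eye, hybrids)
        assert K.matrix[0, 2] == 0  # H1 (T1) vs H3 (T2)
        assert K.matrix[1, 2] == 0

    def test_entrywise_against_hand_products(self, toy_parents):
        G1, G2, hybrids = toy_parents
        K = sca_kernel(G1, G2, hybrids)
        i1 = {"A": 0, "B": 1}
        i2 = {"T1": 0, "T2": 1}
        parents = {h: (p1, p2) for h, p1, p2 in hybrids.hybrids}
        for i, hi in enumerate(hybrids.ids):
            for j, hj in enumerate(hybrids.ids):
                a1, a2 = parents[hi]
                b1, b2 = parents[hj]
                expected = G1.matrix[i1[a1], i1[b1]] * G2.matrix[i2[a2], i2[b2]]
                assert K.matrix[i, j] == pytest.approx(expected)
        K.validate()

    def test_unknown_parent_raises(self, toy_parents):
        G1, G2, _ = toy_parents
        bad = HybridSet([("H1", "A", "T9")])
        with pytest.raises(KeyError):
            sca_kernel(G1, G2, bad)


class TestExpansion:
    def test_identity_incidence_is_noop(self, toy_parents):
        G1, _, _ = toy_parents
        K = expand_to_observations(G1, np.eye(2))
        np.testing.assert_array_equal(K.matrix, G1.matrix)

    def test_duplicated_entity_duplicates_rows(self, toy_parents):
        G1, _, _ = toy_parents
        Z = incidence_matrix(["A", "A", "B"], ["A", "B"])
        K = expand_to_observations(G1, Z)
        np.testing.assert_array_equal(K.matrix[0], K.matrix[1])
        np.testing.assert_array_equal(K.matrix[:, 0], K.matrix[:, 1])

    def test_gather_equals_dense_triple_product(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(3, 3))
        K = Kernel("K", "environment", A @ A.T, ["e1", "e2", "e3"])
        Z = incidence_matrix(["e2", "e1", "e2", "e3", "e1"], K.ids)
        expanded = expand_to_observations(K, Z)
        np.testing.assert_allclose(expanded.matrix, Z @ K.matrix @ Z.T)

    def test_dimension_mismatch_raises(self, toy_parents):
        G1, _, _ = toy_parents
        with pytest.raises(ValueError):
            expand_to_observations(G1, np.eye(3))


class TestInteraction:
    def _obs(self, M, name="K"):
        return Kernel(name, "observation", M, [f"o{i}" for i in range(M.shape[0])])

    def test_ones_is_identity_element(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=(5, 5))
        Ka = self._obs(A @ A.T)
        ones = self._obs(np.ones((5, 5)), "ones")
        np.testing.assert_array_equal(interaction_kernel(Ka, ones).matrix, Ka.matrix)

    def test_environment_identity_factor_zeroes_cross_env_cells(self):
        envs = ["E1", "E1", "E2", "E2", "E3"]
        ZE = incidence_matrix(envs, ["E1", "E2", "E3"])
        Kenv = self._obs(ZE @ ZE.T, "ZEZE")
        rng = np.random.default_rng(5)
        A = rng.normal(size=(5, 5))
        K = interaction_kernel(self._obs(A @ A.T), Kenv)
        for i in range(5):
            for j in range(5):
                if envs[i] != envs[j]:
                    assert K.matrix[i, j] == 0

    def test_triple_product_entrywise(self):
        rng = np.random.default_rng(6)
        mats = [rng.normal(size=(6, 6)) for _ in range(3)]
        ks = [self._obs(m @ m.T, f"K{i}") for i, m in enumerate(mats)]
        K = interaction_kernel(*ks)
        for i in range(6):
            for j in range(6):
                expected = ks[0].matrix[i, j] * ks[1].matrix[i, j] * ks[2].matrix[i, j]
                assert K.matrix[i, j] == pytest.approx(expected)

    def test_ordering_mismatch_raises(self):
        Ka = self._obs(np.eye(3))
        Kb = Kernel("K", "observation", np.eye(3), ["o2", "o1", "o0"])
        with pytest.raises(ValueError, match="ordering"):
            interaction_kernel(Ka, Kb)


def test_schur_product_psd_closure():
    """Hadamard products of PSD kernels stay PSD within tolerance (100 pairs)."""
    rng = np.random.default_rng(11)
    for _ in range(100):
        n = rng.integers(3, 10)
        A = rng.normal(size=(n, n))
        B = rng.normal(size=(n, n))
        H = (A @ A.T) * (B @ B.T)
        ev = np.linalg.eigvalsh(H)
        assert ev[0] >= -1e-8 * max(ev[-1], 1.0)


def test_kernel_csv_round_trip(tmp_path, toy_parents):
    G1, _, _ = toy_parents
    path = tmp_path / "g1.csv"
    G1.to_csv(path)
    back = Kernel.from_csv(path, name="G_P1", level="parent1")
    np.testing.assert_allclose(back.matrix, G1.matrix)
    assert back.ids == G1.ids


def test_kernel_validate_rejects_indefinite():
    M = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
    with pytest.raises(ValueError, match="not PSD"):
        Kernel("bad", "hybrid", M, ["a", "b"]).validate()
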