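import itertools

import numpy as np
import pandas as pd
import pytest

from mklfuse import (ClinicalTable, KernelInputError, KernelMatrix, KernelSet,
                     center_and_normalize, clinical_kernel, combine_kernels,
                     linear_kernel, polynomial_kernel, rbf_kernel,
                     spectrum_kernel, validate_psd)


class TestLinearKernel:
    def test_orthonormal_rows_give_identity(self):
        K = linear_kernel(np.eye(2))
        np.testing.assert_allclose(K.values, np.eye(2))

    def test_duplicate_rows_collapse(self, rng):
        x = rng.normal(size=3)
        K = linear_kernel(np.vstack([x, x]))
        assert K.values[0, 0] == pytest.approx(K.values[1, 1])
        assert K.values[0, 1] == pytest.approx(K.values[0, 0])

    def test_matches_double_loop(self, rng):
        X = rng.normal(size=(5, 3))
        K = linear_kernel(X)
        expect = [[float(np.dot(X[i], X[j])) for j in range(5)] for i in range(5)]
        np.testing.assert_allclose(K.values, expect, atol=1e-12)

    def test_cross_block(self, rng):
        X, Z = rng.normal(size=(4, 3)), rng.normal(size=(2, 3))
        blk = linear_kernel(X, Z=Z)
        np.testing.assert_allclose(blk.values, Z @ X.T)


class TestRbfKernel:
    def test_unit_diagonal(self, rng):
        K = rbf_kernel(rng.normal(size=(6, 2)), 4.0)
        np.testing.assert_allclose(np.diag(K.values), 1.0)

    def test_wider_multiplier_means_larger_offdiagonal(self, rng):
        X = rng.normal(size=(8, 3))
        K4, K6, K8 = (rbf_kernel(X, m).values for m in (4.0, 6.0, 8.0))
        off = ~np.eye(8, dtype=bool)
        assert np.all(K4[off] <= K6[off] + 1e-15)
        assert np.all(K6[off] <= K8[off] + 1e-15)

    def test_matches_pairwise_formula(self, rng):
        X = rng.normal(size=(6, 2))
        sigma2 = 4.0 * np.var(X, axis=0, ddof=1).mean()
        K = rbf_kernel(X, 4.0)
        for i, j in itertools.product(range(6), repeat=2):
            d2 = np.sum((X[i] - X[j]) ** 2)
            assert K.values[i, j] == pytest.approx(np.exp(-d2 / (2 * sigma2)))

    def test_zero_variance_rejected(self):
        with pytest.raises(KernelInputError):
            rbf_kernel(np.ones((5, 2)), 4.0)


class TestPolynomialKernel:
    def test_degree_one_bias_zero_reduces_to_linear(self, rng):
        X = rng.normal(size=(5, 3))
        np.testing.assert_allclose(polynomial_kernel(X, 1, 0.0).values,
                                   linear_kernel(X).values, atol=1e-12)

    def test_zero_vectors_bias_one_cubed(self):
        K = polynomial_kernel(np.zeros((2, 3)), degree=3, bias=1.0)
        np.testing.assert_allclose(K.values, 1.0)

    def test_matches_formula(self, rng):
        X = rng.normal(size=(4, 3))
        K = polynomial_kernel(X, 2, 1.0)
        expect = (X @ X.T + 1.0) ** 2
        np.testing.assert_allclose(K.values, expect, atol=1e-12)

    def test_degree_zero_rejected(self):
        with pytest.raises(KernelInputError):
            polynomial_kernel(np.eye(2), degree=0)


class TestSpectrumKernel:
    def test_single_shared_kmer(self):
        K = spectrum_kernel(["AA", "AA"], k=2)
        np.testing.assert_allclose(K.values, 1.0)

    def test_disjoint_kmer_sets_orthogonal(self):
        K = spectrum_kernel(["AC", "GT"], k=2)
        assert K.values[0, 1] == 0.0

    def test_matches_count_vector_dot_products(self, rng):
        letters = np.array(list("ACGT"))
        seqs = ["".join(rng.choice(letters, 8)) for _ in range(5)]
        K = spectrum_kernel(seqs, k=2)
        # independent enumeration over the full 2-mer alphabet
        vocab = ["".join(t) for t in itertools.product("ACGT", repeat=2)]
        counts = np.array([[sum(s[i:i + 2] == w for i in range(len(s) - 1))
                            for w in vocab] for s in seqs], dtype=float)
        np.testing.assert_allclose(K.values, counts @ counts.T, atol=1e-12)

    def test_equals_linear_kernel_on_count_matrix(self, rng):
        letters = np.array(list("ACGT"))
        seqs = ["".join(rng.choice(letters, 10)) for _ in range(4)]
        vocab = ["".join(t) for t in itertools.product("ACGT", repeat=3)]
        counts = np.array([[sum(s[i:i + 3] == w for i in range(len(s) - 2))
                            for w in vocab] for s in seqs], dtype=float)
        np.testing.assert_allclose(spectrum_kernel(seqs, k=3).values,
                                   linear_kernel(counts).values, atol=1e-12)

    def test_short_sequence_rejected(self):
        with pytest.raises(KernelInputError):
            spectrum_kernel(["A"], k=2)


class TestClinicalKernel:
    @staticmethod
    def _table():
        df = pd.DataFrame({
            "age": [20.0, 40.0, 60.0],
            "stage": [1, 2, 3],
            "smoker": ["y", "n", "y"],
        }, index=["p1", "p2", "p3"])
        kinds = {"age": "continuous", "stage": "ordinal", "smoker": "categorical"}
        return ClinicalTable(df, kinds)

    def test_identical_patients_similarity_one(self):
        K = clinical_kernel(self._table())
        np.testing.assert_allclose(np.diag(K.values), 1.0)

    def test_opposite_ends_similarity_zero(self):
        df = pd.DataFrame({"a": [0.0, 10.0], "b": [5.0, -5.0]})
        K = clinical_kernel(ClinicalTable(df, {"a": "continuous", "b": "continuous"}))
        assert K.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_per_variable_average(self, rng):
        df = pd.DataFrame({
            "x": rng.uniform(0, 1, 5), "y": rng.integers(0, 4, 5),
            "c": rng.choice(["a", "b"], 5),
        })
        tab = ClinicalTable(df, {"x": "continuous", "y": "ordinal", "c": "categorical"})
        K = clinical_kernel(tab)
        for i, j in itertools.product(range(5), repeat=2):
            sims = [1 - abs(df.x[i] - df.x[j]) / (df.x.max() - df.x.min()),
                    1 - abs(df.y[i] - df.y[j]) / (df.y.max() - df.y.min()),
                    float(df.c[i] == df.c[j])]
            assert K.values[i, j] == pytest.approx(np.mean(sims))

    def test_constant_variable_excluded_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 1.0], "b": [0.0, 2.0]})
        with pytest.warns(UserWarning, match="constant"):
            K = clinical_kernel(ClinicalTable(
                df, {"a": "continuous", "b": "continuous"}))
        assert K.values[0, 1] == pytest.approx(0.0)  # only 'b' contributes

    def test_missing_values_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.nan]})
        with pytest.raises(KernelInputError):
            ClinicalTable(df, {"a": "continuous"})


class TestNormalization:
    def test_unit_diag(self, psd_pair):
        K = center_and_normalize(psd_pair.kernels[0], "unit_diag")
        np.testing.assert_allclose(np.diag(K.values), 1.0, atol=1e-12)

    def test_unit_diag_idempotent(self, psd_pair):
        K1 = center_and_normalize(psd_pair.kernels[0], "unit_diag")
        K2 = center_and_normalize(K1, "unit_diag")
        np.testing.assert_allclose(K1.values, K2.values, atol=1e-12)

    def test_trace_mode(self, psd_pair):
        K = center_and_normalize(psd_pair.kernels[0], "trace")
        assert np.trace(K.values) == pytest.approx(K.n, abs=1e-10)

    def test_none_mode_is_identity(self, psd_pair):
        K = center_and_normalize(psd_pair.kernels[0], "none")
        assert K is psd_pair.kernels[0]

    def test_zero_diagonal_rejected(self):
        with pytest.raises(KernelInputError):
            center_and_normalize(KernelMatrix(np.diag([1.0, 0.0])), "unit_diag")


class TestValidatePsd:
    def test_identity_unchanged(self):
        K = KernelMatrix(np.eye(3))
        assert validate_psd(K) is K

    def test_eigenvalue_clipping(self):
        K = validate_psd(KernelMatrix(np.diag([1.0, -0.5])), repair=True)
        np.testing.assert_allclose(K.values, np.diag([1.0, 0.0]), atol=1e-12)

    def test_random_indefinite_repair(self, rng):
        A = rng.normal(size=(8, 8))
        K = validate_psd(KernelMatrix(A + A.T), repair=True)
        assert np.linalg.eigvalsh(K.values).min() >= -1e-10

    def test_indefinite_without_repair_raises(self, rng):
        A = rng.normal(size=(6, 6))
        with pytest.raises(KernelInputError, match="not PSD"):
            validate_psd(KernelMatrix(A + A.T), repair=False)

    def test_asymmetric_input_rejected_at_construction(self, rng):
        with pytest.raises(KernelInputError, match="symmetric"):
            KernelMatrix(rng.normal(size=(4, 4)))


class TestCombine:
    def test_single_kernel_identity(self, psd_pair):
        K = combine_kernels(KernelSet([psd_pair.kernels[0]]), [1.0])
        np.testing.assert_allclose(K.values, psd_pair.kernels[0].values)

    def test_convex_combination_of_copies(self, psd_pair):
        K0 = psd_pair.kernels[0]
        twin = KernelMatrix(K0.values, K0.sample_ids, "twin")
        K = combine_kernels(KernelSet([K0, twin]), [0.5, 0.5])
        np.testing.assert_allclose(K.values, K0.values, atol=1e-12)

    def test_elementwise_weighted_sum(self, psd_pair):
        K = combine_kernels(psd_pair, [0.6, 0.8])
        expect = 0.6 * psd_pair.kernels[0].values + 0.8 * psd_pair.kernels[1].values
        np.testing.assert_allclose(K.values, expect, atol=1e-12)

    def test_preserves_psd(self, rng):
        for _ in range(5):
            X1, X2 = rng.normal(size=(7, 3)), rng.normal(size=(7, 4))
            ks = KernelSet([linear_kernel(X1, name="a"), linear_kernel(X2, name="b")])
            theta = rng.uniform(0, 2, size=2)
            w = np.linalg.eigvalsh(combine_kernels(ks, theta).values)
            assert w.min() >= -1e-8 * max(w.max(), 1.0)

    def test_length_mismatch_rejected(self, psd_pair):
        with pytest.raises(KernelInputError):
            combine_kernels(psd_pair, [1.0])


def test_constructors_yield_psd_kernels(rng):
    X = rng.normal(size=(10, 4))
    seqs = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(10)]
    for K in (linear_kernel(X), rbf_kernel(X, 4.0), polynomial_kernel(X, 3, 1.0),
              spectrum_kernel(seqs, 2)):
        validate_psd(K)  # must not raise


def test_kernelset_requires_shared_ids(rng):
    a = KernelMatrix(np.eye(3), ("x", "y", "z"), "a")
    b = KernelMatrix(np.eye(3), ("x", "y", "w"), "b")
    with pytest.raises(KernelInputError):
        KernelSet([a, b])


def test_subset_and_cross_slicing(rng):
    K = linear_kernel(rng.normal(size=(5, 3)), ["a", "b", "c", "d", "e"])
    sub = K.subset(["b", "d"])
    np.testing.assert_allclose(sub.values, K.values[np.ix_([1, 3], [1, 3])])
    blk = K.cross(["a"], ["b", "d"])
    np.testing.assert_allclose(blk.values, K.values[np.ix_([0], [1, 3])])
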