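import numpy as np
import pytest

from mklfuse import (KernelMatrix, KernelSet, NormSpec, fit_svm, fit_svm_mkl,
                     fit_svm_mkl_multiclass, fit_weighted_svm_mkl,
                     generate_fusion_dataset, linear_kernel)
from mklfuse.svm import predict, svm_dual_objective
from oracles import qp_svm_dual


def _binary_problem(n=60, seed=0, views=(2.0, 1.0), noise=1):
    ds = generate_fusion_dataset(n_samples=n, informative=views,
                                 n_noise_views=noise, n_features=5, seed=seed)
    return ds, ds.kernel_set()


class TestSingleKernel:
    def test_symmetric_separable_pair(self):
        X = np.array([[1.0], [-1.0]])
        K = linear_kernel(X, ["a", "b"])
        y = np.array([1.0, -1.0])
        alpha, b = fit_svm(K, y, C=10.0)
        # decision at the midpoint x=0 must vanish, both points correct
        assert b == pytest.approx(0.0, abs=1e-6)
        dec = K.values @ (alpha * y) + b
        assert np.all(dec * y > 0)

    def test_duplicated_dataset_same_decision_function(self):
        """Duplicating every point while halving C leaves the decision
        function unchanged (total dual mass per point is preserved)."""
        ds, ks = _binary_problem(n=30, noise=0)
        K = ks.kernels[0]
        y = ds.labels
        dup_vals = np.tile(K.values, (2, 2))
        Kdup = KernelMatrix(dup_vals, [f"s{i}" for i in range(60)], K.name)
        a1, b1 = fit_svm(K, y, C=1.0)
        a2, b2 = fit_svm(Kdup, np.tile(y, 2), C=0.5)
        s2 = a2 * np.tile(y, 2)
        d1 = K.values @ (a1 * y) + b1
        d2 = K.values @ (s2[:30] + s2[30:]) + b2
        np.testing.assert_allclose(d1, d2, atol=1e-4)

    def test_objective_matches_generic_qp_reference(self):
        ds, ks = _binary_problem(n=30, noise=0)
        val = svm_dual_objective(ks.kernels[0].values, ds.labels, C=1.0)
        _, ref = qp_svm_dual(ks.kernels[0].values, ds.labels, C=1.0)
        assert val == pytest.approx(ref, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_svm(KernelMatrix(np.eye(4)), np.ones(4))


class TestMklFit:
    @pytest.mark.parametrize("formulation", ["direct", "sip"])
    @pytest.mark.parametrize("mode", ["inf", "two"])
    def test_single_source_reduces_to_plain_svm(self, formulation, mode):
        ds, ks = _binary_problem(noise=0, views=(2.0,))
        m = fit_svm_mkl(KernelSet([ks.kernels[0]]), ds.labels, 1.0,
                        NormSpec(mode), formulation)
        np.testing.assert_allclose(m.theta, [1.0])
        a, b = fit_svm(ks.kernels[0], ds.labels, 1.0)
        np.testing.assert_allclose(m.alpha[:, 0], a, atol=1e-8)
        assert m.b[0] == pytest.approx(b, abs=1e-8)

    def test_identical_kernels_give_single_kernel_predictions(self):
        ds, ks = _binary_problem(noise=0, views=(2.0,))
        K = ks.kernels[0]
        twin = KernelMatrix(K.values, K.sample_ids, "twin")
        pair = KernelSet([K, twin])
        m = fit_svm_mkl(pair, ds.labels, 1.0, NormSpec("inf"), "direct")
        ids = np.array(ds.sample_ids)
        pred, _ = predict(m, pair.cross(ids, ids))
        a, b = fit_svm(K, ds.labels, 1.0)
        single = np.sign(K.values @ (a * ds.labels) + b)
        np.testing.assert_allclose(pred, single)

    def test_sip_and_direct_agree(self):
        ds, ks = _binary_problem(n=80, seed=4, views=(2.0, 1.0), noise=1)
        for mode in ("inf", "two"):
            a = fit_svm_mkl(ks, ds.labels, 1.0, NormSpec(mode), "sip")
            b = fit_svm_mkl(ks, ds.labels, 1.0, NormSpec(mode), "direct")
            assert np.abs(a.theta - b.theta).max() <= 1e-2
            rel = abs(a.objective - b.objective) / abs(b.objective)
            assert rel <= 2 * 5e-4

    def test_mode_one_equals_uniform_average_kernel(self):
        ds, ks = _binary_problem()
        m = fit_svm_mkl(ks, ds.labels, 1.0, NormSpec("one"))
        avg = KernelMatrix(sum(K.values for K in ks) / ks.p, ks.sample_ids)
        a, b = fit_svm(avg, ds.labels, 1.0)
        np.testing.assert_allclose(m.alpha[:, 0], a, atol=1e-6)

    def test_theta_permutation_equivariance(self):
        ds, ks = _binary_problem(seed=2)
        perm = KernelSet(ks.kernels[::-1])
        m1 = fit_svm_mkl(ks, ds.labels, 1.0, NormSpec("two"), "sip")
        m2 = fit_svm_mkl(perm, ds.labels, 1.0, NormSpec("two"), "sip")
        np.testing.assert_allclose(m1.theta, m2.theta[::-1], atol=1e-4)

    def test_sip_insensitive_to_random_start(self):
        ds, ks = _binary_problem(seed=6)
        m1 = fit_svm_mkl(ks, ds.labels, 1.0, NormSpec("two"), "sip", seed=1)
        m2 = fit_svm_mkl(ks, ds.labels, 1.0, NormSpec("two"), "sip", seed=2)
        assert np.abs(m1.theta - m2.theta).max() <= 1e-3

    def test_l2_sip_theta_on_unit_sphere(self):
        ds, ks = _binary_problem(seed=3)
        m = fit_svm_mkl(ks, ds.labels, 1.0, NormSpec("two"), "sip")
        assert np.linalg.norm(m.theta) == pytest.approx(1.0, abs=1e-4)

    def test_sip_trace_is_recorded(self):
        ds, ks = _binary_problem()
        m = fit_svm_mkl(ks, ds.labels, 1.0, NormSpec("inf"), "sip")
        assert m.sip_trace is not None and len(m.sip_trace) >= 2
        assert m.sip_trace[-1].violation <= 5e-4


class TestMulticlass:
    def test_two_classes_reduce_to_binary(self):
        ds, ks = _binary_problem()
        labels = np.where(ds.labels > 0, "pos", "neg")
        m = fit_svm_mkl_multiclass(ks, labels, 1.0, NormSpec("two"), "sip")
        mb = fit_svm_mkl(ks, ds.labels, 1.0, NormSpec("two"), "sip")
        assert m.n_tasks == 1
        np.testing.assert_allclose(m.theta, mb.theta, atol=1e-8)
        np.testing.assert_allclose(m.alpha, mb.alpha, atol=1e-8)

    def test_separable_three_clusters_perfect_training_accuracy(self):
        ds = generate_fusion_dataset(n_samples=60, n_classes=3,
                                     informative=(6.0, 5.0), n_noise_views=0,
                                     n_features=6, seed=11)
        ks = ds.kernel_set()
        m = fit_svm_mkl_multiclass(ks, ds.labels, 10.0, NormSpec("two"), "sip")
        ids = np.array(ds.sample_ids)
        pred, _ = predict(m, ks.cross(ids, ids))
        assert np.mean(pred == ds.labels) == 1.0

    def test_empty_class_rejected(self):
        ds, ks = _binary_problem()
        with pytest.raises(ValueError):
            fit_svm_mkl(ks, np.ones(ks.n))


class TestWeighted:
    def test_neutral_weights_match_unweighted(self):
        ds, ks = _binary_problem(seed=8)
        m0 = fit_svm_mkl(ks, ds.labels, 1.0, NormSpec("two"), "sip")
        m1 = fit_weighted_svm_mkl(ks, ds.labels, 1.0, {-1: 1.0, 1: 1.0},
                                  NormSpec("two"), "sip")
        np.testing.assert_allclose(m0.theta, m1.theta, atol=1e-8)
        np.testing.assert_allclose(m0.alpha, m1.alpha, atol=1e-8)

    def test_inverse_frequency_weights_raise_minority_recall(self):
        rng = np.random.default_rng(21)
        n_maj, n_min = 90, 10
        X = np.vstack([rng.normal(0, 1, (n_maj, 4)),
                       rng.normal(0.8, 1, (n_min, 4))])
        y = np.r_[-np.ones(n_maj), np.ones(n_min)]
        ks = KernelSet([linear_kernel(X, name="lin")])
        ids = np.array(ks.sample_ids)
        w = {-1: 1.0, 1: n_maj / n_min}
        m0 = fit_svm_mkl(ks, y, 1.0, NormSpec("inf"))
        m1 = fit_weighted_svm_mkl(ks, y, 1.0, w, NormSpec("inf"))
        p0, _ = predict(m0, ks.cross(ids, ids))
        p1, _ = predict(m1, ks.cross(ids, ids))
        recall0 = np.mean(p0[y > 0] > 0)
        recall1 = np.mean(p1[y > 0] > 0)
        assert recall1 >= recall0

    def test_single_kernel_weighted_mkl_equals_weighted_svm(self):
        ds, ks = _binary_problem(noise=0, views=(1.5,))
        w = {-1: 2.0, 1: 1.0}
        m = fit_weighted_svm_mkl(KernelSet([ks.kernels[0]]), ds.labels, 1.0, w)
        a, b = fit_svm(ks.kernels[0], ds.labels, 1.0, class_weights=w)
        np.testing.assert_allclose(m.alpha[:, 0], a, atol=1e-8)


class TestPredict:
    def test_training_points_reproduce_decision_values(self):
        ds, ks = _binary_problem(seed=13)
        m = fit_svm_mkl(ks, ds.labels, 1.0, NormSpec("two"), "sip")
        ids = np.array(ds.sample_ids)
        _, dec = predict(m, ks.cross(ids, ids))
        from mklfuse import combine_kernels
        Om = combine_kernels(ks, m.theta).values
        expect = Om @ (m.alpha[:, 0] * ds.labels) + m.b[0]
        np.testing.assert_allclose(dec, expect, atol=1e-10)

    def test_decision_matches_triple_loop(self):
        ds, ks = _binary_problem(n=30, seed=14)
        ids = np.array(ds.sample_ids)
        train, test = ids[:20], ids[20:]
        y = ds.labels[:20]
        m = fit_svm_mkl(ks.subset(train), y, 1.0, NormSpec("two"), "sip")
        blocks = ks.cross(test, train)
        _, dec = predict(m, blocks)
        expect = np.full(len(test), m.b[0])
        for j, blk in enumerate(blocks):
            for t in range(len(test)):
                for i in range(len(train)):
                    expect[t] += m.theta[j] * m.alpha[i, 0] * y[i] * blk.values[t, i]
        np.testing.assert_allclose(dec, expect, atol=1e-10)

    def test_degenerate_theta_selects_single_source(self):
        ds, ks = _binary_problem(seed=15)
        m = fit_svm_mkl(ks, ds.labels, 1.0, NormSpec("inf"), "sip")
        m.theta = np.array([1.0, 0.0, 0.0])
        ids = np.array(ds.sample_ids)
        _, dec = predict(m, ks.cross(ids, ids))
        expect = ks.kernels[0].values @ (m.alpha[:, 0] * ds.labels) + m.b[0]
        np.testing.assert_allclose(dec, expect, atol=1e-10)
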