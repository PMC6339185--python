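"""Loss components against independent brute-force oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haradapt.losses import (
    ClassCenters,
    GradientReversal,
    KernelBank,
    LabeledFeatureBatch,
    LossWeights,
    center_loss,
    center_loss_grad,
    domain_confusion_loss,
    gaussian_kernel,
    mk_mmd2,
    mk_mmd2_grad,
    softmax_xent,
    softmax_xent_grad,
    total_loss,
    update_centers,
    wasserstein_critic_loss,
)


# ---------------------------------------------------------------- oracles


def mmd2_oracle(X, Y, sigmas):
    """Naive triple loop over kernels and sample pairs (V-statistic)."""
    m, n = len(X), len(Y)
    acc = 0.0
    for s in sigmas:
        sxx = sum(gaussian_kernel(X[i], X[j], s) for i in range(m) for j in range(m))
        syy = sum(gaussian_kernel(Y[i], Y[j], s) for i in range(n) for j in range(n))
        sxy = sum(gaussian_kernel(X[i], Y[j], s) for i in range(m) for j in range(n))
        acc += sxx / m**2 + syy / n**2 - 2.0 * sxy / (m * n)
    return acc / len(sigmas)


def center_loss_oracle(values, labels, C):
    return 0.5 * sum(float(np.sum((values[i] - C[labels[i]]) ** 2))
                     for i in range(len(values)))


def xent_oracle(logits, labels):
    total = 0.0
    for row, y in zip(logits, labels):
        total += -(row[y] - np.log(np.sum(np.exp(row))))
    return total / len(labels)


# ---------------------------------------------------------------- kernel


class TestGaussianKernel:
    def test_zero_distance_is_one(self, rng):
        x = rng.normal(size=4)
        assert gaussian_kernel(x, x, 0.7) == 1.0

    def test_closed_form_value(self):
        # ||x-y||^2 = 4, 2 sigma^2 = 4 -> exp(-1)
        assert gaussian_kernel([0.0], [2.0], np.sqrt(2.0)) == pytest.approx(
            np.exp(-1.0), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_symmetry_and_range(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=3), r.normal(size=3)
        s = float(r.uniform(0.1, 5.0))
        k = gaussian_kernel(x, y, s)
        assert 0.0 < k <= 1.0
        assert k == pytest.approx(gaussian_kernel(y, x, s), abs=1e-15)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel([0.0], [1.0], 0.0)


# ---------------------------------------------------------------- MMD


class TestMkMmd2:
    def test_identical_batches_zero(self, rng):
        X = rng.normal(size=(6, 3))
        assert mk_mmd2(X, X.copy(), KernelBank([0.5, 1.0])) <= 1e-10

    def test_singleton_closed_form(self):
        # 1 + 1 - 2 e^{-1} with x=(0), y=(2), sigma = sqrt(2)
        v = mk_mmd2(np.array([[0.0]]), np.array([[2.0]]), KernelBank([np.sqrt(2.0)]))
        assert v == pytest.approx(2.0 - 2.0 * np.exp(-1.0), abs=1e-9)

    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(100):
            m, n, d = rng.integers(1, 9), rng.integers(1, 9), rng.integers(1, 6)
            X, Y = rng.normal(size=(m, d)), rng.normal(size=(n, d))
            sigmas = list(rng.uniform(0.2, 3.0, size=3))
            assert mk_mmd2(X, Y, KernelBank(sigmas)) == pytest.approx(
                mmd2_oracle(X, Y, sigmas), abs=1e-10)

    def test_nonnegative_and_permutation_invariant(self, rng):
        X, Y = rng.normal(size=(7, 4)), rng.normal(size=(5, 4))
        bank = KernelBank([0.3, 1.0, 3.0])
        v = mk_mmd2(X, Y, bank)
        assert v >= 0.0
        pX, pY = rng.permutation(X), rng.permutation(Y)
        assert mk_mmd2(pX, pY, bank) == pytest.approx(v, abs=1e-12)

    def test_translation_invariance(self, rng):
        X, Y = rng.normal(size=(6, 3)), rng.normal(size=(4, 3))
        bank = KernelBank([0.7, 2.0])
        shift = rng.normal(size=3)
        assert mk_mmd2(X + shift, Y + shift, bank) == pytest.approx(
            mk_mmd2(X, Y, bank), abs=1e-12)

    @pytest.mark.parametrize("sigma", [1e-3, 1.0, 1e3])
    def test_finite_across_bandwidths(self, rng, sigma):
        X, Y = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        assert np.isfinite(mk_mmd2(X, Y, KernelBank([sigma])))

    def test_unbiased_variant_can_go_negative_but_matches_scale(self, rng):
        X = rng.normal(size=(20, 2))
        Y = rng.normal(size=(20, 2))
        b = mk_mmd2(X, Y, KernelBank([1.0]))
        u = mk_mmd2(X, Y, KernelBank([1.0]), unbiased=True)
        assert abs(b - u) < 0.2  # diagonal correction only

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            mk_mmd2(np.zeros((0, 2)), np.zeros((3, 2)), KernelBank([1.0]))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="dimension"):
            mk_mmd2(np.zeros((2, 2)), np.zeros((2, 3)), KernelBank([1.0]))

    def test_gradient_matches_finite_differences(self, rng):
        X, Y = rng.normal(size=(5, 3)), rng.normal(size=(4, 3))
        bank = KernelBank([0.5, 1.5])
        gX, gY = mk_mmd2_grad(X, Y, bank)
        eps = 1e-6
        for arr, g in ((X, gX), (Y, gY)):
            for _ in range(5):
                i = rng.integers(0, arr.shape[0])
                j = rng.integers(0, arr.shape[1])
                orig = arr[i, j]
                arr[i, j] = orig + eps
                hi = mk_mmd2(X, Y, bank)
                arr[i, j] = orig - eps
                lo = mk_mmd2(X, Y, bank)
                arr[i, j] = orig
                assert abs((hi - lo) / (2 * eps) - g[i, j]) < 1e-6

    def test_median_heuristic_bandwidths(self, rng):
        X, Y = rng.normal(size=(10, 4)), rng.normal(size=(8, 4))
        bank = KernelBank.median_heuristic(X, Y)
        assert len(bank.sigmas) == 5
        assert all(s > 0 for s in bank.sigmas)
        # factors {1/4 ... 4} around the median distance
        assert bank.sigmas[4] == pytest.approx(16 * bank.sigmas[0])


# ---------------------------------------------------------------- center loss


class TestCenterLoss:
    def test_zero_when_on_centers(self):
        C = ClassCenters(np.array([[1.0, 2.0], [3.0, 4.0]]))
        b = LabeledFeatureBatch(np.array([[1.0, 2.0], [3.0, 4.0]]), labels=[0, 1])
        assert center_loss(b, C) == 0.0
        np.testing.assert_array_equal(center_loss_grad(b, C), np.zeros((2, 2)))

    def test_three_four_five_case(self):
        C = ClassCenters(np.zeros((2, 2)))
        b = LabeledFeatureBatch(np.array([[3.0, 4.0]]), labels=[0])
        assert center_loss(b, C) == pytest.approx(12.5)
        np.testing.assert_array_equal(center_loss_grad(b, C), [[3.0, 4.0]])

    def test_matches_loop_oracle(self, rng):
        for _ in range(100):
            A, d, m = 3, rng.integers(1, 5), 20
            values = rng.normal(size=(m, d))
            labels = rng.integers(0, A, m)
            C = ClassCenters(rng.normal(size=(A, d)))
            b = LabeledFeatureBatch(values, labels=labels)
            assert center_loss(b, C) == pytest.approx(
                center_loss_oracle(values, labels, C.C), abs=1e-10)

    def test_gradient_matches_finite_differences(self, rng):
        values = rng.normal(size=(8, 3))
        labels = rng.integers(0, 4, 8)
        C = ClassCenters(rng.normal(size=(4, 3)))
        b = LabeledFeatureBatch(values, labels=labels)
        g = center_loss_grad(b, C)
        eps = 1e-5
        for _ in range(6):
            i, j = rng.integers(0, 8), rng.integers(0, 3)
            orig = values[i, j]
            values[i, j] = orig + eps
            hi = center_loss(LabeledFeatureBatch(values, labels=labels), C)
            values[i, j] = orig - eps
            lo = center_loss(LabeledFeatureBatch(values, labels=labels), C)
            values[i, j] = orig
            num = (hi - lo) / (2 * eps)
            assert abs(num - g[i, j]) <= 1e-5 * max(1.0, abs(num))

    def test_loss_decreases_along_negative_gradient(self, rng):
        values = rng.normal(size=(10, 2))
        labels = rng.integers(0, 3, 10)
        C = ClassCenters(rng.normal(size=(3, 2)))
        b = LabeledFeatureBatch(values, labels=labels)
        stepped = LabeledFeatureBatch(
            values - 0.1 * center_loss_grad(b, C), labels=labels)
        assert center_loss(stepped, C) < center_loss(b, C)

    def test_out_of_range_label_rejected(self):
        C = ClassCenters(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            center_loss(LabeledFeatureBatch(np.zeros((1, 2)), labels=[5]), C)


class TestUpdateCenters:
    def test_absent_class_unchanged(self):
        C = ClassCenters(np.array([[1.0, 1.0], [5.0, 5.0]]), alpha=1.0)
        b = LabeledFeatureBatch(np.array([[0.0, 0.0]]), labels=[0])
        out = update_centers(b, C)
        np.testing.assert_array_equal(out.C[1], [5.0, 5.0])

    def test_single_sample_halfway(self):
        # dC = (C - x)/2; alpha=1 -> new C = (C + x)/2
        C = ClassCenters(np.array([[4.0, 0.0], [0.0, 0.0]]), alpha=1.0)
        b = LabeledFeatureBatch(np.array([[0.0, 2.0]]), labels=[0])
        np.testing.assert_allclose(update_centers(b, C).C[0], [2.0, 1.0])

    def test_k_samples_at_one_point(self):
        # k identical samples at p: dC = k (C - p) / (1 + k), hand-expanded k=3
        C0 = np.array([[8.0, 0.0], [0.0, 0.0]])
        p = np.array([0.0, 4.0])
        C = ClassCenters(C0.copy(), alpha=1.0)
        b = LabeledFeatureBatch(np.tile(p, (3, 1)), labels=[0, 0, 0])
        expected = C0[0] - 3.0 * (C0[0] - p) / 4.0
        np.testing.assert_allclose(update_centers(b, C).C[0], expected)

    def test_repeated_application_contracts_to_batch_mean(self, rng):
        values = rng.normal(size=(12, 3))
        b = LabeledFeatureBatch(values, labels=np.zeros(12, dtype=int))
        C = ClassCenters(rng.normal(size=(2, 3)) * 10, alpha=1.0)
        for _ in range(200):
            C = update_centers(b, C)
        np.testing.assert_allclose(C.C[0], values.mean(axis=0), atol=1e-6)


# ---------------------------------------------------------------- softmax / totals


class TestSoftmaxXent:
    def test_uniform_logits_give_log_A(self):
        for A in (2, 5, 19):
            assert softmax_xent(np.zeros((3, A)), [0, 1, 0]) == pytest.approx(np.log(A))

    def test_confident_logits_approach_zero(self):
        logits = np.array([[50.0, 0.0, 0.0]])
        assert softmax_xent(logits, [0]) < 1e-9

    def test_matches_per_row_oracle(self, rng):
        logits = rng.normal(size=(10, 4))
        labels = rng.integers(0, 4, 10)
        assert softmax_xent(logits, labels) == pytest.approx(
            xent_oracle(logits, labels), abs=1e-9)

    def test_gradient_matches_finite_differences(self, rng):
        logits = rng.normal(size=(5, 3))
        labels = rng.integers(0, 3, 5)
        g = softmax_xent_grad(logits, labels)
        eps = 1e-6
        for _ in range(6):
            i, j = rng.integers(0, 5), rng.integers(0, 3)
            orig = logits[i, j]
            logits[i, j] = orig + eps
            hi = softmax_xent(logits, labels)
            logits[i, j] = orig - eps
            lo = softmax_xent(logits, labels)
            logits[i, j] = orig
            assert abs((hi - lo) / (2 * eps) - g[i, j]) < 1e-6


class TestTotalLoss:
    def test_zero_weights_reduce_to_source_loss(self):
        b = total_loss(1.7, 9.0, 4.0, LossWeights(0.0, 0.0))
        assert b.total == 1.7

    def test_arithmetic(self):
        b = total_loss(1.0, 2.0, 3.0, LossWeights(lambda_center=0.5, beta_mmd=0.1))
        assert b.total == pytest.approx(2.3, abs=1e-9)
        assert b.total == pytest.approx(b.Ls + 0.5 * b.Lc + 0.1 * b.Lm, abs=1e-9)


# ---------------------------------------------------------------- adversarial


class TestDomainConfusion:
    def test_maximal_confusion_is_log_two(self):
        logits = np.zeros((8, 2))
        labels = np.repeat([0, 1], 4)
        assert domain_confusion_loss(logits, labels) == pytest.approx(np.log(2.0))

    def test_perfect_separation_approaches_zero(self):
        logits = np.array([[40.0, 0.0], [0.0, 40.0]])
        assert domain_confusion_loss(logits, [0, 1]) < 1e-9

    def test_equals_two_class_cross_entropy(self, rng):
        logits = rng.normal(size=(10, 2))
        labels = rng.integers(0, 2, 10)
        assert domain_confusion_loss(logits, labels) == pytest.approx(
            softmax_xent(logits, labels), abs=1e-12)

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError):
            domain_confusion_loss(np.zeros((2, 2)), [0, 2])


class TestGradientReversal:
    def test_forward_is_identity(self, rng):
        x = rng.normal(size=(4, 3))
        np.testing.assert_array_equal(GradientReversal(2.0).forward(x), x)

    def test_backward_scales_by_minus_lambda(self, rng):
        """Composing f(g(x)) where g is the reversal layer: the analytic chain
        rule with the reversal contract matches finite differences."""
        grl = GradientReversal(1.7)
        w = rng.normal(size=3)
        x = rng.normal(size=3)

        def composed(v):  # scalar function through the reversal layer
            return float(np.dot(w, grl.forward(v)))

        upstream = w  # d composed / d (forward output)
        analytic = grl.backward(upstream)
        eps = 1e-6
        for j in range(3):
            e = np.zeros(3)
            e[j] = eps
            num = (composed(x + e) - composed(x - e)) / (2 * eps)
            # forward value gradient is +w; the *contract* delivers -lambda w
            assert num == pytest.approx(w[j], abs=1e-8)
            assert analytic[j] == pytest.approx(-1.7 * w[j], abs=1e-12)

    def test_zero_lambda_blocks_gradient(self, rng):
        g = GradientReversal(0.0).backward(rng.normal(size=5))
        np.testing.assert_array_equal(g, np.zeros(5))

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            GradientReversal(-0.1)


class TestWassersteinCritic:
    def test_identical_batches_zero(self, rng):
        s = rng.normal(size=10)
        assert wasserstein_critic_loss(s, s.copy()) == 0.0

    def test_unit_separation(self):
        assert wasserstein_critic_loss(np.ones(4), np.zeros(6)) == 1.0

    def test_matches_mean_difference_oracle(self, rng):
        for _ in range(100):
            s = rng.normal(size=rng.integers(1, 20))
            t = rng.normal(size=rng.integers(1, 20))
            oracle = sum(s) / len(s) - sum(t) / len(t)
            assert wasserstein_critic_loss(s, t) == pytest.approx(oracle, abs=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            wasserstein_critic_loss(np.array([]), np.ones(3))
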