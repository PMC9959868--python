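"""Softmax output layer: encoding, probabilities, cost, gradients, training."""

import numpy as np
import pytest

from hep2hos.softmax import (
    SoftmaxRegression,
    cost,
    fit,
    gradients,
    one_hot_encode,
    predict,
    softmax,
)


def make_blobs(seed=0, n_per_class=20, k=3):
    """Linearly separable 2-D class blobs."""
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0], [6, 0], [0, 6], [6, 6], [-6, 3], [3, -6]])[:k]
    X = np.vstack(
        [c + rng.normal(scale=0.5, size=(n_per_class, 2)) for c in centers]
    )
    y = np.repeat(np.arange(1, k + 1), n_per_class)
    return X, y


class TestOneHot:
    def test_first_and_last_class(self):
        assert one_hot_encode([1], 6).tolist() == [[1, 0, 0, 0, 0, 0]]
        assert one_hot_encode([6], 6).tolist() == [[0, 0, 0, 0, 0, 1]]

    def test_column_sums_count_labels(self):
        Y = one_hot_encode([2, 2, 5], 6)
        assert Y.sum(axis=0).tolist() == [0, 2, 0, 0, 1, 0]
        assert np.all(Y.sum(axis=1) == 1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            one_hot_encode([0], 6)
        with pytest.raises(ValueError):
            one_hot_encode([7], 6)


class TestSoftmax:
    def test_zeros_give_uniform(self):
        assert np.allclose(softmax(np.zeros((1, 6))), 1 / 6)

    def test_closed_form_two_classes(self):
        out = softmax(np.array([[np.log(2), 0.0]]))
        assert np.allclose(out, [[2 / 3, 1 / 3]], atol=1e-12)

    def test_shift_invariance(self, rng):
        Z = rng.normal(size=(5, 6))
        assert np.allclose(softmax(Z), softmax(Z + 100), atol=1e-12)

    def test_rows_sum_to_one_even_for_huge_inputs(self, rng):
        Z = rng.normal(scale=500, size=(20, 6))
        O = softmax(Z)
        assert np.allclose(O.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(O >= 0) and np.all(O <= 1)


class TestCost:
    def test_perfect_prediction_zero_cost(self):
        Y = one_hot_encode([1, 2, 3], 3)
        assert cost(Y, Y, lam=0.0) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_probabilities_cost_ln6(self):
        Y = one_hot_encode([1, 4, 6], 6)
        O = np.full((3, 6), 1 / 6)
        assert cost(Y, O, lam=0.0) == pytest.approx(np.log(6), abs=1e-12)

    def test_zero_weights_no_penalty(self):
        Y = one_hot_encode([1], 2)
        O = np.array([[0.5, 0.5]])
        assert cost(Y, O, W=np.zeros((3, 2)), lam=5.0) == pytest.approx(np.log(2))

    def test_penalty_added(self):
        Y = one_hot_encode([1], 2)
        W = np.ones((2, 2))
        assert cost(Y, Y, W=W, lam=0.1) == pytest.approx(0.5 * 0.1 * 4, abs=1e-9)


class TestGradients:
    def test_zero_residual_leaves_only_penalty(self, rng):
        X = rng.normal(size=(4, 3))
        Y = one_hot_encode([1, 2, 1, 2], 2)
        W = rng.normal(size=(3, 2))
        gw, gb = gradients(X, Y, Y, W, lam=0.7)
        assert np.allclose(gw, 0.7 * W, atol=1e-12)
        assert np.allclose(gb, 0.0, atol=1e-12)

    def test_single_sample_uniform_residual(self):
        X = np.array([[1.0, 0.0]])
        Y = one_hot_encode([1], 2)
        O = softmax(np.zeros((1, 2)))
        gw, gb = gradients(X, Y, O, np.zeros((2, 2)), lam=0.0)
        assert np.allclose(gw, [[-0.5, 0.5], [0.0, 0.0]])
        assert np.allclose(gb, [-0.5, 0.5])

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            gradients(rng.normal(size=(5, 3)), np.zeros((5, 4)), np.zeros((5, 4)),
                      np.zeros((2, 4)))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_central_finite_differences(self, seed):
        """Analytic gradient vs central finite differences of the
        regularized cost, relative error <= 1e-6."""
        rng = np.random.default_rng(seed)
        n, m, k = 5, 3, 4
        X = rng.normal(size=(n, m))
        y = rng.integers(1, k + 1, size=n)
        Y = one_hot_encode(y, k)
        W = rng.normal(scale=0.5, size=(m, k))
        b = rng.normal(scale=0.1, size=k)
        lam = 0.05

        def J(Wf, bf):
            return cost(Y, softmax(X @ Wf + bf), Wf, lam)

        gw, gb = gradients(X, Y, softmax(X @ W + b), W, lam)
        eps = 1e-6
        num_w = np.zeros_like(W)
        for i in range(m):
            for j in range(k):
                Wp, Wm = W.copy(), W.copy()
                Wp[i, j] += eps
                Wm[i, j] -= eps
                num_w[i, j] = (J(Wp, b) - J(Wm, b)) / (2 * eps)
        num_b = np.zeros_like(b)
        for j in range(k):
            bp, bm = b.copy(), b.copy()
            bp[j] += eps
            bm[j] -= eps
            num_b[j] = (J(W, bp) - J(W, bm)) / (2 * eps)
        scale = max(1.0, np.abs(num_w).max())
        assert np.max(np.abs(gw - num_w)) / scale <= 1e-6
        assert np.max(np.abs(gb - num_b)) / max(1.0, np.abs(num_b).max()) <= 1e-6


class TestTraining:
    def test_separable_blobs_high_training_accuracy(self):
        X, y = make_blobs(seed=3, n_per_class=20, k=3)
        model = SoftmaxRegression(eta=0.01, iterations=500, lam=0.01, random_state=0)
        model.fit(X, y)
        assert (model.predict(X) == y).mean() >= 0.95

    def test_cost_trace_monotone_at_small_step(self):
        X, y = make_blobs(seed=5, n_per_class=10, k=3)
        model = SoftmaxRegression(eta=0.001, iterations=300, lam=0.0, random_state=1)
        model.fit(X, y)
        trace = np.asarray(model.cost_trace_)
        assert np.all(np.diff(trace) <= 1e-12)

    def test_deterministic_given_seed(self):
        X, y = make_blobs(seed=2)
        m1 = SoftmaxRegression(random_state=9).fit(X, y)
        m2 = SoftmaxRegression(random_state=9).fit(X, y)
        assert np.array_equal(m1.W_, m2.W_)
        assert np.array_equal(m1.b_, m2.b_)

    def test_regularization_shrinks_weights(self):
        X, y = make_blobs(seed=4)
        norms = []
        for lam in (0.0, 0.01, 0.1, 1.0):
            m = SoftmaxRegression(lam=lam, iterations=300, random_state=0).fit(X, y)
            norms.append(np.sum(m.W_**2))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_fixed_init_requires_six_classes(self):
        X, y = make_blobs(seed=0, k=3)
        with pytest.raises(ValueError):
            SoftmaxRegression(init="fixed").fit(X, y)

    def test_functional_interface_round_trip(self):
        X, y = make_blobs(seed=1, k=3)
        params, trace = fit(X, y, eta=0.01, iterations=200, lam=0.01, seed=5)
        labels, P = predict(X, params)
        assert (labels == y).mean() >= 0.95
        assert len(trace.cost_per_iteration) == 200
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)


class TestPredict:
    def test_zero_model_ties_break_to_first_class(self):
        X = np.ones((4, 3))
        model = SoftmaxRegression(iterations=1).fit(
            np.eye(6, 3), np.arange(1, 7)
        )
        model.W_ = np.zeros((3, 6))
        model.b_ = np.zeros(6)
        labels = model.predict(X)
        assert np.all(labels == model.classes_[0])
        assert np.allclose(model.predict_proba(X), 1 / 6)

    def test_bias_dominates_when_weights_zero(self):
        model = SoftmaxRegression(iterations=1).fit(np.eye(6, 3), np.arange(1, 7))
        model.W_ = np.zeros((3, 6))
        model.b_ = np.array([10.0, 0, 0, 0, 0, 0])
        P = model.predict_proba(np.zeros((2, 3)))
        expected = np.exp(10) / (np.exp(10) + 5)
        assert np.allclose(P[:, 0], expected, atol=1e-9)

    def test_dimension_mismatch_rejected(self):
        X, y = make_blobs(seed=0, k=3)
        model = SoftmaxRegression(iterations=10).fit(X, y)
        with pytest.raises(ValueError):
            model.predict(np.zeros((2, 5)))
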