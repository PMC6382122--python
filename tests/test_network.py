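"""Unit and property tests for the network primitives.

The attention equations and the convolution branch are checked against
independent step-by-step computations (pure-python loops over math.tanh /
math.exp), and the full backward pass is checked against central finite
differences.
"""

import math

import numpy as np
import pytest

from temporient import AttentionParams, CnnParams, attend, convolve_features
from temporient import network as net


def hand_attention(M, Ww, bw, pw):
    """Step-by-step attention oracle: p_t=tanh(Ww m_t+bw); softmax; sum."""
    N = M.shape[1]
    scores = []
    for t in range(N):
        m_t = M[:, t]
        p_t = [math.tanh(sum(Ww[a][j] * m_t[j] for j in range(len(m_t)))
                         + bw[a]) for a in range(len(bw))]
        scores.append(sum(p_t[a] * pw[a] for a in range(len(pw))))
    mx = max(scores)
    exps = [math.exp(s - mx) for s in scores]
    alpha = [e / sum(exps) for e in exps]
    s_vec = [sum(alpha[t] * M[j, t] for t in range(N))
             for j in range(M.shape[0])]
    return np.array(alpha), np.array(s_vec)


class TestAttend:
    def test_singleton_is_identity(self, rng):
        M = rng.standard_normal((4, 1))
        params = AttentionParams(W_w=rng.standard_normal((3, 4)),
                                 b_w=rng.standard_normal(3),
                                 p_w=rng.standard_normal(3))
        out = attend(M, params)
        assert out.weights == pytest.approx([1.0])
        assert np.allclose(out.sentence_vector, M[:, 0])

    def test_identical_columns_uniform_weights(self, rng):
        col = rng.standard_normal(4)
        M = np.tile(col[:, None], (1, 5))
        params = AttentionParams(W_w=rng.standard_normal((3, 4)),
                                 b_w=rng.standard_normal(3),
                                 p_w=rng.standard_normal(3))
        out = attend(M, params)
        assert np.allclose(out.weights, 0.2)
        assert np.allclose(out.sentence_vector, col)

    def test_matches_hand_computation(self):
        # small integer inputs, fixed parameters; oracle is a pure-python
        # re-derivation of the three attention equations
        M = np.array([[1.0, 2.0, -1.0],
                      [0.0, 1.0, 3.0]])
        Ww = np.array([[0.5, -1.0], [1.0, 0.5]])
        bw = np.array([0.1, -0.2])
        pw = np.array([1.0, 2.0])
        exp_alpha, exp_s = hand_attention(M, Ww, bw, pw)
        out = attend(M, AttentionParams(W_w=Ww, b_w=bw, p_w=pw))
        assert np.allclose(out.weights, exp_alpha, atol=1e-9)
        assert np.allclose(out.sentence_vector, exp_s, atol=1e-9)

    def test_dimension_mismatch_is_fatal(self, rng):
        M = rng.standard_normal((4, 3))
        params = AttentionParams(W_w=rng.standard_normal((3, 4)),
                                 b_w=rng.standard_normal(3),
                                 p_w=rng.standard_normal(5))  # wrong length
        with pytest.raises(ValueError, match="dimension mismatch"):
            attend(M, params)

    def test_weights_normalized_fuzz(self, rng):
        for _ in range(100):
            N = int(rng.integers(1, 12))
            M = rng.standard_normal((6, N)) * 3
            params = AttentionParams(W_w=rng.standard_normal((5, 6)),
                                     b_w=rng.standard_normal(5),
                                     p_w=rng.standard_normal(5))
            out = attend(M, params)
            assert abs(out.weights.sum() - 1.0) < 1e-6
            assert np.all(out.weights > 0)


class TestConvolveFeatures:
    @staticmethod
    def _params(d, windows, filters=1, kernel=None, bias=0.0):
        kernels, biases = {}, {}
        for w in windows:
            K = (np.ones((filters, d, w)) if kernel is None
                 else np.broadcast_to(kernel, (filters, d, w)).copy())
            kernels[w] = K
            biases[w] = np.full(filters, bias)
        return CnnParams(kernels=kernels, biases=biases)

    def test_zero_input_zero_bias(self):
        E = np.zeros((4, 7))
        f = convolve_features(E, self._params(4, (5, 6, 7), filters=2))
        assert np.allclose(f, np.tanh(0.0))

    def test_single_nonzero_column_hand_convolution(self):
        # kernel of ones: every window containing the column sums it
        E = np.zeros((4, 7))
        E[:, 3] = [0.1, 0.2, 0.3, 0.4]
        f = convolve_features(E, self._params(4, (5,)))
        assert f.shape == (1,)
        assert f[0] == pytest.approx(math.tanh(1.0), abs=1e-12)

    def test_appending_zero_columns_leaves_f_unchanged(self, rng):
        E = rng.standard_normal((4, 7))
        params = self._params(4, (5, 6, 7), filters=3,
                              kernel=rng.standard_normal((4, 1)))
        f1 = convolve_features(E, params, n_content=7)
        E2 = np.concatenate([E, np.zeros((4, 7))], axis=1)
        f2 = convolve_features(E2, params, n_content=7)
        assert np.allclose(f1, f2)

    def test_output_length(self, rng):
        E = rng.standard_normal((4, 9))
        params = self._params(4, (5, 6, 7), filters=3)
        assert convolve_features(E, params).shape == (9,)


class TestForwardHead:
    def test_probabilities_sum_to_one_fuzz(self, rng):
        windows = (2, 3)
        params = net.init_params(rng, 4, 3, None, windows, 2)
        for _ in range(100):
            word = rng.standard_normal((2, 6, 4)) * 2
            E = rng.standard_normal((2, 4, 4))
            y, _ = net.model_forward(params, word, E, np.array([3, 1]),
                                     windows)
            assert np.allclose(y.sum(axis=1), 1.0, atol=1e-6)
            assert np.all(y > 0)

    def test_zero_head_uniform_and_tiebreak(self, rng):
        windows = (2,)
        params = net.init_params(rng, 4, 3, None, windows, 2)
        params["out_W"][:] = 0.0
        params["out_b"][:] = 0.0
        word = rng.standard_normal((1, 5, 4))
        E = rng.standard_normal((1, 3, 4))
        y, _ = net.model_forward(params, word, E, np.array([2]), windows)
        assert np.allclose(y, 1.0 / 3.0)
        assert net.CLASSES[int(np.argmax(y[0]))] == "past"


class TestGradients:
    def test_backward_matches_finite_differences(self, rng):
        d, H, N, L = 3, 4, 5, 4
        windows = (2, 3)
        params = net.init_params(rng, d, H, None, windows, 2)
        word = rng.standard_normal((3, N, d))
        E = rng.standard_normal((3, L, d))
        n_content = np.array([4, 2, 1])
        targets = np.array([0, 2, 1])
        _, cache = net.model_forward(params, word, E, n_content, windows)
        grads = net.model_backward(cache, targets)

        def loss():
            y, _ = net.model_forward(params, word, E, n_content, windows)
            return net.cross_entropy(y, targets)

        eps = 1e-5
        for key, g in grads.items():
            assert g.shape == params[key].shape
            flat = params[key].reshape(-1)
            gflat = g.reshape(-1)
            idxs = rng.choice(flat.size, size=min(8, flat.size),
                              replace=False)
            for i in idxs:
                orig = flat[i]
                flat[i] = orig + eps
                lp = loss()
                flat[i] = orig - eps
                lm = loss()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                assert gflat[i] == pytest.approx(num, rel=1e-3, abs=1e-7), key

    def test_permuting_padding_columns_invariant(self, rng):
        # columns of E beyond n_content are zero padding; permuting them (a
        # no-op on values) and appending more must not change y
        d, N = 3, 5
        windows = (2, 3)
        params = net.init_params(rng, d, 4, None, windows, 2)
        word = rng.standard_normal((1, N, d))
        E = np.zeros((1, 6, d))
        E[0, :2] = rng.standard_normal((2, d))
        y1, _ = net.model_forward(params, word, E, np.array([2]), windows)
        E2 = np.concatenate([E, np.zeros((1, 3, d))], axis=1)
        y2, _ = net.model_forward(params, word, E2, np.array([2]), windows)
        assert np.allclose(y1, y2)


class TestOptimizer:
    def test_sgd_step(self):
        params = {"w": np.array([1.0, 2.0])}
        opt = net.Optimizer(params, "sgd", lr=0.1)
        opt.step(params, {"w": np.array([1.0, -1.0])})
        assert np.allclose(params["w"], [0.9, 2.1])

    def test_rmsprop_first_step_magnitude(self):
        # after one step the update is lr * g / (sqrt(0.1 g^2) + eps)
        params = {"w": np.array([0.0])}
        opt = net.Optimizer(params, "rmsprop", lr=0.01)
        g = np.array([2.0])
        opt.step(params, {"w": g})
        expected = -0.01 * 2.0 / (math.sqrt(0.1 * 4.0) + 1e-8)
        assert params["w"][0] == pytest.approx(expected)

    def test_unknown_optimizer_rejected(self):
        with pytest.raises(ValueError):
            net.Optimizer({"w": np.zeros(1)}, "adagrad")
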