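"""Attention building blocks, backprop correctness, training behavior."""

import numpy as np
import pytest
from scipy import stats

from vmdecg.nn import (
    AttentionClassifier,
    EncoderConfig,
    TrainHyperparams,
    encode_modes,
    frame_tokens,
    multi_head_attention,
    paired_ttest,
    position_wise_ffn,
    scaled_dot_product_attention,
    sinusoidal_positions,
)


class TestScaledDotProductAttention:
    def test_zero_scores_average_values(self):
        # QK^T = 0 -> uniform weights 1/n -> rows equal the column mean of V
        Q = np.zeros((2, 2))
        K = np.zeros((3, 2))
        V = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        out = scaled_dot_product_attention(Q, K, V)
        assert out == pytest.approx(np.tile(V.mean(axis=0), (2, 1)))

    def test_single_key_returns_that_value(self, rng):
        Q = rng.normal(0, 1, (4, 3))
        K = rng.normal(0, 1, (1, 3))
        V = rng.normal(0, 1, (1, 5))
        out = scaled_dot_product_attention(Q, K, V)
        assert out == pytest.approx(np.tile(V[0], (4, 1)))

    def test_weight_rows_sum_to_one(self, rng):
        Q, K, V = (rng.normal(0, 1, (6, 4)) for _ in range(3))
        _, W = scaled_dot_product_attention(Q, K, V, return_weights=True)
        assert W.sum(axis=-1) == pytest.approx(np.ones(6), abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_product_attention(np.ones((2, 3)), np.ones((2, 4)), np.ones((2, 2)))


class TestMultiHeadAttention:
    def _identity_params(self, d):
        eye = np.eye(d)
        return {"Wq": eye, "Wk": eye, "Wv": eye, "Wo": eye}

    def test_single_head_identity_reduces_to_sdpa(self, rng):
        X = rng.normal(0, 1, (5, 4))
        out = multi_head_attention(X, self._identity_params(4), h=1)
        assert out == pytest.approx(scaled_dot_product_attention(X, X, X))

    def test_output_shape_preserved(self, rng):
        X = rng.normal(0, 1, (8, 16))
        params = {k: rng.normal(0, 0.5, (16, 16)) for k in ("Wq", "Wk", "Wv", "Wo")}
        assert multi_head_attention(X, params, h=4).shape == (8, 16)

    def test_permutation_equivariance(self, rng):
        X = rng.normal(0, 1, (6, 8))
        params = {k: rng.normal(0, 0.5, (8, 8)) for k in ("Wq", "Wk", "Wv", "Wo")}
        perm = rng.permutation(6)
        out = multi_head_attention(X, params, h=2)
        out_perm = multi_head_attention(X[perm], params, h=2)
        assert out_perm == pytest.approx(out[perm])

    def test_divisibility_enforced(self, rng):
        X = rng.normal(0, 1, (4, 6))
        with pytest.raises(ValueError):
            multi_head_attention(X, self._identity_params(6), h=4)


class TestPositionWiseFFN:
    def test_identity_path(self):
        x = np.array([[1.0, 2.0], [0.5, 3.0]])
        eye = np.eye(2)
        assert position_wise_ffn(x, eye, 0.0, eye, 0.0) == pytest.approx(x)

    def test_relu_zeroes_negative_input(self):
        x = -np.ones((2, 3))
        W1 = np.eye(3)
        W2 = np.eye(3)
        b2 = np.array([7.0, 8.0, 9.0])
        assert position_wise_ffn(x, W1, 0.0, W2, b2) == pytest.approx(np.tile(b2, (2, 1)))

    def test_matches_hand_matrix_arithmetic(self, rng):
        x = rng.normal(0, 1, (3, 4))
        W1, b1 = rng.normal(0, 1, (4, 5)), rng.normal(0, 1, 5)
        W2, b2 = rng.normal(0, 1, (5, 4)), rng.normal(0, 1, 4)
        expected = np.maximum(x @ W1 + b1, 0) @ W2 + b2
        assert position_wise_ffn(x, W1, b1, W2, b2) == pytest.approx(expected)


class TestTokenization:
    def test_token_count(self):
        cfg = EncoderConfig(frame_len=16)
        tok = encode_modes(np.zeros((5, 1024)), cfg)
        assert tok.shape == (64, cfg.d_model)

    def test_token_count_independent_of_channel_count(self):
        assert frame_tokens(np.ones((3, 100)), 16).shape[0] == frame_tokens(
            np.ones((7, 100)), 16
        ).shape[0] == 7  # ceil(100/16)

    def test_zero_modes_give_pure_positional_encoding(self):
        cfg = EncoderConfig(frame_len=8, d_model=16)
        tok = encode_modes(np.zeros((2, 64)), cfg)
        assert tok == pytest.approx(sinusoidal_positions(8, 16))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            frame_tokens(np.empty((0,)), 8)


class TestBackpropagation:
    def test_gradients_match_finite_differences(self, rng):
        X = rng.normal(0, 1, (6, 2, 20))
        y = np.array([0, 1, 2, 0, 1, 2])
        enc = EncoderConfig(d_model=8, n_heads=2, n_layers=2, d_ff=12, frame_len=5)
        m = AttentionClassifier(X, y, enc, dtype=np.float64)
        params = m.init_params(seed=1)
        idx = np.arange(6)
        grads = m.gradients(params, idx)
        eps = 1e-6
        for name in params:
            P = params[name]
            for fi in rng.choice(P.size, size=min(4, P.size), replace=False):
                mi = np.unravel_index(fi, P.shape)
                old = P[mi]
                P[mi] = old + eps
                lp = m.loss(params, idx)
                P[mi] = old - eps
                lm = m.loss(params, idx)
                P[mi] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[name][mi]
                assert abs(num - ana) < 1e-6 + 1e-3 * (abs(num) + abs(ana)), name


class TestTraining:
    def _toy(self, rng, n=180):
        y = rng.integers(0, 3, n)
        X = rng.normal(0, 1, (n, 2, 64)) + y[:, None, None] * 2.0
        return X, y

    def test_separable_toy_reaches_full_accuracy(self, rng):
        X, y = self._toy(rng)
        enc = EncoderConfig(d_model=32, n_heads=4, n_layers=2, d_ff=64, frame_len=8)
        m = AttentionClassifier(X, y, enc)
        res = m.fit(np.arange(140), np.arange(140, 180),
                    TrainHyperparams(epochs=30, batch_size=16, learning_rate=0.01, seed=0))
        assert res.report.accuracy == 100.0

    def test_label_shuffle_is_at_chance(self, rng):
        X, y = self._toy(rng, n=240)
        y_shuf = rng.permutation(y)
        enc = EncoderConfig(d_model=16, n_heads=2, n_layers=1, d_ff=32, frame_len=8)
        m = AttentionClassifier(X, y_shuf, enc)
        res = m.fit(np.arange(180), np.arange(180, 240),
                    TrainHyperparams(epochs=10, batch_size=16, learning_rate=0.01, seed=0))
        assert abs(res.report.accuracy - 33.3) < 15.0

    def test_seeded_runs_are_identical(self, rng):
        X, y = self._toy(rng)
        enc = EncoderConfig(d_model=16, n_heads=2, n_layers=1, d_ff=32, frame_len=8)
        hp = TrainHyperparams(epochs=3, batch_size=16, learning_rate=0.01, seed=7)
        r1 = AttentionClassifier(X, y, enc).fit(np.arange(140), np.arange(140, 180), hp)
        r2 = AttentionClassifier(X, y, enc).fit(np.arange(140), np.arange(140, 180), hp)
        assert np.array_equal(r1.report.confusion, r2.report.confusion)
        assert np.array_equal(r1.report.loss_curve, r2.report.loss_curve)

    def test_confusion_matrix_consistency(self, rng):
        X, y = self._toy(rng)
        enc = EncoderConfig(d_model=16, n_heads=2, n_layers=1, d_ff=32, frame_len=8)
        m = AttentionClassifier(X, y, enc)
        res = m.fit(np.arange(140), np.arange(140, 180),
                    TrainHyperparams(epochs=2, batch_size=16, seed=0))
        C = res.report.confusion
        # row sums equal per-class test counts; trace/total equals accuracy
        counts = np.bincount(y[140:180], minlength=3)
        assert np.array_equal(C.sum(axis=1), counts)
        assert res.report.accuracy == pytest.approx(100.0 * np.trace(C) / C.sum())

    def test_summary_contains_key_numbers(self, rng):
        X, y = self._toy(rng, n=60)
        enc = EncoderConfig(d_model=16, n_heads=2, n_layers=1, d_ff=32, frame_len=8)
        res = AttentionClassifier(X, y, enc).fit(
            np.arange(48), np.arange(48, 60), TrainHyperparams(epochs=1, seed=0)
        )
        s = res.summary()
        assert "test accuracy" in s and "confusion" in s

    def test_mixed_mode_counts_rejected(self):
        with pytest.raises(ValueError):
            AttentionClassifier(np.zeros((3, 20)), np.zeros(3, dtype=int))


class TestPairedTTest:
    def test_identical_samples(self):
        t, p = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_constant_difference_floors_p(self):
        t, p = paired_ttest([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert p == 0.0

    def test_matches_scipy_on_fixture(self):
        a = [91.2, 92.5, 90.8, 93.1, 92.0, 91.7, 92.9, 90.5, 91.9, 92.3]
        b = [90.1, 91.8, 90.9, 92.0, 91.5, 90.8, 92.1, 90.0, 91.2, 91.6]
        t, p = paired_ttest(a, b)
        t_ref, p_ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(float(t_ref))
        assert p == pytest.approx(float(p_ref))

    def test_validation(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0], [1.0])
        with pytest.raises(ValueError):
            paired_ttest([1.0, 2.0], [1.0, 2.0, 3.0])
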