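import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rbcmorph import cnn
from rbcmorph.cnn import NetworkSpec, TrainConfig, cross_entropy, one_hot, softmax

# small spec used for fast training behavior tests
SMALL_SPEC = dict(
    input_size=32, conv_channels=(4, 8, 8), conv_kernels=(3, 3, 3),
    fc_units=24, dropout_p=0.25,
)


def small_shape_data(n_per_class=30, seed=0, size=32):
    """Tiny 3-class geometric dataset (disc / bar / ring) at low resolution."""
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size] - size / 2
    xs, ys = [], []
    for ci in range(3):
        for _ in range(n_per_class):
            img = np.full((size, size), 200.0)
            r = rng.uniform(8, 11)
            if ci == 0:
                body = xx**2 + yy**2 <= r**2
            elif ci == 1:
                body = (np.abs(yy) <= 3) & (np.abs(xx) <= r + 2)
            else:
                rho = np.hypot(xx, yy)
                body = (rho <= r) & (rho >= r - 3)
            img[body] = 120.0
            img += rng.normal(0, 4, img.shape)
            xs.append(np.clip(img, 0, 255))
            ys.append(ci)
    return np.stack(xs), np.array(ys)


class TestSoftmax:
    def test_uniform(self):
        np.testing.assert_allclose(softmax(np.zeros(5)), 0.2)

    def test_hand_computed(self):
        out = softmax(np.array([np.log(2.0), 0.0]))
        np.testing.assert_allclose(out, [2 / 3, 1 / 3], atol=1e-12)

    def test_shift_invariance(self):
        q = np.array([1.0, -2.0, 0.5])
        np.testing.assert_allclose(softmax(q), softmax(q + 123.0), atol=1e-12)

    def test_overflow_guard(self):
        out = softmax(np.array([1e4, 0.0]))
        assert np.isfinite(out).all()

    @given(arrays(np.float64, 6, elements=st.floats(-50, 50)))
    @settings(max_examples=50, deadline=None)
    def test_sums_to_one(self, q):
        out = softmax(q)
        assert abs(out.sum() - 1.0) <= 1e-9
        assert (out > 0).all()


class TestCrossEntropy:
    def test_perfect_prediction_zero(self):
        assert cross_entropy(np.array([[0, 1.0, 0]]), np.array([[0, 1.0, 0]])) == 0.0

    def test_uniform_five(self):
        probs = np.full((1, 5), 0.2)
        target = one_hot(np.array([2]), 5)
        assert cross_entropy(probs, target) == pytest.approx(np.log(5))

    def test_quarter(self):
        probs = np.array([[0.25, 0.75]])
        target = one_hot(np.array([0]), 2)
        assert cross_entropy(probs, target) == pytest.approx(np.log(4))

    def test_zero_clamped(self):
        probs = np.array([[0.0, 1.0]])
        target = one_hot(np.array([0]), 2)
        assert np.isfinite(cross_entropy(probs, target))

    def test_nonnegative(self, rng):
        probs = rng.dirichlet(np.ones(4), size=10)
        targets = one_hot(rng.integers(0, 4, 10), 4)
        assert cross_entropy(probs, targets) >= 0


class TestForward:
    def test_output_dimension_matches_spec(self, rng):
        for n in (5, 8):
            spec = NetworkSpec(n_classes=n, **SMALL_SPEC)
            params = cnn.init_params(spec, seed=0)
            scores = cnn.forward(spec, params, rng.random((3, 32, 32)))
            assert scores.shape == (3, n)

    def test_eval_deterministic(self, rng):
        spec = NetworkSpec(n_classes=4, **SMALL_SPEC)
        params = cnn.init_params(spec, seed=1)
        x = rng.random((2, 32, 32))
        s1 = cnn.forward(spec, params, x)
        s2 = cnn.forward(spec, params, x)
        np.testing.assert_array_equal(s1, s2)

    def test_train_mode_needs_rng(self, rng):
        spec = NetworkSpec(n_classes=4, **SMALL_SPEC)
        params = cnn.init_params(spec, seed=1)
        with pytest.raises(ValueError, match="rng"):
            cnn.forward(spec, params, rng.random((1, 32, 32)), train=True)

    def test_shape_mismatch_rejected(self, rng):
        spec = NetworkSpec(n_classes=4, **SMALL_SPEC)
        params = cnn.init_params(spec, seed=1)
        with pytest.raises(ValueError, match="input shape"):
            cnn.forward(spec, params, rng.random((1, 20, 20)))

    def test_conv_translation_equivariance(self):
        # brute-force correlation oracle on a single conv layer
        rng = np.random.default_rng(7)
        w = rng.normal(size=(2, 1, 3, 3))
        b = np.zeros(2)
        x = np.zeros((1, 1, 12, 12))
        x[0, 0, 4, 5] = 1.0
        out1, _ = cnn.conv_forward(x, w, b)
        x2 = np.zeros_like(x)
        x2[0, 0, 6, 8] = 1.0
        out2, _ = cnn.conv_forward(x2, w, b)
        np.testing.assert_allclose(out1[0, :, 2:6, 3:7], out2[0, :, 4:8, 6:10])
        # direct correlation oracle
        from scipy.ndimage import correlate

        oracle = correlate(x[0, 0], w[0, 0], mode="constant")[1:-1, 1:-1]
        np.testing.assert_allclose(out1[0, 0], oracle, atol=1e-12)


class TestGradients:
    def test_finite_difference_check(self):
        spec = NetworkSpec(n_classes=3, input_size=12, conv_channels=(2,),
                           conv_kernels=(3,), fc_units=5, dropout_p=0.0)
        params = cnn.init_params(spec, seed=0, dtype=np.float64)
        rng = np.random.default_rng(1)
        x = rng.random((4, 12, 12))
        y = np.array([0, 1, 2, 1])
        _, grads, _ = cnn.loss_and_grads(spec, params, x, y, weight_decay=0.01,
                                         train=False)
        pick = np.random.default_rng(2)
        for key in params:
            flat = params[key].ravel()
            for idx in pick.choice(flat.size, size=min(5, flat.size), replace=False):
                eps = 1e-6
                orig = flat[idx]
                flat[idx] = orig + eps
                lp, _, _ = cnn.loss_and_grads(spec, params, x, y, 0.01, train=False)
                flat[idx] = orig - eps
                lm, _, _ = cnn.loss_and_grads(spec, params, x, y, 0.01, train=False)
                flat[idx] = orig
                numeric = (lp - lm) / (2 * eps)
                analytic = grads[key].ravel()[idx]
                rel = abs(numeric - analytic) / max(1e-8, abs(numeric) + abs(analytic))
                assert rel < 1e-4, (key, idx, numeric, analytic)


class TestTrain:
    def test_loss_decreases_and_deterministic(self):
        X, y = small_shape_data(20, seed=3)
        spec = NetworkSpec(n_classes=3, **SMALL_SPEC)
        cfg = TrainConfig(learning_rate=0.03, batch_size=10, weight_decay=0.0005,
                          epochs=8, seed=5)
        p1, h1 = cnn.train(X, y, spec, cfg)
        p2, h2 = cnn.train(X, y, spec, cfg)
        assert h1.loss == h2.loss
        assert h1.train_error == h2.train_error
        for k in p1:
            np.testing.assert_array_equal(p1[k], p2[k])
        assert h1.loss[-1] < h1.loss[0]

    def test_error_trend_smoothed_nonincreasing(self):
        X, y = small_shape_data(20, seed=3)
        spec = NetworkSpec(n_classes=3, **SMALL_SPEC)
        cfg = TrainConfig(learning_rate=0.03, batch_size=10, weight_decay=0.0005,
                          epochs=10, seed=5)
        _, hist = cnn.train(X, y, spec, cfg)
        err = np.array(hist.train_error)
        smoothed = np.convolve(err, np.ones(5) / 5, mode="valid")
        assert smoothed[-1] <= smoothed[0]

    def test_higher_lr_faster_initial_decay(self):
        X, y = small_shape_data(20, seed=3)
        spec = NetworkSpec(n_classes=3, **SMALL_SPEC)
        losses = {}
        for lr in (0.01, 0.03):
            cfg = TrainConfig(learning_rate=lr, batch_size=10,
                              weight_decay=0.0005, epochs=5, seed=5)
            _, hist = cnn.train(X, y, spec, cfg)
            losses[lr] = hist.loss[-1]
        assert losses[0.03] <= losses[0.01]

    def test_history_lengths(self):
        X, y = small_shape_data(10, seed=1)
        spec = NetworkSpec(n_classes=3, **SMALL_SPEC)
        cfg = TrainConfig(learning_rate=0.02, batch_size=10, epochs=4,
                          weight_decay=0.0, seed=0)
        _, hist = cnn.train(X, y, spec, cfg, X[:6], y[:6])
        assert len(hist.loss) == len(hist.train_error) == len(hist.val_error) == 4


class TestPredict:
    def _trained(self):
        X, y = small_shape_data(20, seed=3)
        spec = NetworkSpec(n_classes=3, **SMALL_SPEC)
        cfg = TrainConfig(learning_rate=0.03, batch_size=10, weight_decay=0.0005,
                          epochs=6, seed=5)
        params, _ = cnn.train(X, y, spec, cfg)
        return spec, params, X

    def test_argmax_and_tie_break(self):
        assert np.argmax(np.array([0.1, 0.7, 0.2])) == 1
        assert np.argmax(np.array([0.5, 0.5])) == 0

    def test_batch_invariance(self):
        spec, params, X = self._trained()
        l_all, p_all = cnn.predict(spec, params, X[:12], batch_size=12)
        l_one = np.concatenate(
            [cnn.predict(spec, params, X[i : i + 1])[0] for i in range(12)]
        )
        np.testing.assert_array_equal(l_all, l_one)

    def test_probabilities_valid(self):
        spec, params, X = self._trained()
        _, probs = cnn.predict(spec, params, X[:8])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)


class TestCheckpoint:
    def test_roundtrip(self, tmp_path):
        spec = NetworkSpec(n_classes=4, **SMALL_SPEC)
        params = cnn.init_params(spec, seed=3)
        path = tmp_path / "model.npz"
        cnn.save_checkpoint(path, spec, params)
        spec2, params2 = cnn.load_checkpoint(path)
        assert spec2 == spec
        for k in params:
            np.testing.assert_array_equal(params[k], params2[k])


class TestSpecValidation:
    def test_mismatched_conv_lists(self):
        with pytest.raises(ValueError):
            NetworkSpec(conv_channels=(8, 16), conv_kernels=(5,))

    def test_bad_dropout(self):
        with pytest.raises(ValueError):
            NetworkSpec(dropout_p=1.0)

    def test_bad_lr(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
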