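"""1-D CNN / ResNet architectures, softmax, SGD training, deep features."""

from decimal import Decimal, getcontext

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seedspectra as ss
from seedspectra.errors import StateError, TrainingError
from seedspectra.nn import layers as L
from seedspectra.nn import NetworkSpec, TrainingConfig, build_network, train
from seedspectra.nn.training import extract_features


class TestSoftmax:
    def test_uniform_logits_give_uniform_probabilities(self):
        np.testing.assert_allclose(ss.softmax(np.zeros(3)), 1 / 3, atol=1e-15)

    @given(c=st.floats(-50, 50))
    @settings(max_examples=25, deadline=None)
    def test_shift_invariance(self, c):
        z = np.array([0.3, -1.2, 2.5, 0.0])
        np.testing.assert_allclose(ss.softmax(z + c), ss.softmax(z), atol=1e-12)

    def test_matches_extended_precision_oracle(self):
        """sigma(z)_i = e^{z_i} / sum_k e^{z_k} evaluated with 50-digit
        decimal arithmetic."""
        getcontext().prec = 50
        z = [1.0, 2.0, 3.0]
        exps = [Decimal(v).exp() for v in z]
        total = sum(exps)
        oracle = np.array([float(e / total) for e in exps])
        np.testing.assert_allclose(ss.softmax(np.array(z)), oracle, atol=1e-12)

    def test_always_a_probability_vector(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = ss.softmax(rng.normal(0, 10, size=7))
            assert np.all(p > 0)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            ss.softmax(np.array([]))


def numeric_gradient(f, x, eps=1e-3):
    grad = np.zeros_like(x, dtype=np.float64)
    flat = x.reshape(-1)
    gflat = grad.reshape(-1)
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        hi = f()
        flat[i] = orig - eps
        lo = f()
        flat[i] = orig
        gflat[i] = (hi - lo) / (2 * eps)
    return grad


class TestBackpropagation:
    """Central-difference gradient checks of every layer's backward pass."""

    def check_layer(self, layer, x_shape, seed=0, atol=2e-2):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, x_shape).astype(np.float32)
        out = layer.forward(x.copy(), train=True)
        w = rng.normal(0, 1, out.shape).astype(np.float32)

        def loss():
            return float((layer.forward(x.copy(), train=True) * w).sum())

        loss()  # populate caches for the analytic pass
        dx = layer.backward(w.copy())
        dx_num = numeric_gradient(lambda: float(
            (layer.forward(x.copy(), train=True) * w).sum()), x)
        np.testing.assert_allclose(dx, dx_num, atol=atol)
        for value, grad in layer.params():
            loss()
            layer.backward(w.copy())
            analytic = grad.copy()
            numeric = numeric_gradient(lambda: float(
                (layer.forward(x.copy(), train=True) * w).sum()), value)
            np.testing.assert_allclose(analytic, numeric, atol=atol)

    def test_conv1d_same_padding(self):
        rng = np.random.default_rng(1)
        self.check_layer(L.Conv1d(2, 3, 3, stride=1, rng=rng), (2, 2, 7))

    def test_conv1d_stride_two(self):
        rng = np.random.default_rng(2)
        self.check_layer(L.Conv1d(2, 3, 3, stride=2, rng=rng), (2, 2, 8))

    def test_dense(self):
        rng = np.random.default_rng(3)
        self.check_layer(L.Dense(5, 4, rng=rng), (3, 5))

    def test_maxpool(self):
        self.check_layer(L.MaxPool1d(2), (2, 3, 9))

    def test_global_average_pool(self):
        self.check_layer(L.GlobalAvgPool1d(), (2, 3, 6))

    def test_residual_block_with_projection(self):
        rng = np.random.default_rng(4)
        self.check_layer(
            L.ResidualBlock(2, 4, stride=2, batchnorm=False, rng=rng),
            (2, 2, 8))

    def test_softmax_cross_entropy_gradient(self):
        rng = np.random.default_rng(5)
        logits = rng.normal(0, 1, (4, 3)).astype(np.float64)
        labels = np.array([0, 2, 1, 1])
        loss_fn = L.SoftmaxCrossEntropy()
        loss_fn.forward(logits, labels)
        analytic = loss_fn.backward()
        numeric = numeric_gradient(
            lambda: loss_fn.forward(logits, labels), logits, eps=1e-5)
        np.testing.assert_allclose(analytic, numeric, atol=1e-6)


class TestArchitectures:
    def test_cnn_layer_widths_match_design(self):
        net = build_network(NetworkSpec(architecture="self-design-cnn"), 200)
        audit = net.architecture_audit()
        assert audit["conv_channels"] == [64, 128]
        assert audit["dense_sizes"] == [512, 128, 7]
        assert audit["feature_dim"] == 128

    def test_resnet_layer_widths_match_design(self):
        net = build_network(NetworkSpec(architecture="resnet-1d"), 200)
        audit = net.architecture_audit()
        assert audit["residual_block_channels"] == [64, 128, 256, 512]
        assert audit["dense_sizes"] == [7]
        assert audit["feature_dim"] == 512

    def test_cnn_forward_is_a_probability_vector(self):
        net = build_network(NetworkSpec(architecture="self-design-cnn"), 64)
        proba = net.predict_proba(np.random.default_rng(0).random((1, 64)))
        assert proba.shape == (1, 7)
        assert proba[0].sum() == pytest.approx(1.0, abs=1e-9)

    def test_cnn_dense2_feature_has_128_elements(self):
        net = build_network(NetworkSpec(architecture="self-design-cnn"), 64)
        net.trained = True
        feats = net.features(np.random.default_rng(1).random((3, 64)))
        assert feats.shape == (3, 128)
        assert np.all(feats >= 0)  # ReLU-activated

    def test_resnet_gap_feature_has_512_elements(self):
        net = build_network(NetworkSpec(architecture="resnet-1d"), 64)
        net.trained = True
        feats = net.features(np.random.default_rng(2).random((3, 64)))
        assert feats.shape == (3, 512)

    def test_resnet_gap_equals_explicit_channel_mean_oracle(self):
        net = build_network(NetworkSpec(architecture="resnet-1d"), 32,
                            rng_seed=5)
        net.trained = True
        x = np.random.default_rng(3).random((2, 32))
        feats = net.features(x)
        # oracle: run the layers by hand up to the GAP input, then average
        act = net._prepare(x)
        for layer in net.layers[:net.feature_index]:
            act = layer.forward(act)
        np.testing.assert_allclose(feats, act.mean(axis=2), atol=1e-6)

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(architecture="transformer")

    def test_too_few_bands_name_the_minimum(self):
        with pytest.raises(ValueError, match="4 bands"):
            build_network(NetworkSpec(architecture="self-design-cnn"), 3)
        with pytest.raises(ValueError, match="8 bands"):
            build_network(NetworkSpec(architecture="resnet-1d"), 7)

    def test_initialization_is_seed_deterministic(self):
        a = build_network(NetworkSpec(), 64, rng_seed=7)
        b = build_network(NetworkSpec(), 64, rng_seed=7)
        for (pa, _), (pb, _) in zip(a.params(), b.params()):
            assert pa.tobytes() == pb.tobytes()


class TestTraining:
    def small_data(self, rng, n_per_class=30, bands=32):
        profiles = ss.make_variety_profiles(7, bands, 6, 0.08, rng_seed=2)
        table = ss.make_labeled_spectra(profiles, n_per_class, 0.01,
                                        rng_seed=int(rng.integers(1 << 30)))
        split = ss.split_dataset(table.labels, rng_seed=0)
        return (table.matrix[split.calibration], table.labels[split.calibration],
                table.matrix[split.validation], table.labels[split.validation])

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        rng = np.random.default_rng(6)
        Xc, yc, Xv, yv = self.small_data(rng)
        net = build_network(NetworkSpec(), 32, rng_seed=1)
        before = [p.copy() for p, _ in net.params()]
        train(net, Xc, yc, Xv, yv,
              TrainingConfig(learning_rate=0.0, epochs=2, rng_seed=0))
        for (p, _), orig in zip(net.params(), before):
            np.testing.assert_array_equal(p, orig)

    def test_single_batch_overfit(self):
        """16 samples with arbitrary labels are memorized to near-zero
        loss — the standard optimizer sanity check."""
        rng = np.random.default_rng(7)
        X = rng.random((16, 32)).astype(np.float32)
        y = rng.integers(0, 7, 16)
        net = build_network(NetworkSpec(), 32, rng_seed=2)
        loss_fn = L.SoftmaxCrossEntropy()
        history = train(net, X, y, X, y,
                        TrainingConfig(learning_rate=0.02, batch_size=16,
                                       epochs=500, patience=500, rng_seed=0))
        assert min(history.train_loss) < 0.01

    def test_strong_signal_convergence_within_100_epochs(self):
        rng = np.random.default_rng(8)
        Xc, yc, Xv, yv = self.small_data(rng, n_per_class=100)
        net = build_network(NetworkSpec(), 32, rng_seed=3)
        history = train(net, Xc, yc, Xv, yv,
                        TrainingConfig(epochs=100, patience=100, rng_seed=0))
        assert max(history.train_accuracy) >= 95.0
        assert history.n_epochs <= 100
        # loss decreases over the first epochs of a healthy run
        assert history.train_loss[4] < history.train_loss[0]
        # trained model beats 90 % on held-out validation data
        assert max(history.val_accuracy) > 90.0

    def test_training_is_seed_reproducible(self):
        rng = np.random.default_rng(9)
        Xc, yc, Xv, yv = self.small_data(rng, n_per_class=10)
        runs = []
        for _ in range(2):
            net = build_network(NetworkSpec(), 32, rng_seed=4)
            history = train(net, Xc, yc, Xv, yv,
                            TrainingConfig(epochs=3, patience=3, rng_seed=5))
            runs.append((history.train_loss, [p.copy() for p, _ in net.params()]))
        assert runs[0][0] == runs[1][0]
        for pa, pb in zip(runs[0][1], runs[1][1]):
            assert pa.tobytes() == pb.tobytes()

    def test_non_finite_loss_raises_training_error(self):
        rng = np.random.default_rng(10)
        Xc, yc, Xv, yv = self.small_data(rng, n_per_class=5)
        net = build_network(NetworkSpec(), 32, rng_seed=5)
        net.layers[-1].W[0, 0] = np.inf
        with pytest.raises(TrainingError, match="epoch"):
            train(net, Xc, yc, Xv, yv, TrainingConfig(epochs=2, rng_seed=0))


class TestFeaturesAndPrediction:
    def trained_cnn(self):
        rng = np.random.default_rng(11)
        profiles = ss.make_variety_profiles(7, 32, 6, 0.08, rng_seed=2)
        table = ss.make_labeled_spectra(profiles, 20, 0.01, rng_seed=3)
        split = ss.split_dataset(table.labels, rng_seed=0)
        net = build_network(NetworkSpec(), 32, rng_seed=6)
        train(net, table.matrix[split.calibration],
              table.labels[split.calibration],
              table.matrix[split.validation], table.labels[split.validation],
              TrainingConfig(epochs=10, patience=10, rng_seed=0))
        return net, table

    def test_untrained_network_refuses_feature_extraction(self):
        net = build_network(NetworkSpec(), 32)
        with pytest.raises(StateError):
            net.features(np.zeros((1, 32)))

    def test_feature_extraction_is_deterministic(self):
        net, table = self.trained_cnn()
        a = extract_features(net, table.matrix, table.labels)
        b = extract_features(net, table.matrix, table.labels)
        assert a.matrix.tobytes() == b.matrix.tobytes()
        assert a.source == "cnn-dense2"

    def test_uniform_logits_predict_class_zero(self):
        net = build_network(NetworkSpec(), 32, rng_seed=7)
        net.layers[-1].W[...] = 0
        net.layers[-1].b[...] = 0
        pred = net.predict_classes(np.random.default_rng(0).random((5, 32)))
        assert np.all(pred == 0)

    def test_batch_prediction_equals_row_by_row(self):
        net, table = self.trained_cnn()
        probe = table.matrix[:11]
        batch = net.predict_classes(probe)
        rows = np.array([net.predict_classes(probe[i:i + 1])[0]
                         for i in range(11)])
        np.testing.assert_array_equal(batch, rows)

    def test_deep_features_feed_classical_models(self):
        """Hybrid contract: CNN features plug into the classical estimators
        unchanged and beat chance by a wide margin on strong-signal data."""
        net, table = self.trained_cnn()
        feats = extract_features(net, table.matrix, table.labels)
        split = ss.split_dataset(table.labels, rng_seed=1)
        model = ss.fit_lr(feats.matrix[split.calibration],
                          table.labels[split.calibration])
        acc = ss.accuracy(table.labels[split.prediction],
                          model.predict(feats.matrix[split.prediction]))
        assert acc / 100 >= 5 * (1 / 7)
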