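"""CNN architecture arithmetic, gradients, training behavior, features."""

import numpy as np
import pytest

from drowsyeeg import nn
from drowsyeeg.models import (
    CNNConfig,
    Conv1DClassifier,
    ConvNetClassifier,
    build_cnn,
    build_cnn1d,
    filters_for_depth,
)


def closed_form_param_count(filters, input_shape=(64, 64, 3), dense=128):
    """Layer-arithmetic oracle for the parameter count."""
    h, w, c = input_shape
    total = 0
    for f in filters:
        total += 3 * 3 * c * f + f
        c = f
        h, w = h // 2, w // 2
    total += h * w * c * dense + dense        # penultimate dense
    total += dense * 1 + 1                    # sigmoid head
    return total


class TestArchitecture:
    def test_depth_family_ladder(self):
        assert filters_for_depth(1) == (16,)
        assert filters_for_depth(2) == (16, 64)
        assert filters_for_depth(3) == (16, 32, 64)
        assert filters_for_depth(5) == (16, 32, 64, 128, 128)

    def test_written_two_block_shapes(self):
        """Blocks (16, 64) on 64x64x3: flatten 16384, dense 2,097,280 params."""
        net = build_cnn(CNNConfig(n_conv_blocks=2, filters_per_block=(16, 64)))
        state = net.state_dict()
        dense_w = state["9.w"]
        assert dense_w.shape == (16 * 16 * 64, 128) == (16384, 128)
        assert dense_w.size + state["9.b"].size == 2_097_280

    @pytest.mark.parametrize("depth", [1, 2, 3, 5])
    def test_param_counts_match_closed_form(self, depth):
        filters = filters_for_depth(depth)
        net = build_cnn(CNNConfig(n_conv_blocks=depth, filters_per_block=filters))
        assert net.n_params() == closed_form_param_count(filters)

    def test_depth_10_collapses(self):
        with pytest.raises(ValueError):
            build_cnn(CNNConfig(n_conv_blocks=10))

    def test_cnn1d_kernel_readback_and_shape(self):
        net = build_cnn1d(kernel_sizes=(64, 32))
        convs = [l for l in net.layers if isinstance(l, nn.Conv1D)]
        assert tuple(l.kernel for l in convs) == (64, 32)
        x = np.random.default_rng(0).standard_normal((2, 15360, 1)).astype(np.float32)
        out = net.forward(x)
        assert out.shape == (2, 1)

    def test_cnn1d_too_short_input(self):
        with pytest.raises(ValueError):
            build_cnn1d(input_length=32)


class TestGradients:
    def test_numeric_gradient_small_net(self):
        """Backprop agrees with central finite differences on a tiny net."""
        rng = np.random.default_rng(0)
        layers = [
            nn.Conv2D(2, 3, (3, 3), rng), nn.ReLU(), nn.MaxPool2D(2),
            nn.Flatten(), nn.Dense(4 * 4 * 3, 5, rng), nn.ReLU(),
            nn.Dense(5, 1, rng),
        ]
        net = nn.Sequential(layers)
        X = rng.standard_normal((4, 8, 8, 2)).astype(np.float32)
        y = np.array([0, 1, 1, 0], np.float32)

        def loss_at():
            logits = net.forward(X, training=False)
            return nn.bce_with_logits(logits, y)[0]

        logits = net.forward(X, training=False)
        _, grad = nn.bce_with_logits(logits, y)
        net.backward(grad)
        eps = 1e-3
        checked = 0
        for layer in (layers[0], layers[4], layers[6]):
            w = layer.params["w"]
            flat = w.ravel()
            for idx in rng.choice(flat.size, 5, replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_at()
                flat[idx] = orig - eps
                down = loss_at()
                flat[idx] = orig
                numeric = (up - down) / (2 * eps)
                analytic = layer.grads["w"].ravel()[idx]
                assert numeric == pytest.approx(analytic, rel=0.05, abs=1e-4)
                checked += 1
        assert checked == 15

    def test_conv1d_numeric_gradient(self):
        rng = np.random.default_rng(1)
        layers = [nn.Conv1D(1, 2, 5, 2, rng), nn.ReLU(), nn.MaxPool1D(2),
                  nn.Flatten(), nn.Dense(2 * 5, 1, rng)]
        net = nn.Sequential(layers)
        X = rng.standard_normal((3, 20, 1)).astype(np.float32)
        y = np.array([1, 0, 1], np.float32)
        logits = net.forward(X, training=False)
        _, grad = nn.bce_with_logits(logits, y)
        net.backward(grad)
        w = layers[0].params["w"]
        eps = 1e-3
        for idx in [0, 3, 7]:
            orig = w.ravel()[idx]
            w.ravel()[idx] = orig + eps
            up = nn.bce_with_logits(net.forward(X), y)[0]
            w.ravel()[idx] = orig - eps
            down = nn.bce_with_logits(net.forward(X), y)[0]
            w.ravel()[idx] = orig
            assert (up - down) / (2 * eps) == pytest.approx(
                layers[0].grads["w"].ravel()[idx], rel=0.05, abs=1e-4)


class TestTraining:
    def test_strong_contrast_reaches_high_training_accuracy(self, trained_cnn,
                                                            scalogram_dataset):
        """~200 contrasted synthetic scalograms: training accuracy >= 0.95."""
        pred = trained_cnn.predict(scalogram_dataset.images)
        acc = float(np.mean(pred == scalogram_dataset.labels))
        assert acc >= 0.95
        assert len(trained_cnn.history_) <= 30  # early stopping bound

    def test_shuffled_labels_stay_at_chance(self, scalogram_dataset):
        """Random labels give chance-level validation accuracy (5 seeds)."""
        rng = np.random.default_rng(0)
        images = scalogram_dataset.images[:120]
        accs = []
        for seed in range(5):
            y = rng.permutation(np.resize([0, 1], 120))
            clf = ConvNetClassifier(depth=1, epochs=8, patience=8,
                                    validation_fraction=0.25, random_state=seed)
            clf.fit(images, y)
            accs.append(clf.history_.val_accuracy[-1])
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_feature_extraction_contract(self, trained_cnn, scalogram_dataset):
        imgs = scalogram_dataset.images[:4]
        feats = trained_cnn.transform(imgs)
        assert feats.shape == (4, 128)
        # repeated identical calls are bit-identical; the same image in a
        # different batch context agrees to float32 rounding
        np.testing.assert_array_equal(feats, trained_cnn.transform(imgs))
        np.testing.assert_allclose(feats[:1], trained_cnn.transform(imgs[:1]),
                                   rtol=1e-4, atol=1e-5)
        zero_feat = trained_cnn.transform(np.zeros((1, 64, 64, 3), np.float32))
        assert np.isfinite(zero_feat).all()

    def test_single_class_rejected(self):
        X = np.zeros((8, 64, 64, 3), np.float32)
        with pytest.raises(ValueError):
            ConvNetClassifier(epochs=1).fit(X, np.zeros(8))

    def test_shape_mismatch_rejected(self, trained_cnn):
        with pytest.raises(ValueError):
            trained_cnn.transform(np.zeros((2, 32, 32, 3), np.float32))

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(3)
        X = rng.random((40, 16, 16, 3), dtype=np.float32)
        y = (rng.random(40) > 0.5).astype(int)
        runs = []
        for _ in range(2):
            clf = ConvNetClassifier(depth=1, epochs=3, patience=3,
                                    input_shape=(16, 16, 3), random_state=5)
            clf.fit(X, y)
            runs.append((clf.history_.loss, clf.decision_function(X)))
        assert runs[0][0] == runs[1][0]
        np.testing.assert_array_equal(runs[0][1], runs[1][1])


class TestConv1DBaseline:
    def test_beats_chance_on_contrasted_segments(self, scalogram_dataset):
        """Raw-signal baseline exceeds 0.7 accuracy on held-out segments."""
        segs = scalogram_dataset.segments
        labels = scalogram_dataset.labels
        accs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            idx = rng.permutation(len(labels))
            n_tr = int(0.7 * len(idx))
            tr, te = idx[:n_tr], idx[n_tr:]
            clf = Conv1DClassifier(epochs=12, patience=12, random_state=seed)
            clf.fit(segs[tr], labels[tr])
            accs.append(float(np.mean(clf.predict(segs[te]) == labels[te])))
        assert np.mean(accs) > 0.7

    def test_probability_output_range(self, scalogram_dataset):
        clf = Conv1DClassifier(epochs=1, patience=1, random_state=0)
        clf.fit(scalogram_dataset.segments[:40], scalogram_dataset.labels[:40])
        proba = clf.predict_proba(scalogram_dataset.segments[:3])
        assert proba.shape == (3, 2)
        assert np.all((proba >= 0) & (proba <= 1))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)
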