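"""Classifier architecture, transfer initialization, training and predictions."""

import dataclasses

import numpy as np
import pytest

from mctl3d.autoencoder import AutoencoderConfig, EncoderWeights, extract_patches, train_autoencoder
from mctl3d.classifier import (
    ClassifierConfig,
    build_classifier,
    initialize_from_encoder,
    predict,
    train_classifier,
)
from mctl3d.types import LabeledVolume, Prediction

SHAPE = (12, 12, 4)
FAST_CFG = ClassifierConfig(
    n_conv_layers=1, filters_per_layer=16, fc_nodes=16, epochs=3, batch_size=4, learning_rate=1e-3, seed=0
)


def _toy_samples(n_per_class=4, shape=SHAPE, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for label in (0, 1):
        for _ in range(n_per_class):
            vol = rng.random(shape).astype(np.float32) * 0.1
            if label:
                vol[4:8, 4:8, 1:3] += 0.8
            out.append(LabeledVolume(volume=vol, label=label))
    return out


class TestBuildClassifier:
    def test_forward_probability_in_unit_interval(self):
        model = build_classifier(ClassifierConfig(n_conv_layers=2, filters_per_layer=32, fc_nodes=16), SHAPE)
        pred = predict(model, np.random.default_rng(0).random(SHAPE).astype(np.float32))
        assert 0.0 <= pred.probability <= 1.0

    def test_parameter_count_drops_with_fc_nodes(self):
        # the fully connected layer dominates the parameter count, so fewer
        # nodes mean fewer trainable parameters at fixed depth/filters
        big = build_classifier(ClassifierConfig(n_conv_layers=2, filters_per_layer=32, fc_nodes=64), SHAPE)
        small = build_classifier(ClassifierConfig(n_conv_layers=2, filters_per_layer=32, fc_nodes=16), SHAPE)
        assert small.n_params() < big.n_params()
        # closed-form oracle for the small model's count
        h, w, d = SHAPE
        conv_params = (27 * 1 * 32 + 32) + (27 * 32 * 32 + 32)
        fc_params = (h * w * d * 32) * 16 + 16 + 16 * 1 + 1
        assert small.n_params() == conv_params + fc_params

    def test_seeded_build_deterministic(self):
        a = build_classifier(FAST_CFG, SHAPE)
        b = build_classifier(FAST_CFG, SHAPE)
        for pa, pb in zip(a.net.params(), b.net.params()):
            np.testing.assert_array_equal(pa, pb)

    def test_grid_validation(self):
        with pytest.raises(ValueError, match="n_conv_layers"):
            ClassifierConfig(n_conv_layers=4)
        with pytest.raises(ValueError, match="filters_per_layer"):
            ClassifierConfig(filters_per_layer=24)


@pytest.fixture(scope="module")
def encoder_weights():
    vol = np.random.default_rng(1).random((25, 25, 4)).astype(np.float32)
    patches = extract_patches(vol, n=64, seed=0)
    cfg = AutoencoderConfig(encoder_filters=(16, 32, 64), epochs=1, batch_size=32, seed=0)
    return train_autoencoder(patches, cfg)


class TestTransferInitialization:

    def test_full_prefix_copied_bitwise(self, encoder_weights):
        model = build_classifier(
            ClassifierConfig(n_conv_layers=3, filters_per_layer=16, fc_nodes=16, seed=5), SHAPE
        )
        # filters 16 vs encoder (16,32,64): layer 1 matches exactly
        before_fc = [p.copy() for p in model.net.layers[-3].params() + model.net.layers[-1].params()]
        initialize_from_encoder(model, encoder_weights)
        conv1 = model.conv_layers()[0]
        np.testing.assert_array_equal(conv1.kernel, encoder_weights.layers[0][0])
        np.testing.assert_array_equal(conv1.bias, encoder_weights.layers[0][1])
        after_fc = model.net.layers[-3].params() + model.net.layers[-1].params()
        for b, a in zip(before_fc, after_fc):
            np.testing.assert_array_equal(b, a)  # fully connected untouched

    def test_exact_match_copies_all_layers(self, encoder_weights):
        # single-layer classifier at 16 filters: prefix rule copies layer 1 only
        model = build_classifier(FAST_CFG, SHAPE)
        initialize_from_encoder(model, encoder_weights)
        conv = model.conv_layers()[0]
        np.testing.assert_array_equal(conv.kernel, encoder_weights.layers[0][0])
        assert model.init_mode == "transfer"

    def test_partial_channel_copy_keeps_remainder_random(self, encoder_weights):
        model = build_classifier(
            ClassifierConfig(n_conv_layers=2, filters_per_layer=32, fc_nodes=16, seed=2), SHAPE
        )
        conv1 = model.conv_layers()[0]
        random_tail = conv1.kernel[:, :, :, :, 16:].copy()
        initialize_from_encoder(model, encoder_weights)
        # leading 16 filters copied from the encoder, the rest untouched
        np.testing.assert_array_equal(conv1.kernel[:, :, :, :, :16], encoder_weights.layers[0][0])
        np.testing.assert_array_equal(conv1.kernel[:, :, :, :, 16:], random_tail)


class TestPrediction:
    @pytest.mark.parametrize(
        "p, label, confidence",
        [(0.5, 1, 0.0), (0.9, 1, 0.8), (0.1, 0, 0.8), (1.0, 1, 1.0), (0.0, 0, 1.0)],
    )
    def test_threshold_and_confidence(self, p, label, confidence):
        pred = Prediction.from_probability(p)
        assert pred.label == label
        assert pred.confidence == pytest.approx(confidence)

    def test_confidence_symmetry(self):
        for p in np.linspace(0, 1, 21):
            assert Prediction.from_probability(float(p)).confidence == pytest.approx(
                Prediction.from_probability(float(1 - p)).confidence
            )

    def test_shape_mismatch_rejected(self):
        model = build_classifier(FAST_CFG, SHAPE)
        with pytest.raises(ValueError, match="shape"):
            predict(model, np.zeros((8, 8, 4), dtype=np.float32))


class TestTrainClassifier:
    def test_history_and_checkpoint_contracts(self):
        samples = _toy_samples()
        model = build_classifier(FAST_CFG, SHAPE)
        trained = train_classifier(model, samples, FAST_CFG)
        assert len(trained.train_losses) == FAST_CFG.epochs
        assert len(trained.val_accuracies) == FAST_CFG.epochs
        assert 1 <= trained.checkpoint_epoch <= FAST_CFG.epochs
        # the checkpoint epoch is an argmax of the validation-accuracy history
        best = max(trained.val_accuracies)
        assert trained.checkpoint_val_accuracy == best
        assert trained.val_accuracies[trained.checkpoint_epoch - 1] == best

    def test_single_class_fold_rejected(self):
        samples = [s for s in _toy_samples() if s.label == 0]
        model = build_classifier(FAST_CFG, SHAPE)
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(model, samples, FAST_CFG)

    def test_seeded_training_deterministic(self):
        samples = _toy_samples()
        t1 = train_classifier(build_classifier(FAST_CFG, SHAPE), samples, FAST_CFG)
        t2 = train_classifier(build_classifier(FAST_CFG, SHAPE), samples, FAST_CFG)
        for a, b in zip(t1.model.net.params(), t2.model.net.params()):
            np.testing.assert_array_equal(a, b)

    def test_easy_separation_reaches_high_validation_accuracy(self):
        # strong block signal, more epochs: the inner validation split should
        # be classified nearly perfectly
        samples = _toy_samples(n_per_class=8, seed=3)
        cfg = dataclasses.replace(FAST_CFG, epochs=10)
        hits = 0
        for seed in (0, 1, 2):
            scfg = dataclasses.replace(cfg, seed=seed)
            trained = train_classifier(build_classifier(scfg, SHAPE), samples, scfg)
            if trained.checkpoint_val_accuracy >= 0.9:
                hits += 1
        assert hits >= 2

    def test_training_reduces_loss(self):
        samples = _toy_samples(n_per_class=6, seed=4)
        cfg = dataclasses.replace(FAST_CFG, epochs=8)
        trained = train_classifier(build_classifier(cfg, SHAPE), samples, cfg)
        assert min(trained.train_losses) < trained.train_losses[0]
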