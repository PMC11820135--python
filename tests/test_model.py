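"""Decoder architecture, focal loss, training contracts."""

import numpy as np
import pytest

from miglove import model as M
from miglove import preprocessing, spectral, synthetic
from miglove.model import (FocalLossParams, ModelConfig, TrainingSchedule,
                           build_model, decode_intent, focal_loss,
                           positional_encoding)

# (layer name, expected parameter count) for the default architecture
LAYER_PARAMS = [
    ("multi_head_attention", 17168),
    ("dropout_1", 0),
    ("layer_normalization", 32),
    ("dense", 2176),
    ("dropout_2", 0),
    ("dense_1", 2064),
    ("layer_normalization_2", 32),
    ("multi_head_attention_2", 17168),
    ("dropout_3", 0),
    ("dense_2", 2176),
    ("batch_normalization", 512),
    ("dropout_4", 0),
    ("layer_normalization_3", 256),
    ("dense_3", 8256),
    ("batch_normalization_2", 256),
    ("dropout_5", 0),
    ("layer_normalization_4", 128),
    ("dense_4", 130),
]


class TestArchitecture:
    @pytest.mark.parametrize("name,expected", LAYER_PARAMS)
    def test_per_layer_parameter_count(self, name, expected):
        decoder = build_model()
        assert decoder.count_params(name) == expected

    def test_total_equals_column_sum(self):
        decoder = build_model()
        assert decoder.count_params() == sum(n for _, n in LAYER_PARAMS)

    def test_unknown_layer_name_rejected(self):
        with pytest.raises(KeyError):
            build_model().count_params("dense_99")

    def test_softmax_output_sums_to_one(self, rng):
        decoder = build_model(seed=2)
        x = rng.normal(size=(8, 44, 16)) ** 2
        p = decoder.predict_proba(x)
        assert p.shape == (8, 2)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_feature_shape_mismatch_rejected(self, rng):
        decoder = build_model()
        with pytest.raises(ValueError):
            decoder.predict_proba(rng.normal(size=(40, 16)))

    def test_symmetric_block_variant_adds_second_ffn(self):
        strict = build_model(ModelConfig(symmetric_blocks=False))
        symmetric = build_model(ModelConfig(symmetric_blocks=True))
        assert symmetric.count_params() > strict.count_params()
        assert "dense_b" in symmetric.layers
        assert "dense_b" not in strict.layers


class TestPositionalEncoding:
    def test_row_zero_alternates_zero_one(self):
        pe = positional_encoding(44, 16)
        assert np.allclose(pe[0, 0::2], 0.0)
        assert np.allclose(pe[0, 1::2], 1.0)

    def test_all_entries_bounded_by_one(self):
        pe = positional_encoding(44, 16)
        assert np.all(np.abs(pe) <= 1.0)

    def test_first_column_is_sin_of_position(self):
        pe = positional_encoding(44, 16)
        assert pe[5, 0] == pytest.approx(np.sin(5.0))
        assert pe[5, 0] == pytest.approx(-0.9589, abs=1e-4)

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(44, 15)


class TestFocalLoss:
    def test_perfect_prediction_has_zero_loss(self):
        assert focal_loss(np.array([[0.0, 1.0]]), 1) == 0.0

    def test_gamma_zero_uniform_alpha_is_cross_entropy(self):
        p = np.array([[0.3, 0.7]])
        fl = focal_loss(p, 1, FocalLossParams(gamma=0.0, alpha=(1.0, 1.0)))
        assert fl == pytest.approx(-np.log(0.7))

    def test_gamma_two_value(self):
        # (1 - 0.9)^2 * (-log 0.9) = 0.01 * 0.10536...
        p = np.array([[0.1, 0.9]])
        fl = focal_loss(p, 1, FocalLossParams(gamma=2.0, alpha=(1.0, 1.0)))
        assert fl == pytest.approx(1.0536e-3, rel=1e-3)

    def test_strictly_decreasing_in_true_class_probability(self):
        params = FocalLossParams(gamma=2.0, alpha=(1.0, 1.0))
        probs = np.linspace(0.05, 0.95, 19)
        losses = [focal_loss(np.array([[1 - p, p]]), 1, params)
                  for p in probs]
        assert np.all(np.diff(losses) < 0)
        assert min(losses) >= 0

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.array([[0.5, 0.9]]), 1)

    def test_alpha_weights_scale_per_class(self):
        p = np.array([[0.3, 0.7]])
        base = focal_loss(p, 1, FocalLossParams(gamma=0.0, alpha=(1.0, 1.0)))
        weighted = focal_loss(p, 1, FocalLossParams(gamma=0.0, alpha=(1.0, 2.0)))
        assert weighted == pytest.approx(2 * base)

    def test_gradient_matches_finite_differences(self):
        """Backprop through the full graph agrees with central differences."""
        cfg = ModelConfig(seq_len=5, embed_dim=4, n_heads=2, head_size=3,
                          ffn_units=6, head_units=(5, 4),
                          dropout_attention=0.0, dropout_ffn=0.0,
                          dropout_head=0.0, normalize=False)
        dec = M.MIDecoder(cfg, seed=0)
        for layer in dec.layers.values():
            if hasattr(layer, "momentum"):
                layer.momentum = 1.0  # freeze running stats for the check
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 5, 4))
        y = np.array([0, 1, 0])
        params = FocalLossParams(gamma=2.0, alpha=(1.0, 1.3))

        def loss_value():
            logits = dec._forward(x, training=True)
            z = logits - logits.max(-1, keepdims=True)
            p = np.exp(z) / np.exp(z).sum(-1, keepdims=True)
            return focal_loss(p, y, params)

        dec.zero_grad()
        logits = dec._forward(x, training=True)
        z = logits - logits.max(-1, keepdims=True)
        p = np.exp(z) / np.exp(z).sum(-1, keepdims=True)
        dec._backward(M._focal_grad_wrt_logits(p, y, params))
        eps = 1e-6
        for name, layer in dec.layers.items():
            for key, arr in layer.params.items():
                idx = np.unravel_index(np.argmax(np.abs(layer.grads[key])),
                                       arr.shape)
                analytic = layer.grads[key][idx]
                orig = arr[idx]
                arr[idx] = orig + eps
                up = loss_value()
                arr[idx] = orig - eps
                down = loss_value()
                arr[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert analytic == pytest.approx(numeric, abs=2e-7), \
                    f"{name}.{key}"


class TestTraining:
    def test_single_class_training_rejected(self):
        batch = synthetic.generate_epoch_batch(
            synthetic.SubjectProfile(seed=0), n_per_class=4)
        only = batch.subset([i for i, l in enumerate(batch.labels)
                             if l == "fist"])
        decoder = build_model(seed=0)
        with pytest.raises(ValueError, match="single class"):
            M.train(decoder, only, batch, seed=0)

    def test_training_is_seed_deterministic(self):
        def run():
            batch = synthetic.generate_epoch_batch(
                synthetic.SubjectProfile(effect_size=0.8, seed=3),
                n_per_class=30, seed=3)
            train_set, val_set = preprocessing.split_by_group(
                batch, "trial", 0.3, seed=3)
            decoder = build_model(seed=3)
            M.train(decoder, train_set, val_set,
                    schedule=TrainingSchedule(max_epochs=4, patience=4),
                    seed=3)
            return decoder

        a, b = run(), run()
        wa, wb = a.get_weights(), b.get_weights()
        for layer in wa:
            for key in wa[layer]:
                assert np.array_equal(wa[layer][key], wb[layer][key])
        assert a.history == b.history

    def test_inverse_frequency_alpha_balances_classes(self):
        alpha = M.inverse_frequency_alpha(["rest"] * 30 + ["fist"] * 10)
        # minority fist gets the larger weight; mean normalized to 1
        assert alpha[1] > alpha[0]
        assert np.mean(alpha) == pytest.approx(1.0)


class TestDecodeIntent:
    @pytest.mark.parametrize("p_fist,expected", [(0.8, 1), (0.5, 1), (0.2, 0)])
    def test_threshold_rule_with_fist_tiebreak(self, p_fist, expected,
                                               monkeypatch):
        decoder = build_model(seed=0)
        monkeypatch.setattr(
            decoder, "predict_proba",
            lambda f: np.array([[1 - p_fist, p_fist]]))
        s_t, proba = decode_intent(decoder, np.zeros((44, 16)))
        assert s_t == expected
        assert proba[1] == pytest.approx(p_fist)

    def test_trained_decoder_separates_held_out_classes(self, trained_decoder,
                                                        strong_split):
        _, test_set = strong_split
        feats = spectral.featurize_epochs(test_set)
        hits = 0
        for i in range(len(test_set)):
            s_t, _ = decode_intent(trained_decoder, feats[i])
            hits += int((s_t == 1) == (test_set.labels[i] == "fist"))
        assert hits / len(test_set) >= 0.9


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, trained_decoder, tmp_path,
                                              rng):
        path = tmp_path / "decoder.zip"
        M.save_checkpoint(trained_decoder, path)
        back = M.load_checkpoint(path)
        x = rng.normal(size=(5, 44, 16)) ** 2
        assert np.allclose(back.predict_proba(x),
                           trained_decoder.predict_proba(x))
        assert back.trained
        assert back.config == trained_decoder.config

    def test_missing_checkpoint_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            M.load_checkpoint(tmp_path / "absent.zip")
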