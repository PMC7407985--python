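"""Decoder construction, splitting, schedule semantics and training."""

import numpy as np
import pytest

from semgss import nn
from semgss.decoders import (
    CONCAT_VIEW,
    SEQUENCE_VIEW,
    ConfigurationError,
    DecoderConfig,
    ScheduleState,
    SplitSpec,
    TrainingSchedule,
    build_decoder,
    bundles_to_arrays,
    predict,
    split_indices,
    train,
)
from semgss.features import FeatureBundle
from semgss.synthetic import ParameterError

SMALL_CNN = {"conv1": (4, (2, 5)), "conv2": (4, (2, 3)), "pool": (1, 4),
             "dense": 16, "input_hw": (6, 1000)}
SMALL_BLSTM = {"units": 8, "n_bidirectional": 3, "dense": (16, 8), "step_dim": 1000}


def tiny_bundles(rng, n_per_class=10, n_classes=2, d=1000, channels=6):
    """Linearly separable synthetic feature bundles."""
    out = []
    for k in range(n_classes):
        for _ in range(n_per_class):
            seq = rng.standard_normal((channels, d)) * 0.3
            seq[k % channels, :50] += 3.0  # class-specific block
            out.append(FeatureBundle(sequence=seq, label=k))
    return out


class TestDecoderConfig:
    @pytest.mark.parametrize("family,optimizer,dropout", [
        ("mlp", "adam", 0.2),
        ("cnn", "adadelta", 0.5),
        ("blstm", "rmsprop", 0.2),
    ])
    def test_family_hyperparameter_defaults(self, family, optimizer, dropout):
        cfg = DecoderConfig(family=family)
        assert cfg.optimizer == optimizer
        assert cfg.dropout == dropout
        assert cfg.init_lr == 1e-3 and cfg.batch_size == 32

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigurationError, match="family"):
            DecoderConfig(family="transformer")

    def test_mismatched_view_rejected(self):
        with pytest.raises(ConfigurationError, match="input_view"):
            build_decoder(DecoderConfig(family="blstm", n_classes=3), CONCAT_VIEW)
        with pytest.raises(ConfigurationError, match="input_view"):
            build_decoder(DecoderConfig(family="mlp", n_classes=3), SEQUENCE_VIEW)


class TestTopologies:
    def test_blstm_topology_three_bidirectional_two_dense(self):
        model = build_decoder(DecoderConfig(family="blstm", n_classes=4))
        desc = model.describe()
        assert desc["bidirectional_layers"] == 3
        assert desc["dense_layers_before_softmax"] == 2

    def test_cnn_topology_two_conv(self):
        model = build_decoder(DecoderConfig(family="cnn", n_classes=4, hidden_spec=SMALL_CNN))
        assert model.describe()["conv_layers"] == 2

    @pytest.mark.parametrize("family,spec,shape", [
        ("mlp", (32, 16), (3, 6000)),
        ("cnn", SMALL_CNN, (3, 6000)),
        ("blstm", SMALL_BLSTM, (3, 6, 1000)),
    ])
    def test_output_is_probability_simplex(self, family, spec, shape, rng):
        model = build_decoder(DecoderConfig(family=family, n_classes=5, hidden_spec=spec))
        x = rng.standard_normal(shape).astype(np.float32)
        p = model.network.predict_proba(x)
        assert p.shape == (3, 5)
        assert np.all(p >= 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


class TestSplit:
    def test_exact_7_2_1_sizes(self):
        labels = np.repeat([0, 1], 50)
        tr, va, te = split_indices(labels, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (70, 20, 10)

    def test_disjoint_and_covering(self):
        labels = np.repeat([0, 1, 2], 17)
        tr, va, te = split_indices(labels, SplitSpec(seed=3))
        allidx = np.concatenate([tr, va, te])
        assert len(allidx) == len(labels)
        assert len(np.unique(allidx)) == len(labels)

    def test_seed_determines_split(self):
        labels = np.repeat([0, 1], 20)
        a = split_indices(labels, SplitSpec(seed=5))
        b = split_indices(labels, SplitSpec(seed=5))
        c = split_indices(labels, SplitSpec(seed=6))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)
        assert any(not np.array_equal(x, y) for x, y in zip(a, c))

    def test_stratification_preserves_class_balance(self):
        labels = np.repeat([0, 1, 2], 30)
        tr, va, te = split_indices(labels, SplitSpec(seed=1))
        for part, expect in [(tr, 21), (va, 6), (te, 3)]:
            counts = np.bincount(labels[part], minlength=3)
            np.testing.assert_array_equal(counts, [expect] * 3)

    def test_tiny_class_under_stratification_rejected(self):
        labels = np.array([0] * 20 + [1] * 2)
        with pytest.raises(ParameterError, match="class 1"):
            split_indices(labels, SplitSpec())


class TestScheduleSemantics:
    def test_monotone_improvement_keeps_lr_constant(self):
        state = ScheduleState(TrainingSchedule(), init_lr=1e-3)
        for epoch in range(100):
            lr, stop = state.update(1.0 / (epoch + 1))
            assert lr == 1e-3
            assert not stop

    def test_frozen_loss_trace_matches_hand_computation(self):
        """Validation loss improves through epoch 5 then freezes: the learning
        rate falls to 2e-4 at epoch 25 (patience 20, factor 0.2) and training
        stops at epoch 85 (early-stop patience 80)."""
        state = ScheduleState(TrainingSchedule(), init_lr=1e-3)
        lr_trace, stop_epoch = [], None
        for epoch in range(1, 200):
            val = 1.0 - 0.1 * epoch if epoch <= 5 else 0.5
            lr, stop = state.update(val)
            lr_trace.append(lr)
            if stop:
                stop_epoch = epoch
                break
        assert lr_trace[23] == pytest.approx(1e-3)      # epoch 24
        assert lr_trace[24] == pytest.approx(2e-4)      # epoch 25: first decay
        assert lr_trace[44] == pytest.approx(4e-5)      # epoch 45: second decay
        assert stop_epoch == 85

    def test_lr_floored_at_min_lr(self):
        sched = TrainingSchedule(lr_patience=1, min_lr=0.5e-6)
        state = ScheduleState(sched, init_lr=1e-3)
        for _ in range(60):
            lr, _ = state.update(1.0)
        assert lr == pytest.approx(0.5e-6)

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ParameterError):
            TrainingSchedule(lr_factor=1.5)


class TestTraining:
    def test_overfits_tiny_separable_set(self, rng):
        """Capacity sanity: 2-class, 20-sample set reaches >=99% training
        accuracy within 200 epochs."""
        bundles = tiny_bundles(rng)
        cfg = DecoderConfig(family="mlp", n_classes=2, hidden_spec=(64, 16), seed=0)
        model = build_decoder(cfg)
        x, y = bundles_to_arrays(bundles, model.input_view)
        sched = TrainingSchedule(max_epochs=200, early_stop_patience=200)
        train(model, (x, y), (x, y), sched, seed=1)
        _, acc = model.network.evaluate(x, y)
        assert acc >= 0.99

    def test_training_reproducible_for_fixed_seed(self, rng):
        bundles = tiny_bundles(rng, n_per_class=8)
        accs = []
        for _ in range(2):
            cfg = DecoderConfig(family="mlp", n_classes=2, hidden_spec=(16,), seed=3)
            model = build_decoder(cfg)
            x, y = bundles_to_arrays(bundles, model.input_view)
            sched = TrainingSchedule(max_epochs=10, early_stop_patience=10)
            rep = train(model, (x, y), (x, y), sched, seed=4)
            accs.append((tuple(rep.train_loss), rep.val_acc[-1]))
        assert accs[0] == accs[1]

    def test_report_curves_consistent(self, rng):
        bundles = tiny_bundles(rng, n_per_class=6)
        cfg = DecoderConfig(family="mlp", n_classes=2, hidden_spec=(16,), seed=0)
        model = build_decoder(cfg)
        x, y = bundles_to_arrays(bundles, model.input_view)
        rep = train(model, (x, y), (x, y),
                    TrainingSchedule(max_epochs=5, early_stop_patience=80), seed=0)
        assert rep.stop_epoch == 5 and rep.stop_reason == "max_epochs"
        assert len(rep.val_loss) == 5 == len(rep.lr_trace)
        assert all(np.isfinite(rep.val_loss))
        assert all(0 <= a <= 1 for a in rep.val_acc)
        assert all(l2 <= l1 + 1e-12 for l1, l2 in zip(rep.lr_trace, rep.lr_trace[1:]))


@pytest.mark.parametrize("family,spec", [
    ("mlp", (16,)),
    ("cnn", SMALL_CNN),
    ("blstm", SMALL_BLSTM),
])
def test_checkpoint_roundtrip(family, spec, rng, tmp_path):
    """A saved decoder reloads with identical predictions."""
    from semgss.decoders import load_decoder, save_decoder

    bundles = tiny_bundles(rng, n_per_class=4)
    cfg = DecoderConfig(family=family, n_classes=2, hidden_spec=spec, seed=0)
    model = build_decoder(cfg)
    x, y = bundles_to_arrays(bundles, model.input_view)
    train(model, (x, y), (x, y), TrainingSchedule(max_epochs=2, early_stop_patience=80), seed=0)
    save_decoder(model, str(tmp_path / "ckpt"))
    reloaded = load_decoder(str(tmp_path / "ckpt"))
    assert reloaded.config.family == family
    np.testing.assert_allclose(
        model.network.predict_proba(x), reloaded.network.predict_proba(x), rtol=1e-6
    )


class TestPredict:
    def test_probabilities_and_determinism(self, rng):
        bundles = tiny_bundles(rng, n_per_class=3)
        model = build_decoder(DecoderConfig(family="mlp", n_classes=2, hidden_spec=(16,), seed=0))
        label1, p1 = predict(model, bundles[0])
        label2, p2 = predict(model, bundles[0])
        assert label1 == label2 == int(p1.argmax())
        np.testing.assert_array_equal(p1, p2)
        assert p1.sum() == pytest.approx(1.0, abs=1e-6)

    def test_blstm_channel_order_sensitivity(self, rng):
        """Permuting the 6-step channel sequence changes a trained bLSTM's
        output distribution."""
        bundles = tiny_bundles(rng, n_per_class=5)
        cfg = DecoderConfig(family="blstm", n_classes=2, hidden_spec=SMALL_BLSTM, seed=0)
        model = build_decoder(cfg)
        x, y = bundles_to_arrays(bundles, model.input_view)
        train(model, (x, y), (x, y), TrainingSchedule(max_epochs=5, early_stop_patience=80), seed=0)
        _, p = predict(model, bundles[0])
        permuted = FeatureBundle(sequence=bundles[0].sequence[::-1].copy(), label=bundles[0].label)
        _, p_perm = predict(model, permuted)
        assert not np.allclose(p, p_perm)
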