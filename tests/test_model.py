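"""Model assembly, loss, training schedule and the ablation switchboard."""

import numpy as np
import pytest

from gahtnet.io import TrialSet
from gahtnet.model import (
    ABLATION_FLAGS,
    TABLE_VARIANTS,
    ModelConfig,
    TrainConfig,
    ablate_variant,
    build_model,
    cross_entropy,
    load_checkpoint,
    predict_labels,
    predict_proba,
    save_checkpoint,
    train_model,
)
from gahtnet.synth import SynthConfig, default_erd_map, generate_trials


def tiny_trials(n_per_class=12, attenuation=0.9, snr_db=6.0, seed=3, epoch_s=1.0):
    cfg = SynthConfig(
        n_subjects=1, trials_per_class=n_per_class, n_classes=2,
        erd_map=default_erd_map(2, attenuation), snr_db=snr_db,
        epoch_s=epoch_s, seed=seed,
    )
    return generate_trials(cfg)


def tiny_model(graph, input_samples=250, n_classes=2, flags=frozenset(), seed=0):
    cfg = ModelConfig(
        n_classes=n_classes, n_electrodes=graph.n_channels,
        input_samples=input_samples, ablation_flags=flags,
    )
    return cfg, build_model(cfg, graph, seed=seed)


class TestBuildModel:
    def test_same_config_same_parameter_count(self, graph_2b):
        _, m1 = tiny_model(graph_2b, seed=0)
        _, m2 = tiny_model(graph_2b, seed=99)
        assert m1.n_parameters() == m2.n_parameters()

    @pytest.mark.parametrize("flag", sorted(ABLATION_FLAGS))
    def test_every_ablation_flag_reduces_parameters(self, graph_2b, flag):
        _, full = tiny_model(graph_2b)
        _, ablated = tiny_model(graph_2b, flags=frozenset({flag}))
        assert ablated.n_parameters() < full.n_parameters()

    def test_graph_config_mismatch_rejected(self, graph_2a):
        cfg = ModelConfig(n_classes=2, n_electrodes=3)
        with pytest.raises(ValueError, match="electrodes"):
            build_model(cfg, graph_2a)

    def test_forward_of_zero_batch_yields_valid_distributions(self, graph_2b):
        _, model = tiny_model(graph_2b)
        p = predict_proba(model, np.zeros((3, 3, 250)))
        assert p.shape == (3, 2)
        assert np.isfinite(p).all()
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_wrong_input_shape_rejected(self, graph_2b):
        _, model = tiny_model(graph_2b)
        with pytest.raises(ValueError, match="expected"):
            predict_proba(model, np.zeros((2, 5, 250)))


class TestSoftmaxAndLoss:
    def test_uniform_logits_give_uniform_probabilities(self):
        from gahtnet.nn import Tensor, softmax

        p = softmax(Tensor(np.zeros((1, 4))), axis=1).data
        assert np.allclose(p, 0.25)

    def test_two_logit_hand_example(self):
        from gahtnet.nn import Tensor, softmax

        p = softmax(Tensor(np.array([[1.0, 2.0]])), axis=1).data[0]
        assert np.allclose(p, [0.26894142, 0.73105858], atol=1e-8)

    def test_shift_invariance(self):
        from gahtnet.nn import Tensor, softmax

        z = np.array([[0.3, -1.2, 2.0]])
        a = softmax(Tensor(z), axis=1).data
        b = softmax(Tensor(z + 57.0), axis=1).data
        assert np.allclose(a, b, atol=1e-12)

    def test_perfect_predictions_have_zero_loss(self):
        probs = np.eye(3)[[0, 1, 2]]
        assert cross_entropy(probs, [0, 1, 2]) == 0.0

    def test_uniform_four_class_loss_is_ln4(self):
        probs = np.full((5, 4), 0.25)
        assert abs(cross_entropy(probs, [0, 1, 2, 3, 0]) - np.log(4)) < 1e-12

    def test_mean_reduction_over_batch(self):
        probs = np.array([[0.9, 0.1], [0.4, 0.6]])
        a = -np.log(0.9)
        b = -np.log(0.6)
        assert abs(cross_entropy(probs, [0, 1]) - (a + b) / 2) < 1e-12

    def test_zero_probability_is_clipped_finite(self):
        probs = np.array([[1.0, 0.0]])
        loss = cross_entropy(probs, [1])
        assert np.isfinite(loss)
        assert loss == pytest.approx(-np.log(1e-12))

    def test_one_hot_labels_accepted(self):
        probs = np.array([[0.8, 0.2]])
        assert cross_entropy(probs, np.array([[1, 0]])) == pytest.approx(-np.log(0.8))


class TestTrainModel:
    def test_single_class_training_set_rejected(self, graph_2b):
        _, model = tiny_model(graph_2b)
        ts = TrialSet(data=np.zeros((8, 3, 250)), labels=np.zeros(8), fs=250)
        with pytest.raises(ValueError, match="2 classes"):
            train_model(model, ts, TrainConfig(max_epochs=1, patience=1))

    def test_constant_metric_stops_after_patience(self, graph_2b):
        _, model = tiny_model(graph_2b)
        trials = tiny_trials(n_per_class=8)
        tcfg = TrainConfig(lr=0.0, max_epochs=6, patience=1, seed=0)
        _, hist = train_model(model, trials, tcfg)
        assert hist.stopped_epoch == 2
        assert hist.best_epoch == 1

    def test_same_seed_reproduces_loss_curve(self, graph_2b):
        trials = tiny_trials(n_per_class=8)
        tcfg = TrainConfig(max_epochs=3, patience=3, seed=5)
        _, h1 = train_model(tiny_model(graph_2b, seed=1)[1], trials, tcfg)
        _, h2 = train_model(tiny_model(graph_2b, seed=1)[1], trials, tcfg)
        assert h1.train_loss == h2.train_loss
        assert h1.val_acc == h2.val_acc

    def test_loss_strictly_decreases_on_separable_data(self, graph_2b):
        """With dropout off (the only forward-pass noise), optimisation on
        well-separated z-scored data descends monotonically at first."""
        from gahtnet.gate import GateConfig
        from gahtnet.hadte import HadteConfig
        from gahtnet.io import zscore_channels

        trials = zscore_channels(tiny_trials(n_per_class=24, attenuation=0.9,
                                             snr_db=6.0))
        cfg = ModelConfig(
            n_classes=2, n_electrodes=3, input_samples=250,
            gate=GateConfig(dropout_rate=0.0), hadte=HadteConfig(tcn_dropout=0.0),
        )
        from gahtnet.model import build_model as _build

        model = _build(cfg, graph_2b, seed=2)
        tcfg = TrainConfig(max_epochs=5, patience=5, seed=2)
        _, hist = train_model(model, trials, tcfg)
        assert all(np.diff(hist.train_loss) < 0)

    def test_best_weights_restored(self, graph_2b):
        _, model = tiny_model(graph_2b)
        trials = tiny_trials(n_per_class=10)
        tcfg = TrainConfig(max_epochs=4, patience=4, seed=0)
        model, hist = train_model(model, trials, tcfg)
        assert 1 <= hist.best_epoch <= hist.stopped_epoch


class TestAblation:
    def test_unknown_flag_lists_valid_ones(self, graph_2b):
        cfg, _ = tiny_model(graph_2b)
        with pytest.raises(ValueError, match="channel_attention"):
            ablate_variant(cfg, "spatial_transformer")

    def test_idempotent(self, graph_2b):
        cfg, _ = tiny_model(graph_2b)
        once = ablate_variant(cfg, "hadte")
        twice = ablate_variant(once, "hadte")
        assert once == twice

    def test_seven_table_variants_constructible(self):
        assert len(TABLE_VARIANTS) == 7
        assert all(flags <= ABLATION_FLAGS for flags in TABLE_VARIANTS.values())

    @pytest.mark.parametrize("name", sorted(TABLE_VARIANTS))
    def test_each_variant_builds_and_runs_forward(self, name, graph_2a, rng):
        cfg = ModelConfig(
            n_classes=4, n_electrodes=22, input_samples=250,
            ablation_flags=TABLE_VARIANTS[name],
        )
        model = build_model(cfg, graph_2a, seed=0)
        p = predict_proba(model, rng.normal(size=(2, 22, 250)))
        assert p.shape == (2, 4)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_hadte_flag_classifier_consumes_gate_features(self, graph_2b, rng):
        cfg, model = tiny_model(graph_2b, flags=frozenset({"hadte"}))
        model.eval()
        X = rng.normal(size=(1, 3, 250))
        from gahtnet.nn import Tensor

        gate_out = model.gate(Tensor(X)).data[0]  # (F, T')
        logits = model.logits(Tensor(X)).data[0]
        expect = gate_out[:, -1] @ model.classifier.W.data + model.classifier.b.data
        assert np.abs(logits - expect).max() < 1e-10


def test_checkpoint_round_trip(tmp_path, graph_2b, rng):
    _, model = tiny_model(graph_2b, seed=4)
    X = rng.normal(size=(3, 3, 250))
    before = predict_proba(model, X)
    path = tmp_path / "model.npz"
    save_checkpoint(model, path)
    restored = load_checkpoint(path, graph_2b)
    assert np.allclose(predict_proba(restored, X), before, atol=1e-12)


def test_embedding_export_round_trip(tmp_path, graph_2b):
    import h5py

    _, model = tiny_model(graph_2b)
    trials = tiny_trials(n_per_class=4)
    path = tmp_path / "emb.h5"
    from gahtnet.model import export_embeddings

    export_embeddings(model, trials, path)
    with h5py.File(path) as f:
        assert f["embeddings"].shape == (8, 32)
        assert np.array_equal(f["labels"][()], trials.labels)


def test_predict_labels_batches_consistently(graph_2b, rng):
    _, model = tiny_model(graph_2b)
    X = rng.normal(size=(7, 3, 250))
    full = np.argmax(predict_proba(model, X), axis=1)
    assert np.array_equal(predict_labels(model, X, batch_size=3), full)
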