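"""Training regimen, confusion matrices and derived metrics."""

import numpy as np
import pytest

from hyperseed.nn import ModelConfig, build_model
from hyperseed.train_eval import (
    ConfusionMatrix,
    TrainConfig,
    channel_stats,
    confusion_matrix,
    evaluate_arrays,
    load_checkpoint,
    metrics_from_cm,
    normalize_images,
    save_checkpoint,
    train_arrays,
)


def colored_blob_dataset(n_per_class=40, size=16, noise=0.05, seed=0):
    """Three classes distinguished by dominant channel; trivially separable."""
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for cls in range(3):
        base = np.full((n_per_class, size, size, 3), 0.1)
        base[..., cls] = 0.8
        base += rng.normal(0, noise, base.shape)
        xs.append(np.clip(base * 255, 0, 255).astype(np.uint8))
        ys.append(np.full(n_per_class, cls))
    x = np.concatenate(xs)
    y = np.concatenate(ys).astype(np.int64)
    order = rng.permutation(len(y))
    return x[order], y[order]


class TestTrainConfig:
    def test_defaults_echo_training_regimen(self):
        d = TrainConfig().to_dict()
        assert d["optimizer"] == "sgd"
        assert d["learning_rate"] == 0.001
        assert d["momentum"] == 0.9
        assert d["weight_decay"] == 0.01
        assert d["batch_size"] == 8
        assert d["epochs"] == 50

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(epochs=-1)


class TestTrain:
    def test_zero_epochs_is_identity(self):
        model = build_model(ModelConfig(family="se_resnet_small", num_classes=3,
                                        base_channels=8, rng_seed=0))
        before = {k: v.copy() for k, v in model.state_dict().items()}
        out, history = train_arrays(model, np.zeros((1, 3, 8, 8), np.float32),
                                    np.zeros(1, np.int64), np.zeros((1, 3, 8, 8), np.float32),
                                    np.zeros(1, np.int64), TrainConfig(epochs=0))
        assert history.n_epochs == 0
        for k, v in out.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_tiny_problem_learns(self):
        """Loss falls and accuracy rises over a short seeded run on the
        separable color dataset; the run's own history is the oracle."""
        x, y = colored_blob_dataset()
        mean, sd = channel_stats(x)
        xn = normalize_images(x, mean, sd)
        n_val = 24
        model = build_model(ModelConfig(family="se_resnet_small", num_classes=3,
                                        input_size=16, base_channels=8, rng_seed=1))
        model, history = train_arrays(
            model, xn[n_val:], y[n_val:], xn[:n_val], y[:n_val],
            TrainConfig(epochs=6, rng_seed=1),
        )
        assert history.train_acc[-1] > history.train_acc[0]
        assert np.mean(history.train_loss[-3:]) < np.mean(history.train_loss[:3])
        assert history.best_epoch is not None

    def test_deterministic_training(self):
        x, y = colored_blob_dataset(n_per_class=12)
        mean, sd = channel_stats(x)
        xn = normalize_images(x, mean, sd)

        def run():
            model = build_model(ModelConfig(family="se_resnet_small", num_classes=3,
                                            input_size=16, base_channels=8, rng_seed=5))
            return train_arrays(model, xn[6:], y[6:], xn[:6], y[:6],
                                TrainConfig(epochs=2, rng_seed=5))

        m1, h1 = run()
        m2, h2 = run()
        assert h1.train_loss == h2.train_loss
        for a, b in zip(m1.state_dict().values(), m2.state_dict().values()):
            np.testing.assert_array_equal(a, b)


class TestEvaluate:
    def test_constant_prediction_fills_one_column(self):
        model = build_model(ModelConfig(family="se_resnet_small", num_classes=3,
                                        base_channels=8, rng_seed=0))
        model.fc.weight.data[...] = 0.0
        model.fc.bias.data[...] = np.array([0.0, 5.0, 0.0], dtype=np.float32)
        x = np.random.default_rng(0).standard_normal((9, 3, 8, 8)).astype(np.float32)
        y = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2])
        cm = evaluate_arrays(model, x, y)
        assert cm.counts[:, 1].sum() == 9
        assert cm.counts[:, [0, 2]].sum() == 0

    def test_row_sums_equal_per_class_counts(self):
        model = build_model(ModelConfig(family="se_resnet_small", num_classes=3,
                                        base_channels=8, rng_seed=0))
        x = np.random.default_rng(1).standard_normal((10, 3, 8, 8)).astype(np.float32)
        y = np.array([0, 0, 0, 0, 1, 1, 1, 2, 2, 2])
        cm = evaluate_arrays(model, x, y)
        np.testing.assert_array_equal(cm.counts.sum(axis=1), [4, 3, 3])
        assert cm.total == 10


class TestMetrics:
    def test_diagonal_matrix_all_hundred(self):
        cm = ConfusionMatrix(np.diag([5, 8, 3]))
        r = metrics_from_cm(cm)
        for v in (r.accuracy, r.precision, r.recall, r.specificity, r.f1):
            assert v == pytest.approx(100.0)
        assert r.per_class_accuracy == [100.0, 100.0, 100.0]

    def test_two_class_hand_arithmetic(self):
        """[[5,1],[2,4]]: accuracy 9/12, P0=5/7, R0=5/6, P1=4/5, R1=4/6,
        S0=4/6, S1=5/7, F1 by 2PR/(P+R); macro = plain means."""
        cm = ConfusionMatrix(np.array([[5, 1], [2, 4]]))
        r = metrics_from_cm(cm)
        assert r.accuracy == pytest.approx(75.0)
        p0, r0 = 5 / 7, 5 / 6
        p1, r1 = 4 / 5, 4 / 6
        assert r.precision == pytest.approx(100 * (p0 + p1) / 2)
        assert r.recall == pytest.approx(100 * (r0 + r1) / 2)
        assert r.specificity == pytest.approx(100 * (4 / 6 + 5 / 6) / 2)
        f0 = 2 * p0 * r0 / (p0 + r0)
        f1 = 2 * p1 * r1 / (p1 + r1)
        assert r.f1 == pytest.approx(100 * (f0 + f1) / 2)
        assert r.per_class_accuracy[0] == pytest.approx(100 * 5 / 6)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 30, (4, 4))
        perm = rng.permutation(4)
        r1 = metrics_from_cm(ConfusionMatrix(counts))
        r2 = metrics_from_cm(ConfusionMatrix(counts[np.ix_(perm, perm)]))
        for attr in ("accuracy", "precision", "recall", "specificity", "f1"):
            assert getattr(r1, attr) == pytest.approx(getattr(r2, attr))

    def test_tp_fp_fn_tn_identities(self):
        counts = np.array([[5, 1, 0], [2, 4, 1], [0, 0, 6]])
        cm = ConfusionMatrix(counts)
        tp, fp, fn, tn = cm.tp_fp_fn_tn()
        np.testing.assert_array_equal(tp + fp + fn + tn, np.full(3, cm.total))
        np.testing.assert_array_equal(tp, [5, 4, 6])
        np.testing.assert_array_equal(fp, [2, 1, 1])

    def test_degenerate_class_zero_with_warning(self):
        cm = ConfusionMatrix(np.array([[4, 0], [0, 0]]))  # class 1 absent
        with pytest.warns(UserWarning, match="0/0"):
            r = metrics_from_cm(cm)
        assert 1 in r.degenerate_classes
        assert r.per_class_accuracy[1] == 0.0

    def test_accuracy_differs_from_macro_recall_when_unbalanced(self):
        cm = ConfusionMatrix(np.array([[90, 10], [5, 5]]))
        r = metrics_from_cm(cm)
        assert r.accuracy != pytest.approx(r.recall)

    def test_empty_matrix_raises(self):
        with pytest.raises(ValueError):
            metrics_from_cm(ConfusionMatrix(np.zeros((2, 2), dtype=int)))

    def test_weighted_averaging_flag(self):
        cm = ConfusionMatrix(np.array([[90, 10], [5, 5]]))
        macro = metrics_from_cm(cm, averaging="macro")
        weighted = metrics_from_cm(cm, averaging="weighted")
        assert weighted.recall == pytest.approx(cm.counts.trace() / cm.total * 100)
        assert macro.recall != pytest.approx(weighted.recall)


class TestCheckpoint:
    def test_roundtrip_preserves_outputs(self, tmp_path):
        model = build_model(ModelConfig(family="se_resnet_small", num_classes=3,
                                        base_channels=8, rng_seed=4))
        model.train(False)
        mean = np.array([0.4, 0.5, 0.6], dtype=np.float32)
        sd = np.array([0.2, 0.2, 0.2], dtype=np.float32)
        path = save_checkpoint(tmp_path / "ck.npz", model, mean, sd, TrainConfig(), ["a", "b", "c"])
        back, m2, s2, tc, labels = load_checkpoint(path)
        back.train(False)
        x = np.random.default_rng(0).standard_normal((2, 3, 8, 8)).astype(np.float32)
        np.testing.assert_allclose(back.forward(x), model.forward(x), atol=1e-6)
        np.testing.assert_array_equal(m2, mean)
        assert labels == ["a", "b", "c"]
        assert tc.batch_size == 8


def test_confusion_matrix_builder_counts():
    cm = confusion_matrix(np.array([0, 0, 1, 2]), np.array([0, 1, 1, 2]), k=3)
    np.testing.assert_array_equal(cm.counts, [[1, 1, 0], [0, 1, 0], [0, 0, 1]])
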