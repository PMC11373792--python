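"""Training regimen and confusion-matrix evaluation.

The default regimen is SGD with learning rate 0.001, momentum 0.9,
weight decay 0.01, batch size 8, 50 epochs, cross-entropy on logits
(softmax applied at inference). Inputs are per-channel standardized
with statistics computed on the training split and persisted with the
checkpoint. The checkpoint retained is the best-validation-accuracy
epoch; the final-epoch model is also reported in the history.

Multiclass metrics are macro-averaged (unweighted over classes) by
default; a weighted average is available. A 0/0 ratio (degenerate
class) is defined as 0 and flagged.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .nn import SGD, ModelConfig, ResNet, build_model, cross_entropy, softmax

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "ConfusionMatrix",
    "MetricsReport",
    "train_arrays",
    "evaluate_arrays",
    "confusion_matrix",
    "metrics_from_cm",
    "channel_stats",
    "normalize_images",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.01
    batch_size: int = 8
    epochs: int = 50
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def to_dict(self) -> dict:
        return {
            "optimizer": "sgd",
            "learning_rate": self.learning_rate,
            "momentum": self.momentum,
            "weight_decay": self.weight_decay,
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "rng_seed": self.rng_seed,
        }


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    @property
    def best_epoch(self) -> int | None:
        """0-based index of the best validation-accuracy epoch."""
        if not self.val_acc:
            return None
        return int(np.argmax(self.val_acc))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.n_epochs + 1),
                "train_loss": self.train_loss,
                "train_acc": self.train_acc,
                "val_loss": self.val_loss,
                "val_acc": self.val_acc,
            }
        )


def channel_stats(images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and sd of a (N, H, W, 3) uint8 stack, on [0, 1] scale."""
    x = np.asarray(images, dtype=np.float64) / 255.0
    mean = x.mean(axis=(0, 1, 2))
    sd = x.std(axis=(0, 1, 2))
    sd = np.where(sd < 1e-6, 1.0, sd)
    return mean.astype(np.float32), sd.astype(np.float32)


def normalize_images(images: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """(N, H, W, 3) uint8 -> normalized (N, 3, H, W) float32."""
    x = np.asarray(images, dtype=np.float32) / 255.0
    x = (x - mean[None, None, None, :]) / sd[None, None, None, :]
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _epoch_pass(
    model: ResNet,
    x: np.ndarray,
    y: np.ndarray,
    batch_size: int,
    optimizer: SGD | None,
    rng: np.random.Generator | None,
) -> tuple[float, float]:
    """One pass over the data; trains when an optimizer is given."""
    n = x.shape[0]
    order = rng.permutation(n) if rng is not None else np.arange(n)
    losses, correct = [], 0
    for start in range(0, n, batch_size):
        idx = order[start : start + batch_size]
        logits = model.forward(x[idx])
        loss, dlogits = cross_entropy(logits, y[idx])
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at batch starting {start}")
        losses.append(loss * len(idx))
        correct += int((logits.argmax(axis=1) == y[idx]).sum())
        if optimizer is not None:
            optimizer.zero_grad()
            model.backward(dlogits)
            optimizer.step()
    return float(np.sum(losses) / n), correct / n


def train_arrays(
    model: ResNet,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    config: TrainConfig = TrainConfig(),
    verbose: bool = False,
) -> tuple[ResNet, TrainingHistory]:
    """Train on pre-normalized (N, 3, H, W) arrays; returns best-val model.

    ``epochs=0`` returns the model unchanged with an empty history.
    Data order is shuffled per epoch from ``config.rng_seed``; a
    non-finite loss raises with the epoch index.
    """
    history = TrainingHistory()
    if config.epochs == 0:
        return model, history
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(config.rng_seed)
    optimizer = SGD(
        model.parameters(),
        lr=config.learning_rate,
        momentum=config.momentum,
        weight_decay=config.weight_decay,
    )
    best_state: dict | None = None
    best_acc = -1.0
    for epoch in range(config.epochs):
        model.train(True)
        try:
            tr_loss, tr_acc = _epoch_pass(model, x_train, y_train, config.batch_size, optimizer, rng)
        except FloatingPointError as exc:
            raise FloatingPointError(f"divergence in epoch {epoch + 1}: {exc}") from exc
        model.train(False)
        va_loss, va_acc = _epoch_pass(model, x_val, y_val, config.batch_size, None, None)
        history.train_loss.append(tr_loss)
        history.train_acc.append(tr_acc)
        history.val_loss.append(va_loss)
        history.val_acc.append(va_acc)
        if va_acc > best_acc:
            best_acc = va_acc
            best_state = copy.deepcopy(model.state_dict())
        if verbose:
            print(
                f"epoch {epoch + 1:3d}/{config.epochs}  "
                f"train loss {tr_loss:.4f} acc {tr_acc:.3f}  "
                f"val loss {va_loss:.4f} acc {va_acc:.3f}"
            )
    if best_state is not None:
        model.load_state_dict(best_state)
    model.train(False)
    return model, history


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ConfusionMatrix:
    """k x k counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix entries must be >= 0")

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def tp_fp_fn_tn(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        tp = np.diag(self.counts).astype(np.int64)
        fp = self.counts.sum(axis=0) - tp
        fn = self.counts.sum(axis=1) - tp
        tn = self.total - tp - fp - fn
        return tp, fp, fn, tn


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, k: int,
                     class_labels: Sequence[str] | None = None) -> ConfusionMatrix:
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (np.asarray(y_true), np.asarray(y_pred)), 1)
    return ConfusionMatrix(counts, tuple(class_labels) if class_labels else None)


@dataclass
class MetricsReport:
    """Percentages in [0, 100]; macro = unweighted class mean.

    ``per_class_accuracy`` is per-class recall, the per-variety
    "classification accuracy" sense. ``degenerate_classes`` flags
    classes where a 0/0 ratio was defined as 0.
    """

    accuracy: float
    precision: float
    recall: float
    specificity: float
    f1: float
    per_class_accuracy: list[float]
    degenerate_classes: list[int]
    averaging: str = "macro"

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "f1": self.f1,
            "per_class_accuracy": self.per_class_accuracy,
            "degenerate_classes": self.degenerate_classes,
            "averaging": self.averaging,
        }


def _safe_div(num: np.ndarray, den: np.ndarray, degenerate: set[int]) -> np.ndarray:
    out = np.zeros_like(num, dtype=np.float64)
    for i in range(len(num)):
        if den[i] == 0:
            degenerate.add(i)
        else:
            out[i] = num[i] / den[i]
    return out


def metrics_from_cm(cm: ConfusionMatrix, averaging: str = "macro") -> MetricsReport:
    """Accuracy, precision, recall, specificity, F1 from a confusion matrix.

    Per class: precision TP/(TP+FP), recall TP/(TP+FN), specificity
    TN/(TN+FP), F1 = 2PR/(P+R); aggregated by unweighted (macro) or
    support-weighted mean. All reported as percentages.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    if averaging not in ("macro", "weighted"):
        raise ValueError("averaging must be 'macro' or 'weighted'")
    tp, fp, fn, tn = cm.tp_fp_fn_tn()
    degenerate: set[int] = set()
    precision = _safe_div(tp, tp + fp, degenerate)
    recall = _safe_div(tp, tp + fn, degenerate)
    specificity = _safe_div(tn, tn + fp, degenerate)
    f1 = _safe_div(2 * precision * recall, precision + recall, degenerate)
    if degenerate:
        warnings.warn(
            f"0/0 metric defined as 0 for classes {sorted(degenerate)}", stacklevel=2
        )
    if averaging == "macro":
        weights = np.full(cm.k, 1.0 / cm.k)
    else:
        support = cm.counts.sum(axis=1)
        weights = support / support.sum()
    return MetricsReport(
        accuracy=float(100.0 * np.trace(cm.counts) / cm.total),
        precision=100.0 * float(precision @ weights),
        recall=100.0 * float(recall @ weights),
        specificity=100.0 * float(specificity @ weights),
        f1=100.0 * float(f1 @ weights),
        per_class_accuracy=[float(100.0 * r) for r in recall],
        degenerate_classes=sorted(degenerate),
        averaging=averaging,
    )


def evaluate_arrays(
    model: ResNet,
    x: np.ndarray,
    y: np.ndarray,
    k: int | None = None,
    class_labels: Sequence[str] | None = None,
    batch_size: int = 32,
) -> ConfusionMatrix:
    """Argmax-of-softmax predictions (ties -> lowest class index)."""
    model.train(False)
    k = k or model.config.num_classes
    preds = []
    for start in range(0, x.shape[0], batch_size):
        p = softmax(model.forward(x[start : start + batch_size]))
        preds.append(p.argmax(axis=1))  # argmax returns the first (lowest) index on ties
    y_pred = np.concatenate(preds) if preds else np.empty(0, dtype=int)
    if y.max(initial=-1) >= k:
        raise ValueError("label outside the model's class range")
    return confusion_matrix(y, y_pred, k, class_labels)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(
    path: str | Path,
    model: ResNet,
    mean: np.ndarray,
    sd: np.ndarray,
    train_config: TrainConfig,
    class_labels: Sequence[str],
) -> Path:
    """Single-file .npz checkpoint: weights + config + normalization + labels."""
    path = Path(path)
    meta = {
        "model_config": model.config.to_dict(),
        "train_config": train_config.to_dict(),
        "class_labels": list(class_labels),
    }
    np.savez(
        path,
        _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        _mean=mean,
        _sd=sd,
        **model.state_dict(),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path) -> tuple[ResNet, np.ndarray, np.ndarray, TrainConfig, list[str]]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        model = build_model(ModelConfig.from_dict(meta["model_config"]))
        state = {k: data[k] for k in data.files if not k.startswith("_")}
        model.load_state_dict(state)
        mean, sd = data["_mean"], data["_sd"]
        tc = meta["train_config"]
        train_config = TrainConfig(
            learning_rate=tc["learning_rate"],
            momentum=tc["momentum"],
            weight_decay=tc["weight_decay"],
            batch_size=tc["batch_size"],
            epochs=tc["epochs"],
            rng_seed=tc["rng_seed"],
        )
    return model, mean, sd, train_config, meta["class_labels"]
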