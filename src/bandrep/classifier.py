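"""Exercise-type CNN classifiers and the per-recording majority vote.

Four network variants share one architecture and differ only in the input
height N (the channel count of the windowed features):

====================  ====  =================================
variant                  N  channels
====================  ====  =================================
imu                     10  quaternion + gyro + acceleration
joints                  50  x, y of all 25 Body_25 joints
upper_joints            16  x, y of 8 upper-body joints
imu_joints              60  IMU channels followed by joints
====================  ====  =================================

The stack is: 5x5 conv (32 filters, same padding) -> 2x2 max pool ->
2x2 conv (64 filters, same padding) -> 2x2 max pool -> dropout ->
flatten -> dense 1000 -> dropout -> dense 6 -> softmax, giving e.g.
832 / 8256 / 1,921,000 / 6006 trainable parameters for the 10x60x1 input.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import confusion_matrix

from . import nn
from .datamodel_io import EXERCISES
from .preprocess import FEATURE_VARIANTS, WindowBatch

__all__ = [
    "ClassifierMetrics",
    "TrainResult",
    "build_model",
    "count_parameters",
    "train",
    "evaluate",
    "predict_labels",
    "majority_vote",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

N_CLASSES = len(EXERCISES)
WINDOW_LEN = 60

# architecture constants shared by all variants
CONV1_FILTERS, CONV1_KERNEL = 32, 5
CONV2_FILTERS, CONV2_KERNEL = 64, 2
DENSE1_UNITS = 1000
DROPOUT1_RATE, DROPOUT2_RATE = 0.25, 0.5


@dataclass
class ClassifierMetrics:
    """Per-class precision/recall/F1 and overall accuracy from a 6x6
    confusion matrix (rows = true class, columns = predicted)."""

    confusion: np.ndarray
    precision: dict[str, float | None]
    recall: dict[str, float | None]
    f1: dict[str, float | None]
    accuracy: float

    def as_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
        }


@dataclass
class TrainResult:
    model: "nn.Sequential"
    metrics: ClassifierMetrics
    loss_history: list[float]
    channel_stats: tuple[np.ndarray, np.ndarray] | None


def build_model(variant: str, seed: int = 0) -> nn.Sequential:
    """Build the CNN for one input variant (input shape N x 60 x 1).

    Layer output shapes and trainable-parameter counts are fixed by the
    architecture: conv kernels 5x5 then 2x2 with same padding, 2x2
    floor-semantics pooling, a 1000-unit dense layer and a 6-way softmax.
    """
    if variant not in FEATURE_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; "
                         f"expected one of {sorted(FEATURE_VARIANTS)}")
    n = FEATURE_VARIANTS[variant]
    rng = np.random.default_rng(seed)
    flat = (n // 4) * (WINDOW_LEN // 4) * CONV2_FILTERS
    layers = [
        nn.Conv2DSame(1, CONV1_FILTERS, CONV1_KERNEL, rng=rng, name="conv2d_1"),
        nn.ReLU(name="relu_1"),
        nn.MaxPool2x2(name="max_pooling2d_1"),
        nn.Conv2DSame(CONV1_FILTERS, CONV2_FILTERS, CONV2_KERNEL, rng=rng,
                      name="conv2d_2"),
        nn.ReLU(name="relu_2"),
        nn.MaxPool2x2(name="max_pooling2d_2"),
        nn.Dropout(DROPOUT1_RATE, rng=rng, name="dropout_1"),
        nn.Flatten(name="flatten"),
        nn.Dense(flat, DENSE1_UNITS, rng=rng, name="dense_1"),
        nn.ReLU(name="relu_3"),
        nn.Dropout(DROPOUT2_RATE, rng=rng, name="dropout_2"),
        nn.Dense(DENSE1_UNITS, N_CLASSES, rng=rng, name="dense_2"),
    ]
    model = nn.Sequential(layers, input_shape=(n, WINDOW_LEN, 1))
    model.variant = variant
    return model


def count_parameters(model: nn.Sequential) -> list[tuple[str, tuple, int]]:
    """Per-layer (name, output shape, trainable parameter count) table.

    Activations are fused into their preceding layer in the table, the
    convention of framework model summaries.
    """
    return [row for row in model.summary() if not row[0].startswith("relu")]


def _to_input(batch: WindowBatch) -> np.ndarray:
    # (n_windows, n_channels, 60) -> NHWC (n, N, 60, 1)
    return batch.windows[..., None].astype(np.float32)


def _standardize(x: np.ndarray, stats=None):
    """Per-channel z-scoring; stats computed on the training split only."""
    if stats is None:
        mean = x.mean(axis=(0, 2, 3), keepdims=True)
        std = x.std(axis=(0, 2, 3), keepdims=True)
        std[std == 0] = 1.0
        stats = (mean, std)
    mean, std = stats
    return (x - mean) / std, stats


def _encode_labels(labels: np.ndarray) -> np.ndarray:
    idx = np.array([EXERCISES.index(str(l)) for l in labels])
    return idx


def train(model: nn.Sequential, batch: WindowBatch, split: float = 0.8,
          seed: int = 0, epochs: int = 15, batch_size: int = 64,
          lr: float = 1e-3, standardize: bool = True,
          split_level: str = "window") -> TrainResult:
    """Train on a labeled window batch; report held-out metrics.

    ``split`` of the windows train the network, the remainder is the
    evaluation split. The default window-level split mirrors the original
    protocol but lets overlapping windows from one recording land on both
    sides; ``split_level='recording'`` groups windows by their source
    recording (requires ``batch.source_index``) for a leakage-safe split.
    Deterministic for a fixed seed.
    """
    if batch.labels is None:
        raise ValueError("training requires a labeled batch")
    if not 0 < split < 1:
        raise ValueError(f"split must be in (0, 1), got {split}")
    y = _encode_labels(batch.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training batch must contain more than one class")
    if split_level == "window":
        warnings.warn(
            "window-level split: overlapping windows from one recording may "
            "appear in both splits; use split_level='recording' for a "
            "leakage-safe evaluation", stacklevel=2)
    rng = np.random.default_rng(seed)
    n = len(batch)
    if split_level == "recording":
        if batch.source_index is None:
            raise ValueError("recording-level split requires source_index")
        # group windows into contiguous recordings (source_index resets)
        rec_id = np.cumsum(np.r_[0, np.diff(batch.source_index) < 0])
        recs = np.unique(rec_id)
        perm = rng.permutation(recs)
        train_recs = set(perm[: max(1, int(round(split * len(recs))))].tolist())
        train_mask = np.isin(rec_id, list(train_recs))
        order_train = np.nonzero(train_mask)[0]
        order_eval = np.nonzero(~train_mask)[0]
    elif split_level == "window":
        perm = rng.permutation(n)
        n_train = int(round(split * n))
        order_train, order_eval = perm[:n_train], perm[n_train:]
    else:
        raise ValueError(f"unknown split_level {split_level!r}")
    if len(order_eval) == 0:
        raise ValueError("evaluation split is empty")

    x = _to_input(batch)
    x_train, y_train = x[order_train], y[order_train]
    x_eval, y_eval = x[order_eval], y[order_eval]
    stats = None
    if standardize:
        x_train, stats = _standardize(x_train)
        x_eval, _ = _standardize(x_eval, stats)
    model.channel_stats = stats

    onehot = np.eye(N_CLASSES, dtype=np.float32)[y_train]
    opt = nn.Adam(model.parameters, lr=lr)
    losses: list[float] = []
    for epoch in range(epochs):
        order = rng.permutation(len(x_train))
        epoch_loss = 0.0
        for start in range(0, len(order), batch_size):
            sel = order[start:start + batch_size]
            logits = model.forward(x_train[sel], training=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, onehot[sel])
            model.backward(dlogits)
            opt.step(model.gradients)
            epoch_loss += loss * len(sel)
        losses.append(epoch_loss / len(x_train))
        logger.debug("epoch %d loss %.4f", epoch, losses[-1])

    pred = model.predict_proba(x_eval).argmax(axis=1)
    metrics = _metrics_from_indices(y_eval, pred)
    return TrainResult(model=model, metrics=metrics, loss_history=losses,
                       channel_stats=stats)


def _metrics_from_indices(y_true: np.ndarray, y_pred: np.ndarray) -> ClassifierMetrics:
    cm = confusion_matrix(y_true, y_pred, labels=range(N_CLASSES))
    precision, recall, f1 = {}, {}, {}
    for c, label in enumerate(EXERCISES):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        support = cm[c, :].sum()
        p = tp / (tp + fp) if (tp + fp) > 0 else None
        r = tp / (tp + fn) if support > 0 else None  # undefined, not 0
        precision[label] = None if p is None else float(p)
        recall[label] = None if r is None else float(r)
        f1[label] = (None if (p is None or r is None or p + r == 0)
                     else float(2 * p * r / (p + r)))
    acc = float(np.trace(cm) / cm.sum())
    return ClassifierMetrics(confusion=cm, precision=precision, recall=recall,
                             f1=f1, accuracy=acc)


def evaluate(model: nn.Sequential, batch: WindowBatch) -> ClassifierMetrics:
    """Confusion matrix and per-class precision/recall/F1 on a labeled batch.

    A class with zero support in the batch has undefined recall, reported
    as ``None`` rather than 0.
    """
    if batch.labels is None:
        raise ValueError("evaluation requires a labeled batch")
    y = _encode_labels(batch.labels)
    x = _to_input(batch)
    stats = getattr(model, "channel_stats", None)
    if stats is not None:
        x, _ = _standardize(x, stats)
    pred = model.predict_proba(x).argmax(axis=1)
    return _metrics_from_indices(y, pred)


def predict_labels(model: nn.Sequential, batch: WindowBatch) -> list[str]:
    """Per-window predicted exercise labels."""
    x = _to_input(batch)
    stats = getattr(model, "channel_stats", None)
    if stats is not None:
        x, _ = _standardize(x, stats)
    idx = model.predict_proba(x).argmax(axis=1)
    return [EXERCISES[i] for i in idx]


def majority_vote(window_labels) -> str:
    """Most frequent label across a recording's windows.

    Ties are broken by the earliest first occurrence in the sequence
    (logged when it happens).
    """
    labels = list(window_labels)
    if not labels:
        raise ValueError("majority_vote requires at least one label")
    counts = Counter(labels)
    top = max(counts.values())
    tied = [l for l, c in counts.items() if c == top]
    if len(tied) > 1:
        winner = min(tied, key=labels.index)
        logger.info("majority vote tie among %s; keeping first-seen %s",
                    sorted(tied), winner)
        return winner
    return tied[0]


# ---------------------------------------------------------------------------
# Persistence: weights in .npz, architecture + channel stats in JSON sidecar
# ---------------------------------------------------------------------------

def save_model(model: nn.Sequential, path: str | Path) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.get_weights())
    meta = {"variant": getattr(model, "variant", None),
            "input_shape": list(model.input_shape)}
    stats = getattr(model, "channel_stats", None)
    if stats is not None:
        meta["channel_mean"] = np.asarray(stats[0]).ravel().tolist()
        meta["channel_std"] = np.asarray(stats[1]).ravel().tolist()
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_model(path: str | Path) -> nn.Sequential:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    model = build_model(meta["variant"])
    with np.load(path.with_suffix(".npz")) as data:
        model.set_weights(dict(data))
    if "channel_mean" in meta:
        n = model.input_shape[0]
        mean = np.asarray(meta["channel_mean"]).reshape(1, n, 1, 1)
        std = np.asarray(meta["channel_std"]).reshape(1, n, 1, 1)
        model.channel_stats = (mean, std)
    return model
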