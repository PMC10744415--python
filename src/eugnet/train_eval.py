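"""Class-balanced training and confusion-matrix evaluation.

Metrics follow the two-class (background/foreground) segmentation protocol:

    IoU_k = TP_k / (TP_k + FP_k + FN_k)
    DSC_k = 2 TP_k / (2 TP_k + FP_k + FN_k)
    balanced accuracy (fg.) = (TPR + TNR) / 2, foreground positive

averaged over the K classes.  A class with an empty union (TP+FP+FN = 0)
contributes 1 — a frame with no foreground and no false alarms is a perfect
frame, not a 0/0.  Aggregation over frames is micro (pixel counts summed
over the whole set before ratios); per-frame macro averages are also
reported.

The loss is pixel-averaged cross-entropy with per-class weights inversely
proportional to class frequency (normalized to sum to K), countering the
strong background/instrument imbalance of surgical scenes.  The optimizer
is SGD with momentum 0.9 under a triangular cyclical learning rate (CLR)
oscillating between fixed bounds, default (1e-4, 1e-2).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import augment as _augment
from . import gridmask as _gridmask
from .augment import AugmentConfig
from .gridmask import GridMaskPolicy
from .model import SegModel
from .nn import SGD, Tensor, log_softmax
from .synthdata import SegDataset

__all__ = ["ConfusionCounts", "MetricsReport", "TrainConfig", "confusion",
           "mean_iou", "mean_dsc", "balanced_accuracy_fg", "class_weights",
           "balanced_loss", "clr", "train", "evaluate"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class pixel confusion counts, stored as a K x K matrix with
    rows = true class, columns = predicted class."""

    matrix: np.ndarray  # (K, K) int64

    @property
    def num_classes(self) -> int:
        return self.matrix.shape[0]

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def tp(self, k: int) -> int:
        return int(self.matrix[k, k])

    def fp(self, k: int) -> int:
        return int(self.matrix[:, k].sum() - self.matrix[k, k])

    def fn(self, k: int) -> int:
        return int(self.matrix[k, :].sum() - self.matrix[k, k])

    def tn(self, k: int) -> int:
        return self.total - self.tp(k) - self.fp(k) - self.fn(k)

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.matrix + other.matrix)


def confusion(prediction: np.ndarray, truth: np.ndarray,
              num_classes: int = 2) -> ConfusionCounts:
    """Exact integer confusion counts; entries must lie in {0..K-1}."""
    prediction = np.asarray(prediction)
    truth = np.asarray(truth)
    if prediction.shape != truth.shape:
        raise ValueError(
            f"prediction shape {prediction.shape} != truth shape {truth.shape}"
        )
    for name, arr in (("prediction", prediction), ("truth", truth)):
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError(f"{name} labels must be in [0, {num_classes})")
    idx = num_classes * truth.astype(np.int64).ravel() + prediction.astype(np.int64).ravel()
    mat = np.bincount(idx, minlength=num_classes ** 2).reshape(num_classes, num_classes)
    return ConfusionCounts(mat)


def _per_class(counts: ConfusionCounts, fn) -> list[float]:
    return [fn(counts, k) for k in range(counts.num_classes)]


def _iou_k(c: ConfusionCounts, k: int) -> float:
    union = c.tp(k) + c.fp(k) + c.fn(k)
    return 1.0 if union == 0 else c.tp(k) / union


def _dsc_k(c: ConfusionCounts, k: int) -> float:
    denom = 2 * c.tp(k) + c.fp(k) + c.fn(k)
    return 1.0 if denom == 0 else 2 * c.tp(k) / denom


def mean_iou(counts: ConfusionCounts) -> float:
    """(1/K) sum_k TP_k / (TP_k + FP_k + FN_k), empty unions scoring 1."""
    return float(np.mean(_per_class(counts, _iou_k)))


def mean_dsc(counts: ConfusionCounts) -> float:
    """(1/K) sum_k 2 TP_k / (2 TP_k + FP_k + FN_k), empty unions scoring 1."""
    return float(np.mean(_per_class(counts, _dsc_k)))


def balanced_accuracy_fg(counts: ConfusionCounts) -> float:
    """(sensitivity + specificity) / 2 with the foreground class positive."""
    if counts.num_classes != 2:
        raise ValueError("balanced accuracy (fg.) is defined for K = 2")
    tp, fn = counts.tp(1), counts.fn(1)
    tn, fp = counts.tn(1), counts.fp(1)
    tpr = 1.0 if tp + fn == 0 else tp / (tp + fn)
    tnr = 1.0 if tn + fp == 0 else tn / (tn + fp)
    return (tpr + tnr) / 2.0


def class_weights(label_histogram, mode: str = "dataset",
                  eps: float = 1e-6) -> np.ndarray:
    """Inverse-frequency class weights, normalized so they sum to K.

    mode "dataset" and "batch" share the formula (they differ only in
    which histogram the caller passes); mode "none" yields unit weights.
    Classes absent from the histogram get the 1/eps cap before
    normalization, i.e. the maximum weight.
    """
    hist = np.asarray(label_histogram, dtype=np.float64)
    if hist.ndim != 1 or (hist < 0).any():
        raise ValueError("label_histogram must be a 1-D non-negative array")
    if hist.sum() == 0:
        raise ValueError("label_histogram must have at least one nonzero entry")
    k = hist.size
    if mode == "none":
        return np.ones(k)
    if mode not in ("dataset", "batch"):
        raise ValueError(f"unknown class-weight mode {mode!r}")
    freq = hist / hist.sum()
    w = 1.0 / np.maximum(freq, eps)
    return w * (k / w.sum())


def balanced_loss(scores, truth: np.ndarray, weights) -> "Tensor | float":
    """Pixel-averaged weighted cross-entropy.

    scores : (N, K, H, W) or (K, H, W), Tensor or ndarray of class scores
        (logits).  truth : matching (N, H, W) or (H, W) integer labels.
    Each pixel contributes w[y] * (-log p_y); the sum is divided by the
    pixel count, so with unit weights this is plain mean cross-entropy and
    doubling a class's weight doubles its pixels' contribution.

    Returns a Tensor when given a Tensor (for backprop), else a float.
    """
    is_tensor = isinstance(scores, Tensor)
    t = scores if is_tensor else Tensor(np.asarray(scores, dtype=np.float32))
    squeeze = t.data.ndim == 3
    if squeeze:
        t = t.reshape(1, *t.data.shape)
        truth = np.asarray(truth)[None]
    truth = np.asarray(truth).astype(np.int64)
    n, k, h, w = t.data.shape
    if truth.shape != (n, h, w):
        raise ValueError(f"truth shape {truth.shape} incompatible with scores "
                         f"{t.data.shape}")
    weights = np.asarray(weights, dtype=np.float32)
    onehot = np.zeros((n, k, h, w), dtype=np.float32)
    np.put_along_axis(onehot, truth[:, None], 1.0, axis=1)
    wmap = weights[truth][:, None]  # (N, 1, H, W)
    logp = log_softmax(t, axis=1)
    loss = -(logp * (onehot * wmap)).sum() * (1.0 / float(n * h * w))
    return loss if is_tensor else float(loss.data)


@dataclass(frozen=True)
class TrainConfig:
    """Training-loop hyperparameters.

    CLR follows a triangular schedule between (base_lr, max_lr) with a
    cycle of `clr_cycle_steps` optimizer steps (None = two epochs).
    """

    epochs: int = 10
    batch_size: int = 8
    seed: int = 0
    base_lr: float = 1e-4
    max_lr: float = 1e-2
    clr_cycle_steps: int | None = None
    momentum: float = 0.9
    class_weight_mode: str = "dataset"
    val_fraction: float = 0.2
    gridmask: GridMaskPolicy = field(default_factory=GridMaskPolicy)
    augment: AugmentConfig = field(default_factory=AugmentConfig)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 < self.base_lr < self.max_lr):
            raise ValueError("train.clr: need 0 < base_lr < max_lr, got "
                             f"({self.base_lr}, {self.max_lr})")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ValueError("val_fraction must be in [0, 1)")
        if self.clr_cycle_steps is not None and self.clr_cycle_steps < 2:
            raise ValueError("clr_cycle_steps must be >= 2")


def clr(step: int, config: TrainConfig) -> float:
    """Triangular cyclical learning rate: rises linearly from base_lr to
    max_lr over half a cycle and falls back; never leaves the bounds."""
    if step < 0:
        raise ValueError("step must be >= 0")
    cycle = config.clr_cycle_steps
    if cycle is None:
        raise ValueError("clr_cycle_steps is unresolved; set it explicitly")
    x = step % cycle
    half = cycle / 2.0
    if x == 0:
        return config.base_lr
    if x == half:
        return config.max_lr
    frac = x / half if x < half else (cycle - x) / half
    return config.base_lr + (config.max_lr - config.base_lr) * frac


def _augment_batch(images, masks, config: TrainConfig, rng):
    out_i, out_m = [], []
    for img, msk in zip(images, masks):
        img, msk = _augment.apply_standard(img, msk, config.augment, rng)
        img, msk = _gridmask.augment_sample(img, msk, config.gridmask, rng)
        out_i.append(img)
        out_m.append(msk)
    return np.stack(out_i), np.stack(out_m)


def train(model: SegModel, dataset: SegDataset, config: TrainConfig,
          rng: np.random.Generator | None = None) -> list[dict]:
    """Train `model` in place; returns the per-epoch history.

    Each epoch visits the training split in a fresh random order, applies
    the standard augmentations then GridMask per policy to every sample,
    and takes SGD steps under the CLR schedule.  History entries carry the
    mean training loss plus pixel accuracy and mean DSC on the held-out
    split — the three curves usually monitored for this task.  Fully
    reproducible under a fixed seed.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    rng = rng or np.random.default_rng(config.seed)
    k = model.config.num_classes

    order = rng.permutation(len(dataset))
    n_val = int(round(config.val_fraction * len(dataset)))
    n_val = min(n_val, len(dataset) - 1)
    val_idx, tr_idx = order[:n_val], order[n_val:]
    train_ds = dataset.subset(tr_idx)
    val_ds = dataset.subset(val_idx) if n_val else dataset.subset(tr_idx)

    steps_per_epoch = int(np.ceil(len(train_ds) / config.batch_size))
    if config.clr_cycle_steps is None:
        config = replace(config, clr_cycle_steps=max(2, 2 * steps_per_epoch))

    if config.class_weight_mode == "dataset":
        hist = np.bincount(train_ds.masks.ravel(), minlength=k)
        weights = class_weights(hist, "dataset")
    else:
        weights = np.ones(k)

    opt = SGD(model.parameters(), momentum=config.momentum)
    history: list[dict] = []
    step = 0
    for epoch in range(config.epochs):
        perm = rng.permutation(len(train_ds))
        losses = []
        for a in range(0, len(perm), config.batch_size):
            idx = perm[a:a + config.batch_size]
            imgs, msks = _augment_batch(train_ds.images[idx], train_ds.masks[idx],
                                        config, rng)
            if config.class_weight_mode == "batch":
                weights = class_weights(np.bincount(msks.ravel(), minlength=k),
                                        "batch")
            x = Tensor(imgs.transpose(0, 3, 1, 2))
            scores = model(x)
            loss = balanced_loss(scores, msks, weights)
            model.zero_grad()
            loss.backward()
            opt.step(clr(step, config))
            step += 1
            losses.append(loss.item())
        report = evaluate(model, val_ds)
        acc = (report.counts.tp(0) + report.counts.tp(1)) / report.counts.total \
            if k == 2 else float(np.trace(report.counts.matrix)) / report.counts.total
        history.append({
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "accuracy": float(acc),
            "mean_dsc": report.mean_dsc,
        })
    return history


@dataclass(frozen=True)
class MetricsReport:
    """Evaluation summary.  Headline fields are micro-aggregated (pixel
    counts summed over all frames before ratios); macro_* fields average
    the same metrics computed per frame."""

    mean_iou: float
    mean_dsc: float
    balanced_accuracy_fg: float
    iou_per_class: tuple[float, ...]
    dsc_per_class: tuple[float, ...]
    macro_mean_iou: float
    macro_mean_dsc: float
    macro_balanced_accuracy_fg: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "mean_iou": self.mean_iou,
            "mean_dsc": self.mean_dsc,
            "balanced_accuracy_fg": self.balanced_accuracy_fg,
            "iou_per_class": list(self.iou_per_class),
            "dsc_per_class": list(self.dsc_per_class),
            "macro_mean_iou": self.macro_mean_iou,
            "macro_mean_dsc": self.macro_mean_dsc,
            "macro_balanced_accuracy_fg": self.macro_balanced_accuracy_fg,
            "confusion_matrix": self.counts.matrix.tolist(),
        }


def report_from_counts(total: ConfusionCounts,
                       per_frame: list[ConfusionCounts]) -> MetricsReport:
    k2 = total.num_classes == 2
    return MetricsReport(
        mean_iou=mean_iou(total),
        mean_dsc=mean_dsc(total),
        balanced_accuracy_fg=balanced_accuracy_fg(total) if k2 else float("nan"),
        iou_per_class=tuple(_per_class(total, _iou_k)),
        dsc_per_class=tuple(_per_class(total, _dsc_k)),
        macro_mean_iou=float(np.mean([mean_iou(c) for c in per_frame])),
        macro_mean_dsc=float(np.mean([mean_dsc(c) for c in per_frame])),
        macro_balanced_accuracy_fg=float(np.mean(
            [balanced_accuracy_fg(c) for c in per_frame])) if k2 else float("nan"),
        counts=total,
    )


def evaluate(model: SegModel, dataset: SegDataset, batch_size: int = 8) -> MetricsReport:
    """Argmax predictions, confusion counts aggregated over all frames,
    and the derived metric report."""
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    k = model.config.num_classes
    preds = model.predict(dataset.images, batch_size=batch_size)
    per_frame = [confusion(p, t, k) for p, t in zip(preds, dataset.masks)]
    total = ConfusionCounts(sum(c.matrix for c in per_frame))
    return report_from_counts(total, per_frame)
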