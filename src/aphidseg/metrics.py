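"""Segmentation metrics over accumulated confusion counts, plus an FPS harness.

All quality metrics derive from a per-class confusion accumulator:

    mIoU = (1/N) sum_i TP_i / (TP_i + FP_i + FN_i)
    mPA  = (1/N) sum_i TP_i / (TP_i + FN_i)
    Accuracy = sum_i TP_i / total pixels          (pooled pixel accuracy)
    mF1  = (1/N) sum_i 2 TP_i / (2 TP_i + FP_i + FN_i)

Accumulation over batches is additive and order-independent, so streaming
evaluation equals single-shot evaluation on concatenated masks.

Zero-division rule: a class absent from both prediction and ground truth
(TP+FP+FN = 0) contributes a vacuously perfect 1.0 to the per-class means by
default; ``absent_class="skip"`` drops such classes from the mean instead.

FPS times only the network forward pass - no data loading, resizing,
visualisation or disk I/O - and is hardware-dependent by nature.
"""

from __future__ import annotations

import csv
import json
import time
from dataclasses import asdict, dataclass

import numpy as np

from .nn import Tensor, no_grad

__all__ = ["ConfusionMatrix", "MetricReport", "compute_metrics", "benchmark_fps"]


class ConfusionMatrix:
    """N-class pixel confusion accumulator.

    Stores the full N x N table (rows = ground truth, columns = prediction);
    per-class TP/FP/FN/TN are derived views.
    """

    def __init__(self, num_classes: int = 2):
        if num_classes < 2:
            raise ValueError("need at least 2 classes")
        self.num_classes = num_classes
        self.table = np.zeros((num_classes, num_classes), dtype=np.int64)

    def update(self, pred: np.ndarray, gt: np.ndarray) -> "ConfusionMatrix":
        pred = np.asarray(pred)
        gt = np.asarray(gt)
        if pred.shape != gt.shape:
            raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")
        if pred.size == 0:
            return self
        p = pred.ravel().astype(np.int64)
        g = gt.ravel().astype(np.int64)
        n = self.num_classes
        for name, lab in (("pred", p), ("gt", g)):
            if lab.min() < 0 or lab.max() >= n:
                raise ValueError(f"{name} labels outside [0, {n})")
        self.table += np.bincount(g * n + p, minlength=n * n).reshape(n, n)
        return self

    # -- derived counts -------------------------------------------------------
    @property
    def total(self) -> int:
        return int(self.table.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.table)

    @property
    def fn(self) -> np.ndarray:
        return self.table.sum(axis=1) - self.tp

    @property
    def fp(self) -> np.ndarray:
        return self.table.sum(axis=0) - self.tp

    @property
    def tn(self) -> np.ndarray:
        return self.total - self.tp - self.fn - self.fp

    def merge(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if other.num_classes != self.num_classes:
            raise ValueError("class-count mismatch")
        self.table += other.table
        return self


@dataclass
class MetricReport:
    miou: float
    mpa: float
    accuracy: float
    mf1: float
    fps: float | None = None

    def __post_init__(self):
        for name in ("miou", "mpa", "accuracy", "mf1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.fps is not None and self.fps < 0:
            raise ValueError("fps must be non-negative")

    def as_percent(self) -> dict[str, float]:
        d = {k: round(v * 100, 2) for k, v in asdict(self).items()
             if k != "fps" and v is not None}
        if self.fps is not None:
            d["fps"] = round(self.fps, 3)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_percent(), fh, indent=2)

    def to_csv(self, path) -> None:
        d = self.as_percent()
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(list(d))
            writer.writerow([d[k] for k in d])


def _per_class_ratio(num: np.ndarray, den: np.ndarray, absent: np.ndarray,
                     absent_class: str) -> float:
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(den > 0, num / np.maximum(den, 1), 1.0)
    if absent_class == "skip":
        keep = ~absent
        if not keep.any():
            raise ValueError("all classes absent; nothing to average")
        return float(vals[keep].mean())
    return float(np.where(absent, 1.0, vals).mean())


def compute_metrics(cm: ConfusionMatrix, absent_class: str = "perfect") -> MetricReport:
    """Macro mIoU/mPA/mF1 and pooled Accuracy from accumulated counts.

    ``absent_class`` selects the zero-division rule: "perfect" (default)
    credits a class absent from both masks with 1.0; "skip" excludes it.
    """
    if absent_class not in ("perfect", "skip"):
        raise ValueError(f"unknown absent_class {absent_class!r}")
    if cm.total == 0:
        raise ValueError("empty confusion accumulator")
    tp, fp, fn = cm.tp, cm.fp, cm.fn
    absent = (tp + fp + fn) == 0
    miou = _per_class_ratio(tp, tp + fp + fn, absent, absent_class)
    mpa = _per_class_ratio(tp, tp + fn, (tp + fn) == 0, absent_class)
    mf1 = _per_class_ratio(2 * tp, 2 * tp + fp + fn, absent, absent_class)
    accuracy = float(tp.sum() / cm.total)
    return MetricReport(miou=miou, mpa=mpa, accuracy=accuracy, mf1=mf1)


def benchmark_fps(model, n_images: int = 50, resolution: int = 480,
                  warmup: int = 10, seed: int = 0) -> float:
    """Forward-only throughput: n_images / elapsed time, single-image batches.

    Warm-up forwards are excluded from timing. The returned number depends on
    the executing hardware and is reported, never asserted against published
    values.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if resolution % 16:
        raise ValueError(f"resolution must be divisible by 16, got {resolution}")
    rng = np.random.default_rng(seed)
    model.eval()
    img = rng.normal(size=(1, 3, resolution, resolution)).astype(np.float32)
    with no_grad():
        for _ in range(warmup):
            model(Tensor(img))
        start = time.perf_counter()
        for _ in range(n_images):
            model(Tensor(img))
        elapsed = time.perf_counter() - start
    return n_images / elapsed
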