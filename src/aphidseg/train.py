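"""Training, evaluation and prediction engine.

The loss is an equally weighted sum of pixel cross-entropy and soft Dice
over the class probabilities - the standard hybrid for class-imbalanced
binary segmentation, where the Dice term keeps the small foreground class
from being drowned out by background pixels. Optimisation uses Adam.

Runs are fully seeded: weight initialisation, batch order and the synthetic
data pipeline all derive from the one seed in :class:`TrainConfig`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .backbone import ModelConfig, UNet, build_model, save_checkpoint
from .data import SegSample, save_mask_png
from .metrics import ConfusionMatrix, MetricReport, compute_metrics
from .nn import Adam, Tensor, no_grad

__all__ = ["TrainConfig", "TrainResult", "train", "evaluate", "predict",
           "hybrid_loss", "samples_to_arrays"]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    batch_size: int = 8
    epochs: int = 100
    steps: int | None = None        # optional hard cap on optimisation steps
    learning_rate: float = 1e-4
    dice_weight: float = 0.5        # loss = (1-w)*CE + w*Dice
    seed: int = 0
    eval_every: int = 10            # steps between training-mIoU probes
    target_miou: float | None = None  # early stop once training mIoU exceeds
    checkpoint_path: str | None = None
    log_path: str | None = None

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if not 0 <= self.dice_weight <= 1:
            raise ValueError("dice_weight must be in [0, 1]")


@dataclass
class TrainResult:
    steps: int
    final_loss: float
    train_miou: float
    history: list[dict] = field(default_factory=list)
    checkpoint_path: str | None = None


def samples_to_arrays(samples: list[SegSample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack samples into (N,3,H,W) float32 in [0,1] and (N,H,W) int64."""
    imgs = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    x = np.ascontiguousarray(imgs.transpose(0, 3, 1, 2))
    y = np.stack([s.mask for s in samples]).astype(np.int64)
    return x, y


def _log_softmax(logits: Tensor) -> Tensor:
    # stable log-softmax over the channel axis
    shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    return shifted - shifted.exp().sum(axis=1, keepdims=True).log()


def hybrid_loss(logits: Tensor, target: np.ndarray,
                dice_weight: float = 0.5) -> Tensor:
    """(1-w) * cross-entropy + w * soft Dice, macro over classes."""
    N, C, H, W = logits.shape
    onehot = np.zeros((N, C, H, W), dtype=np.float32)
    idx0, idx2, idx3 = np.ogrid[:N, :H, :W]
    onehot[idx0, target, idx2, idx3] = 1.0
    oh = Tensor(onehot)

    logp = _log_softmax(logits)
    ce = -(logp * oh).sum(axis=1).mean()

    probs = logp.exp()
    inter = (probs * oh).sum(axis=(0, 2, 3))
    denom = probs.sum(axis=(0, 2, 3)) + oh.sum(axis=(0, 2, 3))
    dice = 1.0 - ((inter * 2.0 + 1.0) / (denom + 1.0)).mean()
    return ce * (1.0 - dice_weight) + dice * dice_weight


def _train_miou(model: UNet, x: np.ndarray, y: np.ndarray,
                classes: int, batch: int = 8) -> float:
    cm = ConfusionMatrix(classes)
    was_training = model.training
    model.eval()
    with no_grad():
        for i in range(0, len(x), batch):
            logits = model(Tensor(x[i : i + batch]))
            cm.update(logits.data.argmax(axis=1), y[i : i + batch])
    model.train(was_training)
    return compute_metrics(cm).miou


def train(model_cfg: ModelConfig, train_cfg: TrainConfig,
          samples: list[SegSample]) -> tuple[UNet, TrainResult]:
    """Seeded training loop; returns the model and a per-probe metric log."""
    if not samples:
        raise ValueError("train: empty dataset")
    x, y = samples_to_arrays(samples)
    H, W = x.shape[2:]
    if H % 16 or W % 16:
        raise ValueError(
            f"training resolution must be divisible by 16, got {(H, W)}"
        )

    model = build_model(model_cfg, seed=train_cfg.seed)
    opt = Adam(model.parameters(), lr=train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed + 1)

    max_steps = train_cfg.steps
    if max_steps is None:
        steps_per_epoch = int(np.ceil(len(x) / train_cfg.batch_size))
        max_steps = train_cfg.epochs * steps_per_epoch

    history: list[dict] = []
    step = 0
    loss_val = float("nan")
    miou = 0.0
    order = np.array([], dtype=np.int64)
    while step < max_steps:
        if order.size < train_cfg.batch_size:
            order = rng.permutation(len(x))
        take, order = order[: train_cfg.batch_size], order[train_cfg.batch_size :]
        xb, yb = x[take], y[take]

        model.train()
        logits = model(Tensor(xb))
        loss = hybrid_loss(logits, yb, train_cfg.dice_weight)
        opt.zero_grad()
        loss.backward()
        opt.step()
        loss_val = float(loss.data)
        step += 1

        if step % train_cfg.eval_every == 0 or step == max_steps:
            miou = _train_miou(model, x, y, model_cfg.classes)
            history.append({"step": step, "loss": loss_val, "train_miou": miou})
            logger.info("step %d  loss %.4f  train mIoU %.4f", step, loss_val, miou)
            if train_cfg.target_miou is not None and miou > train_cfg.target_miou:
                break

    ckpt = None
    if train_cfg.checkpoint_path:
        ckpt = str(train_cfg.checkpoint_path)
        save_checkpoint(model, ckpt)
    if train_cfg.log_path:
        with open(train_cfg.log_path, "w") as fh:
            json.dump(history, fh, indent=2)
    return model, TrainResult(steps=step, final_loss=loss_val, train_miou=miou,
                              history=history, checkpoint_path=ckpt)


def evaluate(model: UNet, samples: list[SegSample],
             batch_size: int = 8) -> MetricReport:
    """Stream batches through the confusion accumulator and report metrics."""
    if not samples:
        raise ValueError("evaluate: empty dataset")
    x, y = samples_to_arrays(samples)
    classes = model.cfg.classes
    if y.max() >= classes:
        raise ValueError(
            f"mask labels up to {y.max()} exceed model classes ({classes})"
        )
    cm = ConfusionMatrix(classes)
    model.eval()
    with no_grad():
        for i in range(0, len(x), batch_size):
            logits = model(Tensor(x[i : i + batch_size]))
            cm.update(logits.data.argmax(axis=1), y[i : i + batch_size])
    return compute_metrics(cm)


def predict(model: UNet, images: list, out_dir) -> list[Path]:
    """Argmax masks + red-overlay renderings for a list of image paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model.eval()
    written: list[Path] = []
    for path in images:
        path = Path(path)
        try:
            img = Image.open(path).convert("RGB")
        except Exception as exc:  # unreadable input: report, continue
            logger.warning("skipping unreadable image %s (%s)", path, exc)
            continue
        arr = np.asarray(img).astype(np.float32) / 255.0
        H, W = arr.shape[:2]
        Hc, Wc = H - H % 16, W - W % 16
        arr = arr[:Hc, :Wc]
        x = np.ascontiguousarray(arr.transpose(2, 0, 1))[None]
        with no_grad():
            mask = model(Tensor(x)).data.argmax(axis=1)[0].astype(np.uint8)

        mask_path = out_dir / f"{path.stem}_mask.png"
        save_mask_png(mask, mask_path)

        overlay = np.rint(arr * 255).astype(np.uint8).copy()
        fg = mask.astype(bool)
        overlay[fg] = (0.5 * overlay[fg] + 0.5 * np.array([255, 0, 0])).astype(np.uint8)
        overlay_path = out_dir / f"{path.stem}_overlay.png"
        Image.fromarray(overlay).save(overlay_path)
        written += [mask_path, overlay_path]
    return written
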