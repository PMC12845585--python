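"""Dataset plumbing and a synthetic aphid-scene generator.

Real field photographs of aphid-infested sorghum combine a handful of
statistical nuisances: quasi-periodic leaf-vein striping, smooth illumination
gradients across the leaf, occasional shadows, sensor speckle, and
low-contrast clusters of small elliptical insects whose density varies
widely. :func:`synth_scene` emulates exactly these axes so the whole test
suite runs without any downloaded data:

* background: a base green tone + sinusoidal vein stripes + a linear
  illumination gradient + Gaussian speckle (+ optional dark shadow band);
* foreground: ``n_clusters`` clusters, each a union of overlapping ellipses
  rendered at the base tone shifted by a configurable contrast offset;
* mask: the exact rasterised ellipse union.

Everything is deterministic given (parameters, seed).

The module also implements the dataset-expansion protocol used for the
field-collected image set: originals are randomly partitioned into four
equal subsets, each receiving exactly one of {horizontal flip, vertical
flip, brightness perturbation, noise injection}, doubling the dataset; and
a seeded 7:3 train/test split.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "SegSample",
    "SceneParams",
    "synth_scene",
    "synth_dataset",
    "augment_expand",
    "split_dataset",
    "load_pairs",
    "write_dataset",
    "save_mask_png",
    "load_mask_png",
]

logger = logging.getLogger(__name__)

AUGMENTATIONS = ("hflip", "vflip", "brightness", "noise")


@dataclass
class SegSample:
    image: np.ndarray  # (H, W, 3) uint8 RGB
    mask: np.ndarray   # (H, W) uint8 in {0, 1}
    id: str
    provenance: str = "original"

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask must share height/width")
        if not set(np.unique(self.mask)).issubset({0, 1}):
            raise ValueError("mask values must be in {0, 1}")


@dataclass
class SceneParams:
    """Knobs of the synthetic scene; defaults give plausible field imagery."""

    size: int = 64
    n_clusters: int = 3
    aphids_per_cluster: tuple[int, int] = (3, 8)
    aphid_axes: tuple[float, float] = (3.0, 6.0)   # semi-axis range, px
    cluster_spread: float = 8.0                    # sd of ellipse centres, px
    contrast_offset: float = 35.0                  # aphid tone delta, 8-bit units
    vein_amplitude: float = 12.0
    vein_frequency: float = 0.35                   # cycles per pixel * 2*pi scale
    illumination_strength: float = 25.0
    speckle_sd: float = 4.0
    shadow_probability: float = 0.3
    base_green: tuple[int, int, int] = (70, 120, 60)
    seed: int = 0

    def __post_init__(self):
        if self.size < 8:
            raise ValueError("size must be >= 8")
        if min(self.aphid_axes) <= 0:
            raise ValueError("aphid axes must be positive")
        if max(self.aphid_axes) * 2 >= self.size:
            raise ValueError("aphid axes larger than the image")
        for name in ("contrast_offset", "vein_amplitude", "illumination_strength",
                     "speckle_sd", "cluster_spread"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.shadow_probability <= 1:
            raise ValueError("shadow_probability must be in [0, 1]")


def sample_ellipses(p: SceneParams, rng: np.random.Generator):
    """Draw the ellipse population (cx, cy, a, b, theta) for one scene."""
    ellipses = []
    for _ in range(p.n_clusters):
        cx = rng.uniform(0.15 * p.size, 0.85 * p.size)
        cy = rng.uniform(0.15 * p.size, 0.85 * p.size)
        count = rng.integers(p.aphids_per_cluster[0], p.aphids_per_cluster[1] + 1)
        for _ in range(count):
            ex = cx + rng.normal(0, p.cluster_spread)
            ey = cy + rng.normal(0, p.cluster_spread)
            a = rng.uniform(*p.aphid_axes)
            b = rng.uniform(*p.aphid_axes) * 0.6
            theta = rng.uniform(0, np.pi)
            ellipses.append((ex, ey, a, b, theta))
    return ellipses


def _rasterise(ellipses, size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    mask = np.zeros((size, size), dtype=bool)
    for ex, ey, a, b, theta in ellipses:
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx + 0.5 - ex) * ct + (yy + 0.5 - ey) * st
        v = -(xx + 0.5 - ex) * st + (yy + 0.5 - ey) * ct
        mask |= (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return mask


def synth_scene(p: SceneParams) -> SegSample:
    """Render one synthetic leaf scene with its exact segmentation mask."""
    rng = np.random.default_rng(p.seed)
    s = p.size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)

    base = np.array(p.base_green, dtype=np.float64)
    img = np.broadcast_to(base, (s, s, 3)).copy()

    # leaf-vein striping along a random orientation
    phase = rng.uniform(0, 2 * np.pi)
    angle = rng.uniform(0, np.pi)
    coord = xx * np.cos(angle) + yy * np.sin(angle)
    img += (p.vein_amplitude * np.sin(p.vein_frequency * coord + phase))[..., None]

    # smooth illumination gradient across the frame
    gdir = rng.uniform(0, 2 * np.pi)
    ramp = (xx * np.cos(gdir) + yy * np.sin(gdir)) / s
    img += (p.illumination_strength * (ramp - ramp.mean()))[..., None]

    # occasional soft shadow band
    if rng.uniform() < p.shadow_probability:
        centre = rng.uniform(0, s)
        width = rng.uniform(0.15 * s, 0.4 * s)
        band = np.exp(-0.5 * ((coord - centre) / width) ** 2)
        img -= 30.0 * band[..., None]

    # aphid clusters: low-contrast dark ellipses on the leaf
    ellipses = sample_ellipses(p, rng)
    mask = _rasterise(ellipses, s)
    tone = base - p.contrast_offset + rng.normal(0, 3, size=3)
    img[mask] = tone

    # sensor speckle on top of everything
    img += rng.normal(0, p.speckle_sd, size=img.shape)

    image = np.clip(img, 0, 255).astype(np.uint8)
    return SegSample(
        image=image,
        mask=mask.astype(np.uint8),
        id=f"synth-{p.seed:06d}",
        provenance=f"synthetic(seed={p.seed})",
    )


def synth_dataset(n: int, params: SceneParams | None = None,
                  seed: int = 0) -> list[SegSample]:
    """n scenes with per-scene seeds derived from ``seed``."""
    params = params or SceneParams()
    return [synth_scene(replace(params, seed=seed * 100003 + i)) for i in range(n)]


# ---------------------------------------------------------------------------
# augmentation expansion


def _apply_augmentation(sample: SegSample, kind: str,
                        rng: np.random.Generator) -> SegSample:
    img, mask = sample.image, sample.mask
    if kind == "hflip":
        img, mask = img[:, ::-1].copy(), mask[:, ::-1].copy()
    elif kind == "vflip":
        img, mask = img[::-1].copy(), mask[::-1].copy()
    elif kind == "brightness":
        factor = rng.uniform(0.7, 1.3)
        img = np.clip(img.astype(np.float64) * factor, 0, 255).astype(np.uint8)
        mask = mask.copy()
    elif kind == "noise":
        noise = rng.normal(0, 0.05 * 255, size=img.shape)
        img = np.clip(img.astype(np.float64) + noise, 0, 255).astype(np.uint8)
        mask = mask.copy()
    else:  # pragma: no cover
        raise ValueError(f"unknown augmentation {kind!r}")
    return SegSample(image=img, mask=mask, id=f"{sample.id}-{kind}",
                     provenance=f"augmented({kind})")


def augment_expand(samples: list[SegSample], seed: int = 0) -> list[SegSample]:
    """Double a dataset by the four-subset single-transform protocol.

    Samples are randomly partitioned into four subsets; each subset yields one
    extra sample per image via exactly one transform type (horizontal flip,
    vertical flip, brightness perturbation, noise injection). Flips act on
    image and mask jointly; photometric transforms leave the mask untouched.
    When the input size is not divisible by 4, subset sizes differ by at most
    one (the remainder spills over the first subsets in shuffled order).
    """
    if not samples:
        raise ValueError("augment_expand: empty input")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    groups = np.array_split(order, 4)
    out = list(samples)
    for kind, idxs in zip(AUGMENTATIONS, groups):
        for i in idxs:
            out.append(_apply_augmentation(samples[int(i)], kind, rng))
    return out


def split_dataset(samples: list[SegSample], ratio: float = 0.7,
                  seed: int = 0) -> tuple[list[SegSample], list[SegSample]]:
    """Seeded shuffle split; the training side receives ceil(ratio * n)."""
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = int(np.ceil(ratio * len(samples)))
    train = [samples[int(i)] for i in order[:n_train]]
    test = [samples[int(i)] for i in order[n_train:]]
    return train, test


# ---------------------------------------------------------------------------
# disk I/O: PNG/JPEG images, {0,255} single-channel PNG masks, CSV manifest


def save_mask_png(mask: np.ndarray, path) -> None:
    Image.fromarray((np.asarray(mask, dtype=np.uint8) * 255)).save(path)


def load_mask_png(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr > 127).astype(np.uint8)


def load_pairs(image_dir, mask_dir, resolution: int | None = None,
               strict: bool = False) -> tuple[list[SegSample], list[str]]:
    """Match images to masks by filename stem.

    Images are resized bilinearly and masks by nearest neighbour when
    ``resolution`` is given. Returns (samples, orphans); orphan stems are
    logged, and raise instead when ``strict`` is true.
    """
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    if not image_dir.is_dir() or not mask_dir.is_dir():
        raise FileNotFoundError("image or mask directory does not exist")
    masks = {p.stem: p for p in sorted(mask_dir.iterdir())
             if p.suffix.lower() == ".png"}
    samples: list[SegSample] = []
    orphans: list[str] = []
    images = [p for p in sorted(image_dir.iterdir())
              if p.suffix.lower() in (".png", ".jpg", ".jpeg")]
    if not images:
        logger.warning("no images found in %s", image_dir)
    for img_path in images:
        mask_path = masks.get(img_path.stem)
        if mask_path is None:
            orphans.append(img_path.stem)
            continue
        img = Image.open(img_path).convert("RGB")
        msk = Image.open(mask_path).convert("L")
        if resolution is not None:
            img = img.resize((resolution, resolution), Image.BILINEAR)
            msk = msk.resize((resolution, resolution), Image.NEAREST)
        samples.append(
            SegSample(
                image=np.asarray(img),
                mask=(np.asarray(msk) > 127).astype(np.uint8),
                id=img_path.stem,
            )
        )
    if orphans:
        msg = f"{len(orphans)} image(s) without matching mask: {orphans[:5]}"
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    return samples, orphans


def write_dataset(samples: list[SegSample], out_dir,
                  split_of: dict[str, str] | None = None) -> Path:
    """Write images, masks and a CSV manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "image", "mask", "split", "provenance"])
        for s in samples:
            img_rel = f"images/{s.id}.png"
            msk_rel = f"masks/{s.id}.png"
            Image.fromarray(s.image).save(out_dir / img_rel)
            save_mask_png(s.mask, out_dir / msk_rel)
            writer.writerow(
                [s.id, img_rel, msk_rel,
                 (split_of or {}).get(s.id, ""), s.provenance]
            )
    return manifest
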