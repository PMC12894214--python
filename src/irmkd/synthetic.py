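"""Seed-deterministic synthetic leaf images for desk-scale distillation runs.

Real plant-disease corpora are large and external; this module generates
small labelled datasets that keep the properties the distillation pipeline
actually depends on: an RGB image containing a leaf-shaped foreground, a
clean (uniform) or cluttered (textured) background, and a class signal
carried by lesion spots whose colour/size/count differ per class.  Every
image is a pure function of the spec (including its seed), so fixtures are
reproducible bit-for-bit across runs and machines.

Rendering conventions: images are channel-first float arrays in [0, 1];
the leaf is an axis-aligned ellipse covering roughly 60% of the frame;
lesions are anti-aliased filled circles placed uniformly inside the leaf;
"cluttered" backgrounds are multi-octave value noise, "clean" backgrounds
are a constant grey with small Gaussian noise.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "ValidationError",
    "SyntheticLeafSpec",
    "LabeledImageBatch",
    "AugmentationPlan",
    "HorizontalFlip",
    "VerticalFlip",
    "RandomCrop",
    "Rotation",
    "Shift",
    "default_lesion_params",
    "generate_dataset",
    "augment",
    "write_dataset",
    "read_image_folder",
]


class ValidationError(ValueError):
    """A spec/plan/batch field violates its contract; the message names it."""


# distinct, saturated lesion colours — classes built from this palette are
# pairwise separable by colour alone
_PALETTE: tuple[tuple[float, float, float], ...] = (
    (0.80, 0.12, 0.10),  # rust red
    (0.92, 0.85, 0.15),  # chlorotic yellow
    (0.55, 0.15, 0.60),  # purple blotch
    (0.95, 0.95, 0.90),  # powdery white
    (0.45, 0.25, 0.10),  # necrotic brown
    (0.15, 0.35, 0.85),  # (non-biological) blue control
)


def default_lesion_params(n_classes: int, image_size: int) -> list[tuple]:
    """Per-class (spot_count_range, spot_radius_range_px, spot_color) defaults.

    Colours cycle through a fixed palette; count and radius ranges are
    staggered so classes sharing a colour (n_classes > palette size) still
    differ geometrically.
    """
    lo = max(2.0, 0.04 * image_size)
    hi = max(lo + 1.0, 0.09 * image_size)
    params = []
    for k in range(n_classes):
        shift = k // len(_PALETTE)
        count_range = (3 + 2 * shift, 6 + 2 * shift)
        params.append((count_range, (lo, hi), _PALETTE[k % len(_PALETTE)]))
    return params


@dataclass(frozen=True)
class SyntheticLeafSpec:
    """Parameters of the synthetic leaf-image dataset generator."""

    n_classes: int = 4
    images_per_class: int = 30
    image_size: int = 128
    background: str = "clean"
    lesion_params_per_class: list[tuple] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValidationError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.images_per_class < 1:
            raise ValidationError(f"images_per_class must be >= 1, got {self.images_per_class}")
        if self.image_size < 32:
            raise ValidationError(f"image_size must be >= 32, got {self.image_size}")
        if self.background not in ("clean", "cluttered"):
            raise ValidationError(
                f"background must be 'clean' or 'cluttered', got {self.background!r}"
            )
        if self.lesion_params_per_class is not None:
            lp = list(self.lesion_params_per_class)
            if len(lp) != self.n_classes:
                raise ValidationError(
                    "lesion_params_per_class must have exactly n_classes="
                    f"{self.n_classes} entries, got {len(lp)}"
                )
            canon = [(tuple(c), tuple(r), tuple(col)) for (c, r, col) in lp]
            if len(set(canon)) != len(canon):
                raise ValidationError(
                    "lesion_params_per_class entries must be pairwise distinct "
                    "(classes would be indistinguishable)"
                )

    @property
    def lesion_params(self) -> list[tuple]:
        if self.lesion_params_per_class is not None:
            return list(self.lesion_params_per_class)
        return default_lesion_params(self.n_classes, self.image_size)


@dataclass
class LabeledImageBatch:
    """A batch of channel-first RGB images in [0, 1] with integer labels."""

    images: np.ndarray  # (n, 3, S, S)
    labels: np.ndarray  # (n,)

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.images.ndim != 4 or self.images.shape[1] != 3:
            raise ValidationError(f"images must have shape (n, 3, S, S), got {self.images.shape}")
        if self.labels.shape != (self.images.shape[0],):
            raise ValidationError(
                f"labels length {self.labels.shape} does not match batch size "
                f"{self.images.shape[0]}"
            )
        if self.images.size and (self.images.min() < 0 or self.images.max() > 1):
            raise ValidationError("images must have pixel values within [0, 1]")

    @property
    def n(self) -> int:
        return self.images.shape[0]

    @property
    def image_size(self) -> int:
        return self.images.shape[-1]


# --------------------------------------------------------------------------
# rendering


def _value_noise(rng: np.random.Generator, size: int) -> np.ndarray:
    """Multi-octave value noise in [0, 1] (Perlin-like cluttered texture)."""
    acc = np.zeros((size, size))
    amp_total = 0.0
    for octave in range(4):
        cells = min(size, 4 * 2**octave)
        amp = 1.0 / 2**octave
        coarse = rng.random((cells, cells))
        acc += amp * ndimage.zoom(coarse, size / cells, order=1, grid_mode=True, mode="nearest")
        amp_total += amp
    acc /= amp_total
    return np.clip(acc, 0.0, 1.0)


def _render_background(rng: np.random.Generator, size: int, mode: str) -> np.ndarray:
    if mode == "clean":
        base = 0.72 + 0.06 * (rng.random() - 0.5)
        img = np.full((3, size, size), base)
        img += rng.normal(0.0, 0.02, size=img.shape)
        return np.clip(img, 0.0, 1.0)
    # cluttered: green-brown tinted noise, per-channel weights
    tex = _value_noise(rng, size)
    tint = np.array([0.35, 0.45, 0.25]) + 0.2 * rng.random(3)
    img = tint[:, None, None] * (0.4 + 0.6 * tex[None])
    img += rng.normal(0.0, 0.02, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def _leaf_mask(rng: np.random.Generator, size: int) -> np.ndarray:
    """Soft ellipse occupying ~60% of the frame, with mild jitter."""
    yy, xx = np.mgrid[0:size, 0:size]
    cy = size / 2 + rng.uniform(-0.03, 0.03) * size
    cx = size / 2 + rng.uniform(-0.03, 0.03) * size
    ry = size * rng.uniform(0.40, 0.46)
    rx = size * rng.uniform(0.32, 0.38)
    r = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    # anti-aliased edge: 1 inside, linear falloff over ~1px
    edge = np.sqrt(np.maximum(r, 1e-12))
    falloff = np.clip((1.0 - edge) * (0.5 * (rx + ry)) + 0.5, 0.0, 1.0)
    return falloff


def _draw_spot(img: np.ndarray, mask: np.ndarray, cy, cx, radius, color) -> None:
    """Blend an anti-aliased filled circle (clipped to the leaf) into img."""
    size = img.shape[-1]
    y0, y1 = int(max(0, cy - radius - 2)), int(min(size, cy + radius + 3))
    x0, x1 = int(max(0, cx - radius - 2)), int(min(size, cx + radius + 3))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    cov = np.clip(radius + 0.5 - dist, 0.0, 1.0) * mask[y0:y1, x0:x1]
    for c in range(3):
        img[c, y0:y1, x0:x1] = (1 - cov) * img[c, y0:y1, x0:x1] + cov * color[c]


def _render_image(rng: np.random.Generator, spec: SyntheticLeafSpec, class_k: int) -> np.ndarray:
    size = spec.image_size
    img = _render_background(rng, size, spec.background)
    mask = _leaf_mask(rng, size)
    leaf_color = np.array([0.18, 0.45, 0.12]) + rng.uniform(-0.05, 0.08, size=3)
    for c in range(3):
        img[c] = (1 - mask) * img[c] + mask * np.clip(leaf_color[c], 0, 1)
    # vein-like brightness modulation keeps the leaf from being flat
    tex = rng.normal(0.0, 0.015, size=(size, size))
    img += (mask * tex)[None]

    (cnt_lo, cnt_hi), (r_lo, r_hi), color = spec.lesion_params[class_k]
    n_spots = int(rng.integers(cnt_lo, cnt_hi + 1))
    for _ in range(n_spots):
        # rejection-sample a centre inside the leaf
        for _attempt in range(50):
            cy = rng.uniform(0, size)
            cx = rng.uniform(0, size)
            if mask[int(cy), int(cx)] > 0.9:
                break
        radius = rng.uniform(r_lo, r_hi)
        _draw_spot(img, mask, cy, cx, radius, color)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(spec: SyntheticLeafSpec) -> tuple[LabeledImageBatch, list[str]]:
    """Render the full dataset for ``spec``.

    Returns the batch (``n_classes * images_per_class`` images, grouped by
    class in label order) and the class names.  Identical specs — including
    the seed — produce bit-identical arrays.
    """
    images = []
    labels = []
    for k in range(spec.n_classes):
        # one independent stream per (class, image) so per-class edits don't
        # reshuffle other classes
        for i in range(spec.images_per_class):
            rng = np.random.default_rng([spec.seed, k, i])
            images.append(_render_image(rng, spec, k))
            labels.append(k)
    batch = LabeledImageBatch(np.stack(images), np.array(labels))
    class_names = [f"class_{k}" for k in range(spec.n_classes)]
    return batch, class_names


# --------------------------------------------------------------------------
# augmentation


@dataclass(frozen=True)
class HorizontalFlip:
    """Mirror left-right with probability ``p`` per image (p=1: always)."""

    p: float = 0.5

    def __post_init__(self):
        if not 0 <= self.p <= 1:
            raise ValidationError(f"flip probability p must be in [0, 1], got {self.p}")

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.p >= 1.0 or rng.random() < self.p:
            return img[:, :, ::-1]
        return img


@dataclass(frozen=True)
class VerticalFlip:
    p: float = 0.5

    def __post_init__(self):
        if not 0 <= self.p <= 1:
            raise ValidationError(f"flip probability p must be in [0, 1], got {self.p}")

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.p >= 1.0 or rng.random() < self.p:
            return img[:, ::-1, :]
        return img


@dataclass(frozen=True)
class RandomCrop:
    """Crop a random ``fraction``-sized window and resize back to full size."""

    fraction: float = 0.8

    def __post_init__(self):
        if not 0 < self.fraction <= 1:
            raise ValidationError(f"crop fraction must be in (0, 1], got {self.fraction}")

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        size = img.shape[-1]
        crop = max(1, int(round(self.fraction * size)))
        if crop >= size:
            return img
        y0 = int(rng.integers(0, size - crop + 1))
        x0 = int(rng.integers(0, size - crop + 1))
        window = img[:, y0 : y0 + crop, x0 : x0 + crop]
        out = ndimage.zoom(window, (1, size / crop, size / crop), order=1, mode="nearest", grid_mode=True)
        return np.clip(out[:, :size, :size], 0.0, 1.0)


@dataclass(frozen=True)
class Rotation:
    """Rotate by a uniform angle in [-max_degrees, +max_degrees]."""

    max_degrees: float = 15.0

    def __post_init__(self):
        if not 0 <= self.max_degrees <= 180:
            raise ValidationError(f"max_degrees must be in [0, 180], got {self.max_degrees}")

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.max_degrees == 0:
            return img
        angle = rng.uniform(-self.max_degrees, self.max_degrees)
        out = ndimage.rotate(img, angle, axes=(1, 2), reshape=False, order=1, mode="nearest")
        return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class Shift:
    """Translate by a uniform offset up to ``max_fraction`` of the image size."""

    max_fraction: float = 0.1

    def __post_init__(self):
        if not 0 <= self.max_fraction <= 0.5:
            raise ValidationError(f"max_fraction must be in [0, 0.5], got {self.max_fraction}")

    def apply(self, img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.max_fraction == 0:
            return img
        size = img.shape[-1]
        dy, dx = rng.uniform(-self.max_fraction, self.max_fraction, size=2) * size
        out = ndimage.shift(img, (0, dy, dx), order=1, mode="nearest")
        return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class AugmentationPlan:
    """Ordered augmentation ops applied per image, seeded for determinism."""

    ops: tuple = ()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "ops", tuple(self.ops))

    def with_seed(self, seed: int) -> "AugmentationPlan":
        return replace(self, seed=seed)


def augment(batch: LabeledImageBatch, plan: AugmentationPlan) -> LabeledImageBatch:
    """Apply the plan's ops in order to every image; labels pass through.

    A pure function of (batch, plan): each image gets its own RNG stream
    derived from ``plan.seed`` and its index.
    """
    out = np.empty_like(batch.images)
    for i in range(batch.n):
        rng = np.random.default_rng([plan.seed, i])
        img = batch.images[i]
        for op in plan.ops:
            img = op.apply(img, rng)
        out[i] = np.clip(img, 0.0, 1.0)
    return LabeledImageBatch(out, batch.labels.copy())


# --------------------------------------------------------------------------
# disk IO (class-per-subfolder layout)


def write_dataset(batch: LabeledImageBatch, class_names: list[str], out_dir) -> Path:
    """Write ``out_dir/<class>/img_<i>.png`` plus a ``manifest.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    counters = {k: 0 for k in range(len(class_names))}
    for i in range(batch.n):
        k = int(batch.labels[i])
        cls_dir = out_dir / class_names[k]
        cls_dir.mkdir(exist_ok=True)
        fname = cls_dir / f"img_{counters[k]:04d}.png"
        counters[k] += 1
        arr = np.round(batch.images[i] * 255).astype(np.uint8).transpose(1, 2, 0)
        Image.fromarray(arr).save(fname)
        rows.append((str(fname.relative_to(out_dir)), k))
    with open(out_dir / "manifest.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["filename", "label"])
        w.writerows(rows)
    return out_dir


def read_image_folder(data_dir, image_size: int | None = None) -> tuple[LabeledImageBatch, list[str]]:
    """Load any class-per-subfolder directory of PNG/JPEG images.

    Class labels are assigned by sorted subfolder name.  If ``image_size``
    is given, images are resized (bilinear) to that square size.
    """
    data_dir = Path(data_dir)
    if not data_dir.is_dir():
        raise IOError(f"data directory not found: {data_dir}")
    class_dirs = sorted(d for d in data_dir.iterdir() if d.is_dir())
    if not class_dirs:
        raise IOError(f"no class subfolders in {data_dir}")
    images, labels, names = [], [], []
    for k, cdir in enumerate(class_dirs):
        names.append(cdir.name)
        files = sorted(p for p in cdir.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
        for p in files:
            im = Image.open(p).convert("RGB")
            if image_size is not None and im.size != (image_size, image_size):
                im = im.resize((image_size, image_size), Image.BILINEAR)
            images.append(np.asarray(im, dtype=np.float64).transpose(2, 0, 1) / 255.0)
            labels.append(k)
    if not images:
        raise IOError(f"no images found under {data_dir}")
    return LabeledImageBatch(np.stack(images), np.array(labels)), names
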