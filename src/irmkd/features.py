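"""Tap capture and canonicalization of heterogeneous feature maps.

Cross-layer and cross-model Euclidean distances are only well defined once
every feature map lives in a common space.  A teacher block may emit a
64x8x8 map where the student emits 8x4x4, so each raw C x H x W map is
reduced to a fixed-length unit vector:

1. aggregate over channels (mean of raw activations by default; absolute
   or squared means are available as config options),
2. bilinearly resize the resulting H x W spatial map to a common
   ``canonical_size`` grid S_c x S_c,
3. flatten and divide by the Euclidean norm (an all-zero map stays zero).

All three steps are linear or smooth, so gradients flow through them to
the student's parameters.  Distances between canonical vectors are then
bounded by 2 (unit sphere diameter), which keeps the relational losses on
a comparable scale regardless of architecture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, as_tensor, stack
from .nn import ToyCNN

__all__ = ["FeatureTapSet", "capture_taps", "canonicalize", "build_tap_set", "bilinear_matrix"]

_AGGS = ("mean", "abs_mean", "sq_mean")

_resize_cache: dict[tuple[int, int, int], np.ndarray] = {}


def bilinear_matrix(h: int, w: int, s_c: int) -> np.ndarray:
    """Dense (h*w, s_c*s_c) matrix implementing bilinear resize to s_c x s_c.

    Uses the half-pixel-centre convention: output pixel j samples source
    coordinate (j + 0.5) * (size / s_c) - 0.5, clipped to the frame.
    Expressing the resize as a constant matrix makes it differentiable for
    free (it is a matmul) and exactly the identity when the sizes match.
    """
    key = (h, w, s_c)
    if key in _resize_cache:
        return _resize_cache[key]

    def axis_weights(src: int, dst: int) -> np.ndarray:
        wts = np.zeros((src, dst))
        pos = (np.arange(dst) + 0.5) * (src / dst) - 0.5
        pos = np.clip(pos, 0, src - 1)
        lo = np.floor(pos).astype(int)
        hi = np.minimum(lo + 1, src - 1)
        frac = pos - lo
        for j in range(dst):
            wts[lo[j], j] += 1 - frac[j]
            wts[hi[j], j] += frac[j]
        return wts

    wy = axis_weights(h, s_c)  # (h, s_c)
    wx = axis_weights(w, s_c)  # (w, s_c)
    mat = np.einsum("ys,xt->yxst", wy, wx).reshape(h * w, s_c * s_c)
    _resize_cache[key] = mat
    return mat


def canonicalize(raw_map, canonical_size: int, channel_agg: str = "mean") -> Tensor:
    """Reduce raw maps ``(n, C, H, W)`` (or one ``(C, H, W)`` map) to unit vectors.

    Returns a tensor of shape ``(n, canonical_size**2)`` (or a single
    vector).  The Euclidean norm of every row is 1, except for all-zero
    maps which stay exactly zero.
    """
    if channel_agg not in _AGGS:
        raise ValueError(f"channel_agg must be one of {_AGGS}, got {channel_agg!r}")
    x = as_tensor(raw_map)
    single = x.ndim == 3
    if single:
        x = x.reshape(1, *x.shape)
    if x.ndim != 4:
        raise ValueError(f"expected a (n, C, H, W) feature map, got shape {x.shape}")
    if not np.all(np.isfinite(x.data)):
        raise FloatingPointError("feature map contains non-finite values")
    n, c, h, w = x.shape
    if channel_agg == "abs_mean":
        x = x.relu() + (-x).relu()  # |x| with a well-defined gradient at 0
    elif channel_agg == "sq_mean":
        x = x**2
    spatial = x.mean(axis=1)  # (n, h, w)
    flat = spatial.reshape(n, h * w)
    resized = flat @ bilinear_matrix(h, w, canonical_size)  # (n, S_c^2)
    norm_sq = (resized**2).sum(axis=1, keepdims=True)
    # zero maps keep a zero vector; sqrt gradient guarded away from 0
    norm = (norm_sq + 1e-24) ** 0.5
    out = resized / norm
    return out.reshape(-1) if single else out


@dataclass
class FeatureTapSet:
    """Canonical unit vectors for every (sample, tap) pair in a batch.

    ``vectors`` is an ``(n, m, d)`` tensor with ``d = canonical_size**2``;
    rows are unit vectors (or exactly zero for dead maps).
    """

    vectors: Tensor
    tap_names: tuple[str, ...]
    canonical_size: int

    def __post_init__(self):
        if self.vectors.ndim != 3:
            raise ValueError(f"vectors must be (n, m, d), got shape {self.vectors.shape}")
        if self.vectors.shape[1] != len(self.tap_names):
            raise ValueError(
                f"{len(self.tap_names)} tap names but {self.vectors.shape[1]} vector layers"
            )
        if not np.all(np.isfinite(self.vectors.data)):
            raise FloatingPointError("tap vectors contain non-finite values")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    @property
    def m(self) -> int:
        return self.vectors.shape[1]

    @property
    def d(self) -> int:
        return self.vectors.shape[2]

    def layer(self, index: int) -> Tensor:
        """The (n, d) canonical vectors of one tap layer."""
        if not 0 <= index < self.m:
            raise IndexError(f"layer index {index} out of range for m={self.m}")
        n, m, d = self.vectors.shape
        sel = np.zeros((m, 1))
        sel[index, 0] = 1.0
        # differentiable single-layer selection via matmul with a unit column
        picked = self.vectors.transpose((0, 2, 1)) @ sel  # (n, d, 1)
        return picked.reshape(n, d)


def capture_taps(model: ToyCNN, images) -> tuple[Tensor, dict[str, Tensor]]:
    """Forward the batch and return (logits, raw tap maps) for the model's taps.

    The pass is differentiable; run the model in ``eval()`` mode first if
    batch statistics must not update (the engine does this for teachers).
    No parameters are mutated.
    """
    images = np.asarray(images, dtype=np.float64)
    logits, blocks = model.forward(images)
    taps = {name: blocks[name] for name in model.tap_spec.tap_names}
    return logits, taps


def build_tap_set(
    model: ToyCNN,
    images,
    canonical_size: int | None = None,
    channel_agg: str = "mean",
) -> tuple[FeatureTapSet, Tensor]:
    """Capture and canonicalize all taps of a model in one differentiable pass.

    ``canonical_size`` defaults to the smallest tap spatial size, avoiding
    upsampling artefacts dominating the distances.
    """
    logits, taps = capture_taps(model, images)
    maps = [taps[name] for name in model.tap_spec.tap_names]
    if canonical_size is None:
        canonical_size = min(mp.shape[-1] for mp in maps)
    vecs = [canonicalize(mp, canonical_size, channel_agg) for mp in maps]
    tap_set = FeatureTapSet(
        vectors=stack(vecs, axis=1),
        tap_names=tuple(model.tap_spec.tap_names),
        canonical_size=canonical_size,
    )
    return tap_set, logits
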