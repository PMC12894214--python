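"""Small CNN classifiers with named tap layers, built on the autograd engine.

The distillation method needs two things from its networks that ordinary
classifier wrappers do not expose: (a) the post-activation feature map of
every selected intermediate ("tap") layer, returned alongside the logits in
one differentiable forward pass, and (b) exact parameter accounting for the
compression comparison between teacher and student.

The architecture is deliberately simple and fixed in shape: a stack of
conv(3x3, stride 2) -> batch-norm -> ReLU blocks, global average pooling,
and a linear head.  Tap names are ``block1 .. blockN`` and refer to the
post-ReLU block outputs.  Teacher/student pairs may have arbitrarily
different channel widths and spatial sizes per tap; reconciling those
shapes is the features module's job.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autograd import Tensor

__all__ = [
    "ConfigurationError",
    "TapSpec",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ToyCNN",
    "build_toy_cnn",
    "parameter_count",
    "size_bytes",
    "SGD",
    "save_checkpoint",
    "load_checkpoint",
    "parameter_checksum",
]


class ConfigurationError(ValueError):
    """Invalid model/tap configuration."""


@dataclass(frozen=True)
class TapSpec:
    """Ordered list of tap-layer names; the relation matrix needs m >= 2."""

    tap_names: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "tap_names", tuple(self.tap_names))
        if len(self.tap_names) < 2:
            raise ConfigurationError(
                "TapSpec needs at least 2 tap layers (the instance relation "
                f"matrix is built from layer pairs); got {list(self.tap_names)}"
            )
        if len(set(self.tap_names)) != len(self.tap_names):
            raise ConfigurationError(f"duplicate tap names: {list(self.tap_names)}")

    @property
    def m(self) -> int:
        return len(self.tap_names)


class Conv2d:
    """3x3 convolution, stride 2, zero padding 1, with bias.

    Implemented as an im2col gather followed by a matrix product so the
    gradient comes for free from the autograd primitives.
    """

    KERNEL = 3
    STRIDE = 2
    PAD = 1

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels * self.KERNEL * self.KERNEL
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, in_channels, 3, 3))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self._idx_cache: dict[tuple[int, int], np.ndarray] = {}

    def parameters(self):
        return [self.weight, self.bias]

    def _col_indices(self, h: int, w: int) -> np.ndarray:
        key = (h, w)
        if key not in self._idx_cache:
            hp, wp = h + 2 * self.PAD, w + 2 * self.PAD
            oh = (hp - self.KERNEL) // self.STRIDE + 1
            ow = (wp - self.KERNEL) // self.STRIDE + 1
            c = self.in_channels
            # flat index into (C, Hp, Wp) for every (output position, patch element)
            ci, ki, kj = np.meshgrid(
                np.arange(c), np.arange(self.KERNEL), np.arange(self.KERNEL), indexing="ij"
            )
            patch = (ci * hp * wp + ki * wp + kj).reshape(-1)  # (C*9,)
            oi, oj = np.meshgrid(np.arange(oh), np.arange(ow), indexing="ij")
            origin = (oi * self.STRIDE * wp + oj * self.STRIDE).reshape(-1)  # (OH*OW,)
            self._idx_cache[key] = origin[:, None] + patch[None, :]
        return self._idx_cache[key]

    def out_spatial(self, h: int, w: int) -> tuple[int, int]:
        hp, wp = h + 2 * self.PAD, w + 2 * self.PAD
        return (hp - 3) // 2 + 1, (wp - 3) // 2 + 1

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ConfigurationError(f"expected {self.in_channels} input channels, got {c}")
        oh, ow = self.out_spatial(h, w)
        idx = self._col_indices(h, w)
        xp = x.pad2d(self.PAD).reshape(n, -1)
        cols = xp.take_cols(idx)  # (n, OH*OW, C*9)
        w2 = self.weight.reshape(self.out_channels, -1).transpose((1, 0))  # (C*9, O)
        out = cols @ w2 + self.bias  # bias broadcasts over (n, OH*OW, O)
        return out.reshape(n, oh, ow, self.out_channels).transpose((0, 3, 1, 2))


class BatchNorm2d:
    """Per-channel batch normalisation with running statistics for eval mode."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.training = True

    def parameters(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (var.data.reshape(-1) - self.running_var)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        g = self.gamma.reshape(1, self.channels, 1, 1)
        b = self.beta.reshape(1, self.channels, 1, 1)
        return xhat * g + b


class Linear:
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.in_features = in_features
        self.out_features = out_features
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def parameters(self):
        return [self.weight, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class ToyCNN:
    """Stack of stride-2 conv blocks with named taps and a linear head.

    Parameters
    ----------
    widths
        Output channel count of each conv block; ``len(widths)`` blocks.
    n_classes
        Width of the logit layer.
    tap_names
        Which block outputs to expose as taps; defaults to all blocks.
    seed
        Seed for deterministic parameter initialisation.
    """

    def __init__(
        self,
        widths: list[int],
        n_classes: int,
        tap_names: list[str] | None = None,
        seed: int = 0,
    ):
        if not widths:
            raise ConfigurationError("widths must be a non-empty list of channel counts")
        if n_classes < 2:
            raise ConfigurationError("n_classes must be >= 2")
        self.widths = [int(w) for w in widths]
        self.n_classes = int(n_classes)
        self.seed = int(seed)
        self.block_names = [f"block{i + 1}" for i in range(len(widths))]
        names = list(tap_names) if tap_names is not None else list(self.block_names)
        unknown = [t for t in names if t not in self.block_names]
        if unknown:
            raise ConfigurationError(
                f"unknown tap name(s) {unknown}; available: {self.block_names}"
            )
        self.tap_spec = TapSpec(tuple(names))

        rng = np.random.default_rng(seed)
        self.convs: list[Conv2d] = []
        self.bns: list[BatchNorm2d] = []
        c_in = 3
        for w in self.widths:
            self.convs.append(Conv2d(c_in, w, rng))
            self.bns.append(BatchNorm2d(w))
            c_in = w
        self.head = Linear(self.widths[-1], n_classes, rng)

    # -- mode and parameter plumbing --------------------------------------

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        for conv, bn in zip(self.convs, self.bns):
            ps += conv.parameters() + bn.parameters()
        ps += self.head.parameters()
        return ps

    def named_parameters(self) -> dict[str, Tensor]:
        out = {}
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns), start=1):
            out[f"block{i}.conv.weight"] = conv.weight
            out[f"block{i}.conv.bias"] = conv.bias
            out[f"block{i}.bn.gamma"] = bn.gamma
            out[f"block{i}.bn.beta"] = bn.beta
        out["head.weight"] = self.head.weight
        out["head.bias"] = self.head.bias
        return out

    def train(self) -> "ToyCNN":
        for bn in self.bns:
            bn.training = True
        return self

    def eval(self) -> "ToyCNN":
        for bn in self.bns:
            bn.training = False
        return self

    @property
    def training(self) -> bool:
        return self.bns[0].training

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- forward -----------------------------------------------------------

    def forward(self, x, n_blocks: int | None = None) -> tuple[Tensor, dict[str, Tensor]]:
        """Run the network; return logits and all block outputs (post-ReLU).

        ``n_blocks`` truncates the network after that many blocks (used as
        the tap-correctness oracle in the tests); logits are then not
        meaningful and are returned as the pooled features' head output only
        for the full network.
        """
        from .autograd import as_tensor

        h = as_tensor(x)
        if h.ndim != 4 or h.shape[1] != 3:
            raise ValueError(f"expected input of shape (n, 3, S, S); got {h.shape}")
        taps: dict[str, Tensor] = {}
        upto = len(self.convs) if n_blocks is None else n_blocks
        for i, (conv, bn) in enumerate(zip(self.convs, self.bns), start=1):
            if i > upto:
                break
            h = bn(conv(h)).relu()
            taps[f"block{i}"] = h
        if upto < len(self.convs):
            return None, taps  # truncated run: the head does not apply
        pooled = h.mean(axis=(2, 3))
        logits = self.head(pooled)
        return logits, taps

    def __call__(self, x):
        return self.forward(x)

    def predict(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Argmax class predictions in eval mode; ties break to the lowest index."""
        was_training = self.training
        self.eval()
        preds = []
        for i in range(0, len(images), batch_size):
            logits, _ = self.forward(images[i : i + batch_size])
            preds.append(np.argmax(logits.data, axis=1))
        if was_training:
            self.train()
        return np.concatenate(preds) if preds else np.zeros(0, dtype=int)

    @property
    def descriptor(self) -> dict:
        return {
            "widths": self.widths,
            "n_classes": self.n_classes,
            "tap_names": list(self.tap_spec.tap_names),
            "seed": self.seed,
        }


def build_toy_cnn(
    widths: list[int],
    n_classes: int,
    tap_names: list[str] | None = None,
    seed: int = 0,
) -> ToyCNN:
    """Build a toy conv classifier; see :class:`ToyCNN`."""
    return ToyCNN(widths, n_classes, tap_names=tap_names, seed=seed)


def parameter_count(model: ToyCNN) -> int:
    """Exact number of trainable scalars in the model."""
    return int(sum(p.data.size for p in model.parameters()))


def size_bytes(model: ToyCNN) -> int:
    """Model size in bytes at 4 bytes (float32) per parameter."""
    return 4 * parameter_count(model)


def parameter_checksum(model: ToyCNN) -> int:
    """Order-sensitive hash of all parameter values (frozen-teacher check)."""
    h = 0
    for name, p in sorted(model.named_parameters().items()):
        h = hash((h, name, p.data.tobytes()))
    return h


class SGD:
    """SGD with momentum and L2 weight decay (applied to all parameters)."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.0, weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError(f"lr must be > 0, got {lr}")
        if not (0 <= momentum < 1):
            raise ValueError(f"momentum must be in [0, 1), got {momentum}")
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


# -- checkpoints -----------------------------------------------------------


def save_checkpoint(model: ToyCNN, path) -> None:
    """Write a self-describing checkpoint (architecture + parameters + BN stats)."""
    arrays = {f"param.{k}": v.data for k, v in model.named_parameters().items()}
    for i, bn in enumerate(model.bns, start=1):
        arrays[f"stat.block{i}.bn.running_mean"] = bn.running_mean
        arrays[f"stat.block{i}.bn.running_var"] = bn.running_var
    meta = json.dumps(model.descriptor)
    with open(path, "wb") as f:  # keep the exact filename (np.savez appends .npz)
        np.savez(f, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> ToyCNN:
    """Rebuild a :class:`ToyCNN` from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        model = ToyCNN(
            meta["widths"], meta["n_classes"], tap_names=meta["tap_names"], seed=meta["seed"]
        )
        for k, p in model.named_parameters().items():
            p.data = z[f"param.{k}"].copy()
        for i, bn in enumerate(model.bns, start=1):
            bn.running_mean = z[f"stat.block{i}.bn.running_mean"].copy()
            bn.running_var = z[f"stat.block{i}.bn.running_var"].copy()
    return model
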