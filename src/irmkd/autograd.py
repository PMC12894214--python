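"""Minimal reverse-mode automatic differentiation over numpy arrays.

The relational distillation losses are functions of intermediate feature
maps, so the student must be trained by backpropagation through channel
aggregation, bilinear resizing, L2 normalisation and pairwise Euclidean
distances — not just through a classifier head.  This module provides the
small differentiable-tensor engine the rest of the package is built on:
a :class:`Tensor` wrapping a float64 ndarray, a closed set of primitive
operations with hand-written vector-Jacobian products, and topological-sort
backpropagation.

Only the primitives the package actually needs are implemented (broadcasted
arithmetic, matmul with a 2-D right operand, exp/log/power, axis reductions,
reshape/transpose/stack, gather on columns, zero-padding, ReLU, and a
square root with a guarded gradient at zero).  Everything is double
precision: the toy networks are small enough that speed is not a concern
and the finite-difference gradient checks in the test-suite want the
headroom.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, inverting numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # collapse extra leading axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # collapse axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward recipe."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    # -- basic protocol ----------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- graph construction helpers ---------------------------------------

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        requires = any(p.requires_grad for p in parents)
        if not requires:
            return Tensor(data)
        return Tensor(data, requires_grad=True, parents=parents, backward=backward)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = as_tensor(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.shape))

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other) -> "Tensor":
        return as_tensor(other) / self

    def __pow__(self, p: float) -> "Tensor":
        p = float(p)

        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g * p * a.data ** (p - 1.0))

        return Tensor._make(self.data**p, (self,), backward)

    def __matmul__(self, other) -> "Tensor":
        """Matrix product; the right operand must be 2-D."""
        other = as_tensor(other)
        if other.ndim != 2:
            raise ValueError("matmul: right operand must be 2-D")

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                k = b.shape[0]
                b._accumulate(a.data.reshape(-1, k).T @ g.reshape(-1, b.shape[1]))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- elementwise non-linearities ---------------------------------------

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def backward(g, a=self, od=out_data):
            if a.requires_grad:
                a._accumulate(g * od)

        return Tensor._make(out_data, (self,), backward)

    def log(self) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt_safe(self, eps: float = 1e-12) -> "Tensor":
        """Exact ``sqrt`` forward with a gradient bounded near zero.

        The pairwise-distance tensors have an exactly-zero diagonal;
        d sqrt(x)/dx diverges there, so the backward pass uses
        ``0.5 / sqrt(x + eps)`` to keep gradients finite while the
        forward value stays exact.
        """

        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g * 0.5 / np.sqrt(a.data + eps))

        return Tensor._make(np.sqrt(self.data), (self,), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accumulate(g * m)

        return Tensor._make(self.data * mask, (self,), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            if ax is None:
                a._accumulate(np.full(a.shape, g))
            else:
                gg = g if kd else np.expand_dims(g, ax)
                a._accumulate(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max_const(self, axis=None, keepdims: bool = False) -> "Tensor":
        """Axis maximum treated as a constant (no gradient flows through it).

        Used for the standard max-subtraction stabilisation of softmax,
        where the subtracted constant cancels analytically.
        """
        return Tensor(self.data.max(axis=axis, keepdims=keepdims))

    # -- shape manipulation ------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g.reshape(a.shape))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, axes: Sequence[int]) -> "Tensor":
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))

        def backward(g, a=self, iv=inv):
            if a.requires_grad:
                a._accumulate(g.transpose(iv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def pad2d(self, pad: int) -> "Tensor":
        """Zero-pad the trailing two axes by ``pad`` on each side."""
        if pad == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]

        def backward(g, a=self, p=pad):
            if a.requires_grad:
                sl = (Ellipsis, slice(p, -p), slice(p, -p))
                a._accumulate(g[sl])

        return Tensor._make(np.pad(self.data, width), (self,), backward)

    def take_cols(self, idx: np.ndarray) -> "Tensor":
        """Gather ``self[:, idx]`` for a 2-D tensor and integer index array.

        ``idx`` may have any shape; the result has shape ``(n,) + idx.shape``.
        The backward pass scatter-adds, so repeated indices (overlapping
        convolution windows) accumulate correctly.
        """
        if self.ndim != 2:
            raise ValueError("take_cols expects a 2-D tensor")
        n = self.shape[0]

        def backward(g, a=self, ix=idx):
            if a.requires_grad:
                ga = np.zeros(a.shape)
                np.add.at(ga, (np.arange(n).reshape((n,) + (1,) * ix.ndim), ix[None]), g)
                a._accumulate(ga)

        return Tensor._make(self.data[:, idx], (self,), backward)

    # -- backpropagation ---------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from a scalar output."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_: list[tuple[Tensor, bool]] = [(self, False)]
        while stack_:
            node, processed = stack_.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack_.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack_.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free intermediate gradients/graph references eagerly
            if node._parents:
                node._backward = None


def as_tensor(x) -> Tensor:
    """Wrap an array-like as a constant :class:`Tensor` (no-op on tensors)."""
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def stack(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    """Stack tensors along a new axis, differentiably."""
    tensors = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g, ts=tensors, ax=axis):
        for i, t in enumerate(ts):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=ax))

    return Tensor._make(data, tuple(tensors), backward)
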