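"""Minimal reverse-mode autodiff over NumPy arrays.

Just enough machinery to express and train the volumetric segmentation
networks in this package: broadcast-aware elementwise arithmetic,
reductions, a few activation primitives, and (in :mod:`lka3d.nn.conv`)
im2col-based 3D convolutions.  Everything is float32.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "Parameter", "as_tensor", "no_grad", "grad_enabled"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def grad_enabled() -> bool:
    return _grad_enabled


def _attach(out: "Tensor", back) -> None:
    if _grad_enabled:
        out._backward = back


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reversing NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: Iterable["Tensor"] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = _backward if _grad_enabled else None
        self._prev = tuple(_prev) if _grad_enabled else ()

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node.grad = None if node is not self and not node.requires_grad else node.grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise ops --------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def back(g):
            self.accumulate(_unbroadcast(g, self.data.shape))
            other.accumulate(_unbroadcast(g, other.data.shape))

        _attach(out, back)
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def back(g):
            self.accumulate(_unbroadcast(g * other.data, self.data.shape))
            other.accumulate(_unbroadcast(g * self.data, other.data.shape))

        _attach(out, back)
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def back(g):
            self.accumulate(_unbroadcast(g / other.data, self.data.shape))
            other.accumulate(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        _attach(out, back)
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))

        def back(g):
            self.accumulate(g * p * self.data ** (p - 1))

        _attach(out, back)
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, _prev=(self,))

        def back(g):
            self.accumulate(g * y)

        _attach(out, back)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def back(g):
            self.accumulate(g / self.data)

        _attach(out, back)
        return out

    # -- reductions / shaping ---------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def back(g):
            if axis is None:
                self.accumulate(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.accumulate(np.broadcast_to(gg, self.data.shape).copy())

        _attach(out, back)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def narrow(self, axis: int, start: int, length: int):
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)
        out = Tensor(self.data[idx], _prev=(self,))

        def back(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self.accumulate(full)

        _attach(out, back)
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def back(g):
            self.accumulate(g.reshape(self.data.shape))

        _attach(out, back)
        return out

    # -- activations ------------------------------------------------------

    def leaky_relu(self, slope: float = 0.01):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), _prev=(self,))

        def back(g):
            self.accumulate(g * np.where(self.data > 0, 1.0, slope).astype(np.float32))

        _attach(out, back)
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, _prev=(self,))

        def back(g):
            self.accumulate(g * y * (1.0 - y))

        _attach(out, back)
        return out

    def softmax(self, axis: int = 1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, _prev=(self,))

        def back(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            self.accumulate(y * (g - dot))

        _attach(out, back)
        return out

    def clip(self, lo: float, hi: float):
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))

        def back(g):
            mask = ((self.data >= lo) & (self.data <= hi)).astype(np.float32)
            self.accumulate(g * mask)

        _attach(out, back)
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), _prev=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t.accumulate(g[tuple(idx)])

    _attach(out, back)
    return out
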