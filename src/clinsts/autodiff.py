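"""Minimal reverse-mode automatic differentiation over numpy arrays.

The multi-task model is small enough to run on one CPU, so instead of a
deep-learning framework the encoder and heads are built from a handful of
differentiable primitives on a :class:`Tensor` wrapper.  Gradients are
accumulated by topological-order backpropagation; correctness is pinned by
central-finite-difference checks in the test suite.

Only what the transformer encoder and the four task objectives need is
implemented: broadcasting arithmetic, (stacked) matmul, elementwise
transcendentals, reductions, reshaping, embedding lookup, basic-slice
indexing, softmax and log-sum-exp along the last axis.
"""
from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "embedding", "softmax", "logsumexp", "gelu"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str = ""):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        tag = f" {self.name!r}" if self.name else ""
        return f"Tensor{tag}(shape={self.shape}, grad={self.requires_grad})"

    # -- autodiff engine ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = _wrap(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-_wrap(other))

    def __rsub__(self, other):
        return _wrap(other) + (-self)

    def __mul__(self, other):
        other = _wrap(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * (_wrap(other) ** -1.0)

    def __rtruediv__(self, other):
        return _wrap(other) * (self ** -1.0)

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = _wrap(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accumulate(_unbroadcast(gb, other.shape))

        out._backward = bwd
        return out

    # -- transcendentals ------------------------------------------------------
    def exp(self):
        value = np.exp(self.data)
        out = Tensor(value, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g * value)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(g / self.data)
        return out

    def tanh(self):
        value = np.tanh(self.data)
        out = Tensor(value, self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g * (1.0 - value ** 2))
        return out

    # -- reductions and shape -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), self.requires_grad, (self,))
        inverse = np.argsort(axes)
        out._backward = lambda g: self.requires_grad and self._accumulate(
            g.transpose(*inverse))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], self.requires_grad, (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                full[key] = g
                self._accumulate(full)

        out._backward = bwd
        return out


def _wrap(value) -> Tensor:
    return value if isinstance(value, Tensor) else Tensor(value)


def tensor(data, requires_grad: bool = False, name: str = "") -> Tensor:
    return Tensor(data, requires_grad=requires_grad, name=name)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)
    if ids.size and (ids.min() < 0 or ids.max() >= weight.shape[0]):
        raise ValueError(
            f"token id out of range: ids in [{ids.min()}, {ids.max()}] "
            f"vs table of {weight.shape[0]} rows")
    out = Tensor(weight.data[ids], weight.requires_grad, (weight,))

    def bwd(g):
        if weight.requires_grad:
            full = np.zeros_like(weight.data)
            np.add.at(full, ids.reshape(-1), g.reshape(-1, weight.shape[1]))
            weight._accumulate(full)

    out._backward = bwd
    return out


def softmax(x: Tensor) -> Tensor:
    """Numerically stable softmax along the last axis."""
    shifted = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    value = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(value, x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            inner = (g * value).sum(axis=-1, keepdims=True)
            x._accumulate(value * (g - inner))

    out._backward = bwd
    return out


def logsumexp(x: Tensor) -> Tensor:
    """log(sum(exp(x))) along the last axis, keepdims; gradient is softmax."""
    m = x.data.max(axis=-1, keepdims=True)
    e = np.exp(x.data - m)
    s = e.sum(axis=-1, keepdims=True)
    out = Tensor(m + np.log(s), x.requires_grad, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g * (e / s))

    out._backward = bwd
    return out


_GELU_C = np.sqrt(2.0 / np.pi)


def gelu(x: Tensor) -> Tensor:
    """Gaussian error linear unit (tanh approximation), composed of primitives."""
    inner = (x + (x ** 3.0) * 0.044715) * _GELU_C
    return x * 0.5 * (inner.tanh() + 1.0)
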