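"""Minimal reverse-mode automatic differentiation over NumPy arrays.

All trainable components in this package (the directed message-passing
encoder, the graph-convolutional policy network, the value head and the
discriminator) are small dense networks interleaved with sparse graph
aggregations, so a compact tape-based autodiff layer over ``numpy`` /
``scipy.sparse`` is sufficient. Gradients are validated against central
differences in the test suite.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "tensor",
    "relu",
    "sigmoid",
    "softplus",
    "exp",
    "log",
    "tanh",
    "clip",
    "minimum",
    "concat",
    "spmm",
    "log_softmax",
    "softmax",
    "dropout",
    "xavier_uniform",
    "Adam",
    "SGD",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def bw():
                if self.requires_grad:
                    self._accum(out.grad)
                if other.requires_grad:
                    other._accum(out.grad)
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _make(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda: self._accum(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def bw():
                if self.requires_grad:
                    self._accum(out.grad * other.data)
                if other.requires_grad:
                    other._accum(out.grad * self.data)
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out.requires_grad:
            def bw():
                if self.requires_grad:
                    self._accum(out.grad / other.data)
                if other.requires_grad:
                    other._accum(-out.grad * self.data / other.data ** 2)
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, k: float):
        out = _make(self.data ** k, (self,))
        if out.requires_grad:
            out._backward = lambda: self._accum(out.grad * k * self.data ** (k - 1))
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _make(self.data @ other.data, (self, other))
        if out.requires_grad:
            def bw():
                g = out.grad
                if self.requires_grad:
                    self._accum(g @ other.data.T)
                if other.requires_grad:
                    other._accum(self.data.T @ g)
            out._backward = bw
        return out

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def bw():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = _make(self.data.reshape(*shape), (self,))
        if out.requires_grad:
            out._backward = lambda: self._accum(out.grad.reshape(self.data.shape))
        return out

    def rows(self, idx) -> "Tensor":
        """Gather rows (first-axis fancy indexing)."""
        idx = np.asarray(idx)
        out = _make(self.data[idx], (self,))
        if out.requires_grad:
            def bw():
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)
            out._backward = bw
        return out

    def __getitem__(self, idx):
        return self.rows(idx)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- backward -------------------------------------------------------------
    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def _make(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = parents
    return out


# -- elementwise nonlinearities ------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = _make(np.maximum(x.data, 0.0), (x,))
    if out.requires_grad:
        out._backward = lambda: x._accum(out.grad * (x.data > 0))
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = _make(s, (x,))
    if out.requires_grad:
        out._backward = lambda: x._accum(out.grad * s * (1.0 - s))
    return out


def softplus(x: Tensor) -> Tensor:
    v = np.logaddexp(0.0, x.data)
    out = _make(v, (x,))
    if out.requires_grad:
        out._backward = lambda: x._accum(out.grad / (1.0 + np.exp(-x.data)))
    return out


def exp(x: Tensor) -> Tensor:
    v = np.exp(x.data)
    out = _make(v, (x,))
    if out.requires_grad:
        out._backward = lambda: x._accum(out.grad * v)
    return out


def log(x: Tensor) -> Tensor:
    out = _make(np.log(x.data), (x,))
    if out.requires_grad:
        out._backward = lambda: x._accum(out.grad / x.data)
    return out


def tanh(x: Tensor) -> Tensor:
    v = np.tanh(x.data)
    out = _make(v, (x,))
    if out.requires_grad:
        out._backward = lambda: x._accum(out.grad * (1.0 - v ** 2))
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp; gradient is zero outside [lo, hi] (PPO clipping semantics)."""
    out = _make(np.clip(x.data, lo, hi), (x,))
    if out.requires_grad:
        mask = (x.data >= lo) & (x.data <= hi)
        out._backward = lambda: x._accum(out.grad * mask)
    return out


def minimum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise min; ties route the gradient to ``a``."""
    b = _as_tensor(b)
    take_a = a.data <= b.data
    out = _make(np.where(take_a, a.data, b.data), (a, b))
    if out.requires_grad:
        def bw():
            if a.requires_grad:
                a._accum(out.grad * take_a)
            if b.requires_grad:
                b._accum(out.grad * ~take_a)
        out._backward = bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)
        def bw():
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * out.grad.ndim
                    sl[axis] = slice(a, b)
                    t._accum(out.grad[tuple(sl)])
        out._backward = bw
    return out


def spmm(S: sp.spmatrix, x: Tensor) -> Tensor:
    """Multiply a constant sparse matrix by a dense tensor: ``S @ x``."""
    S = S.tocsr()
    out = _make(S @ x.data, (x,))
    if out.requires_grad:
        St = S.T.tocsr()
        out._backward = lambda: x._accum(St @ out.grad)
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)  # constant shift
    z = x - Tensor(m)
    return z - log(exp(z).sum(axis=axis, keepdims=True))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return exp(log_softmax(x, axis=axis))


def dropout(x: Tensor, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout. ``rng=None`` (evaluation) is the identity."""
    if rng is None or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


# -- initialisation & optimisers -----------------------------------------------

def xavier_uniform(shape: tuple[int, int], rng: np.random.Generator) -> Tensor:
    fan_in, fan_out = shape[0], shape[-1]
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Adam:
    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class SGD:
    def __init__(self, params: Iterable[Tensor], lr: float = 1e-2):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad
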