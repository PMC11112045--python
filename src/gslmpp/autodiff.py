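"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides a :class:`Tensor` wrapping an ``ndarray`` plus the small set of
differentiable operations the models in this package need (elementwise
arithmetic, matrix products, sparse-constant matmul, reductions, gather,
concatenation, the usual nonlinearities) and an Adam optimizer.

Every functional op dispatches: if no argument is a :class:`Tensor` the
computation falls through to plain NumPy and returns an ``ndarray``, so the
same model formulas can be exercised with and without gradient tracking.
All tensors are float64; matrices are kept 2-D throughout the package.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "as_tensor",
    "parameter",
    "add", "sub", "mul", "div", "neg", "matmul", "spmm",
    "relu", "sigmoid", "exp", "log", "sqrt", "square", "absolute", "power",
    "tsum", "tmean", "transpose", "concat", "take",
    "Adam",
]


class Tensor:
    """A node in the autodiff graph: value, gradient, and backward closures."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjps")
    __array_priority__ = 200  # defer ndarray binary ops to Tensor

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._vjps: tuple[Callable[[np.ndarray], np.ndarray], ...] = ()

    # -- graph bookkeeping ------------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        """Backpropagate from a scalar output through the recorded graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; training graphs can be deep
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, vjp in zip(node._parents, node._vjps):
                if parent.requires_grad:
                    parent._accumulate(vjp(node.grad))

    # -- conveniences ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def T(self) -> "Tensor":
        return transpose(self)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # operator overloads
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(other, self)

    def __pow__(self, p):
        return power(self, p)


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data, rng: np.random.Generator | None = None, scale: float | None = None) -> Tensor:
    """A trainable leaf tensor; with `rng` and `scale`, Glorot-style init."""
    if rng is not None:
        shape = tuple(data) if isinstance(data, (tuple, list)) else np.asarray(data).shape
        if scale is None:
            fan_in = shape[0] if shape else 1
            fan_out = shape[-1] if shape else 1
            scale = np.sqrt(6.0 / (fan_in + fan_out))
        data = rng.uniform(-scale, scale, size=shape)
    return Tensor(data, requires_grad=True)


def _make(data: np.ndarray, parents: Sequence[Tensor], vjps: Sequence[Callable]) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._vjps = tuple(vjps)
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient down to `shape` after NumPy broadcasting."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, (gdim, sdim) in enumerate(zip(g.shape, shape)):
        if sdim == 1 and gdim != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


# -- elementwise binary ----------------------------------------------------

def add(a, b):
    if not (_is_tensor(a) or _is_tensor(b)):
        return np.add(a, b)
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data + b.data, (a, b),
                 (lambda g: _unbroadcast(g, a.data.shape),
                  lambda g: _unbroadcast(g, b.data.shape)))


def sub(a, b):
    if not (_is_tensor(a) or _is_tensor(b)):
        return np.subtract(a, b)
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data - b.data, (a, b),
                 (lambda g: _unbroadcast(g, a.data.shape),
                  lambda g: _unbroadcast(-g, b.data.shape)))


def mul(a, b):
    if not (_is_tensor(a) or _is_tensor(b)):
        return np.multiply(a, b)
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data * b.data, (a, b),
                 (lambda g: _unbroadcast(g * b.data, a.data.shape),
                  lambda g: _unbroadcast(g * a.data, b.data.shape)))


def div(a, b):
    if not (_is_tensor(a) or _is_tensor(b)):
        return np.divide(a, b)
    a, b = as_tensor(a), as_tensor(b)
    return _make(a.data / b.data, (a, b),
                 (lambda g: _unbroadcast(g / b.data, a.data.shape),
                  lambda g: _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)))


def neg(a):
    if not _is_tensor(a):
        return np.negative(a)
    return _make(-a.data, (a,), (lambda g: -g,))


# -- linear algebra --------------------------------------------------------

def matmul(a, b):
    if not (_is_tensor(a) or _is_tensor(b)):
        return np.asarray(a) @ np.asarray(b)
    a, b = as_tensor(a), as_tensor(b)
    if a.data.ndim != 2 or b.data.ndim != 2:
        raise ValueError("matmul supports 2-D tensors only")
    return _make(a.data @ b.data, (a, b),
                 (lambda g: g @ b.data.T,
                  lambda g: a.data.T @ g))


def spmm(a_sparse, b):
    """Constant sparse matrix times (dense) tensor."""
    if not _is_tensor(b):
        return a_sparse @ np.asarray(b)
    a_csr = sp.csr_matrix(a_sparse)
    return _make(a_csr @ b.data, (b,), (lambda g: a_csr.T @ g,))


def transpose(a):
    if not _is_tensor(a):
        return np.asarray(a).T
    return _make(a.data.T, (a,), (lambda g: g.T,))


# -- nonlinearities --------------------------------------------------------

def relu(a):
    if not _is_tensor(a):
        return np.maximum(a, 0.0)
    mask = a.data > 0
    return _make(np.where(mask, a.data, 0.0), (a,), (lambda g: g * mask,))


def sigmoid(a):
    if not _is_tensor(a):
        return 1.0 / (1.0 + np.exp(-np.asarray(a, dtype=np.float64)))
    s = 1.0 / (1.0 + np.exp(-a.data))
    return _make(s, (a,), (lambda g: g * s * (1.0 - s),))


def exp(a):
    if not _is_tensor(a):
        return np.exp(a)
    e = np.exp(a.data)
    return _make(e, (a,), (lambda g: g * e,))


def log(a):
    if not _is_tensor(a):
        return np.log(a)
    return _make(np.log(a.data), (a,), (lambda g: g / a.data,))


def sqrt(a):
    if not _is_tensor(a):
        return np.sqrt(a)
    r = np.sqrt(a.data)
    return _make(r, (a,), (lambda g: g * 0.5 / r,))


def square(a):
    if not _is_tensor(a):
        return np.square(a)
    return _make(a.data ** 2, (a,), (lambda g: g * 2.0 * a.data,))


def absolute(a):
    if not _is_tensor(a):
        return np.abs(a)
    s = np.sign(a.data)
    return _make(np.abs(a.data), (a,), (lambda g: g * s,))


def power(a, p: float):
    if not _is_tensor(a):
        return np.power(a, p)
    return _make(a.data ** p, (a,), (lambda g: g * p * a.data ** (p - 1),))


# -- reductions ------------------------------------------------------------

def tsum(a, axis=None, keepdims: bool = False):
    if not _is_tensor(a):
        return np.sum(a, axis=axis, keepdims=keepdims)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def _vjp(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return np.broadcast_to(g, a.data.shape).copy()

    return _make(out, (a,), (_vjp,))


def tmean(a, axis=None, keepdims: bool = False):
    if not _is_tensor(a):
        return np.mean(a, axis=axis, keepdims=keepdims)
    n = a.data.size if axis is None else a.data.shape[axis]
    return div(tsum(a, axis=axis, keepdims=keepdims), float(n))


# -- shape ops -------------------------------------------------------------

def concat(parts, axis: int = 1):
    if not any(_is_tensor(p) for p in parts):
        return np.concatenate([np.asarray(p) for p in parts], axis=axis)
    parts = [as_tensor(p) for p in parts]
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def _vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            return g[tuple(sl)]
        return _vjp

    data = np.concatenate([p.data for p in parts], axis=axis)
    return _make(data, parts, tuple(make_vjp(i) for i in range(len(parts))))


def take(a, indices, axis: int = 0):
    """Gather rows (axis=0) or columns (axis=1) by integer index."""
    idx = np.asarray(indices, dtype=np.intp)
    if not _is_tensor(a):
        return np.take(a, idx, axis=axis)

    def _vjp(g):
        out = np.zeros_like(a.data)
        if axis == 0:
            np.add.at(out, idx, g)
        else:
            np.add.at(out.T, idx, np.asarray(g).T)
        return out

    return _make(np.take(a.data, idx, axis=axis), (a,), (_vjp,))


# -- optimizer -------------------------------------------------------------

class Adam:
    """Adam over a list of parameter tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
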