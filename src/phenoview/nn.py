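"""Minimal reverse-mode automatic differentiation over NumPy arrays.

All trainable components in this package (the bipartite graph encoder, the
autoencoder teacher, the contrastive learner encoders with their adaptive
temperature network, and the two-stage classifier) are small feed-forward
models; this module provides exactly the primitives they need: a ``Tensor``
wrapping an ``ndarray`` with a gradient tape, the handful of differentiable
ops used by those models, dense/sparse layers, and an Adam optimizer.

Gradients are accumulated with float64 throughout; all randomness is taken
from an explicit :class:`numpy.random.Generator` so training is bit-for-bit
reproducible under a fixed seed.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "spmm",
    "softmax",
    "Linear",
    "MLP",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over broadcast axes so it matches ``shape``."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node on a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(
            requires_grad or any(p.requires_grad for p in _parents)
        )
        self.grad = None
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- graph utilities ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, _parents=(self, other), _backward=bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return Tensor(-self.data, _parents=(self,), _backward=bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, _parents=(self, other), _backward=bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other).pow(-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * self.pow(-1.0)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, _parents=(self, other), _backward=bw)

    def pow(self, p: float):
        def bw(g):
            self._accum(g * p * np.power(self.data, p - 1.0))

        return Tensor(np.power(self.data, p), _parents=(self,), _backward=bw)

    def sqrt(self):
        return self.pow(0.5)

    # -- nonlinearities ----------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return Tensor(np.log(self.data), _parents=(self,), _backward=bw)

    def relu(self):
        mask = self.data > 0.0

        def bw(g):
            self._accum(g * mask)

        return Tensor(self.data * mask, _parents=(self,), _backward=bw)

    def softplus(self):
        # log(1 + e^x), computed stably
        out_data = np.logaddexp(0.0, self.data)

        def bw(g):
            self._accum(g / (1.0 + np.exp(-self.data)))

        return Tensor(out_data, _parents=(self,), _backward=bw)

    def clip_min(self, floor: float):
        """max(x, floor); gradient flows only where x > floor."""
        mask = self.data > floor

        def bw(g):
            self._accum(g * mask)

        return Tensor(np.maximum(self.data, floor), _parents=(self,), _backward=bw)

    # -- reductions / reshaping -------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            _parents=(self,),
            _backward=bw,
        )

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def take_rows(self, idx):
        idx = np.asarray(idx)

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor(self.data[idx], _parents=(self,), _backward=bw)

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        _parents=tuple(tensors),
        _backward=bw,
    )


def spmm(matrix: sp.spmatrix, x: Tensor) -> Tensor:
    """Sparse-constant @ dense-tensor product (used for graph aggregation)."""
    x = as_tensor(x)
    matrix = matrix.tocsr()

    def bw(g):
        x._accum(matrix.T @ g)

    return Tensor(matrix @ x.data, _parents=(x,), _backward=bw)


def softmax(t: Tensor, axis: int = 1) -> Tensor:
    # subtracting the (constant) row max leaves both value and gradient intact
    shifted = t - Tensor(t.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# layers and optimizer
# ---------------------------------------------------------------------------


class Linear:
    """Dense affine map with Glorot-normal initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias=True):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = as_tensor(x) @ self.W
        if self.b is not None:
            out = out + self.b
        return out

    @property
    def parameters(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class MLP:
    """Feed-forward stack; activation applied on hidden layers only."""

    def __init__(self, sizes, rng, activation: str = "relu"):
        if activation not in ("relu", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.layers = [
            Linear(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])
        ]

    def __call__(self, x) -> Tensor:
        h = as_tensor(x)
        for i, layer in enumerate(self.layers):
            h = layer(h)
            if i < len(self.layers) - 1 and self.activation == "relu":
                h = h.relu()
        return h

    @property
    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters]


class Adam:
    """Adam optimizer (β1=0.9, β2=0.999) over a list of parameter tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
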