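"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the two encoders and the sextuplet loss
need: affine maps (with an optionally sparse, non-differentiable input),
elementwise nonlinearities, row gather/scatter, column slicing,
concatenation, row L2-normalization, reductions, and hinge terms.
Graphs are built eagerly; ``backward`` runs a topological sweep.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "concat_cols", "gather_rows"]


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = _parents

    # -- graph plumbing -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=self.data.dtype)
        self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic -----------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    def __sub__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = Tensor(self.data - other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(-_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    def __mul__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__
    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = bw
        return out

    # -- nonlinearities -------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0), self.requires_grad, (self,))
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        out._backward = bw
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, self.requires_grad, (self,))

        def bw(g):
            self._accum(g * y * (1.0 - y))

        out._backward = bw
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def bw(g):
            self._accum(g * (1.0 - y * y))

        out._backward = bw
        return out

    # -- shaping --------------------------------------------------------

    def cols(self, j0: int, j1: int) -> "Tensor":
        """Column slice [:, j0:j1]."""
        out = Tensor(self.data[:, j0:j1], self.requires_grad, (self,))

        def bw(g):
            full = np.zeros_like(self.data)
            full[:, j0:j1] = g
            self._accum(full)

        out._backward = bw
        return out

    def sum_rows(self) -> "Tensor":
        """Sum along axis 1 -> shape (n,)."""
        out = Tensor(self.data.sum(axis=1), self.requires_grad, (self,))

        def bw(g):
            self._accum(np.repeat(g[:, None], self.data.shape[1], axis=1))

        out._backward = bw
        return out

    def mean(self) -> "Tensor":
        out = Tensor(np.asarray(self.data.mean()), self.requires_grad, (self,))
        n = self.data.size

        def bw(g):
            self._accum(np.full_like(self.data, g / n))

        out._backward = bw
        return out

    def dot(self, w: np.ndarray) -> "Tensor":
        """Weighted sum of a vector tensor with a constant weight vector."""
        w = np.asarray(w, dtype=self.data.dtype)
        out = Tensor(np.asarray(self.data @ w), self.requires_grad, (self,))

        def bw(g):
            self._accum(g * w)

        out._backward = bw
        return out

    def normalize_rows(self, eps: float = 1e-12) -> "Tensor":
        """Project each row onto the unit sphere; y = x / max(||x||, eps)."""
        norms = np.linalg.norm(self.data, axis=1, keepdims=True)
        safe = np.maximum(norms, eps)
        y = self.data / safe
        out = Tensor(y, self.requires_grad, (self,))

        def bw(g):
            # d/dx (x/||x||) = (g - y <y, g>) / ||x||
            dots = (g * y).sum(axis=1, keepdims=True)
            self._accum((g - y * dots) / safe)

        out._backward = bw
        return out


def _as_tensor(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Reduce gradient g back to `shape` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def affine(x, w: Tensor, b: Tensor) -> Tensor:
    """x @ W + b where x is a constant ndarray or scipy sparse matrix.

    Gradients flow to W and b only; the sparse product keeps the wide
    first layer of the spectrum encoder cheap for peak-sparse inputs.
    """
    xw = x @ w.data
    if sp.issparse(xw):  # pragma: no cover - scipy returns ndarray here
        xw = np.asarray(xw)
    out = Tensor(xw + b.data, w.requires_grad or b.requires_grad, (w, b))

    def bw(g):
        w._accum((x.T @ g) if not sp.issparse(x) else np.asarray(x.T @ g))
        b._accum(g.sum(axis=0))

    out._backward = bw
    return out


def gather_rows(table: Tensor, idx: np.ndarray) -> Tensor:
    """table[idx] row gather with scatter-add backward."""
    idx = np.asarray(idx)
    out = Tensor(table.data[idx], table.requires_grad, (table,))

    def bw(g):
        full = np.zeros_like(table.data)
        np.add.at(full, idx, g)
        table._accum(full)

    out._backward = bw
    return out


def concat_cols(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate two (n, d) tensors along axis 1."""
    out = Tensor(np.concatenate([a.data, b.data], axis=1),
                 a.requires_grad or b.requires_grad, (a, b))
    da = a.data.shape[1]

    def bw(g):
        a._accum(g[:, :da])
        b._accum(g[:, da:])

    out._backward = bw
    return out
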