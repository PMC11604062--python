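"""Minimal reverse-mode automatic differentiation on numpy arrays.

The network in :mod:`stmmr.model` is small (a handful of dense layers over a
few hundred to a few thousand spots) and trains full-batch, so a compact
tape-based autodiff over numpy's BLAS-backed primitives is entirely adequate.
Only the operations the model needs are implemented: broadcasting arithmetic,
matmul (with a constant-sparse left operand for graph propagation), the usual
pointwise nonlinearities, reductions, row-wise softmax and ``lgamma`` for the
negative-binomial likelihood.

Gradients are accumulated by a topological-order sweep from a scalar loss.
All data is kept in float64.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import digamma as _digamma
from scipy.special import gammaln as _gammaln

__all__ = ["Tensor", "as_tensor", "concat", "spmm", "logaddexp"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were broadcast from size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape entry needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype != np.float32:  # float32 is kept (training mode); else float64
            arr = arr.astype(np.float64, copy=False)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], tuple] | None = None

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _op(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        return Tensor._op(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = as_tensor(other)
        return Tensor._op(
            self.data - other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)),
        )

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor._op(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape) if self.requires_grad else None,
                _unbroadcast(g * self.data, other.shape) if other.requires_grad else None,
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor._op(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            ),
        )

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        return Tensor._op(
            self.data**e,
            (self,),
            lambda g: (g * e * self.data ** (e - 1.0),),
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        return Tensor._op(
            self.data @ other.data,
            (self, other),
            lambda g: (
                g @ other.data.T if self.requires_grad else None,
                self.data.T @ g if other.requires_grad else None,
            ),
        )

    @property
    def T(self) -> "Tensor":
        return Tensor._op(self.data.T, (self,), lambda g: (g.T,))

    # -- pointwise -----------------------------------------------------------

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)
        return Tensor._op(out_data, (self,), lambda g: (g * out_data,))

    def log(self) -> "Tensor":
        return Tensor._op(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)
        return Tensor._op(out_data, (self,), lambda g: (g / (2.0 * out_data),))

    def relu(self) -> "Tensor":
        mask = self.data > 0
        return Tensor._op(np.where(mask, self.data, 0.0), (self,), lambda g: (g * mask,))

    def sigmoid(self) -> "Tensor":
        # stable: use tanh formulation
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        return Tensor._op(out_data, (self,), lambda g: (g * out_data * (1.0 - out_data),))

    def softplus(self) -> "Tensor":
        # log(1 + exp(x)) computed without overflow
        out_data = np.maximum(self.data, 0.0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        return Tensor._op(out_data, (self,), lambda g: (g * sig,))

    def clip(self, lo: float, hi: float) -> "Tensor":
        mask = (self.data > lo) & (self.data < hi)
        return Tensor._op(np.clip(self.data, lo, hi), (self,), lambda g: (g * mask,))

    def lgamma(self) -> "Tensor":
        return Tensor._op(
            _gammaln(self.data), (self,), lambda g: (g * _digamma(self.data),)
        )

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- structured ops ------------------------------------------------------

    def row_softmax(self) -> "Tensor":
        """Row-wise softmax of a 2-D tensor (stable, fused backward)."""
        shifted = self.data - self.data.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=1, keepdims=True)

        def backward(g):
            dot = (g * s).sum(axis=1, keepdims=True)
            return (s * (g - dot),)

        return Tensor._op(s, (self,), backward)

    # -- backward sweep ------------------------------------------------------

    def backward(self) -> None:
        """Backpropagate from a scalar tensor, filling ``.grad`` fields."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative post-order DFS (graphs can be deep)
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is None or node.grad is None:
                continue
            for parent, grad in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad or grad is None:
                    continue
                if parent.grad is None:
                    # first contribution: keep the array (accumulation below is
                    # out-of-place, so aliasing a child's grad is safe)
                    parent.grad = grad
                else:
                    parent.grad = parent.grad + grad


def as_tensor(x) -> Tensor:
    """Wrap ``x`` as a constant :class:`Tensor` (no-op if already one)."""
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    """Concatenate 2-D tensors along ``axis``."""
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._op(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def spmm(mat, x: Tensor) -> Tensor:
    """Multiply a *constant* (sparse or dense) matrix by a tensor: ``mat @ x``.

    The matrix carries no gradient; this is the graph-propagation step where
    ``mat`` is the normalized adjacency.
    """
    x = as_tensor(x)
    if sp.issparse(mat):
        mat = mat.tocsr()
        mat_t = mat.T.tocsr()
        return Tensor._op(mat @ x.data, (x,), lambda g: (mat_t @ g,))
    mat = np.asarray(mat, dtype=np.float64)
    return Tensor._op(mat @ x.data, (x,), lambda g: (mat.T @ g,))


def logaddexp(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise ``log(exp(a) + exp(b))``, stable via a detached max shift."""
    a, b = as_tensor(a), as_tensor(b)
    m = np.maximum(a.data, b.data)  # constant shift; gradient is unaffected
    return ((a - m).exp() + (b - m).exp()).log() + as_tensor(m)
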