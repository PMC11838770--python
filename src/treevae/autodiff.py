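"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it
on a tape; :meth:`Tensor.backward` walks the tape in reverse topological
order accumulating gradients.  Broadcasting is supported by summing upstream
gradients over broadcast axes.  The op set is exactly what the models in
this package need (affine maps, batched matmul, pointwise nonlinearities,
reductions, gather, logsumexp); it is not a general framework.

Graph recording can be switched off with :func:`no_grad` for evaluation-only
forward passes.
"""

from __future__ import annotations

import contextlib
from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

__all__ = ["Tensor", "no_grad", "as_tensor", "concat", "logsumexp", "log_softmax"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable tape recording inside the context (pure forward passes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (undo numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


ArrayLike = Union["Tensor", np.ndarray, float, int]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents: Tuple[Tensor, ...] = ()
        self._backward: Optional[Callable[[np.ndarray], None]] = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- properties --------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other: ArrayLike) -> "Tensor":
        o = as_tensor(other)
        out_data = self.data + o.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g, o.data.shape))

        return Tensor._make(out_data, (self, o), bwd)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bwd(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other: ArrayLike) -> "Tensor":
        o = as_tensor(other)
        out_data = self.data * o.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(g * self.data, o.data.shape))

        return Tensor._make(out_data, (self, o), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        o = as_tensor(other)
        out_data = self.data / o.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / o.data, self.data.shape))
            if o.requires_grad:
                o._accumulate(_unbroadcast(-g * self.data / o.data**2, o.data.shape))

        return Tensor._make(out_data, (self, o), bwd)

    def __pow__(self, p: float) -> "Tensor":
        out_data = self.data**p

        def bwd(g):
            self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._make(out_data, (self,), bwd)

    def __matmul__(self, other: ArrayLike) -> "Tensor":
        o = as_tensor(other)
        out_data = self.data @ o.data

        def bwd(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(o.data, -1, -2)
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if o.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                o._accumulate(_unbroadcast(gb, o.data.shape))

        return Tensor._make(out_data, (self, o), bwd)

    # -- pointwise ---------------------------------------------------------

    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bwd(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bwd(g):
            self._accumulate(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), bwd)

    def sigmoid(self) -> "Tensor":
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bwd)

    def elu(self, alpha: float = 1.0) -> "Tensor":
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * np.expm1(self.data))

        def bwd(g):
            self._accumulate(g * np.where(pos, 1.0, out_data + alpha))

        return Tensor._make(out_data, (self,), bwd)

    def clip(self, lo: float, hi: float) -> "Tensor":
        """Clamp values; gradient is 1 inside the interval, 0 outside."""
        inside = (self.data >= lo) & (self.data <= hi)
        out_data = np.clip(self.data, lo, hi)

        def bwd(g):
            self._accumulate(g * inside)

        return Tensor._make(out_data, (self,), bwd)

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape
        out_data = self.data.reshape(*shape)

        def bwd(g):
            self._accumulate(g.reshape(orig))

        return Tensor._make(out_data, (self,), bwd)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        return Tensor._make(out_data, (self,), bwd)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def gather_last(self, indices: np.ndarray) -> "Tensor":
        """Pick one entry along the last axis per leading position.

        ``indices`` has the shape of ``self`` minus the last axis.
        """
        idx = np.asarray(indices)
        out_data = np.take_along_axis(self.data, idx[..., None], axis=-1)[..., 0]

        def bwd(g):
            full = np.zeros_like(self.data)
            np.put_along_axis(full, idx[..., None], g[..., None], axis=-1)
            self._accumulate(full)

        return Tensor._make(out_data, (self,), bwd)


def as_tensor(x: ArrayLike) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]

    def bwd(g):
        pieces = np.split(g, np.cumsum(sizes)[:-1], axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._make(out_data, tensors, bwd)


def logsumexp(t: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp; the max shift is treated as constant
    (its subgradient contribution cancels in the composite)."""
    m = np.max(t.data, axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    shifted = t - Tensor(m)
    out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    if not keepdims:
        out = out.reshape(*np.squeeze(out.data, axis=axis).shape)
    return out


def log_softmax(t: Tensor, axis: int = -1) -> Tensor:
    return t - logsumexp(t, axis=axis, keepdims=True)
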