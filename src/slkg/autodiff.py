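"""Minimal reverse-mode automatic differentiation over numpy arrays.

The encoder, scorer and loss are small computation graphs built from a dozen
primitives (matmul, broadcasting arithmetic, pointwise nonlinearities, row
gather/scatter).  This module provides exactly those primitives as a
``Tensor`` wrapper with a topologically-ordered backward pass.  Gradients of
every primitive are verified against central finite differences in the test
suite.

All arrays are float64; constants (plain numbers or ndarrays) participate in
any op and receive no gradient.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing ---------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operators --------------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __neg__(self):
        return mul(self, -1.0)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes introduced or stretched by broadcasting to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


def _make(data, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(a.data + b.data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(a.data * b.data, (a, b), bw)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def bw(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    return _make(a.data @ b.data, (a, b), bw)


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0

    def bw(g):
        a._accumulate(g * mask)

    return _make(a.data * mask, (a,), bw)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    with np.errstate(over="ignore"):
        y = 1.0 / (1.0 + np.exp(-a.data))

    def bw(g):
        a._accumulate(g * y * (1.0 - y))

    return _make(y, (a,), bw)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    y = np.tanh(a.data)

    def bw(g):
        a._accumulate(g * (1.0 - y * y))

    return _make(y, (a,), bw)


def exp(a) -> Tensor:
    a = as_tensor(a)
    y = np.exp(a.data)

    def bw(g):
        a._accumulate(g * y)

    return _make(y, (a,), bw)


def log(a) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        a._accumulate(g / a.data)

    return _make(np.log(a.data), (a,), bw)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)

    def bw(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
        else:
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(gg, a.data.shape).copy())

    return _make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)


def gather_rows(a, idx) -> Tensor:
    """Row-gather a[idx]; gradient scatter-adds back."""
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.int64)

    def bw(g):
        acc = np.zeros_like(a.data)
        np.add.at(acc, idx, g)
        a._accumulate(acc)

    return _make(a.data[idx], (a,), bw)


def segment_sum(a, idx, n: int) -> Tensor:
    """Scatter-add rows of ``a`` into ``n`` buckets given by ``idx``."""
    a = as_tensor(a)
    idx = np.asarray(idx, dtype=np.int64)
    out = np.zeros((n,) + a.data.shape[1:], dtype=np.float64)
    np.add.at(out, idx, a.data)

    def bw(g):
        a._accumulate(g[idx])

    return _make(out, (a,), bw)


def pad_zero_row(a) -> Tensor:
    """Append one all-zero row (used as the 'absent from previous frontier' state)."""
    a = as_tensor(a)
    padded = np.concatenate([a.data, np.zeros((1,) + a.data.shape[1:])], axis=0)

    def bw(g):
        a._accumulate(g[:-1])

    return _make(padded, (a,), bw)


def logsumexp_with_zeros(scores: Tensor, n_zeros: int) -> Tensor:
    """log( sum_i exp(scores_i) + n_zeros * exp(0) ), max-stabilized.

    Implements the normalizer of a softmax over the scored items plus
    ``n_zeros`` items pinned at score 0 (unreached candidates).
    """
    c = float(max(scores.data.max(initial=0.0), 0.0))
    shifted = exp(scores - c)
    total = tsum(shifted) + n_zeros * np.exp(-c)
    return log(total) + c
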