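"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package's network is a recurrent + convolutional classifier; training it
requires gradients of a scalar loss with respect to every parameter tensor.
This module provides exactly the operator set the network needs (affine maps,
element-wise nonlinearities, concatenation/slicing, embedding lookup, window
maxima, log-softmax) as a tape-based autodiff over ``float64`` arrays.

Correctness of every backward rule is enforced end-to-end by a
numerical-vs-analytic gradient test on the full network + loss.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "relu", "sigmoid", "tanh", "exp", "log",
           "max_axis", "maxpool1d", "pad_time", "log_softmax", "clip_min"]


class Tensor:
    """A node in the computation graph: an ndarray plus its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ---- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- graph machinery -----------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the whole graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative DFS post-order
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                stack_.pop()
                topo.append(node)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # ---- operators -----------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add,
                       lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __mul__(self, other):
        return _binary(self, other, np.multiply,
                       lambda g, a, b: g * b.data, lambda g, a, b: g * a.data)

    __rmul__ = __mul__

    def __sub__(self, other):
        return _binary(self, other, np.subtract,
                       lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return _wrap(other) - self

    def __neg__(self):
        return self * (-1.0)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * (other ** -1.0)
        return self * (1.0 / float(other))

    def __pow__(self, exponent: float):
        e = float(exponent)
        out = _node(self.data ** e, (self,))

        def bwd(g):
            if self.requires_grad:
                base = self.data
                # d/dx x^e; guard 0^(e-1) for e>=1 (gradient 0 at the kink)
                with np.errstate(divide="ignore", invalid="ignore"):
                    d = e * base ** (e - 1.0)
                d = np.where(np.isfinite(d), d, 0.0)
                self._accum(g * d)
        out._backward = bwd
        return out

    def __matmul__(self, other):
        """Matrix product ``x @ W`` with ``W`` strictly 2-D (the only case used)."""
        if not isinstance(other, Tensor):
            other = _wrap(other)
        if other.data.ndim != 2:
            raise ValueError("matmul right operand must be 2-D")
        out = _node(self.data @ other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                axes = tuple(range(g.ndim - 1))
                other._accum(np.tensordot(self.data, g, (axes, axes)))
        out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))

        def bwd(g):
            if self.requires_grad:
                gz = np.zeros_like(self.data)
                np.add.at(gz, idx, g)
                self._accum(gz)
        out._backward = bwd
        return out

    def sum(self, axis=None, keepdims=False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bwd(g):
            if self.requires_grad:
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def item(self) -> float:
        return float(self.data)


# ---------------------------------------------------------------------------
# helpers

def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _node(data, parents) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    out.requires_grad = any(p.requires_grad for p in out._parents)
    return out


def _sum_to_shape(g, shape):
    """Reduce a broadcast gradient back to the original operand shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _binary(a, b, fwd, da, db):
    a, b = _wrap(a), _wrap(b)
    out = _node(fwd(a.data, b.data), (a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(_sum_to_shape(da(g, a, b), a.data.shape))
        if b.requires_grad:
            b._accum(_sum_to_shape(db(g, a, b), b.data.shape))
    out._backward = bwd
    return out


def _unary(x, fdata, dgrad):
    x = _wrap(x)
    out = _node(fdata(x.data), (x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * dgrad(out.data, x.data))
    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# nonlinearities

def relu(x: Tensor) -> Tensor:
    return _unary(x, lambda d: np.maximum(d, 0.0), lambda o, d: (d > 0).astype(np.float64))


def sigmoid(x: Tensor) -> Tensor:
    return _unary(x, lambda d: 1.0 / (1.0 + np.exp(-d)), lambda o, d: o * (1.0 - o))


def tanh(x: Tensor) -> Tensor:
    return _unary(x, np.tanh, lambda o, d: 1.0 - o * o)


def exp(x: Tensor) -> Tensor:
    return _unary(x, np.exp, lambda o, d: o)


def log(x: Tensor) -> Tensor:
    return _unary(x, np.log, lambda o, d: 1.0 / d)


def clip_min(x: Tensor, lo: float) -> Tensor:
    """max(x, lo) element-wise; gradient passes only where x > lo."""
    return _unary(x, lambda d: np.maximum(d, lo), lambda o, d: (d > lo).astype(np.float64))


# ---------------------------------------------------------------------------
# structural ops

def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)
    out._backward = bwd
    return out


def stack(tensors, axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = _node(np.stack([t.data for t in tensors], axis=axis), tensors)

    def bwd(g):
        pieces = np.split(g, len(tensors), axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(np.squeeze(piece, axis=axis))
    out._backward = bwd
    return out


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add backward."""
    ids = np.asarray(ids)
    out = _node(table.data[ids], (table,))

    def bwd(g):
        if table.requires_grad:
            gz = np.zeros_like(table.data)
            np.add.at(gz, ids, g)
            table._accum(gz)
    out._backward = bwd
    return out


def pad_time(x: Tensor, left: int, right: int) -> Tensor:
    """Zero-pad along axis 1 (the time/token axis) of a (B, L, C) tensor."""
    if left == 0 and right == 0:
        return x
    pads = [(0, 0)] * x.ndim
    pads[1] = (left, right)
    out = _node(np.pad(x.data, pads), (x,))
    L = x.data.shape[1]

    def bwd(g):
        if x.requires_grad:
            x._accum(g[:, left:left + L])
    out._backward = bwd
    return out


def max_axis(x: Tensor, axis: int) -> Tensor:
    """Maximum along one axis (ties broken by first argmax)."""
    idx = np.argmax(x.data, axis=axis)
    out_data = np.take_along_axis(x.data, np.expand_dims(idx, axis), axis).squeeze(axis)
    out = _node(out_data, (x,))

    def bwd(g):
        if x.requires_grad:
            gz = np.zeros_like(x.data)
            np.put_along_axis(gz, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis)
            x._accum(gz)
    out._backward = bwd
    return out


def maxpool1d(x: Tensor, window: int, stride: int | None = None) -> Tensor:
    """Sliding maximum over the time axis of a (B, L, C) tensor."""
    if stride is None:
        stride = window
    B, L, C = x.data.shape
    if L < window:
        raise ValueError(f"sequence length {L} shorter than pooling window {window}")
    starts = np.arange(0, L - window + 1, stride)
    gather = starts[:, None] + np.arange(window)[None, :]      # (n_out, w)
    win = x.data[:, gather, :]                                  # (B, n_out, w, C)
    arg = np.argmax(win, axis=2)                                # (B, n_out, C)
    out = _node(win.max(axis=2), (x,))

    def bwd(g):
        if x.requires_grad:
            gz = np.zeros_like(x.data)
            b_idx, o_idx, c_idx = np.meshgrid(
                np.arange(B), np.arange(len(starts)), np.arange(C), indexing="ij")
            pos = starts[o_idx] + arg
            np.add.at(gz, (b_idx, pos, c_idx), g)
            x._accum(gz)
    out._backward = bwd
    return out


def log_softmax(x: Tensor) -> Tensor:
    """Numerically stable log-softmax over the last axis."""
    m = x.data.max(axis=-1, keepdims=True)
    z = x.data - m
    ls = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    out = _node(ls, (x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g - np.exp(ls) * g.sum(axis=-1, keepdims=True))
    out._backward = bwd
    return out
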