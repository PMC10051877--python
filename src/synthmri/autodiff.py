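"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine exists to train the single-image GAN and the segmentation
network on CPU.  It is deliberately small: a :class:`Tensor` wraps an
ndarray together with the closures that map an output cotangent back to
input cotangents.  Every vector-Jacobian product is itself expressed in
terms of these same primitives, so gradients are ordinary graph tensors
and ``grad`` can be applied to expressions built from gradients.  That
second-order capability is what the Wasserstein critic's gradient
penalty requires (the penalty is a function of an input gradient, and
its parameter gradient differentiates through the first backward pass).

Conventions
-----------
* float32 storage by default (``DTYPE``); callers may pass float64.
* Image tensors are NCHW.
* ``grad`` prunes the graph: only nodes on a path from a requested input
  to the output are traversed.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32

__all__ = [
    "Tensor", "constant", "grad",
    "add", "sub", "mul", "neg", "cmul", "add_const", "powc", "exp", "log",
    "sumt", "meant", "reshape", "transpose", "matmul", "leaky_relu", "relu",
    "absolute", "sigmoid", "tanh", "im2col", "col2im",
    "upsample_nearest", "sumpool", "narrow", "concat", "broadcast_to",
]


class Tensor:
    """Node in the computation graph: an ndarray plus backward closures."""

    __slots__ = ("data", "parents", "vjps")

    def __init__(self, data, parents=(), vjps=()):
        if isinstance(data, np.generic):
            data = np.asarray(data)        # keep numpy scalar dtypes
        elif not isinstance(data, np.ndarray):
            data = np.asarray(data, dtype=DTYPE)
        self.data = data
        self.parents = parents
        self.vjps = vjps

    # -- convenience -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, leaf={not self.parents})"

    # operator sugar
    def __add__(self, other):
        return add(self, _as_tensor(other, self))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, _as_tensor(other, self))

    def __rsub__(self, other):
        return sub(_as_tensor(other, self), self)

    def __mul__(self, other):
        if np.isscalar(other):
            return cmul(self, other)
        return mul(self, _as_tensor(other, self))

    __rmul__ = __mul__

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return powc(self, p)

    def __truediv__(self, other):
        if np.isscalar(other):
            return cmul(self, 1.0 / other)
        return mul(self, powc(_as_tensor(other, self), -1.0))


def constant(x, dtype=None) -> Tensor:
    return Tensor(np.asarray(x, dtype=dtype or DTYPE))


def _as_tensor(x, like: Tensor) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=like.data.dtype))


# ---------------------------------------------------------------------
# broadcasting helper: reduce g to `shape` (inverse of numpy broadcast)
# ---------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    if g.shape == shape:
        return g
    # sum the leading extra axes
    extra = g.ndim - len(shape)
    if extra > 0:
        g = sumt(g, axis=tuple(range(extra)), keepdims=False)
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, (a, b) in enumerate(zip(g.shape, shape)) if b == 1 and a != 1)
    if axes:
        g = sumt(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------
# arithmetic primitives
# ---------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data + b.data, (a, b),
                  (lambda g: _unbroadcast(g, a.shape),
                   lambda g: _unbroadcast(g, b.shape)))


def sub(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data - b.data, (a, b),
                  (lambda g: _unbroadcast(g, a.shape),
                   lambda g: _unbroadcast(neg(g), b.shape)))


def neg(a: Tensor) -> Tensor:
    return Tensor(-a.data, (a,), (lambda g: neg(g),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data * b.data, (a, b),
                  (lambda g: _unbroadcast(mul(g, b), a.shape),
                   lambda g: _unbroadcast(mul(g, a), b.shape)))


def cmul(a: Tensor, c) -> Tensor:
    """Multiply by a constant scalar or ndarray (not differentiated)."""
    c = np.asarray(c, dtype=a.data.dtype) if not np.isscalar(c) else c
    return Tensor(a.data * c, (a,), (lambda g: _unbroadcast(cmul(g, c), a.shape),))


def add_const(a: Tensor, c) -> Tensor:
    return Tensor(a.data + np.asarray(c, dtype=a.data.dtype), (a,),
                  (lambda g: _unbroadcast(g, a.shape),))


def powc(a: Tensor, p: float) -> Tensor:
    out = a.data ** p
    return Tensor(out, (a,), (lambda g: mul(g, cmul(powc(a, p - 1.0), p)),))


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)
    out = Tensor(out_data, (a,), ())
    out.vjps = (lambda g: mul(g, out),)
    return out


def log(a: Tensor) -> Tensor:
    return Tensor(np.log(a.data), (a,), (lambda g: mul(g, powc(a, -1.0)),))


# ---------------------------------------------------------------------
# reductions / shape ops
# ---------------------------------------------------------------------

def sumt(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)
    if not isinstance(out, np.ndarray):
        out = np.asarray(out, dtype=a.data.dtype)

    def vjp(g):
        if axis is None:
            return broadcast_to(reshape(g, (1,) * a.ndim), a.shape)
        ax = axis if isinstance(axis, tuple) else (axis,)
        ax = tuple(i % a.ndim for i in ax)
        if not keepdims:
            kshape = tuple(1 if i in ax else s for i, s in enumerate(a.shape))
            g = reshape(g, kshape)
        return broadcast_to(g, a.shape)

    return Tensor(out, (a,), (vjp,))


def meant(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        n = a.data.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[i % a.ndim] for i in ax]))
    return cmul(sumt(a, axis=axis, keepdims=keepdims), 1.0 / n)


def broadcast_to(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    return Tensor(np.broadcast_to(a.data, shape).copy(), (a,),
                  (lambda g: _unbroadcast(g, a.shape),))


def reshape(a: Tensor, shape) -> Tensor:
    shape = tuple(shape)
    return Tensor(a.data.reshape(shape), (a,), (lambda g: reshape(g, a.shape),))


def transpose(a: Tensor, axes) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return Tensor(a.data.transpose(axes), (a,), (lambda g: transpose(g, inv),))


def _swap_last(t: Tensor) -> Tensor:
    axes = list(range(t.ndim))
    axes[-2], axes[-1] = axes[-1], axes[-2]
    return transpose(t, axes)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data @ b.data
    return Tensor(out, (a, b),
                  (lambda g: _unbroadcast(matmul(g, _swap_last(b)), a.shape),
                   lambda g: _unbroadcast(matmul(_swap_last(a), g), b.shape)))


# ---------------------------------------------------------------------
# nonlinearities
# ---------------------------------------------------------------------

def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    coeff = np.where(a.data > 0, 1.0, slope).astype(a.data.dtype)
    return Tensor(a.data * coeff, (a,), (lambda g: cmul(g, coeff),))


def relu(a: Tensor) -> Tensor:
    return leaky_relu(a, 0.0)


def absolute(a: Tensor) -> Tensor:
    return leaky_relu(a, -1.0)


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable piecewise form; vjp uses the output tensor
    x = a.data
    out_data = np.empty_like(x)
    pos = x >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out_data[~pos] = ex / (1.0 + ex)
    out = Tensor(out_data, (a,), ())
    out.vjps = (lambda g: mul(g, mul(out, add_const(neg(out), 1.0))),)
    return out


def tanh(a: Tensor) -> Tensor:
    return add_const(cmul(sigmoid(cmul(a, 2.0)), 2.0), -1.0)


# ---------------------------------------------------------------------
# image primitives: im2col / col2im, pooling, upsampling, concat
# ---------------------------------------------------------------------

def _conv_out_size(H, W, k, stride, pad):
    return (H + 2 * pad - k) // stride + 1, (W + 2 * pad - k) // stride + 1


def _im2col_data(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    N, C, H, W = x.shape
    Ho, Wo = _conv_out_size(H, W, k, stride, pad)
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((N, C, k, k, Ho, Wo), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = x[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride]
    return cols.reshape(N, C * k * k, Ho * Wo)


def _col2im_data(cols: np.ndarray, xshape, k: int, stride: int, pad: int) -> np.ndarray:
    N, C, H, W = xshape
    Ho, Wo = _conv_out_size(H, W, k, stride, pad)
    cols = cols.reshape(N, C, k, k, Ho, Wo)
    out = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            out[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += cols[:, :, i, j]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


def im2col(a: Tensor, k: int, stride: int = 1, pad: int = 0) -> Tensor:
    """Rearrange NCHW into (N, C*k*k, L) patch columns; linear, so its
    vjp is :func:`col2im` and vice versa (second order comes free)."""
    shape = a.shape
    return Tensor(_im2col_data(a.data, k, stride, pad), (a,),
                  (lambda g: col2im(g, shape, k, stride, pad),))


def col2im(a: Tensor, xshape, k: int, stride: int = 1, pad: int = 0) -> Tensor:
    return Tensor(_col2im_data(a.data, xshape, k, stride, pad), (a,),
                  (lambda g: im2col(g, k, stride, pad),))


def upsample_nearest(a: Tensor, f: int) -> Tensor:
    N, C, H, W = a.shape
    out = np.repeat(np.repeat(a.data, f, axis=2), f, axis=3)
    return Tensor(out, (a,), (lambda g: sumpool(g, f),))


def sumpool(a: Tensor, f: int) -> Tensor:
    N, C, H, W = a.shape
    out = a.data.reshape(N, C, H // f, f, W // f, f).sum(axis=(3, 5))
    return Tensor(out, (a,), (lambda g: upsample_nearest(g, f),))


def avgpool(a: Tensor, f: int) -> Tensor:
    return cmul(sumpool(a, f), 1.0 / (f * f))


def narrow(a: Tensor, axis: int, start: int, length: int) -> Tensor:
    idx = [slice(None)] * a.ndim
    idx[axis] = slice(start, start + length)
    idx = tuple(idx)
    total = a.shape[axis]
    return Tensor(a.data[idx], (a,),
                  (lambda g: _embed(g, axis, start, total),))


def _embed(g: Tensor, axis: int, start: int, total: int) -> Tensor:
    shape = list(g.shape)
    length = shape[axis]
    shape[axis] = total
    out = np.zeros(tuple(shape), dtype=g.data.dtype)
    idx = [slice(None)] * g.ndim
    idx[axis] = slice(start, start + length)
    out[tuple(idx)] = g.data
    return Tensor(out, (g,), (lambda gg: narrow(gg, axis, start, length),))


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + [t.shape[axis] for t in tensors])
    vjps = tuple(
        (lambda s, l: (lambda g: narrow(g, axis, s, l)))(int(offsets[i]), t.shape[axis])
        for i, t in enumerate(tensors)
    )
    return Tensor(out, tuple(tensors), vjps)


# ---------------------------------------------------------------------
# reverse-mode driver
# ---------------------------------------------------------------------

def grad(output: Tensor, wrt, cotangent: Tensor | None = None):
    """Cotangents of ``output`` with respect to each tensor in ``wrt``.

    The returned tensors are graph nodes, so expressions built from them
    (e.g. a gradient-penalty term) can be differentiated again.
    """
    wrt = list(wrt)
    if cotangent is None:
        cotangent = Tensor(np.ones_like(output.data))

    # topological order of the subgraph reachable from `output`
    topo: list[Tensor] = []
    visited: set[int] = set()
    stack = [(output, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in visited:
                stack.append((p, False))

    # mark nodes through which gradient must flow (reach some wrt leaf)
    needed: set[int] = {id(w) for w in wrt}
    for node in topo:  # topo is children-after-parents
        if any(id(p) in needed for p in node.parents):
            needed.add(id(node))

    grads: dict[int, Tensor] = {id(output): cotangent}
    for node in reversed(topo):
        g = grads.pop(id(node), None)
        if g is None or id(node) not in needed and node is not output:
            continue
        for parent, vjp in zip(node.parents, node.vjps):
            if id(parent) not in needed:
                continue
            pg = vjp(g)
            acc = grads.get(id(parent))
            grads[id(parent)] = pg if acc is None else add(acc, pg)
        # keep gradients of requested leaves
        if id(node) in (id(w) for w in wrt):
            grads[id(node)] = g

    out = []
    for w in wrt:
        gw = grads.get(id(w))
        if gw is None:
            gw = Tensor(np.zeros_like(w.data))
        out.append(gw)
    return out
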