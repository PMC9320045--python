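"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine exists because the gradient-inversion attack needs gradients of a
function *of gradients*: the attack loss compares the autodiff gradient of the
classifier loss (w.r.t. the model parameters) against an observed parameter
delta, and is itself minimised w.r.t. the dummy input pixels.  Every vector-
Jacobian product below is therefore expressed in terms of the same primitive
operations, so backward passes build ordinary graphs and can be differentiated
again (double backprop) to arbitrary order.

Supported primitives are exactly what a small convolutional classifier needs:
elementwise arithmetic, matmul with broadcasting, reductions, reshapes,
gather/scatter (from which convolution via im2col and image shifts for total
variation are built), relu/abs/exp/log.  Arrays are float64 throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "constant", "leaf", "add", "sub", "mul", "div", "neg",
    "add_const", "mul_const", "pow_const", "exp", "log", "abs_", "relu",
    "sum_", "mean_", "reshape", "broadcast_to", "transpose_last2", "matmul",
    "take_flat", "scatter_flat", "take_ax1", "scatter_ax1", "grad",
    "conv2d", "conv2d_indices",
]


class Tensor:
    """A node in the computation graph: a numpy array plus its provenance."""

    __slots__ = ("data", "parents", "vjps")

    def __init__(self, data, parents=(), vjps=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = parents
        self.vjps = vjps

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    # -- operator sugar (all defer to the module-level ops) --
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __rsub__(self, other):
        return sub(_as_tensor(other), self)

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __neg__(self):
        return neg(self)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, leaf={not self.parents})"


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x):
    """Wrap an array as a graph constant (no gradient flows into it)."""
    return Tensor(x)


def leaf(x):
    """Alias of :func:`constant`; leaves are distinguished by identity, not flags."""
    return Tensor(x)


# ---------------------------------------------------------------------------
# broadcasting helpers


def _unbroadcast(g: Tensor, shape) -> Tensor:
    """Reduce a cotangent ``g`` back to ``shape`` after numpy broadcasting."""
    if g.data.shape == tuple(shape):
        return g
    extra = g.data.ndim - len(shape)
    if extra > 0:
        g = sum_(g, axis=tuple(range(extra)))
    keep = tuple(i for i, s in enumerate(shape) if s == 1 and g.data.shape[i] != 1)
    if keep:
        g = sum_(g, axis=keep, keepdims=True)
    if g.data.shape != tuple(shape):
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# elementwise arithmetic


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return Tensor(a.data + b.data, (a, b),
                  (lambda g: _unbroadcast(g, a.data.shape),
                   lambda g: _unbroadcast(g, b.data.shape)))


def sub(a: Tensor, b: Tensor) -> Tensor:
    return add(a, neg(_as_tensor(b)))


def neg(a: Tensor) -> Tensor:
    return Tensor(-a.data, (a,), (lambda g: neg(g),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return Tensor(a.data * b.data, (a, b),
                  (lambda g: _unbroadcast(mul(g, b), a.data.shape),
                   lambda g: _unbroadcast(mul(g, a), b.data.shape)))


def div(a: Tensor, b: Tensor) -> Tensor:
    return mul(_as_tensor(a), pow_const(_as_tensor(b), -1.0))


def add_const(a: Tensor, c) -> Tensor:
    return Tensor(a.data + c, (a,), (lambda g: g,))


def mul_const(a: Tensor, c) -> Tensor:
    return Tensor(a.data * c, (a,), (lambda g: mul_const(g, c),))


def pow_const(a: Tensor, p: float) -> Tensor:
    return Tensor(a.data ** p, (a,),
                  (lambda g: mul(g, mul_const(pow_const(a, p - 1.0), p)),))


def exp(a: Tensor) -> Tensor:
    out = Tensor(np.exp(a.data), (a,), ())
    out.vjps = (lambda g: mul(g, out),)
    return out


def log(a: Tensor) -> Tensor:
    return Tensor(np.log(a.data), (a,), (lambda g: mul(g, pow_const(a, -1.0)),))


def abs_(a: Tensor) -> Tensor:
    s = np.sign(a.data)
    return Tensor(np.abs(a.data), (a,), (lambda g: mul(g, constant(s)),))


def relu(a: Tensor) -> Tensor:
    m = (a.data > 0).astype(np.float64)
    return Tensor(a.data * m, (a,), (lambda g: mul(g, constant(m)),))


# ---------------------------------------------------------------------------
# reductions and shape ops


def sum_(a: Tensor, axis=None, keepdims=False) -> Tensor:
    ashape = a.data.shape

    def vjp(g):
        if axis is None:
            return broadcast_to(reshape(g, (1,) * len(ashape)), ashape)
        axes = axis if isinstance(axis, tuple) else (axis,)
        axes = tuple(ax % len(ashape) for ax in axes)
        if not keepdims:
            kshape = tuple(1 if i in axes else s for i, s in enumerate(ashape))
            g = reshape(g, kshape)
        return broadcast_to(g, ashape)

    return Tensor(np.sum(a.data, axis=axis, keepdims=keepdims), (a,), (vjp,))


def mean_(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul_const(sum_(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape
    return Tensor(a.data.reshape(shape), (a,), (lambda g: reshape(g, old),))


def broadcast_to(a: Tensor, shape) -> Tensor:
    old = a.data.shape
    return Tensor(np.broadcast_to(a.data, shape), (a,),
                  (lambda g: _unbroadcast(g, old),))


def transpose_last2(a: Tensor) -> Tensor:
    return Tensor(np.swapaxes(a.data, -1, -2), (a,),
                  (lambda g: transpose_last2(g),))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    ashape, bshape = a.data.shape, b.data.shape

    def vjp_a(g):
        return _unbroadcast(matmul(g, transpose_last2(b)), ashape)

    def vjp_b(g):
        return _unbroadcast(matmul(transpose_last2(a), g), bshape)

    return Tensor(np.matmul(a.data, b.data), (a, b), (vjp_a, vjp_b))


# ---------------------------------------------------------------------------
# gather / scatter (closed under differentiation: each is the other's VJP)


def take_flat(a: Tensor, idx: np.ndarray) -> Tensor:
    """Index the flattened array; output has ``idx.shape``."""
    size, shape = a.data.size, a.data.shape
    return Tensor(a.data.reshape(-1)[idx], (a,),
                  (lambda g: reshape(scatter_flat(g, idx, size), shape),))


def scatter_flat(g: Tensor, idx: np.ndarray, size: int) -> Tensor:
    out = np.zeros(size)
    np.add.at(out, idx.reshape(-1), g.data.reshape(-1))
    return Tensor(out, (g,), (lambda c: reshape(take_flat(c, idx), g.data.shape),))


def take_ax1(a: Tensor, idx: np.ndarray) -> Tensor:
    """``a[:, idx]`` for 2-D ``a``; output shape ``(a.shape[0],) + idx.shape``."""
    m = a.data.shape[1]
    return Tensor(a.data[:, idx], (a,), (lambda g: scatter_ax1(g, idx, m),))


def scatter_ax1(g: Tensor, idx: np.ndarray, m: int) -> Tensor:
    n = g.data.shape[0]
    out = np.zeros((n, m))
    np.add.at(out, (np.arange(n)[:, None], idx.reshape(-1)[None, :]),
              g.data.reshape(n, -1))
    return Tensor(out, (g,),
                  (lambda c: reshape(take_ax1(c, idx.reshape(-1)),
                                     g.data.shape),))


# ---------------------------------------------------------------------------
# convolution via im2col

_CONV_CACHE: dict = {}


def conv2d_indices(c, h, w, kh, kw, stride, pad):
    """Flat gather indices and validity mask for im2col on a (c, h, w) image.

    Out-of-bounds taps index position 0 and are zeroed by the mask, which
    implements zero padding without a dedicated pad op.
    """
    key = (c, h, w, kh, kw, stride, pad)
    if key in _CONV_CACHE:
        return _CONV_CACHE[key]
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    ci, di, dj = np.meshgrid(np.arange(c), np.arange(kh), np.arange(kw),
                             indexing="ij")
    ci, di, dj = ci.reshape(-1, 1), di.reshape(-1, 1), dj.reshape(-1, 1)
    oi, oj = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
    ri = oi.reshape(1, -1) * stride - pad + di
    rj = oj.reshape(1, -1) * stride - pad + dj
    valid = (ri >= 0) & (ri < h) & (rj >= 0) & (rj < w)
    flat = ci * (h * w) + np.clip(ri, 0, h - 1) * w + np.clip(rj, 0, w - 1)
    flat = np.where(valid, flat, 0)
    out = (flat, valid.astype(np.float64), ho, wo)
    _CONV_CACHE[key] = out
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, zero padding."""
    n, c, h, wd = x.data.shape
    o, cw, kh, kw = w.data.shape
    if c != cw:
        raise ValueError(f"channel mismatch: input {c}, kernel {cw}")
    idx, mask, ho, wo = conv2d_indices(c, h, wd, kh, kw, stride, pad)
    cols = take_ax1(reshape(x, (n, c * h * wd)), idx)      # (n, ckk, p)
    cols = mul(cols, constant(mask))
    out = matmul(reshape(w, (o, c * kh * kw)), cols)       # (n, o, p)
    if b is not None:
        out = add(out, reshape(b, (1, o, 1)))
    return reshape(out, (n, o, ho, wo))


# ---------------------------------------------------------------------------
# backward pass


def grad(out: Tensor, wrt, cotangent: Tensor | None = None):
    """Gradients of scalar ``out`` w.r.t. each tensor in ``wrt``.

    The returned gradients are themselves graph tensors built from primitive
    ops, so they can be differentiated again.
    """
    wrt = list(wrt)
    if out.data.size != 1 and cotangent is None:
        raise ValueError("grad of a non-scalar requires an explicit cotangent")

    # iterative post-order topological sort
    topo, state, stack = [], {}, [out]
    while stack:
        t = stack[-1]
        s = state.get(id(t), 0)
        if s == 0:
            state[id(t)] = 1
            for p in t.parents:
                if state.get(id(p), 0) == 0:
                    stack.append(p)
        else:
            stack.pop()
            if s == 1:
                state[id(t)] = 2
                topo.append(t)

    # mark nodes through which gradient must flow (reach some wrt leaf)
    needed = {id(t) for t in wrt}
    for t in topo:  # children appear after parents in post-order
        if id(t) not in needed and any(id(p) in needed for p in t.parents):
            needed.add(id(t))

    grads = {id(out): cotangent if cotangent is not None
             else constant(np.ones_like(out.data))}
    for t in reversed(topo):
        g = grads.get(id(t))
        if g is None or not t.parents:
            continue
        for p, vjp in zip(t.parents, t.vjps):
            if id(p) not in needed:
                continue
            pg = vjp(g)
            acc = grads.get(id(p))
            grads[id(p)] = pg if acc is None else add(acc, pg)

    return [grads.get(id(w_), constant(np.zeros_like(w_.data))) for w_ in wrt]
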