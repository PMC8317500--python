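"""Minimal reverse-mode autodiff on NumPy arrays.

Implements exactly the operator set the segmentation networks in this
package need: stride-1 "same" 2-D convolution, 2x2 max pooling, bilinear
resizing, ReLU/sigmoid, channel concatenation, elementwise arithmetic and
the reductions used by the Dice + cross-entropy objective.  Everything is
float32 and NCHW.

Gradients are accumulated on :class:`Var` leaves created with
``requires_grad=True``; call :meth:`Var.backward` on a scalar result.
"""

from __future__ import annotations

import functools

import numpy as np

__all__ = [
    "Var",
    "as_var",
    "conv2d",
    "relu",
    "sigmoid",
    "maxpool2",
    "resize_bilinear",
    "concat",
    "clip",
    "log",
    "vsum",
    "vmean",
    "softmax_pixels",
]


class Var:
    """A node in the computation tape: an array plus its gradient."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_back", "name")

    # defer ndarray <op> Var to the reflected Var operators
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad=False, parents=(), back=None, name=""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._back = back
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Var] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topological sort; graphs here can be deep
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._back is not None and node.grad is not None:
                node._back(node.grad)

    # -- elementwise arithmetic ------------------------------------------
    def __add__(self, other):
        return _binop(self, other, np.add, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binop(self, other, np.subtract, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return as_var(other) - self

    def __mul__(self, other):
        return _binop(self, other, np.multiply, lambda g, a, b: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binop(
            self, other, np.divide, lambda g, a, b: (g / b, -g * a / (b * b))
        )

    def __rtruediv__(self, other):
        return as_var(other) / self

    def __neg__(self):
        return self * -1.0

    def item(self):
        return float(self.data)


def as_var(x) -> Var:
    return x if isinstance(x, Var) else Var(x)


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (reverse of NumPy broadcasting)."""
    extra = g.ndim - len(shape)
    if extra:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _binop(a, b, fwd, bwd):
    a, b = as_var(a), as_var(b)
    out_data = fwd(a.data, b.data)

    def back(g):
        ga, gb = bwd(g, a.data, b.data)
        if a.requires_grad or a._parents:
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad or b._parents:
            b._accum(_unbroadcast(gb, b.data.shape))

    return Var(out_data, parents=(a, b), back=back)


def _unop(a, out_data, grad_fn):
    a = as_var(a)

    def back(g):
        if a.requires_grad or a._parents:
            a._accum(grad_fn(g))

    return Var(out_data, parents=(a,), back=back)


# -- activations ----------------------------------------------------------

def relu(x: Var) -> Var:
    x = as_var(x)
    mask = x.data > 0
    return _unop(x, np.where(mask, x.data, 0.0), lambda g: g * mask)


def sigmoid(x: Var) -> Var:
    x = as_var(x)
    d = x.data
    e = np.exp(-np.abs(d))  # stable for large |x|
    s = np.where(d >= 0, 1.0 / (1.0 + e), e / (1.0 + e)).astype(np.float32)
    return _unop(x, s, lambda g: g * s * (1.0 - s))


def softmax_pixels(x: Var) -> Var:
    """Softmax over the spatial dimensions of each (n, c) plane."""
    x = as_var(x)
    n, c, h, w = x.data.shape
    flat = x.data.reshape(n, c, h * w)
    flat = flat - flat.max(axis=2, keepdims=True)
    e = np.exp(flat)
    s = e / e.sum(axis=2, keepdims=True)

    def grad(g):
        gf = g.reshape(n, c, h * w)
        dot = (gf * s).sum(axis=2, keepdims=True)
        return (s * (gf - dot)).reshape(n, c, h, w)

    return _unop(x, s.reshape(n, c, h, w), grad)


def clip(x: Var, lo: float, hi: float) -> Var:
    x = as_var(x)
    mask = (x.data > lo) & (x.data < hi)
    return _unop(x, np.clip(x.data, lo, hi), lambda g: g * mask)


def log(x: Var) -> Var:
    x = as_var(x)
    return _unop(x, np.log(x.data), lambda g: g / x.data)


def vsum(x: Var) -> Var:
    x = as_var(x)
    return _unop(x, np.array(x.data.sum()), lambda g: np.broadcast_to(g, x.data.shape))


def vmean(x: Var) -> Var:
    x = as_var(x)
    n = x.data.size
    return _unop(
        x, np.array(x.data.mean()), lambda g: np.broadcast_to(g / n, x.data.shape)
    )


# -- structured ops -------------------------------------------------------

def _tap_regions(kh, kw, h, w):
    """Output/input slice pairs for each kernel tap of a same-padded,
    stride-1 convolution (out[o] += W_tap @ x[o + tap - pad])."""
    ph, pw = kh // 2, kw // 2
    for a in range(kh):
        for b in range(kw):
            da, db = a - ph, b - pw
            y0, y1 = max(0, -da), h - max(0, da)
            x0, x1 = max(0, -db), w - max(0, db)
            yield (a, b), (slice(y0, y1), slice(x0, x1)), (
                slice(y0 + da, y1 + da),
                slice(x0 + db, x1 + db),
            )


def _conv_fwd(x, w):
    """One batch-collapsed GEMM per kernel tap; no im2col materialisation."""
    n, c, h, wd = x.shape
    co, _, kh, kw = w.shape
    # channels-first flat layout so every tap is a single (co,c)@(c,n*h*w)
    xT = np.ascontiguousarray(x.transpose(1, 0, 2, 3)).reshape(c, n * h * wd)
    if kh == kw == 1:
        out = (w[:, :, 0, 0] @ xT).reshape(co, n, h, wd)
        return np.ascontiguousarray(out.transpose(1, 0, 2, 3))
    out = np.zeros((co, n, h, wd), dtype=np.float32)
    for (a, b), out_sl, in_sl in _tap_regions(kh, kw, h, wd):
        prod = (w[:, :, a, b] @ xT).reshape(co, n, h, wd)
        out[:, :, out_sl[0], out_sl[1]] += prod[:, :, in_sl[0], in_sl[1]]
    return np.ascontiguousarray(out.transpose(1, 0, 2, 3))


def _conv_grad_w(x, g, kh, kw):
    n, c, h, w = x.shape
    co = g.shape[1]
    ph, pw = kh // 2, kw // 2
    gT = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(co, n * h * w)
    xpT = np.pad(x.transpose(1, 0, 2, 3), ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    gw = np.empty((co, c, kh, kw), dtype=np.float32)
    for a in range(kh):
        for b in range(kw):
            xs = xpT[:, :, a : a + h, b : b + w].reshape(c, n * h * w)
            gw[:, :, a, b] = gT @ xs.T
    return gw


def conv2d(x: Var, w: Var) -> Var:
    """Stride-1, zero-padded "same" convolution; odd kernels only, no bias."""
    x, w = as_var(x), as_var(w)
    co, ci, kh, kw = w.data.shape
    if x.data.shape[1] != ci:
        raise ValueError(
            f"conv2d channel mismatch: input has {x.data.shape[1]}, kernel wants {ci}"
        )
    out_data = _conv_fwd(x.data, w.data)

    def back(g):
        g = np.ascontiguousarray(g, dtype=np.float32)
        if w.requires_grad or w._parents:
            w._accum(_conv_grad_w(x.data, g, kh, kw))
        if x.requires_grad or x._parents:
            # dL/dx is the correlation of g with the spatially flipped,
            # channel-transposed kernel (valid because stride 1 + same pad).
            w_rot = w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
            x._accum(_conv_fwd(g, np.ascontiguousarray(w_rot)))

    return Var(out_data, parents=(x, w), back=back)


def maxpool2(x: Var) -> Var:
    x = as_var(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {h}x{w}")
    xr = (
        x.data.reshape(n, c, h // 2, 2, w // 2, 2)
        .transpose(0, 1, 2, 4, 3, 5)
        .reshape(n, c, h // 2, w // 2, 4)
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def back(g):
        gr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(gr, idx[..., None], g[..., None], axis=-1)
        gx = (
            gr.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )
        x._accum(gx)

    return _with_back(x, out, back)


def _with_back(parent, out_data, back):
    def guarded(g):
        if parent.requires_grad or parent._parents:
            back(g)

    return Var(out_data, parents=(parent,), back=guarded)


@functools.lru_cache(maxsize=64)
def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear interpolation operator (half-pixel centres, edge clamp)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    for i in range(n_out):
        s = (i + 0.5) * n_in / n_out - 0.5
        f = int(np.floor(s))
        t = s - f
        i0 = min(max(f, 0), n_in - 1)
        i1 = min(max(f + 1, 0), n_in - 1)
        m[i, i0] += 1.0 - t
        m[i, i1] += t
    return m


def resize_bilinear(x: Var, out_h: int, out_w: int) -> Var:
    x = as_var(x)
    _, _, h, w = x.data.shape
    mh = _interp_matrix(out_h, h)
    mw = _interp_matrix(out_w, w)
    out = np.matmul(np.matmul(mh, x.data), mw.T)

    def back(g):
        x._accum(np.matmul(np.matmul(mh.T, g), mw))

    return _with_back(x, out, back)


def concat(vars_: list, axis: int = 1) -> Var:
    vars_ = [as_var(v) for v in vars_]
    out = np.concatenate([v.data for v in vars_], axis=axis)
    sizes = [v.data.shape[axis] for v in vars_]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        for v, piece in zip(vars_, np.split(g, splits, axis=axis)):
            if v.requires_grad or v._parents:
                v._accum(piece)

    return Var(out, parents=tuple(vars_), back=back)
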