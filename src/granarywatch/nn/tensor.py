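"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Runs in float64 by default (float32 via the :func:`default_dtype` context
for faster training).  The op set is exactly what the granarywatch models
need: dense algebra, the usual activations, stride-1 3D convolution, 2x
pooling, nearest-neighbour resizing, dropout, and fused losses.
Convolutions are im2col gathers feeding single BLAS GEMMs.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "default_dtype",
    "concat",
    "conv3d",
    "maxpool3d",
    "avgpool3d",
    "nearest_resize3d",
    "dropout",
    "softmax_cross_entropy",
    "bce_with_logits",
]


DTYPE = np.float64


@contextlib.contextmanager
def default_dtype(dtype):
    """Set the dtype used for new non-floating tensor leaves (e.g. float32
    for faster model training).  Floating-point inputs keep their dtype, so
    the precision of a model follows its parameters and input arrays."""
    global DTYPE
    old = DTYPE
    DTYPE = np.dtype(dtype)
    try:
        yield
    finally:
        DTYPE = old


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64) or arr.dtype != DTYPE and DTYPE == np.float32:
            arr = arr.astype(DTYPE)
        self.data = arr
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # -- graph plumbing ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _child(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _wrap(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._child(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return self._child(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._child(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor._wrap(other).pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        out_data = self.data**exponent

        def bw(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        return self._child(out_data, (self,), bw)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        if self.ndim != 2 or other.ndim != 2:
            raise ValueError("matmul supports 2D operands only")

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._child(self.data @ other.data, (self, other), bw)

    # -- activations ---------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._child(self.data * mask, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._child(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return self._child(out_data, (self,), bw)

    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._child(out_data, (self,), bw)

    def log(self):
        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._child(np.log(self.data), (self,), bw)

    def sqrt(self):
        return self.pow(0.5)

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._child(self.data.reshape(shape), (self,), bw)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._child(self.data.transpose(axes), (self,), bw)

    def __getitem__(self, index):
        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, index, g)
                self._accum(full)

        return self._child(self.data[index], (self,), bw)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.shape).copy())

        return self._child(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


# -- multi-input / structured ops --------------------------------------


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = bw
    return out


_IM2COL_CACHE: dict = {}


def _gather_idx(sp: tuple, ksz: tuple):
    """Cached (S, k) flat gather index for valid windows of `ksz` over `sp`."""
    key = (tuple(sp), tuple(ksz))
    cached = _IM2COL_CACHE.get(key)
    if cached is None:
        ox, oy, oz = (s - k + 1 for s, k in zip(sp, ksz))
        base = (
            np.arange(ox)[:, None, None] * sp[1] * sp[2]
            + np.arange(oy)[None, :, None] * sp[2]
            + np.arange(oz)[None, None, :]
        ).ravel()
        off = (
            np.arange(ksz[0])[:, None, None] * sp[1] * sp[2]
            + np.arange(ksz[1])[None, :, None] * sp[2]
            + np.arange(ksz[2])[None, None, :]
        ).ravel()
        cached = (base[:, None] + off[None, :], (ox, oy, oz))
        _IM2COL_CACHE[key] = cached
    return cached


def _im2col_cl(x_cl: np.ndarray, sp: tuple, ksz: tuple):
    """Channels-last im2col: (B, P, C) flat input -> ((B*S, k*C), out dims).

    The gather lands directly in (B, S, k, C) order, so the reshape to the
    GEMM matrix is copy-free.
    """
    idx, osh = _gather_idx(sp, ksz)
    cols = np.take(x_cl, idx.ravel(), axis=1)  # (B, S*k, C)
    B, _, C = cols.shape
    return cols.reshape(B * idx.shape[0], idx.shape[1] * C), osh


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, padding=0) -> Tensor:
    """Stride-1 3D convolution. x: (B,C,X,Y,Z); w: (O,C,kx,ky,kz); b: (O,).

    Internally channels-last: one transpose of the padded input, one gather,
    one GEMM per direction.  The input gradient is the full correlation with
    the flipped, channel-swapped kernel; im2col columns are cached for the
    weight gradient.
    """
    if isinstance(padding, int):
        padding = (padding, padding, padding)
    px, py, pz = padding
    ksz = tuple(w.shape[2:])
    k = int(np.prod(ksz))
    O, C = w.shape[0], w.shape[1]
    B = x.shape[0]
    xp = np.pad(x.data, ((0, 0), (0, 0), (px, px), (py, py), (pz, pz)))
    sp = xp.shape[2:]
    x_cl = np.ascontiguousarray(np.moveaxis(xp, 1, -1)).reshape(B, -1, C)
    needs_grad = any(p.requires_grad for p in (x, w))
    cols, (ox, oy, oz) = _im2col_cl(x_cl, sp, ksz)
    # weight matrix in (k, C) row order to match the gathered columns
    w_mat = w.data.transpose(2, 3, 4, 1, 0).reshape(k * C, O)
    y = cols @ w_mat  # (B*S, O)
    if b is not None:
        y += b.data
    y = np.moveaxis(y.reshape(B, ox, oy, oz, O), -1, 1)
    if not needs_grad and (b is None or not b.requires_grad):
        return Tensor(y)
    cache = cols if w.requires_grad else None

    def bw(g):
        g_cl = np.ascontiguousarray(np.moveaxis(g, 1, -1))  # (B, ox, oy, oz, O)
        g2 = g_cl.reshape(-1, O)
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=0))
        if w.requires_grad:
            dw = (cache.T @ g2).reshape(*ksz, C, O)
            w._accum(dw.transpose(4, 3, 0, 1, 2))
        if x.requires_grad:
            kx, ky, kz = ksz
            gp = np.pad(
                g_cl,
                ((0, 0), (kx - 1, kx - 1), (ky - 1, ky - 1), (kz - 1, kz - 1), (0, 0)),
            )
            gsp = gp.shape[1:4]
            gcols, (fx, fy, fz) = _im2col_cl(gp.reshape(B, -1, O), gsp, ksz)
            # flipped kernel, channels swapped, (k, O) row order
            wf = np.flip(w.data, axis=(2, 3, 4)).transpose(2, 3, 4, 0, 1).reshape(k * O, C)
            dxp = gcols @ wf  # (B * P, C)
            dxp = np.moveaxis(dxp.reshape(B, fx, fy, fz, C), -1, 1)
            sx = slice(px, dxp.shape[2] - px) if px else slice(None)
            sy = slice(py, dxp.shape[3] - py) if py else slice(None)
            sz = slice(pz, dxp.shape[4] - pz) if pz else slice(None)
            x._accum(dxp[:, :, sx, sy, sz])

    out = Tensor(y)
    out.requires_grad = True
    out._parents = (x, w) if b is None else (x, w, b)
    out._backward = bw
    return out


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, mean: np.ndarray, var: np.ndarray,
              eps: float = 1e-5, batch_stats: bool = True) -> Tensor:
    """Channel-axis-1 batch normalization with supplied statistics.

    With ``batch_stats=True`` the statistics are treated as functions of x
    (training); with ``batch_stats=False`` they are constants (evaluation
    with running statistics).
    """
    axes = (0,) + tuple(range(2, x.ndim))
    shp = (1, -1) + (1,) * (x.ndim - 2)
    mean = np.asarray(mean, dtype=x.data.dtype)
    var = np.asarray(var, dtype=x.data.dtype)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(shp)) * inv_std.reshape(shp)
    y = xhat * gamma.data.reshape(shp) + beta.data.reshape(shp)
    n = x.data.size // x.shape[1]

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gamma.data.reshape(shp)
            if batch_stats:
                s1 = dxhat.sum(axis=axes, keepdims=True)
                s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
                dx = (dxhat - s1 / n - xhat * s2 / n) * inv_std.reshape(shp)
            else:
                dx = dxhat * inv_std.reshape(shp)
            x._accum(dx)

    return x._child(y, (x, gamma, beta), bw)


def _pool_view(x: np.ndarray, k: int):
    B, C = x.shape[:2]
    ox, oy, oz = (s // k for s in x.shape[2:])
    xc = x[:, :, : ox * k, : oy * k, : oz * k]
    r = xc.reshape(B, C, ox, k, oy, k, oz, k)
    r = r.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(B, C, ox, oy, oz, k**3)
    return r, (ox, oy, oz)


def _pool_unview(flat: np.ndarray, in_shape, k: int):
    B, C = in_shape[:2]
    ox, oy, oz = (s // k for s in in_shape[2:])
    r = flat.reshape(B, C, ox, oy, oz, k, k, k)
    r = r.transpose(0, 1, 2, 5, 3, 6, 4, 7).reshape(B, C, ox * k, oy * k, oz * k)
    full = np.zeros(in_shape, dtype=flat.dtype)
    full[:, :, : ox * k, : oy * k, : oz * k] = r
    return full


def maxpool3d(x: Tensor, k: int = 2) -> Tensor:
    r, out_sp = _pool_view(x.data, k)
    if min(out_sp) < 1:
        raise ValueError(f"maxpool3d: spatial dims {x.shape[2:]} too small for kernel {k}")
    idx = r.argmax(axis=-1)
    y = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        if not x.requires_grad:
            return
        flat = np.zeros_like(r)
        np.put_along_axis(flat, idx[..., None], g[..., None], axis=-1)
        x._accum(_pool_unview(flat, x.shape, k))

    out = Tensor(y)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = bw
    return out


def avgpool3d(x: Tensor, k: int = 2) -> Tensor:
    r, out_sp = _pool_view(x.data, k)
    if min(out_sp) < 1:
        raise ValueError(f"avgpool3d: spatial dims {x.shape[2:]} too small for kernel {k}")
    y = r.mean(axis=-1)

    def bw(g):
        if not x.requires_grad:
            return
        flat = np.repeat(g[..., None] / k**3, k**3, axis=-1)
        x._accum(_pool_unview(flat, x.shape, k))

    out = Tensor(y)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = bw
    return out


def nearest_resize3d(x: Tensor, out_shape) -> Tensor:
    """Nearest-neighbour spatial resize of (B,C,X,Y,Z) to (B,C,*out_shape)."""
    in_sp = x.shape[2:]
    maps = [
        np.minimum((np.arange(o) * i) // o, i - 1).astype(int)
        for o, i in zip(out_shape, in_sp)
    ]
    ix, iy, iz = maps
    y = x.data[:, :, ix[:, None, None], iy[None, :, None], iz[None, None, :]]

    def bw(g):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        np.add.at(
            dx,
            (slice(None), slice(None), ix[:, None, None], iy[None, :, None], iz[None, None, :]),
            g,
        )
        x._accum(dx)

    out = Tensor(y)
    if x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)
        out._backward = bw
    return out


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0:
        return x
    mask = ((rng.random(x.shape) >= p) / (1.0 - p)).astype(x.data.dtype)

    def bw(g):
        if x.requires_grad:
            x._accum(g * mask)

    return x._child(x.data * mask, (x,), bw)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray, weights: np.ndarray | None = None) -> Tensor:
    """Mean (optionally class-weighted) cross-entropy over a (B, K) logit batch."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    B = z.shape[0]
    w = np.ones(B, dtype=z.dtype) if weights is None else np.asarray(weights, dtype=z.dtype)[labels]
    losses = lse - z[np.arange(B), labels]
    loss = float((w * losses).mean())

    def bw(g):
        if not logits.requires_grad:
            return
        soft = np.exp(z - zmax)
        soft /= soft.sum(axis=1, keepdims=True)
        soft[np.arange(B), labels] -= 1.0
        logits._accum(g * soft * (w / B)[:, None])

    return logits._child(np.array(loss), (logits,), bw)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    z = logits.data
    t = np.asarray(targets, dtype=z.dtype)
    loss = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))

    def bw(g):
        if not logits.requires_grad:
            return
        sig = 1.0 / (1.0 + np.exp(-z))
        logits._accum(g * (sig - t) / z.size)

    return logits._child(np.array(loss), (logits,), bw)
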