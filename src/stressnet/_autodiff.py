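"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Provides exactly the operator set the water-stress classifier needs:
broadcast-aware elementwise arithmetic, matrix products, the sigmoid/tanh/
rectifier nonlinearities, reductions, shape ops, 2-D convolution (im2col),
max / adaptive-average pooling, and deformable convolution with bilinear
offset sampling.  Gradients are accumulated by topological sweep from the
loss tensor.  All arithmetic is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "deform_conv2d", "maxpool2d", "adaptive_avgpool2d",
           "stack", "softmax", "clip_min"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
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
            if t._backward is not None:
                t._backward()
        # free the graph: backward closures reference their output tensor,
        # forming cycles that would otherwise wait for the cycle collector
        for t in topo:
            t._backward = None
            t._parents = ()

    def zero_grad(self):
        self.grad = None

    # -- shape / dtype conveniences ---------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor._make(self.data + other.data, (self, other), None)

        def back():
            if self.requires_grad:
                self._accum(out.grad)
            if other.requires_grad:
                other._accum(out.grad)
        out._backward = back if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,), None)

        def back():
            if self.requires_grad:
                self._accum(-out.grad)
        out._backward = back if out.requires_grad else None
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor._make(self.data * other.data, (self, other), None)

        def back():
            if self.requires_grad:
                self._accum(out.grad * other.data)
            if other.requires_grad:
                other._accum(out.grad * self.data)
        out._backward = back if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor._make(self.data / other.data, (self, other), None)

        def back():
            if self.requires_grad:
                self._accum(out.grad / other.data)
            if other.requires_grad:
                other._accum(-out.grad * self.data / other.data ** 2)
        out._backward = back if out.requires_grad else None
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor._make(self.data @ other.data, (self, other), None)

        def back():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)
        out._backward = back if out.requires_grad else None
        return out

    # -- nonlinearities ----------------------------------------------------
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._make(s, (self,), None)

        def back():
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 - s))
        out._backward = back if out.requires_grad else None
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor._make(t, (self,), None)

        def back():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - t * t))
        out._backward = back if out.requires_grad else None
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor._make(self.data * mask, (self,), None)

        def back():
            if self.requires_grad:
                self._accum(out.grad * mask)
        out._backward = back if out.requires_grad else None
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor._make(e, (self,), None)

        def back():
            if self.requires_grad:
                self._accum(out.grad * e)
        out._backward = back if out.requires_grad else None
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)

        def back():
            if self.requires_grad:
                self._accum(out.grad / self.data)
        out._backward = back if out.requires_grad else None
        return out

    # -- reductions / shape ops -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def back():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = back if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor._make(self.data.reshape(shape), (self,), None)

        def back():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))
        out._backward = back if out.requires_grad else None
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor._make(self.data.transpose(axes), (self,), None)

        def back():
            if self.requires_grad:
                inv = np.argsort(axes) if axes else None
                self._accum(out.grad.transpose(inv))
        out._backward = back if out.requires_grad else None
        return out

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,), None)

        def back():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)
        out._backward = back if out.requires_grad else None
        return out


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def stack(tensors, axis=0) -> Tensor:
    """Stack tensors along a new axis."""
    data = np.stack([t.data for t in tensors], axis=axis)
    out = Tensor._make(data, tuple(tensors), None)

    def back():
        grads = np.split(out.grad, len(tensors), axis=axis)
        for t, g in zip(tensors, grads):
            if t.requires_grad:
                t._accum(np.squeeze(g, axis=axis))
    out._backward = back if out.requires_grad else None
    return out


def clip_min(x: Tensor, lo: float) -> Tensor:
    """max(x, lo); gradient passes only where x > lo."""
    mask = x.data > lo
    out = Tensor._make(np.maximum(x.data, lo), (x,), None)

    def back():
        if x.requires_grad:
            x._accum(out.grad * mask)
    out._backward = back if out.requires_grad else None
    return out


def softmax(x: Tensor, axis=-1) -> Tensor:
    """Numerically stable softmax along `axis` (max shift is a constant)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


# -- convolution -------------------------------------------------------------

def _conv_out_size(n, k, p, s):
    return (n + 2 * p - k) // s + 1


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1,
           padding: int = 0) -> Tensor:
    """Standard 2-D convolution (cross-correlation), NCHW layout."""
    N, C, H, W = x.shape
    O, Cw, kh, kw = w.shape
    if Cw != C:
        raise ValueError(f"channel mismatch: input {C}, weights {Cw}")
    OH, OW = _conv_out_size(H, kh, padding, stride), _conv_out_size(W, kw, padding, stride)
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    K = kh * kw
    cols = np.empty((N, C, K, OH, OW))
    for t in range(K):
        u, v = divmod(t, kw)
        cols[:, :, t] = xp[:, :, u:u + OH * stride:stride, v:v + OW * stride:stride]
    wr = w.data.reshape(O, C * K)
    out_data = (wr @ cols.reshape(N, C * K, OH * OW)).reshape(N, O, OH, OW)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._make(out_data, parents, None)

    def back():
        g = out.grad  # (N,O,OH,OW)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        gflat = g.reshape(N, O, OH * OW)
        if w.requires_grad:
            dw = np.einsum("nol,ncl->oc", gflat, cols.reshape(N, C * K, OH * OW))
            w._accum(dw.reshape(O, C, kh, kw))
        if x.requires_grad:
            dcols = np.einsum("oc,nol->ncl", wr, gflat).reshape(N, C, K, OH, OW)
            dxp = np.zeros_like(xp)
            for t in range(K):
                u, v = divmod(t, kw)
                dxp[:, :, u:u + OH * stride:stride, v:v + OW * stride:stride] += dcols[:, :, t]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)
    out._backward = back if out.requires_grad else None
    return out


def maxpool2d(x: Tensor, k: int, stride: int) -> Tensor:
    """Max pooling, no padding."""
    N, C, H, W = x.shape
    OH, OW = (H - k) // stride + 1, (W - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x.data, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N,C,OH,OW,k,k)
    flat = win.reshape(N, C, OH, OW, k * k)
    arg = flat.argmax(axis=-1)
    out = Tensor._make(flat.max(axis=-1), (x,), None)

    def back():
        if not x.requires_grad:
            return
        g = np.zeros_like(x.data)
        du, dv = np.divmod(arg, k)
        ii = np.arange(OH)[None, None, :, None] * stride + du
        jj = np.arange(OW)[None, None, None, :] * stride + dv
        nn = np.arange(N)[:, None, None, None]
        cc = np.arange(C)[None, :, None, None]
        np.add.at(g, (nn, cc, ii, jj), out.grad)
        x._accum(g)
    out._backward = back if out.requires_grad else None
    return out


def adaptive_avgpool2d(x: Tensor, out_hw: tuple) -> Tensor:
    """Average pooling to a fixed output grid with near-equal bins."""
    N, C, H, W = x.shape
    oh, ow = out_hw
    hb = [(int(np.floor(i * H / oh)), int(np.ceil((i + 1) * H / oh))) for i in range(oh)]
    wb = [(int(np.floor(j * W / ow)), int(np.ceil((j + 1) * W / ow))) for j in range(ow)]
    out_data = np.empty((N, C, oh, ow))
    for i, (h0, h1) in enumerate(hb):
        for j, (w0, w1) in enumerate(wb):
            out_data[:, :, i, j] = x.data[:, :, h0:h1, w0:w1].mean(axis=(2, 3))
    out = Tensor._make(out_data, (x,), None)

    def back():
        if not x.requires_grad:
            return
        g = np.zeros_like(x.data)
        for i, (h0, h1) in enumerate(hb):
            for j, (w0, w1) in enumerate(wb):
                area = (h1 - h0) * (w1 - w0)
                g[:, :, h0:h1, w0:w1] += out.grad[:, :, i, j][:, :, None, None] / area
        x._accum(g)
    out._backward = back if out.requires_grad else None
    return out


# -- deformable convolution ---------------------------------------------------

def _bilinear_gather(xd: np.ndarray, py: np.ndarray, px: np.ndarray):
    """Sample xd (N,C,H,W) at fractional (py,px) of shape (N,OH,OW).

    Out-of-bounds neighbours contribute zero (zero padding).  Returns the
    sampled values (N,C,OH,OW) plus the pieces needed for the backward pass.
    """
    N, C, H, W = xd.shape
    y0 = np.floor(py).astype(np.int64)
    x0 = np.floor(px).astype(np.int64)
    fy, fx = py - y0, px - x0
    nn = np.arange(N)[:, None, None]
    vals, coefs, idxs = [], [], []
    for dy, dx, cf in ((0, 0, (1 - fy) * (1 - fx)), (0, 1, (1 - fy) * fx),
                       (1, 0, fy * (1 - fx)), (1, 1, fy * fx)):
        yy, xx = y0 + dy, x0 + dx
        valid = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
        yc, xc = np.clip(yy, 0, H - 1), np.clip(xx, 0, W - 1)
        v = xd[nn, :, yc, xc]                       # (N,OH,OW,C)
        v = np.where(valid[..., None], v, 0.0).transpose(0, 3, 1, 2)
        vals.append(v)
        coefs.append(np.where(valid, cf, 0.0))
        idxs.append((yc, xc, valid))
    sampled = sum(v * c[:, None] for v, c in zip(vals, coefs))
    return sampled, vals, coefs, idxs, (fy, fx)


def deform_conv2d(x: Tensor, w: Tensor, b: Tensor | None, offsets: Tensor,
                  stride: int = 1, padding: int = 0) -> Tensor:
    """Deformable 2-D convolution.

    Each kernel tap a_i at output location a_0 samples the input at
    a_0 + a_i + Δa_i, with the fractional offsets Δa_i supplied per tap and
    per output location through `offsets` (layout: channel 2t is the row
    offset of tap t, channel 2t+1 the column offset; taps row-major).
    Sampling is bilinear with zero padding outside the map, so with all
    offsets zero the operation equals a standard convolution.
    """
    N, C, H, W = x.shape
    O, Cw, kh, kw = w.shape
    K = kh * kw
    if offsets.shape[1] != 2 * K:
        raise ValueError(f"offset channels {offsets.shape[1]} != 2*taps {2 * K}")
    OH, OW = _conv_out_size(H, kh, padding, stride), _conv_out_size(W, kw, padding, stride)
    if offsets.shape[2:] != (OH, OW):
        raise ValueError("offset field does not match the output grid")

    base_i = np.arange(OH)[:, None] * stride - padding
    base_j = np.arange(OW)[None, :] * stride - padding
    cols = np.empty((N, C, K, OH, OW))
    cache = []
    for t in range(K):
        u, v = divmod(t, kw)
        py = base_i[None] + u + offsets.data[:, 2 * t]
        px = base_j[None] + v + offsets.data[:, 2 * t + 1]
        sampled, vals, coefs, idxs, fr = _bilinear_gather(x.data, py, px)
        cols[:, :, t] = sampled
        cache.append((vals, coefs, idxs, fr))
    wr = w.data.reshape(O, C * K)
    out_data = (wr @ cols.reshape(N, C * K, OH * OW)).reshape(N, O, OH, OW)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w, offsets) if b is None else (x, w, offsets, b)
    out = Tensor._make(out_data, parents, None)

    def back():
        g = out.grad
        gflat = g.reshape(N, O, OH * OW)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.einsum("nol,ncl->oc", gflat, cols.reshape(N, C * K, OH * OW))
            w._accum(dw.reshape(O, C, kh, kw))
        need_x = x.requires_grad
        need_off = offsets.requires_grad
        if not (need_x or need_off):
            return
        dcols = np.einsum("oc,nol->ncl", wr, gflat).reshape(N, C, K, OH, OW)
        dx = np.zeros((N, C, H * W)) if need_x else None
        doff = np.zeros_like(offsets.data) if need_off else None
        nn = np.arange(N)[:, None, None, None]
        cc = np.arange(C)[None, :, None, None]
        for t in range(K):
            vals, coefs, idxs, (fy, fx) = cache[t]
            ds = dcols[:, :, t]                      # (N,C,OH,OW)
            if need_x:
                for (yc, xc, valid), cf in zip(idxs, coefs):
                    flat = (yc * W + xc)[:, None]    # (N,1,OH,OW)
                    contrib = ds * cf[:, None]
                    np.add.at(dx, (nn, cc, np.broadcast_to(flat, ds.shape)), contrib)
            if need_off:
                v00, v01, v10, v11 = vals
                # derivative of the bilinear formula w.r.t. fractional coords;
                # out-of-bounds neighbour values are already zeroed
                d_dy = (v10 - v00) * (1 - fx)[:, None] + (v11 - v01) * fx[:, None]
                d_dx = (v01 - v00) * (1 - fy)[:, None] + (v11 - v10) * fy[:, None]
                doff[:, 2 * t] += (ds * d_dy).sum(axis=1)
                doff[:, 2 * t + 1] += (ds * d_dx).sum(axis=1)
        if need_x:
            x._accum(dx.reshape(N, C, H, W))
        if need_off:
            offsets._accum(doff)
    out._backward = back if out.requires_grad else None
    return out
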