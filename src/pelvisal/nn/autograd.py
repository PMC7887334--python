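"""Minimal reverse-mode autodiff on NumPy arrays.

Just enough machinery for a small convolutional pyramid network: a
:class:`Tensor` wrapping an ``ndarray``, a handful of differentiable ops
(convolution via im2col, ReLU, pooling, nearest upsampling, concatenation,
pixel-wise binary cross-entropy from logits) and topological backprop.
Everything is float32 end to end; gradients are accumulated densely.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "conv2d",
    "relu",
    "add",
    "concat",
    "maxpool2",
    "upsample2",
    "bce_with_logits",
    "add_scalars",
]

_DTYPE = np.float32

# im2col buffers above this many elements take a chunked inference-only path
_CHUNK_ELEMS = 48_000_000


class Tensor:
    """An array node in the autodiff tape."""

    __slots__ = ("data", "grad", "parents", "_bwd", "requires_grad")

    def __init__(self, data, requires_grad=False, parents=(), bwd=None):
        self.data = np.asarray(data, dtype=_DTYPE)
        self.grad = None
        self.parents = parents
        self._bwd = bwd
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        order = []
        seen = set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t.parents:
                visit(p)
            order.append(t)

        visit(self)
        for t in order:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._bwd is not None:
                t._bwd(t.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(_DTYPE, copy=True)
        else:
            self.grad += g


def parameter(data):
    return Tensor(np.asarray(data, dtype=_DTYPE), requires_grad=True)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# im2col convolution

def _im2col(x, kh, kw, stride, ph, pw):
    n, c, h, w = x.shape
    ho = (h + 2 * ph - kh) // stride + 1
    wo = (w + 2 * pw - kw) // stride + 1
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=_DTYPE)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride]
    return cols.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(gcols, x_shape, kh, kw, stride, ph, pw, ho, wo):
    n, c, h, w = x_shape
    gxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=_DTYPE)
    gcols = gcols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            gxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += gcols[:, :, i, j]
    if ph or pw:
        return gxp[:, :, ph : ph + h, pw : pw + w]
    return gxp


def _conv_forward_chunked(x, w2, b, kh, kw, stride, ph, pw):
    """Inference-only convolution, chunking output rows to bound memory."""
    n, c, h, wd = x.shape
    ho = (h + 2 * ph - kh) // stride + 1
    wo = (wd + 2 * pw - kw) // stride + 1
    cout = w2.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x
    out = np.empty((n, cout, ho, wo), dtype=_DTYPE)
    rows_per_chunk = max(1, _CHUNK_ELEMS // max(1, n * c * kh * kw * wo))
    for r0 in range(0, ho, rows_per_chunk):
        r1 = min(ho, r0 + rows_per_chunk)
        cols = np.empty((n, c, kh, kw, r1 - r0, wo), dtype=_DTYPE)
        for i in range(kh):
            for j in range(kw):
                cols[:, :, i, j] = xp[
                    :, :, r0 * stride + i : r0 * stride + i + (r1 - r0) * stride : stride,
                    j : j + wo * stride : stride,
                ]
        flat = cols.reshape(n, c * kh * kw, (r1 - r0) * wo)
        y = np.matmul(w2, flat) + b[None, :, None]
        out[:, :, r0:r1] = y.reshape(n, cout, r1 - r0, wo)
    return out


def conv2d(x, w, b, stride=1, padding="same"):
    """2-D convolution (cross-correlation), NCHW layout.

    ``w`` has shape (cout, cin, kh, kw); ``padding='same'`` pads so an odd
    kernel at stride 1 preserves the spatial size (at stride 2, halves it).
    """
    x = _as_tensor(x)
    cout, cin, kh, kw = w.shape
    if padding == "same":
        ph, pw = kh // 2, kw // 2
    else:
        ph = pw = int(padding)
    w2 = w.data.reshape(cout, cin * kh * kw)
    n, c, h, wd = x.shape
    if c != cin:
        raise ValueError(f"conv2d: expected {cin} input channels, got {c}")

    need_grad = x.requires_grad or w.requires_grad or b.requires_grad
    ho = (h + 2 * ph - kh) // stride + 1
    wo = (wd + 2 * pw - kw) // stride + 1
    if not need_grad and n * c * kh * kw * ho * wo > _CHUNK_ELEMS:
        out = _conv_forward_chunked(x.data, w2, b.data, kh, kw, stride, ph, pw)
        return Tensor(out)

    cols, ho, wo = _im2col(x.data, kh, kw, stride, ph, pw)
    y = np.matmul(w2, cols) + b.data[None, :, None]
    out = Tensor(y.reshape(n, cout, ho, wo), parents=(x, w, b))

    def bwd(g):
        g2 = g.reshape(n, cout, ho * wo)
        if w.requires_grad:
            w._accum(np.einsum("nop,nkp->ok", g2, cols, optimize=True).reshape(w.shape))
        if b.requires_grad:
            b._accum(g2.sum(axis=(0, 2)))
        if x.requires_grad:
            gcols = np.matmul(w2.T, g2)
            x._accum(_col2im(gcols, x.data.shape, kh, kw, stride, ph, pw, ho, wo))

    out._bwd = bwd
    return out


def relu(x):
    x = _as_tensor(x)
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * mask)

    out._bwd = bwd
    return out


def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a._accum(g)
        if b.requires_grad:
            b._accum(g)

    out._bwd = bwd
    return out


def concat(tensors):
    """Concatenate along the channel axis (NCHW)."""
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=1), parents=tuple(tensors))
    sizes = [t.shape[1] for t in tensors]

    def bwd(g):
        off = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                t._accum(g[:, off : off + s])
            off += s

    out._bwd = bwd
    return out


def maxpool2(x):
    """2x2 max pooling with stride 2."""
    x = _as_tensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2 requires even spatial dimensions")
    h2, w2 = h // 2, w // 2
    r = x.data.reshape(n, c, h2, 2, w2, 2)
    out_data = r.max(axis=(3, 5))
    out = Tensor(out_data, parents=(x,))
    # window elements as a trailing length-4 axis, row-major within the window
    flat = (r == out_data[:, :, :, None, :, None]).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
    first = np.zeros_like(flat)
    np.put_along_axis(first, flat.argmax(axis=-1)[..., None], True, axis=-1)
    win_mask = first.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)

    def bwd(g):
        if x.requires_grad:
            gx = win_mask * g[:, :, :, None, :, None]
            x._accum(gx.reshape(n, c, h, w))

    out._bwd = bwd
    return out


def upsample2(x):
    """Nearest-neighbour 2x spatial upsampling."""
    x = _as_tensor(x)
    n, c, h, w = x.shape
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3), parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    out._bwd = bwd
    return out


def instance_norm(x, eps=1e-5):
    """Per-sample, per-channel spatial standardization (no affine)."""
    x = _as_tensor(x)
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (x.data - mu) * inv
    out = Tensor(y, parents=(x,))

    def bwd(g):
        if x.requires_grad:
            gm = g.mean(axis=(2, 3), keepdims=True)
            gym = (g * y).mean(axis=(2, 3), keepdims=True)
            x._accum(inv * (g - gm - y * gym))

    out._bwd = bwd
    return out


def bce_with_logits(logits, target, weight=1.0):
    """Mean pixel-wise binary cross-entropy from logits, times ``weight``.

    Uses the numerically stable log-sum-exp form
    ``max(z,0) - z*t + log(1+exp(-|z|))``.
    """
    logits = _as_tensor(logits)
    z = logits.data
    t = np.asarray(target, dtype=_DTYPE)
    if z.shape != t.shape:
        raise ValueError(f"bce_with_logits: shape mismatch {z.shape} vs {t.shape}")
    per_pixel = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    scale = weight / z.size
    out = Tensor(np.float64(per_pixel.sum()) * scale, parents=(logits,))

    def bwd(g):
        if logits.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-z))
            logits._accum((g * scale) * (sig - t))

    out._bwd = bwd
    return out


def add_scalars(terms):
    """Sum a list of scalar tensors."""
    out = Tensor(sum(float(t.data) for t in terms), parents=tuple(terms))

    def bwd(g):
        for t in terms:
            if t.requires_grad:
                t._accum(np.asarray(g, dtype=_DTYPE))

    out._bwd = bwd
    return out
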