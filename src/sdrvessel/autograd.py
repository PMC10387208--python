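"""Compact reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operations the segmentation network needs: broadcasted
arithmetic, ReLU/sigmoid/log/clip, reductions, channel softmax, 2-D convolution
(with dilation), 2x2 max pooling, bilinear upsampling, 2x2-stride-2 transposed
convolution, batch normalization and channel concatenation.  Tensors carry the
dtype of the data they are built from (float32 in the network, float64 in
gradient-check tests).

Gradients are accumulated by a tape: each operation returns a ``Tensor`` whose
``_backward`` closure scatters the output gradient to its parents;
``Tensor.backward`` walks the tape in reverse topological order.
"""

from __future__ import annotations

import contextlib
from functools import lru_cache

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "relu",
    "sigmoid",
    "log",
    "clip",
    "softmax_channels",
    "concat_channels",
    "conv2d",
    "conv_transpose2x2",
    "max_pool2x2",
    "upsample_bilinear",
    "batch_norm",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference fast path)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_array(data):
    a = np.asarray(data)
    if a.dtype.kind in "iub":
        a = a.astype(np.float32)
    return a


class Tensor:
    """N-d array with an optional gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- construction -----------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # -- basic introspection ----------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"

    # -- autodiff ----------------------------------------------------------
    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar tensor")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p._backward is not None or p.requires_grad:
                    stack.append((p, False))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic ---------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_sum_to_shape(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_sum_to_shape(-g * self.data / other.data**2, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape))

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(np.asarray(g).reshape(self.data.shape))

        return Tensor._make(out_data, (self,), backward)


def _sum_to_shape(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reverse NumPy broadcasting: reduce ``g`` down to ``shape``."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _ensure_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- pointwise nonlinearities --------------------------------------------------

def relu(x: Tensor) -> Tensor:
    x = _ensure_tensor(x)
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._make(out_data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    x = _ensure_tensor(x)
    # numerically stable in both tails
    out_data = np.empty_like(x.data)
    pos = x.data >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-x.data[pos]))
    ex = np.exp(x.data[~pos])
    out_data[~pos] = ex / (1.0 + ex)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * out_data * (1.0 - out_data))

    return Tensor._make(out_data, (x,), backward)


def log(x: Tensor) -> Tensor:
    x = _ensure_tensor(x)
    out_data = np.log(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g / x.data)

    return Tensor._make(out_data, (x,), backward)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through unclamped entries."""
    x = _ensure_tensor(x)
    out_data = np.clip(x.data, lo, hi)
    mask = (x.data >= lo) & (x.data <= hi)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._make(out_data, (x,), backward)


def softmax_channels(x: Tensor, axis: int = 1) -> Tensor:
    x = _ensure_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accumulate(s * (g - dot))

    return Tensor._make(s, (x,), backward)


def concat_channels(tensors) -> Tensor:
    tensors = [_ensure_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=1)
    splits = np.cumsum([t.data.shape[1] for t in tensors])[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=1)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(p)

    return Tensor._make(out_data, tuple(tensors), backward)


# -- convolutions ----------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, dilation: int = 1) -> Tensor:
    """'Same' 2-D convolution (cross-correlation) in NCHW layout.

    ``weight`` has shape (C_out, C_in, k, k); padding is ``dilation * (k // 2)``
    so spatial size is preserved for odd k.  The k*k kernel taps are applied as
    shifted views with one BLAS contraction each, which keeps memory flat.
    """
    x = _ensure_tensor(x)
    weight = _ensure_tensor(weight)
    co, ci, kh, kw = weight.data.shape
    b, c, h, w = x.data.shape
    if c != ci:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {ci}")
    pad = dilation * (kh // 2)

    if kh == 1 and kw == 1:
        out_data = np.tensordot(weight.data[:, :, 0, 0], x.data, axes=([1], [1])).transpose(1, 0, 2, 3)
        xpad = None
    else:
        xpad = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        out_data = np.zeros((b, co, h, w), dtype=x.data.dtype)
        for ky in range(kh):
            oy = ky * dilation
            for kx in range(kw):
                ox = kx * dilation
                patch = xpad[:, :, oy : oy + h, ox : ox + w]
                out_data += np.tensordot(weight.data[:, :, ky, kx], patch, axes=([1], [1])).transpose(1, 0, 2, 3)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, co, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        g = np.ascontiguousarray(g)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if kh == 1 and kw == 1:
            if weight.requires_grad:
                gw = np.tensordot(g, x.data, axes=([0, 2, 3], [0, 2, 3]))
                weight._accumulate(gw.reshape(weight.data.shape))
            if x.requires_grad:
                gx = np.tensordot(weight.data[:, :, 0, 0], g, axes=([0], [1])).transpose(1, 0, 2, 3)
                x._accumulate(gx)
            return
        xp = xpad  # captured padded input
        if weight.requires_grad:
            gw = np.empty_like(weight.data)
            for ky in range(kh):
                oy = ky * dilation
                for kx in range(kw):
                    ox = kx * dilation
                    patch = xp[:, :, oy : oy + h, ox : ox + w]
                    gw[:, :, ky, kx] = np.tensordot(g, patch, axes=([0, 2, 3], [0, 2, 3]))
            weight._accumulate(gw)
        if x.requires_grad:
            gxpad = np.zeros_like(xp)
            for ky in range(kh):
                oy = ky * dilation
                for kx in range(kw):
                    ox = kx * dilation
                    gxpad[:, :, oy : oy + h, ox : ox + w] += np.tensordot(
                        weight.data[:, :, ky, kx], g, axes=([0], [1])
                    ).transpose(1, 0, 2, 3)
            x._accumulate(gxpad[:, :, pad : pad + h, pad : pad + w])

    return Tensor._make(out_data, parents, backward)


def conv_transpose2x2(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Transposed convolution with a 2x2 kernel and stride 2 (exact 2x upsampling).

    ``weight`` has shape (C_in, C_out, 2, 2); each input pixel paints a disjoint
    2x2 output patch, so forward and backward are simple strided scatters.
    """
    x = _ensure_tensor(x)
    weight = _ensure_tensor(weight)
    ci, co, _, _ = weight.data.shape
    b, c, h, w = x.data.shape
    if c != ci:
        raise ValueError(f"conv_transpose2x2: input has {c} channels, weight expects {ci}")
    out_data = np.zeros((b, co, 2 * h, 2 * w), dtype=x.data.dtype)
    for dy in range(2):
        for dx in range(2):
            out_data[:, :, dy::2, dx::2] = np.tensordot(
                weight.data[:, :, dy, dx], x.data, axes=([0], [1])
            ).transpose(1, 0, 2, 3)
    if bias is not None:
        out_data += bias.data.reshape(1, co, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if weight.requires_grad:
            gw = np.empty_like(weight.data)
            for dy in range(2):
                for dx in range(2):
                    gw[:, :, dy, dx] = np.tensordot(
                        x.data, g[:, :, dy::2, dx::2], axes=([0, 2, 3], [0, 2, 3])
                    )
            weight._accumulate(gw)
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            for dy in range(2):
                for dx in range(2):
                    gx += np.tensordot(
                        weight.data[:, :, dy, dx], g[:, :, dy::2, dx::2], axes=([1], [1])
                    ).transpose(1, 0, 2, 3)
            x._accumulate(gx)

    return Tensor._make(out_data, parents, backward)


def max_pool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; ties route the gradient to the first max."""
    x = _ensure_tensor(x)
    b, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2x2 requires even spatial dimensions")
    windows = x.data.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
    idx = windows.argmax(axis=-1)
    out_data = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gwin = np.zeros_like(windows)
        np.put_along_axis(gwin, idx[..., None], np.asarray(g)[..., None], axis=-1)
        gx = gwin.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w)
        x._accumulate(gx)

    return Tensor._make(out_data, (x,), backward)


@lru_cache(maxsize=64)
def _bilinear_matrix(n_in: int, factor: int, dtype_str: str) -> np.ndarray:
    """Row-stochastic (n_in * factor, n_in) interpolation matrix, half-pixel centers."""
    n_out = n_in * factor
    a = np.zeros((n_out, n_in), dtype=np.dtype(dtype_str))
    src = (np.arange(n_out) + 0.5) / factor - 0.5
    lo = np.floor(src).astype(int)
    frac = src - lo
    lo_c = np.clip(lo, 0, n_in - 1)
    hi_c = np.clip(lo + 1, 0, n_in - 1)
    for i in range(n_out):
        a[i, lo_c[i]] += 1.0 - frac[i]
        a[i, hi_c[i]] += frac[i]
    return a


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    """Bilinear upsampling by an integer factor (align_corners=False convention)."""
    x = _ensure_tensor(x)
    if factor == 1:
        return x
    b, c, h, w = x.data.shape
    ah = _bilinear_matrix(h, factor, x.data.dtype.str)
    aw = _bilinear_matrix(w, factor, x.data.dtype.str)
    # interpolate rows then columns with BLAS
    t = np.tensordot(x.data, ah, axes=([2], [1]))  # (b, c, w, H_out)
    out_data = np.tensordot(t, aw, axes=([2], [1]))  # (b, c, H_out, W_out)

    def backward(g):
        if not x.requires_grad:
            return
        gt = np.tensordot(np.asarray(g), aw, axes=([3], [0]))  # (b,c,Hout,w)
        gx = np.tensordot(gt, ah, axes=([2], [0])).transpose(0, 1, 3, 2)
        x._accumulate(gx)

    out = Tensor._make(np.ascontiguousarray(out_data), (x,), backward)
    return out


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over (N, H, W) per channel, NCHW layout.

    In training mode batch statistics are used and the running buffers are
    updated in place; in inference mode the running buffers are used, making
    the op a fixed per-channel affine map.
    """
    x = _ensure_tensor(x)
    c = x.data.shape[1]
    gview = gamma.data.reshape(1, c, 1, 1)
    bview = beta.data.reshape(1, c, 1, 1)
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mean.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
        out_data = gview * xhat + bview

        def backward(g):
            g = np.asarray(g)
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=(0, 2, 3)))
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gh = g * gview  # dL/dxhat
                mean_gh = gh.mean(axis=(0, 2, 3), keepdims=True)
                mean_gh_xhat = (gh * xhat).mean(axis=(0, 2, 3), keepdims=True)
                gx = (gh - mean_gh - xhat * mean_gh_xhat) * inv_std.reshape(1, c, 1, 1)
                x._accumulate(gx)

        return Tensor._make(out_data, (x, gamma, beta), backward)

    inv_std = 1.0 / np.sqrt(running_var + eps)
    scale = (gamma.data * inv_std).reshape(1, c, 1, 1)
    shift = (beta.data - gamma.data * running_mean * inv_std).reshape(1, c, 1, 1)
    out_data = x.data * scale + shift
    xh = None
    if gamma.requires_grad and is_grad_enabled():
        xh = (x.data - running_mean.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)

    def backward(g):
        g = np.asarray(g)
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xh).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            x._accumulate(g * scale)

    return Tensor._make(out_data, (x, gamma, beta), backward)
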