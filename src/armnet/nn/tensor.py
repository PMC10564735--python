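"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine supports exactly the operations the fusion networks need:
broadcast add/multiply, matmul, ReLU, logistic sigmoid, channel
concatenation, 2-D convolution (im2col), batch normalization, 2x2 max
pooling, x2 bilinear upsampling, global average pooling and softmax
cross-entropy.  Arrays are float32 by default; float64 inputs are kept
as float64 so finite-difference gradient checks can run at full
precision.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "add", "mul", "matmul", "relu", "sigmoid", "concat",
    "conv2d", "batchnorm2d", "maxpool2x2", "upsample_bilinear",
    "global_avg_pool", "linear", "cross_entropy",
]


class Tensor:
    """An n-d array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar ------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return _reshape(self, shape)

    # -- autodiff ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate ``grad`` (default: ones) through the graph."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            grad = np.ones_like(self.data)

        # iterative topological sort (graphs can be deep for big backbones)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not parent.requires_grad:
                    continue
                key = id(parent)
                grads[key] = pg if key not in grads else grads[key] + pg


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward_fn) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward_fn
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, (gs, ss) in enumerate(zip(g.shape, shape)):
        if ss == 1 and gs != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


# ---------------------------------------------------------------------
# elementwise / shape ops
# ---------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(a.data + b.data, (a, b),
                 lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(a.data * b.data, (a, b),
                 lambda g: (_unbroadcast(g * b.data, a.shape),
                            _unbroadcast(g * a.data, b.shape)))


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return _make(a.data @ b.data, (a, b),
                 lambda g: (g @ b.data.T, a.data.T @ g))


def _reshape(a: Tensor, shape) -> Tensor:
    old = a.shape
    return _make(a.data.reshape(shape), (a,), lambda g: (g.reshape(old),))


def relu(x) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    return _make(np.where(mask, x.data, 0), (x,), lambda g: (g * mask,))


def sigmoid(x) -> Tensor:
    x = _as_tensor(x)
    # numerically stable logistic
    d = x.data
    y = np.empty_like(d)
    pos = d >= 0
    y[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    e = np.exp(d[~pos])
    y[~pos] = e / (1.0 + e)
    return _make(y, (x,), lambda g: (g * y * (1.0 - y),))


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), backward)


# ---------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) on NCHW input.

    ``w`` has shape (C_out, C_in, k, k); ``b`` (C_out,) or None.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    if b is not None:
        b = _as_tensor(b)
    n, c_in, h, wdt = x.shape
    c_out, c_in_w, k, k2 = w.shape
    if c_in != c_in_w or k != k2:
        raise ValueError(f"conv2d weight {w.shape} incompatible with input {x.shape}")
    s, p = stride, padding
    h_out = (h + 2 * p - k) // s + 1
    w_out = (wdt + 2 * p - k) // s + 1

    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    # (N, C, Ho, Wo, k, k) -> rows of the im2col matrix
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * h_out * w_out, c_in * k * k)
    wmat = w.data.reshape(c_out, -1)
    out = cols @ wmat.T
    if b is not None:
        out = out + b.data
    out = out.reshape(n, h_out, w_out, c_out).transpose(0, 3, 1, 2)

    def backward(g):
        gcols = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(
            n * h_out * w_out, c_out)
        gw = (gcols.T @ cols).reshape(w.shape)
        gb = gcols.sum(axis=0) if b is not None else None
        gx = None
        if x.requires_grad:
            dcols = gcols @ wmat  # (N*Ho*Wo, C*k*k)
            dwin = dcols.reshape(n, h_out, w_out, c_in, k, k).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros((n, c_in, h + 2 * p, wdt + 2 * p), dtype=g.dtype)
            for ki in range(k):
                for kj in range(k):
                    dxp[:, :, ki:ki + s * h_out:s, kj:kj + s * w_out:s] += dwin[:, :, :, :, ki, kj]
            gx = dxp[:, :, p:p + h, p:p + wdt] if p else dxp
        if b is not None:
            return gx, gw, gb
        return gx, gw

    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, backward)


# ---------------------------------------------------------------------
# normalization / pooling / resampling
# ---------------------------------------------------------------------

def batchnorm2d(x, gamma, beta, running_mean, running_var, *,
                training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) per channel.

    ``running_mean``/``running_var`` are plain arrays updated in place
    during training (biased batch variance, as is conventional for the
    normalization itself; running variance uses the unbiased estimate).
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    axes = (0, 2, 3)
    n_red = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    shape = (1, -1, 1, 1)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= (1 - momentum)
        running_mean += momentum * mean
        unbiased = var * n_red / max(n_red - 1, 1)
        running_var *= (1 - momentum)
        running_var += momentum * unbiased
    else:
        mean, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(shape)) * inv_std.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

    def backward(g):
        ggamma = (g * xhat).sum(axis=axes)
        gbeta = g.sum(axis=axes)
        gx = None
        if x.requires_grad:
            gxh = g * gamma.data.reshape(shape)
            if training:
                m1 = gxh.mean(axis=axes).reshape(shape)
                m2 = (gxh * xhat).mean(axis=axes).reshape(shape)
                gx = inv_std.reshape(shape) * (gxh - m1 - xhat * m2)
            else:
                gx = gxh * inv_std.reshape(shape)
        return gx, ggamma, gbeta

    return _make(out, (x, gamma, beta), backward)


def maxpool2x2(x) -> Tensor:
    x = _as_tensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial sides, got {h}x{w}")
    ho, wo = h // 2, w // 2
    win = x.data.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, ho, wo, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gwin = np.zeros_like(win)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w)
        return (gx,)

    return _make(out, (x,), backward)


def maxpool2d(x, kernel_size: int = 3, stride: int = 1, padding: int = 1) -> Tensor:
    """General max pooling (used by inception pool branches)."""
    x = _as_tensor(x)
    n, c, h, w = x.shape
    k, s, p = kernel_size, stride, padding
    neg = np.finfo(x.dtype).min
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                constant_values=neg) if p else x.data
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    h_out, w_out = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, h_out, w_out, k * k)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=g.dtype)
        ky, kx = np.unravel_index(idx, (k, k))
        oy = np.arange(h_out)[None, None, :, None] * s + ky
        ox = np.arange(w_out)[None, None, None, :] * s + kx
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, :, None, None]
        np.add.at(gxp, (ni, ci, oy, ox), g)
        return (gxp[:, :, p:p + h, p:p + w] if p else gxp,)

    return _make(out, (x,), backward)


def _interp_matrix(n_out: int, n_in: int, dtype=np.float64) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (half-pixel centers)."""
    a = np.zeros((n_out, n_in), dtype=dtype)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        lo = int(np.floor(src))
        frac = src - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        a[i, lo_c] += 1.0 - frac
        a[i, hi_c] += frac
    return a


_INTERP_CACHE: dict = {}


def _interp_cached(n_out: int, n_in: int) -> np.ndarray:
    key = (n_out, n_in)
    if key not in _INTERP_CACHE:
        _INTERP_CACHE[key] = _interp_matrix(n_out, n_in)
    return _INTERP_CACHE[key]


def upsample_bilinear(x, factor: int = 2) -> Tensor:
    """Bilinear spatial resampling by an integer factor (channels kept)."""
    x = _as_tensor(x)
    n, c, h, w = x.shape
    ah = _interp_cached(h * factor, h).astype(x.dtype)
    aw = _interp_cached(w * factor, w).astype(x.dtype)
    out = np.einsum("ij,ncjk,lk->ncil", ah, x.data, aw, optimize=True)

    def backward(g):
        return (np.einsum("ij,ncjk,lk->ncil", ah.T, g, aw.T, optimize=True),)

    return _make(out, (x,), backward)


def global_avg_pool(x) -> Tensor:
    x = _as_tensor(x)
    n, c, h, w = x.shape
    out = x.data.mean(axis=(2, 3))

    def backward(g):
        return (np.broadcast_to(g[:, :, None, None] / (h * w), x.shape).copy(),)

    return _make(out, (x,), backward)


def linear(x, w, b=None) -> Tensor:
    """Affine map: x (N, F) @ w.T (F, K) + b."""
    x, w = _as_tensor(x), _as_tensor(w)
    if b is None:
        return matmul(x, _transpose(w))
    return add(matmul(x, _transpose(w)), b)


def _transpose(a: Tensor) -> Tensor:
    return _make(a.data.T, (a,), lambda g: (g.T,))


def cross_entropy(logits, labels) -> Tensor:
    """Mean softmax cross-entropy; ``labels`` are integer class indices."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels)
    n = logits.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    loss = -log_probs[np.arange(n), labels].mean()

    def backward(g):
        probs = np.exp(log_probs)
        probs[np.arange(n), labels] -= 1.0
        return (g * probs / n,)

    return _make(np.asarray(loss, dtype=logits.dtype), (logits,), backward)
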