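"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the enhancement networks and their
reconstruction loss need: broadcasting arithmetic, ReLU, [0,1] clamping,
reductions, same-padded 3x3/1x1 convolution (im2col), 2x2 average
pooling, factor-2 bilinear upsampling, 2x2 stride-2 transposed
convolution, channel concatenation, and separable fixed-kernel filtering
with reflect boundaries (used by the differentiable SSIM term).

Linear resampling/filtering operators are expressed as small dense
per-axis matrices so that the backward pass is the exact adjoint.
All data is float64; batches are laid out (N, C, H, W).
"""

from __future__ import annotations

from functools import lru_cache
from typing import Callable, Iterable

import numpy as np


class Tensor:
    """Node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray | float,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) node through the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative topo sort; graphs can be deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------
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

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __neg__(self):
        return mul(self, Tensor(-1.0))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a gradient back to the shape of a broadcast operand."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _node(data, parents: Iterable[Tensor], backward) -> Tensor:
    parents = tuple(parents)
    rg = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=rg, parents=parents, backward=backward if rg else None)


# -- elementwise -------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), bwd)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.data.shape))

    return _node(out_data, (a, b), bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), bwd)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _node(out_data, (a, b), bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bwd(g):
        x._accumulate(g * mask)

    return _node(np.where(mask, x.data, 0.0), (x,), bwd)


def clamp01(x: Tensor) -> Tensor:
    """Clamp to [0, 1]; gradient passes only through the interior."""
    mask = (x.data > 0.0) & (x.data < 1.0)

    def bwd(g):
        x._accumulate(g * mask)

    return _node(np.clip(x.data, 0.0, 1.0), (x,), bwd)


def absolute(x: Tensor) -> Tensor:
    sign = np.sign(x.data)

    def bwd(g):
        x._accumulate(g * sign)

    return _node(np.abs(x.data), (x,), bwd)


def mean(x: Tensor) -> Tensor:
    n = x.data.size

    def bwd(g):
        x._accumulate(np.full(x.data.shape, float(g) / n))

    return _node(x.data.mean(), (x,), bwd)


# -- convolution and resampling ---------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded (zero) 2-D convolution, batch layout (N, C, H, W).

    ``w`` has shape (C_out, C_in, kh, kw) with odd kh == kw;
    ``b`` has shape (C_out,).
    """
    co, ci, kh, kw = w.data.shape
    pad = kh // 2
    n, c, h, wd = x.data.shape
    if c != ci:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel expects {ci}")
    if pad:
        xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    else:
        xp = x.data
    cols = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # cols: (N, C, H, W, kh, kw)
    cols = cols.reshape(n, c, h, wd, kh * kw)
    wr = w.data.reshape(co, ci, kh * kw)
    out_data = np.einsum("nchwk,ock->nohw", cols, wr, optimize=True) + b.data[None, :, None, None]

    def bwd(g):
        if w.requires_grad:
            dw = np.einsum("nchwk,nohw->ock", cols, g, optimize=True)
            w._accumulate(dw.reshape(co, ci, kh, kw))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.einsum("nohw,ock->nchwk", g, wr, optimize=True)
            dxp = np.zeros((n, c, h + 2 * pad, wd + 2 * pad))
            k = 0
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + h, j : j + wd] += dcols[..., k]
                    k += 1
            x._accumulate(dxp[:, :, pad : pad + h, pad : pad + wd] if pad else dxp)

    return _node(out_data, (x, w, b), bwd)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling with stride 2 (even spatial dims required)."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"avg_pool2 needs even spatial dims, got {h}x{w}")
    out_data = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def bwd(g):
        up = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        x._accumulate(up)

    return _node(out_data, (x,), bwd)


@lru_cache(maxsize=64)
def _bilinear_matrix(n: int) -> np.ndarray:
    """Factor-2 linear interpolation operator (2n x n), half-pixel centers."""
    u = np.zeros((2 * n, n))
    for i in range(2 * n):
        c = (i + 0.5) / 2.0 - 0.5
        f = int(np.floor(c))
        t = c - f
        f0 = min(max(f, 0), n - 1)
        f1 = min(max(f + 1, 0), n - 1)
        u[i, f0] += 1.0 - t
        u[i, f1] += t
    return u


def upsample_bilinear2(x: Tensor) -> Tensor:
    """Double both spatial dimensions by bilinear interpolation."""
    n, c, h, w = x.data.shape
    uh = _bilinear_matrix(h)
    uw = _bilinear_matrix(w)
    out_data = np.einsum("ih,nchw,jw->ncij", uh, x.data, uw, optimize=True)

    def bwd(g):
        x._accumulate(np.einsum("ih,ncij,jw->nchw", uh, g, uw, optimize=True))

    return _node(out_data, (x,), bwd)


def conv_transpose2(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """2x2 stride-2 transposed convolution; doubles both spatial dims.

    ``w`` has shape (C_in, C_out, 2, 2).
    """
    n, c, h, wd = x.data.shape
    ci, co, _, _ = w.data.shape
    if c != ci:
        raise ValueError(f"conv_transpose2 channel mismatch: input {c}, kernel expects {ci}")
    t = np.einsum("nchw,codk->nohdwk", x.data, w.data, optimize=True)
    out_data = t.reshape(n, co, 2 * h, 2 * wd) + b.data[None, :, None, None]

    def bwd(g):
        gr = g.reshape(n, co, h, 2, wd, 2)
        if x.requires_grad:
            x._accumulate(np.einsum("nohdwk,codk->nchw", gr, w.data, optimize=True))
        if w.requires_grad:
            w._accumulate(np.einsum("nchw,nohdwk->codk", x.data, gr, optimize=True))
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return _node(out_data, (x, w, b), bwd)


def concat_channels(tensors: list[Tensor]) -> Tensor:
    sizes = [t.data.shape[1] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=1)

    def bwd(g):
        start = 0
        for t, s in zip(tensors, sizes):
            if t.requires_grad:
                t._accumulate(g[:, start : start + s])
            start += s

    return _node(out_data, tuple(tensors), bwd)


def _reflect_filter_matrix(n: int, kernel: tuple[float, ...]) -> np.ndarray:
    """Dense correlation operator along one axis with reflect ('symmetric')
    boundary handling, matching scipy.ndimage's default mode."""
    k = np.asarray(kernel)
    r = (len(k) - 1) // 2
    f = np.zeros((n, n))
    period = 2 * n
    for i in range(n):
        for off in range(-r, r + 1):
            j = (i + off) % period
            if j < 0:
                j += period
            jj = j if j < n else period - 1 - j
            f[i, jj] += k[off + r]
    return f


_FILTER_CACHE: dict[tuple[int, tuple[float, ...]], np.ndarray] = {}


def _filter_matrix(n: int, kernel: tuple[float, ...]) -> np.ndarray:
    key = (n, kernel)
    if key not in _FILTER_CACHE:
        _FILTER_CACHE[key] = _reflect_filter_matrix(n, kernel)
    return _FILTER_CACHE[key]


def sepfilter2d(x: Tensor, kernel: tuple[float, ...]) -> Tensor:
    """Separable fixed-kernel filtering along H and W with reflect boundary.

    The kernel carries no trainable parameters; gradients flow through the
    image only (exact adjoint of the linear operator).
    """
    h, w = x.data.shape[-2:]
    fh = _filter_matrix(h, kernel)
    fw = _filter_matrix(w, kernel)
    out_data = np.einsum("ih,...hw,jw->...ij", fh, x.data, fw, optimize=True)

    def bwd(g):
        x._accumulate(np.einsum("ih,...ij,jw->...hw", fh, g, fw, optimize=True))

    return _node(out_data, (x,), bwd)


def crop_border(x: Tensor, pad: int) -> Tensor:
    """Drop ``pad`` pixels from each spatial border (last two axes)."""
    sl = (Ellipsis, slice(pad, x.data.shape[-2] - pad), slice(pad, x.data.shape[-1] - pad))
    out_data = x.data[sl]

    def bwd(g):
        full = np.zeros_like(x.data)
        full[sl] = g
        x._accumulate(full)

    return _node(out_data, (x,), bwd)


def gaussian_kernel1d(sigma: float, radius: int) -> tuple[float, ...]:
    """Normalized sampled Gaussian, identical to scipy.ndimage's kernel."""
    xs = np.arange(-radius, radius + 1)
    phi = np.exp(-0.5 * (xs / sigma) ** 2)
    phi /= phi.sum()
    return tuple(phi.tolist())
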