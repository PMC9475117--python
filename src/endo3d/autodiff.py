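"""Reverse-mode automatic differentiation over numpy arrays.

A compact define-by-run autodiff core: every operation on :class:`Tensor`
records its inputs and a backward closure, and :meth:`Tensor.backward`
replays the tape in reverse topological order.  It implements exactly the
operations the endoscopy networks need — elementwise arithmetic, matrix
products, 2-D convolution (and its transposed form via zero dilation),
axis reductions, slicing/concatenation, width-axis gathering for
differentiable horizontal warps, and bilinear resizing — all on float32
``numpy`` arrays, single threaded and bit-deterministic.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "dilate2d",
    "pad2d",
    "reflect_pad2d",
    "gather_w",
    "gather_h",
    "bilinear_resize",
    "no_grad",
]

_grad_enabled = True


class no_grad:
    """Context manager disabling tape recording (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _sum_to_shape(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ---- construction helpers -------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ---- autodiff driver -------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free closures
                node._parents = ()

    def _accum(self, g: np.ndarray) -> None:
        g = _sum_to_shape(g, self.data.shape)
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # ---- elementwise arithmetic -----------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data + other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g)
            if other.requires_grad:
                other._accum(g)

        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data * other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g * other.data)
            if other.requires_grad:
                other._accum(g * self.data)

        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data / other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g / other.data)
            if other.requires_grad:
                other._accum(-g * self.data / (other.data * other.data))

        out._backward = bw if out.requires_grad else None
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor._make(self.data ** p, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    # ---- nonlinearities --------------------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor._make(y, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * y)
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor._make(y, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * 0.5 / y)
        return out

    def abs(self):
        out = Tensor._make(np.abs(self.data), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor._make(self.data * mask, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * mask)
        return out

    def sigmoid(self):
        x = self.data
        y = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                     np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))).astype(np.float32)
        out = Tensor._make(y, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * y * (1.0 - y))
        return out

    def clamp(self, lo: float | None = None, hi: float | None = None):
        y = np.clip(self.data, lo, hi)
        mask = np.ones_like(self.data)
        if lo is not None:
            mask *= self.data >= lo
        if hi is not None:
            mask *= self.data <= hi
        out = Tensor._make(y, (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * mask)
        return out

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)
        if out.requires_grad:
            shp = self.data.shape

            def bw(g):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, shp))

            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        y = self.data.max(axis=axis, keepdims=True)
        mask = self.data == y  # ties share gradient equally
        counts = mask.sum(axis=axis, keepdims=True)
        out_data = y if keepdims else np.squeeze(y, axis=axis)
        out = Tensor._make(out_data, (self,), None)
        if out.requires_grad:

            def bw(g):
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(g * mask / counts)

            out._backward = bw
        return out

    # ---- elementwise min/max of two tensors ------------------------------
    def minimum(self, other: "Tensor"):
        other = as_tensor(other)
        take_self = self.data <= other.data
        out = Tensor._make(np.where(take_self, self.data, other.data), (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g * take_self)
            if other.requires_grad:
                other._accum(g * (~take_self))

        out._backward = bw if out.requires_grad else None
        return out

    # ---- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor._make(self.data.reshape(*shape), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes):
        out = Tensor._make(self.data.transpose(*axes), (self,), None)
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda g: self._accum(g.transpose(*inv))
        return out

    def flip(self, axis: int):
        out = Tensor._make(np.flip(self.data, axis=axis), (self,), None)
        if out.requires_grad:
            out._backward = lambda g: self._accum(np.flip(g, axis=axis))
        return out

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,), None)
        if out.requires_grad:

            def bw(g):
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accum(full)

            out._backward = bw
        return out

    def matmul(self, other: "Tensor"):
        other = as_tensor(other)
        out = Tensor._make(self.data @ other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bw if out.requires_grad else None
        return out

    __matmul__ = matmul


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, None)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)

        out._backward = bw
    return out


def pad2d(x: Tensor, pads: tuple[int, int, int, int]) -> Tensor:
    """Zero-pad the last two axes by (top, bottom, left, right)."""
    t, b, l, r = pads
    x = as_tensor(x)
    data = np.pad(x.data, [(0, 0)] * (x.ndim - 2) + [(t, b), (l, r)])
    out = Tensor._make(data, (x,), None)
    if out.requires_grad:
        H, W = x.data.shape[-2:]

        def bw(g):
            x._accum(g[..., t:t + H, l:l + W])

        out._backward = bw
    return out


def reflect_pad2d(x: Tensor, pads: tuple[int, int, int, int]) -> Tensor:
    """Reflect-pad (edge-mirroring without repeating the border pixel)."""
    t, b, l, r = pads
    x = as_tensor(x)
    data = np.pad(x.data, [(0, 0)] * (x.ndim - 2) + [(t, b), (l, r)], mode="reflect")
    out = Tensor._make(data, (x,), None)
    if out.requires_grad:
        H, W = x.data.shape[-2:]
        # index map: padded position -> source position, scatter-add gradient
        iy = np.pad(np.arange(H), (t, b), mode="reflect")
        ix = np.pad(np.arange(W), (l, r), mode="reflect")

        def bw(g):
            acc = np.zeros_like(x.data)
            np.add.at(acc, (..., iy[:, None], ix[None, :]), g)
            x._accum(acc)

        out._backward = bw
    return out


def dilate2d(x: Tensor, stride: int) -> Tensor:
    """Insert ``stride-1`` zeros between rows/cols (transposed-conv helper)."""
    x = as_tensor(x)
    if stride == 1:
        return x
    *lead, H, W = x.data.shape
    data = np.zeros((*lead, (H - 1) * stride + 1, (W - 1) * stride + 1), dtype=np.float32)
    data[..., ::stride, ::stride] = x.data
    out = Tensor._make(data, (x,), None)
    if out.requires_grad:
        out._backward = lambda g: x._accum(g[..., ::stride, ::stride])
    return out


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    cols = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return cols[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """NCHW 2-D cross-correlation with square stride/padding."""
    x, w = as_tensor(x), as_tensor(w)
    O, C, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols = _im2col(xp, kh, kw, stride)
    N, _, Ho, Wo = cols.shape[:4]
    # contiguous im2col + GEMM: the fast path for CPU convolution
    cols2 = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * Ho * Wo, C * kh * kw)
    w2 = w.data.reshape(O, -1)
    y = (cols2 @ w2.T).reshape(N, Ho, Wo, O).transpose(0, 3, 1, 2)
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor._make(np.ascontiguousarray(y), parents, None)
    if out.requires_grad:

        def bw(g):
            g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, O)
            if w.requires_grad:
                w._accum((g2.T @ cols2).reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                t = (g2 @ w2).reshape(N, Ho, Wo, C, kh, kw)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + (Ho - 1) * stride + 1:stride,
                            j:j + (Wo - 1) * stride + 1:stride] += \
                            t[..., i, j].transpose(0, 3, 1, 2)
                H, W = x.data.shape[2:]
                x._accum(gxp[:, :, padding:padding + H, padding:padding + W])

        out._backward = bw
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2, padding: int = 1,
                     output_padding: int = 1) -> Tensor:
    """Transposed convolution; ``w`` has shape (C_in, C_out, kh, kw).

    Realised as zero-dilation followed by a stride-1 convolution with the
    spatially flipped, in/out-swapped kernel, so gradients come for free.
    """
    w = as_tensor(w)
    kh, kw = w.data.shape[2:]
    xd = dilate2d(x, stride)
    p0 = kh - 1 - padding
    xd = pad2d(xd, (p0, p0 + output_padding, p0, p0 + output_padding))
    wf = w.flip(2).flip(3).transpose(1, 0, 2, 3)
    return conv2d(xd, wf, b, stride=1, padding=0)


def _box_sum(a: np.ndarray, k: int) -> np.ndarray:
    """Sum over all k x k windows (valid, stride 1), separable shift-adds."""
    out = a
    for axis in (-2, -1):
        n = out.shape[axis] - k + 1
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(0, n)
        acc = out[tuple(sl)].copy()
        for off in range(1, k):
            sl[axis] = slice(off, off + n)
            acc += out[tuple(sl)]
        out = acc
    return out


def box_sum_valid(x: Tensor, k: int) -> Tensor:
    """Differentiable k x k window sum (valid); the adjoint is a full
    correlation with the same ones kernel, again via integral images."""
    x = as_tensor(x)
    out = Tensor._make(_box_sum(x.data, k), (x,), None)
    if out.requires_grad:

        def bw(g):
            pad = [(0, 0)] * (g.ndim - 2) + [(k - 1, k - 1), (k - 1, k - 1)]
            x._accum(_box_sum(np.pad(g, pad), k))

        out._backward = bw
    return out


def gather_w(x: Tensor, ix: np.ndarray) -> Tensor:
    """``out[n, c, y, j] = x[n, c, y, ix[n, y, j]]`` — width-axis gather.

    ``ix`` is an integer array of shape (N, H, Wo), already clipped to range.
    Backward scatter-adds into the source, making horizontal warps
    differentiable with respect to the image being sampled.
    """
    x = as_tensor(x)
    N, C, H, W = x.data.shape
    idx = ix[:, None, :, :]  # broadcast over channels
    data = np.take_along_axis(x.data, np.broadcast_to(idx, (N, C, H, ix.shape[-1])), axis=3)
    out = Tensor._make(data, (x,), None)
    if out.requires_grad:

        def bw(g):
            acc = np.zeros_like(x.data)
            n_i, c_i, y_i = np.ogrid[:N, :C, :H, :1][:3]
            np.add.at(acc, (n_i, c_i, y_i, idx), g)
            x._accum(acc)

        out._backward = bw
    return out


def gather_h(x: Tensor, iy: np.ndarray) -> Tensor:
    """Height-axis analogue of :func:`gather_w`; ``iy`` shape (N, Ho, W)."""
    xt = x.transpose(0, 1, 3, 2)
    it = np.swapaxes(iy, 1, 2)
    return gather_w(xt, it).transpose(0, 1, 3, 2)


def _resize_axis_idx(n_src: int, n_dst: int):
    """Bilinear sample positions, align-corners-false convention."""
    scale = n_src / n_dst
    pos = (np.arange(n_dst, dtype=np.float64) + 0.5) * scale - 0.5
    pos = np.clip(pos, 0, n_src - 1)
    i0 = np.floor(pos).astype(np.int64)
    i0 = np.minimum(i0, n_src - 2) if n_src > 1 else i0
    frac = (pos - i0).astype(np.float32)
    return i0, frac


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Separable bilinear resize of an NCHW tensor (align corners false)."""
    x = as_tensor(x)
    N, C, H, W = x.data.shape
    if H != out_h:
        i0, f = _resize_axis_idx(H, out_h)
        iy0 = np.broadcast_to(i0[None, :, None], (N, out_h, W))
        iy1 = np.minimum(iy0 + 1, H - 1)
        fw = Tensor(f[None, None, :, None])
        x = gather_h(x, iy0) * (1.0 - fw) + gather_h(x, iy1) * fw
    if W != out_w:
        i0, f = _resize_axis_idx(W, out_w)
        ix0 = np.broadcast_to(i0[None, None, :], (N, out_h, out_w))
        ix1 = np.minimum(ix0 + 1, W - 1)
        fw = Tensor(f[None, None, None, :])
        x = gather_w(x, ix0) * (1.0 - fw) + gather_w(x, ix1) * fw
    return x
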