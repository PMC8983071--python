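"""Reverse-mode automatic differentiation on NumPy arrays.

A define-by-run tape of :class:`Tensor` nodes, sized for the small 2-D
convolutional networks this package trains on CPU.  Only the operations the
SR-CycleGAN generators, discriminators and losses need are provided: broadcast
arithmetic, reductions, pointwise nonlinearities, 2-D padding/convolution and
the resampling operators (average pooling, nearest upsampling, sub-pixel
shuffle, zero dilation) that appear both inside the networks and inside the
multi-modality super-resolution loss.

All arrays are float64.  Gradients are accumulated into ``Tensor.grad`` by
:meth:`Tensor.backward` via a topological sort of the tape.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "pad2d",
    "conv2d",
    "avg_pool2d",
    "nearest_upsample2d",
    "pixel_shuffle",
    "dilate2d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` (shaped like a broadcast result) back to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed the recursion limit
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
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    # python-number operands take a fast path that keeps the array dtype
    # (no float64 upcast) and stays off the tape
    def _scalar_op(self, value, forward, d_self):
        out = Tensor(forward(self.data, value), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(d_self(g, value))

        out._backward = bwd
        return out

    def __add__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(other, lambda d, v: d + v, lambda g, v: g)
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._backward = bwd
        return out

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            return (-self) + other
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(other, lambda d, v: d * v, lambda g, v: g * v)
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self._scalar_op(other, lambda d, v: d / v, lambda g, v: g / v)
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out = Tensor(self.data**exponent, _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = bwd
        return out

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------- pointwise
    def sqrt(self):
        return self**0.5

    def exp(self):
        out = Tensor(np.exp(self.data), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * out.data)

        out._backward = bwd
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out.data**2))

        out._backward = bwd
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        out._backward = bwd
        return out

    def leaky_relu(self, slope: float = 0.2):
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * np.where(self.data > 0, 1.0, slope))

        out._backward = bwd
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bwd
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ------------------------------------------------------------------ 2-D ops


def pad2d(x: Tensor, pad: int, mode: str = "reflect") -> Tensor:
    """Pad the two trailing (spatial) axes of an NCHW tensor."""
    if pad == 0:
        return x
    if pad < 0:
        raise ValueError("pad must be >= 0")
    widths = [(0, 0)] * (x.ndim - 2) + [(pad, pad), (pad, pad)]
    if mode == "zero":
        out = Tensor(np.pad(x.data, widths, mode="constant"), _parents=(x,))

        def bwd(g):
            if x.requires_grad:
                sl = tuple([slice(None)] * (x.ndim - 2) + [slice(pad, -pad)] * 2)
                x._accumulate(g[sl])

        out._backward = bwd
        return out
    if mode != "reflect":
        raise ValueError(f"unknown pad mode {mode!r}")
    H, W = x.shape[-2], x.shape[-1]
    if pad >= H or pad >= W:
        raise ValueError("reflect pad must be smaller than the spatial size")
    # index maps: padded position -> source position (mirror without edge repeat)
    iy = _reflect_index(H, pad)
    ix = _reflect_index(W, pad)
    out_data = x.data[..., iy[:, None], ix[None, :]]
    out = Tensor(out_data, _parents=(x,))

    def bwd(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        # scatter-add over the mirror map; lead dims flattened for add.at
        flat_g = g.reshape(-1, H + 2 * pad, W + 2 * pad)
        flat_gx = gx.reshape(-1, H, W)
        np.add.at(flat_gx, (slice(None), iy[:, None], ix[None, :]), flat_g)
        x._accumulate(flat_gx.reshape(x.data.shape))

    out._backward = bwd
    return out


def _reflect_index(n: int, pad: int) -> np.ndarray:
    idx = np.arange(-pad, n + pad)
    idx = np.abs(idx)  # left mirror
    idx = np.where(idx >= n, 2 * (n - 1) - idx, idx)  # right mirror
    return idx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """Valid (no padding) 2-D cross-correlation.

    x: (N, Cin, H, W); w: (Cout, Cin, kh, kw); b: (Cout,) or None.
    """
    N, Cin, H, W = x.shape
    Cout, Cin_w, kh, kw = w.shape
    if Cin != Cin_w:
        raise ValueError(f"channel mismatch: input {Cin}, kernel {Cin_w}")
    if H < kh or W < kw:
        raise ValueError(f"input {H}x{W} smaller than kernel {kh}x{kw}")
    s = int(stride)
    windows = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::s, ::s]  # (N, Cin, Ho, Wo, kh, kw)
    Ho, Wo = windows.shape[2], windows.shape[3]
    needs_grad = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    if not needs_grad and windows.nbytes > 64 * 2**20:
        # inference on large maps: row-chunked im2col, nothing kept for backward
        wmat_ = w.data.reshape(Cout, -1)
        out_data = np.empty((N, Cout, Ho, Wo), dtype=x.data.dtype)
        rows = max(1, int((64 * 2**20) // max(1, windows.nbytes // Ho)))
        for r0 in range(0, Ho, rows):
            chunk = windows[:, :, r0 : r0 + rows]
            hc = chunk.shape[2]
            cols_ = np.ascontiguousarray(chunk.transpose(0, 2, 3, 1, 4, 5)).reshape(
                N * hc * Wo, -1
            )
            out_data[:, :, r0 : r0 + rows] = (
                (cols_ @ wmat_.T).reshape(N, hc, Wo, Cout).transpose(0, 3, 1, 2)
            )
        if b is not None:
            out_data += b.data[None, :, None, None]
        return Tensor(out_data)
    # im2col: one contiguous copy, reused by the backward pass
    cols = np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * Ho * Wo, Cin * kh * kw
    )
    wmat = w.data.reshape(Cout, -1)
    out_data = (cols @ wmat.T).reshape(N, Ho, Wo, Cout).transpose(0, 3, 1, 2)
    out_data = np.ascontiguousarray(out_data)
    if b is not None:
        out_data += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _parents=parents)

    def bwd(g):
        # g: (N, Cout, Ho, Wo)
        g_mat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, Cout)
        if w.requires_grad:
            w._accumulate((g_mat.T @ cols).reshape(Cout, Cin, kh, kw))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            # col2im: scatter the column gradients back with strided adds
            dcols = (g_mat @ wmat).reshape(N, Ho, Wo, Cin, kh, kw)
            dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (N, Cin, Ho, Wo, kh, kw)
            gx = np.zeros_like(x.data)
            for u in range(kh):
                for v in range(kw):
                    gx[:, :, u : u + s * Ho : s, v : v + s * Wo : s] += dcols[..., u, v]
            x._accumulate(gx)

    out._backward = bwd
    return out


def avg_pool2d(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping average pooling on the two trailing axes."""
    f = int(factor)
    if f < 1:
        raise ValueError("factor must be >= 1")
    if f == 1:
        return x
    H, W = x.shape[-2], x.shape[-1]
    if H % f or W % f:
        raise ValueError(f"spatial size {H}x{W} not divisible by pooling factor {f}")
    lead = x.shape[:-2]
    blocks = x.data.reshape(*lead, H // f, f, W // f, f)
    out = Tensor(blocks.mean(axis=(-3, -1)), _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            gb = np.repeat(np.repeat(g, f, axis=-2), f, axis=-1) / (f * f)
            x._accumulate(gb)

    out._backward = bwd
    return out


def nearest_upsample2d(x: Tensor, factor: int) -> Tensor:
    """Replicate each pixel over a factor x factor block (trailing axes)."""
    f = int(factor)
    if f < 1:
        raise ValueError("factor must be >= 1")
    if f == 1:
        return x
    out = Tensor(np.repeat(np.repeat(x.data, f, axis=-2), f, axis=-1), _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            H, W = x.shape[-2], x.shape[-1]
            lead = g.shape[:-2]
            gb = g.reshape(*lead, H, f, W, f).sum(axis=(-3, -1))
            x._accumulate(gb)

    out._backward = bwd
    return out


def pixel_shuffle(x: Tensor, r: int) -> Tensor:
    """Sub-pixel shuffle: (N, C*r^2, H, W) -> (N, C, r*H, r*W).

    out[n, c, y, x] = in[n, c*r^2 + r*(y mod r) + (x mod r), y//r, x//r]
    """
    r = int(r)
    if r < 1:
        raise ValueError("r must be >= 1")
    if r == 1:
        return x
    N, C2, H, W = x.shape
    if C2 % (r * r):
        raise ValueError(f"channel count {C2} not divisible by r^2={r * r}")
    C = C2 // (r * r)
    d = x.data.reshape(N, C, r, r, H, W)
    out_data = d.transpose(0, 1, 4, 2, 5, 3).reshape(N, C, r * H, r * W)
    out = Tensor(np.ascontiguousarray(out_data), _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            gb = g.reshape(N, C, H, r, W, r).transpose(0, 1, 3, 5, 2, 4)
            x._accumulate(gb.reshape(N, C2, H, W))

    out._backward = bwd
    return out


def dilate2d(x: Tensor, stride: int) -> Tensor:
    """Insert ``stride - 1`` zeros between pixels (transposed-conv expansion)."""
    s = int(stride)
    if s < 1:
        raise ValueError("stride must be >= 1")
    if s == 1:
        return x
    N, C, H, W = x.shape
    out_data = np.zeros((N, C, s * H - (s - 1), s * W - (s - 1)), dtype=x.data.dtype)
    out_data[:, :, ::s, ::s] = x.data
    out = Tensor(out_data, _parents=(x,))

    def bwd(g):
        if x.requires_grad:
            x._accumulate(g[:, :, ::s, ::s])

    out._backward = bwd
    return out
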