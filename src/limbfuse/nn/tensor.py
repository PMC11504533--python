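"""Minimal reverse-mode autodiff on numpy arrays.

Supports exactly the operations the limbfuse networks need: broadcasting
arithmetic, matmul, reshape/transpose/slice/concat, the usual pointwise
nonlinearities, reductions, 2D (cross-correlation style) convolution and its
transpose, and average pooling.  Gradients are plain numpy arrays accumulated
into ``Tensor.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "conv_transpose2d", "avg_pool2d", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (the inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_array(x, dtype_hint=np.float32) -> np.ndarray:
    a = np.asarray(x)
    if not np.issubdtype(a.dtype, np.floating):
        a = a.astype(dtype_hint)
    return a


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = requires_grad and _grad_enabled
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- basics -------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
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
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad,
                     (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad,
                     (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data, other.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * p * self.data ** (p - 1.0))
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, self.requires_grad or other.requires_grad,
                     (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    ga = g @ np.swapaxes(other.data, -1, -2)
                    self._accum(_unbroadcast(ga, self.shape))
                if other.requires_grad:
                    gb = np.swapaxes(self.data, -1, -2) @ g
                    other._accum(_unbroadcast(gb, other.shape))
            out._backward = bw
        return out

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        src = self.shape
        out = Tensor(self.data.reshape(shape), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(src))
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))
        if out.requires_grad:
            def bw(g):
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accum(full)
            out._backward = bw
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))
        if out.requires_grad:
            def bw(g):
                if axis is None:
                    self._accum(np.broadcast_to(g, self.shape).copy())
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    self._accum(np.broadcast_to(gg, self.shape).copy())
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- pointwise -----------------------------------------------------------
    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g / self.data)
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * (1.0 - t * t))
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.01):
        mask = self.data > 0
        factor = np.where(mask, 1.0, slope).astype(self.data.dtype)
        out = Tensor(self.data * factor, self.requires_grad, (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * factor)
        return out

    def softmax(self, axis=-1):
        m = self.data.max(axis=axis, keepdims=True)
        e = (self - m).exp()
        return e / e.sum(axis=axis, keepdims=True)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, req, tuple(tensors))
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            parts = np.split(g, splits, axis=axis)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(p)
        out._backward = bw
    return out


# -- convolution machinery ---------------------------------------------------
#
# Convolutions are computed as a loop over the (small) kernel taps in a
# channels-last layout: each tap contributes matmul(x_slice, w_tap).  This
# keeps every copy a large block copy and every product a plain GEMM, which
# is much faster in numpy than materializing im2col patch tensors.

def _pad_cl(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    """[B, C, H, W] -> padded channels-last [B, H+2ph, W+2pw, C] in one copy."""
    b, c, h, w = x.shape
    out = np.zeros((b, h + 2 * ph, w + 2 * pw, c), dtype=x.dtype)
    out[:, ph:ph + h, pw:pw + w, :] = x.transpose(0, 2, 3, 1)
    return out


def _conv2d_raw(x: np.ndarray, w: np.ndarray, stride, pad) -> np.ndarray:
    """x [B,C,H,W], w [O,C,kh,kw] -> [B,O,OH,OW] cross-correlation."""
    sh, sw = stride
    ph, pw = pad
    o_ch, c_ch, kh, kw = w.shape
    b, _, h, w_in = x.shape
    oh = (h + 2 * ph - kh) // sh + 1
    ow = (w_in + 2 * pw - kw) // sw + 1
    xpl = _pad_cl(x, ph, pw)
    wl = np.ascontiguousarray(w.transpose(2, 3, 1, 0))  # [kh, kw, C, O]
    # unit-stride temporal kernels admit a zero-copy merged view per tap
    view_path = (sh == 1 and sw == 1 and kw == 1 and pw == 0)
    out2 = np.zeros((b * oh * ow, o_ch), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            sl = xpl[:, i:i + sh * oh:sh, j:j + sw * ow:sw, :]
            if view_path:
                m = sl.reshape(b, oh * ow, c_ch)  # stride-mergeable view
                out2 += np.matmul(m, wl[i, j]).reshape(-1, o_ch)
            else:
                sl2 = np.ascontiguousarray(sl).reshape(-1, c_ch)
                out2 += sl2 @ wl[i, j]
    return np.ascontiguousarray(
        out2.reshape(b, oh, ow, o_ch).transpose(0, 3, 1, 2))


def _conv2d_dw(x: np.ndarray, g: np.ndarray, stride, pad,
               kh: int, kw: int) -> np.ndarray:
    """Weight gradient: dw[o,c,i,j] = sum_{b,oh,ow} g[b,o,oh,ow] *
    xp[b,c,oh*sh+i,ow*sw+j]."""
    sh, sw = stride
    ph, pw = pad
    b, c_ch = x.shape[0], x.shape[1]
    o_ch, oh, ow = g.shape[1], g.shape[2], g.shape[3]
    xpl = _pad_cl(x, ph, pw)
    g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, o_ch)
    dw = np.empty((o_ch, c_ch, kh, kw), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            sl = xpl[:, i:i + sh * oh:sh, j:j + sw * ow:sw, :]
            sl2 = np.ascontiguousarray(sl).reshape(-1, c_ch)
            dw[:, :, i, j] = g2.T @ sl2
    return dw


def _dilate(x: np.ndarray, sh: int, sw: int, extra_h: int = 0, extra_w: int = 0):
    """Insert (s-1) zeros between elements along H and W, plus trailing zeros."""
    if sh == 1 and sw == 1 and extra_h == 0 and extra_w == 0:
        return x
    b, c, h, w = x.shape
    out = np.zeros((b, c, (h - 1) * sh + 1 + extra_h, (w - 1) * sw + 1 + extra_w),
                   dtype=x.dtype)
    out[:, :, ::sh, ::sw][:, :, :h, :w] = x
    return out


def _conv2d_input_grad(g: np.ndarray, w: np.ndarray, x_shape, stride, pad):
    """Gradient wrt conv2d input, via dilated full convolution (matmul only)."""
    sh, sw = stride
    ph, pw = pad
    kh, kw = w.shape[2], w.shape[3]
    _, _, h, w_in = x_shape
    oh = (h + 2 * ph - kh) // sh + 1
    ow = (w_in + 2 * pw - kw) // sw + 1
    # zeros so the dilated grad covers the whole (padded) input extent
    extra_h = (h + 2 * ph - kh) - (oh - 1) * sh
    extra_w = (w_in + 2 * pw - kw) - (ow - 1) * sw
    gd = _dilate(g, sh, sw, extra_h, extra_w)
    w_flip = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # [C, O, kh, kw]
    dx_pad = _conv2d_raw(gd, w_flip, (1, 1), (kh - 1, kw - 1))
    if ph or pw:
        dx_pad = dx_pad[:, :, ph:ph + h, pw:pw + w_in]
    return dx_pad


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=(1, 1), pad=(0, 0)) -> Tensor:
    """2D cross-correlation: x [B,C,H,W], w [O,C,kh,kw], b [O]."""
    stride = tuple(stride)
    pad = tuple(pad)
    out_data = _conv2d_raw(x.data, w.data, stride, pad)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    req = any(t.requires_grad for t in parents)
    out = Tensor(out_data, req, parents)
    if out.requires_grad:
        kh, kw = w.shape[2], w.shape[3]
        sh, sw = stride
        ph, pw = pad

        def bw(g):
            if x.requires_grad:
                x._accum(_conv2d_input_grad(g, w.data, x.shape, stride, pad))
            if w.requires_grad:
                w._accum(_conv2d_dw(x.data, g, stride, pad, kh, kw))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
        out._backward = bw
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride=(1, 1), pad=(0, 0), output_padding=(0, 0)) -> Tensor:
    """Transposed conv: x [B,C,H,W], w [C,O,kh,kw]; out spatial
    (H-1)*s - 2p + k + op."""
    sh, sw = tuple(stride)
    ph, pw = tuple(pad)
    oph, opw = tuple(output_padding)
    kh, kw = w.shape[2], w.shape[3]
    xd = _dilate(x.data, sh, sw, oph, opw)
    w_flip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # [O, C, kh, kw]
    out_data = _conv2d_raw(xd, w_flip, (1, 1), (kh - 1 - ph, kw - 1 - pw))
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    req = any(t.requires_grad for t in parents)
    out = Tensor(out_data, req, parents)
    if out.requires_grad:
        def bw(g):
            if x.requires_grad:
                # forward strided conv of g with w ([C, O, kh, kw] layout
                # already maps output channels to x's channels)
                dx = _conv2d_raw(g, w.data, (sh, sw), (ph, pw))
                x._accum(dx[:, :, :x.shape[2], :x.shape[3]])
            if w.requires_grad:
                # same tap pattern with the roles of g and x swapped; the
                # helper then yields [C, O, kh, kw] directly
                w._accum(_conv2d_dw(g, x.data, (sh, sw), (ph, pw), kh, kw))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))
        out._backward = bw
    return out


def avg_pool2d(x: Tensor, kernel) -> Tensor:
    """Non-overlapping average pooling; spatial dims must divide by kernel."""
    kh, kw = (kernel, kernel) if isinstance(kernel, int) else tuple(kernel)
    b, c, h, w = x.shape
    if h % kh or w % kw:
        raise ValueError(f"avg_pool2d: input {h}x{w} not divisible by {kh}x{kw}")
    r = x.reshape(b, c, h // kh, kh, w // kw, kw)
    return r.mean(axis=(3, 5))
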