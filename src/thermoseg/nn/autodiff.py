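"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: each :class:`Tensor` wraps an
``ndarray`` and records the operation that produced it, so a scalar loss can
be backpropagated through arbitrary compositions of the primitives defined
here.  Only the operations the models in this package need are provided —
broadcasted arithmetic, (batched) matmul, reductions, shape manipulation,
the usual nonlinearities, windowed indexing, and a direct 2-D convolution.

Arrays are kept in float64 throughout; at the model sizes this package
targets, accuracy is worth more than memory.
"""

from __future__ import annotations

import numpy as np
from scipy import special

__all__ = [
    "Tensor",
    "Parameter",
    "concatenate",
    "stack",
    "roll",
    "pad2d",
    "softmax",
    "gelu",
    "take",
    "conv2d",
    "interp2d",
    "upsample_nearest2d",
    "as_tensor",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helper for op outputs ---------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- introspection -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- backward pass -------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order over the reachable graph
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return Tensor._make(a.data / b.data, (a, b), bwd)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        a = self

        def bwd(g):
            a._accum(g * exponent * a.data ** (exponent - 1))

        return Tensor._make(a.data ** exponent, (a,), bwd)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        if a.ndim < 2 or b.ndim < 2:
            raise ValueError("matmul operands must have ndim >= 2")

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g @ b.data.swapaxes(-1, -2), a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(a.data.swapaxes(-1, -2) @ g, b.shape))

        return Tensor._make(a.data @ b.data, (a, b), bwd)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bwd(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy()
                         if np.ndim(g) == a.ndim else np.full(a.shape, g))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) / n

    def amax(self, axis, keepdims=False):
        """Max reduction; gradient is split evenly among tied maxima."""
        a = self
        out_data = a.data.max(axis=axis, keepdims=True)
        mask = (a.data == out_data).astype(np.float64)
        mask /= mask.sum(axis=axis, keepdims=True)

        def bwd(g):
            gg = g if keepdims else np.expand_dims(g, axis)
            a._accum(mask * gg)

        res = out_data if keepdims else np.squeeze(out_data, axis=axis)
        return Tensor._make(res, (a,), bwd)

    # -- shape ---------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def bwd(g):
            a._accum(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def bwd(g):
            a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bwd)

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            out = np.zeros(a.shape, dtype=np.float64)
            if _is_advanced(idx):
                np.add.at(out, idx, g)
            else:
                out[idx] += g
            a._accum(out)

        return Tensor._make(a.data[idx], (a,), bwd)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bwd)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def bwd(g):
            a._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), bwd)

    def sigmoid(self):
        a = self
        out_data = special.expit(a.data)

        def bwd(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), bwd)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bwd(g):
            a._accum(g * (1.0 - out_data ** 2))

        return Tensor._make(out_data, (a,), bwd)

    def relu(self):
        a = self
        mask = (a.data > 0).astype(np.float64)

        def bwd(g):
            a._accum(g * mask)

        return Tensor._make(a.data * mask, (a,), bwd)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _is_advanced(idx) -> bool:
    if isinstance(idx, np.ndarray):
        return True
    if isinstance(idx, tuple):
        return any(isinstance(i, np.ndarray) for i in idx)
    return False


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._make(data, tensors, bwd)


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bwd(g):
        parts = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(np.squeeze(p, axis=axis))

    return Tensor._make(np.stack([t.data for t in tensors], axis=axis), tensors, bwd)


def roll(x: Tensor, shift, axis) -> Tensor:
    x = as_tensor(x)
    shifts = shift if isinstance(shift, tuple) else (shift,)
    axes = axis if isinstance(axis, tuple) else (axis,)

    def bwd(g):
        x._accum(np.roll(g, tuple(-s for s in shifts), axes))

    return Tensor._make(np.roll(x.data, shifts, axes), (x,), bwd)


def pad2d(x: Tensor, pad_h: tuple, pad_w: tuple) -> Tensor:
    """Zero-pad the H and W axes of a (B, H, W, C) tensor."""
    x = as_tensor(x)
    widths = ((0, 0), pad_h, pad_w, (0, 0))

    def bwd(g):
        sl = tuple(slice(lo, g.shape[i] - hi if hi else None)
                   for i, (lo, hi) in enumerate(widths))
        x._accum(g[sl])

    return Tensor._make(np.pad(x.data, widths), (x,), bwd)


def softmax(x: Tensor, axis=-1) -> Tensor:
    x = as_tensor(x)
    # max-shift for stability; the shift is a constant w.r.t. the gradient
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


_SQRT2 = np.sqrt(2.0)


def gelu(x: Tensor) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x = as_tensor(x)
    erf = special.erf(x.data / _SQRT2)
    out_data = 0.5 * x.data * (1.0 + erf)

    def bwd(g):
        pdf = np.exp(-0.5 * x.data ** 2) / np.sqrt(2.0 * np.pi)
        x._accum(g * (0.5 * (1.0 + erf) + x.data * pdf))

    return Tensor._make(out_data, (x,), bwd)


def take(table: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows of ``table`` by an integer index array (embedding lookup)."""
    table = as_tensor(table)

    def bwd(g):
        out = np.zeros(table.shape, dtype=np.float64)
        np.add.at(out, idx, g)
        table._accum(out)

    return Tensor._make(table.data[idx], (table,), bwd)


def conv2d(x: Tensor, kernel: Tensor, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution on (B, H, W, C_in) with kernel (kh, kw, C_in, C_out).

    Implemented by explicit patch extraction (im2col); the backward pass
    scatters gradients back with ``np.add.at``.
    """
    x = as_tensor(x)
    kernel = as_tensor(kernel)
    if padding:
        x = pad2d(x, (padding, padding), (padding, padding))
    b, h, w, cin = x.shape
    kh, kw, kcin, cout = kernel.shape
    if kcin != cin:
        raise ValueError(f"kernel expects {kcin} input channels, got {cin}")
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    view = np.lib.stride_tricks.sliding_window_view(x.data, (kh, kw), axis=(1, 2))
    # view: (b, oh', ow', cin, kh, kw) -> strided
    view = view[:, ::stride, ::stride]
    cols = view.transpose(0, 1, 2, 4, 5, 3).reshape(b, oh, ow, kh * kw * cin)
    kmat = kernel.data.reshape(kh * kw * cin, cout)
    out_data = cols @ kmat

    def bwd(g):
        gflat = g.reshape(b * oh * ow, cout)
        if kernel.requires_grad:
            gk = cols.reshape(b * oh * ow, -1).T @ gflat
            kernel._accum(gk.reshape(kernel.shape))
        if x.requires_grad:
            gcols = (gflat @ kmat.T).reshape(b, oh, ow, kh, kw, cin)
            gx = np.zeros(x.shape, dtype=np.float64)
            for i in range(kh):
                for j in range(kw):
                    gx[:, i:i + oh * stride:stride, j:j + ow * stride:stride] += gcols[:, :, :, i, j]
            x._accum(gx)

    return Tensor._make(out_data, (x, kernel), bwd)


def upsample_nearest2d(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour upsampling of (B, H, W, C) by an integer factor."""
    x = as_tensor(x)
    b, h, w, c = x.shape
    f = factor

    def bwd(g):
        gg = g.reshape(b, h, f, w, f, c).sum(axis=(2, 4))
        x._accum(gg)

    data = np.repeat(np.repeat(x.data, f, axis=1), f, axis=2)
    return Tensor._make(data, (x,), bwd)


def _interp_matrix(n_in: int, factor: int) -> np.ndarray:
    """Linear-interpolation matrix mapping n_in samples to n_in*factor
    (align_corners=False convention, edge-clamped)."""
    n_out = n_in * factor
    pos = (np.arange(n_out) + 0.5) / factor - 0.5
    lo = np.clip(np.floor(pos).astype(int), 0, n_in - 1)
    hi = np.clip(lo + 1, 0, n_in - 1)
    frac = np.clip(pos - lo, 0.0, 1.0)
    mat = np.zeros((n_out, n_in))
    mat[np.arange(n_out), lo] += 1.0 - frac
    mat[np.arange(n_out), hi] += frac
    return mat


def interp2d(x: Tensor, factor: int) -> Tensor:
    """Bilinear upsampling of (B, H, W, C) by an integer factor."""
    x = as_tensor(x)
    b, h, w, c = x.shape
    ah = _interp_matrix(h, factor)
    aw = _interp_matrix(w, factor)
    data = np.einsum("ih,bhwc,jw->bijc", ah, x.data, aw, optimize=True)

    def bwd(g):
        x._accum(np.einsum("ih,bijc,jw->bhwc", ah, g, aw, optimize=True))

    return Tensor._make(data, (x,), bwd)
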