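"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the counting network and its losses
need: broadcasted arithmetic, matmul, 2-D convolution (im2col), 2x2 max
pooling, bilinear resampling, reductions, relu/sigmoid/exp, concatenation.
Gradients are accumulated on a dynamically built tape and released by a
topological backward pass.  Every operator's backward is exercised against
central finite differences in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "conv2d", "maxpool2x2", "bilinear_resize", "no_grad"]

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode): outputs carry no tape."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """An ndarray plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype if self.data.dtype.kind == "f" else float)
        self.grad = self.grad + g

    def backward(self, grad=None) -> None:
        """Reverse-propagate from this (typically scalar) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
                node.grad = None  # interior grads are consumed; leaves keep theirs

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        return _binary(self, other, np.add, lambda g, a, b: (g, g))

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, lambda g, a, b: (g, -g))

    def __rsub__(self, other):
        return _binary(other, self, np.subtract, lambda g, a, b: (g, -g))

    def __neg__(self):
        return _unary(self, lambda x: -x, lambda g, x, y: -g)

    def __mul__(self, other):
        return _binary(self, other, np.multiply, lambda g, a, b: (g * b, g * a))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, np.divide, lambda g, a, b: (g / b, -g * a / (b * b)))

    def __rtruediv__(self, other):
        return _binary(other, self, np.divide, lambda g, a, b: (g / b, -g * a / (b * b)))

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        return _unary(self, lambda x: x**p, lambda g, x, y: g * p * x ** (p - 1))

    def __matmul__(self, other):
        other = _wrap(other)

        def backward(g, a, b):
            return g @ np.swapaxes(b, -1, -2), np.swapaxes(a, -1, -2) @ g

        return _binary(self, other, np.matmul, backward, broadcast=False)

    # -- elementwise nonlinearity ----------------------------------------

    def relu(self):
        return _unary(self, lambda x: np.maximum(x, 0), lambda g, x, y: g * (x > 0))

    def sigmoid(self):
        def fwd(x):
            out = np.empty_like(x)
            pos = x >= 0
            out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
            ex = np.exp(x[~pos])
            out[~pos] = ex / (1.0 + ex)
            return out

        return _unary(self, fwd, lambda g, x, y: g * y * (1.0 - y))

    def exp(self):
        return _unary(self, np.exp, lambda g, x, y: g * y)

    def sqrt(self):
        return _unary(self, np.sqrt, lambda g, x, y: g * 0.5 / y)

    # -- reductions and shaping ------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, x, y):
            if axis is None:
                return np.broadcast_to(g, x.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, x.shape).copy()

        return _unary(self, lambda x: x.sum(axis=axis, keepdims=keepdims), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int | tuple[int, ...], keepdims: bool = False):
        """Max-reduction; ties share the gradient equally."""
        def fwd(x):
            return x.max(axis=axis, keepdims=keepdims)

        def backward(g, x, y):
            yk = y if keepdims else np.expand_dims(y, axis)
            gk = g if keepdims else np.expand_dims(g, axis)
            mask = (x == yk).astype(x.dtype)
            mask /= mask.sum(axis=axis, keepdims=True)
            return mask * gk

        return _unary(self, fwd, backward)

    def reshape(self, *shape):
        old = self.data.shape
        return _unary(
            self, lambda x: x.reshape(*shape), lambda g, x, y: g.reshape(old)
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return _unary(
            self, lambda x: x.transpose(*axes), lambda g, x, y: g.transpose(*inv)
        )


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _unary(a: Tensor, fwd, backward) -> Tensor:
    out = Tensor(fwd(a.data))
    if _GRAD_ENABLED and a.requires_grad:
        out.requires_grad = True
        out._parents = (a,)

        def _bw():
            a._accumulate(backward(out.grad, a.data, out.data))

        out._backward = _bw
    return out


def _binary(a, b, fwd, backward, broadcast: bool = True) -> Tensor:
    # keep python scalars out of _wrap: 0-d float64 arrays are "strong" under
    # NumPy 2 promotion and would silently upcast float32 graphs
    if isinstance(b, (int, float)) or (isinstance(a, (int, float)) and isinstance(b, Tensor)):
        if isinstance(a, (int, float)):
            a, b = b, a
            fwd_, backward_ = fwd, backward
            fwd = lambda x, y: fwd_(y, x)  # noqa: E731
            backward = lambda g, x, y: backward_(g, y, x)[::-1]  # noqa: E731
        out = Tensor(fwd(a.data, b))
        if _GRAD_ENABLED and a.requires_grad:
            out.requires_grad = True
            out._parents = (a,)

            def _bw_scalar():
                ga, _ = backward(out.grad, a.data, b)
                a._accumulate(_unbroadcast(ga, a.data.shape) if broadcast else ga)

            out._backward = _bw_scalar
        return out

    a, b = _wrap(a), _wrap(b)
    out = Tensor(fwd(a.data, b.data))
    if _GRAD_ENABLED and (a.requires_grad or b.requires_grad):
        out.requires_grad = True
        out._parents = (a, b)

        def _bw():
            ga, gb = backward(out.grad, a.data, b.data)
            if a.requires_grad:
                a._accumulate(_unbroadcast(ga, a.data.shape) if broadcast else ga)
            if b.requires_grad:
                b._accumulate(_unbroadcast(gb, b.data.shape) if broadcast else gb)

        out._backward = _bw
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _bw():
            for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(g)

        out._backward = _bw
    return out


# -- 2-D convolution ------------------------------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int, dilation: int):
    """(B, C, Hp, Wp) -> (B, oh*ow, C*kh*kw) patch matrix (stride 1)."""
    eh, ew = (kh - 1) * dilation + 1, (kw - 1) * dilation + 1
    win = sliding_window_view(xp, (eh, ew), axis=(2, 3))[..., ::dilation, ::dilation]
    b, c, oh, ow = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b, oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0, dilation: int = 1) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation), NCHW layout.

    ``x``: (B, C, H, W); ``w``: (O, C, kh, kw); ``b``: (O,) or None.
    """
    x, w = _wrap(x), _wrap(w)
    xd, wd = x.data, w.data
    B, C, H, W = xd.shape
    O, Cw, kh, kw = wd.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else xd
    cols, oh, ow = _im2col(xp, kh, kw, dilation)
    wf = wd.reshape(O, -1)
    out_d = cols @ wf.T  # (B, oh*ow, O)
    if b is not None:
        out_d = out_d + b.data
    out = Tensor(out_d.transpose(0, 2, 1).reshape(B, O, oh, ow))
    del cols  # rebuilt on demand in backward; keeping it would dominate memory

    needs = _GRAD_ENABLED and (x.requires_grad or w.requires_grad or (b is not None and b.requires_grad))
    if needs:
        out.requires_grad = True
        out._parents = (x, w) if b is None else (x, w, b)

        def _bw():
            g = out.grad.reshape(B, O, oh * ow).transpose(0, 2, 1)  # (B, ohw, O)
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 1)))
            if w.requires_grad:
                cols2, _, _ = _im2col(xp, kh, kw, dilation)
                gw = np.einsum("bpo,bpk->ok", g, cols2, optimize=True)
                del cols2
                w._accumulate(gw.reshape(wd.shape))
            if x.requires_grad:
                dcols = g @ wf  # (B, ohw, C*kh*kw)
                dcols = dcols.reshape(B, oh, ow, C, kh, kw).transpose(0, 3, 1, 2, 4, 5)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i * dilation : i * dilation + oh, j * dilation : j * dilation + ow] += dcols[
                            :, :, :, :, i, j
                        ]
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                x._accumulate(gxp)

        out._backward = _bw
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; H and W must be even."""
    x = _wrap(x)
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {H}x{W}")
    blocks = x.data.reshape(B, C, H // 2, 2, W // 2, 2)
    out = Tensor(blocks.max(axis=(3, 5)))
    if _GRAD_ENABLED and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def _bw():
            yk = out.data[:, :, :, None, :, None]
            mask = (blocks == yk).astype(x.data.dtype)
            mask /= mask.sum(axis=(3, 5), keepdims=True)
            g = mask * out.grad[:, :, :, None, :, None]
            x._accumulate(g.reshape(B, C, H, W))

        out._backward = _bw
    return out


# -- bilinear resampling --------------------------------------------------

_RESIZE_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}


def _resize_axis_weights(n_in: int, n_out: int):
    """Index/weight arrays for 1-D bilinear resampling (half-pixel centers)."""
    key = (n_in, n_out)
    hit = _RESIZE_CACHE.get(key)
    if hit is not None:
        return hit
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    i0 = np.floor(src).astype(int)
    frac = src - i0
    i0c = np.clip(i0, 0, n_in - 1)
    i1c = np.clip(i0 + 1, 0, n_in - 1)
    _RESIZE_CACHE[key] = (i0c, i1c, frac)
    return _RESIZE_CACHE[key]


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of (B, C, H, W) to (B, C, out_h, out_w).

    Half-pixel (align_corners=False) coordinate convention, edges clamped.
    """
    x = _wrap(x)
    B, C, H, W = x.data.shape
    r0, r1, fr = _resize_axis_weights(H, out_h)
    c0, c1, fc = _resize_axis_weights(W, out_w)
    d = x.data
    fr = fr.astype(d.dtype, copy=False)
    fc = fc.astype(d.dtype, copy=False)
    top = d[:, :, r0, :]
    bot = d[:, :, r1, :]
    # interpolate rows then columns
    mid = top * (1 - fr)[None, None, :, None] + bot * fr[None, None, :, None]
    out_d = mid[:, :, :, c0] * (1 - fc)[None, None, None, :] + mid[:, :, :, c1] * fc[None, None, None, :]
    out = Tensor(out_d)
    if _GRAD_ENABLED and x.requires_grad:
        out.requires_grad = True
        out._parents = (x,)

        def _bw():
            g = out.grad
            gmid = np.zeros((B, C, out_h, W), dtype=g.dtype)
            np.add.at(gmid, (slice(None), slice(None), slice(None), c0), g * (1 - fc)[None, None, None, :])
            np.add.at(gmid, (slice(None), slice(None), slice(None), c1), g * fc[None, None, None, :])
            gx = np.zeros_like(x.data)
            np.add.at(gx, (slice(None), slice(None), r0), gmid * (1 - fr)[None, None, :, None])
            np.add.at(gx, (slice(None), slice(None), r1), gmid * fr[None, None, :, None])
            x._accumulate(gx)

        out._backward = _bw
    return out
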