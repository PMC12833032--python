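"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations applied
to it; :meth:`Tensor.backward` accumulates gradients by walking the recorded
graph in reverse topological order.  Only the operations the segmentation /
regression network needs are implemented: broadcast arithmetic, matmul,
pointwise nonlinearities, reductions, concatenation, 2-D convolution
(im2col), non-overlapping average pooling and bilinear upsampling.

The engine is deliberately small: define-by-run closures in the style of
micrograd, but vectorised over ndarrays.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "avg_pool2d", "upsample_bilinear"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of NumPy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- basic protocol ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    # -- autograd ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape)
                )

        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = _bw
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = _bw
        return out

    # -- pointwise nonlinearities -------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = _bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = _bw
        return out

    def softplus(self):
        # numerically stable: log(1+exp(x)) = max(x,0) + log1p(exp(-|x|))
        d = self.data
        val = np.maximum(d, 0.0) + np.log1p(np.exp(-np.abs(d)))
        out = Tensor(val, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g / (1.0 + np.exp(-d)))

        out._backward = _bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = _bw
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g * e)

        out._backward = _bw
        return out

    def sqrt(self):
        return self ** 0.5

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient passes only where the input is interior."""
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))
        mask = (self.data >= lo) & (self.data <= hi)

        def _bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = _bw
        return out

    # -- reductions / reshaping ---------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = _bw
        return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(a, b)
                t._accum(g[tuple(idx)])

    out._backward = _bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) on NCHW input via im2col.

    ``w`` has shape (F, C, KH, KW); output (N, F, OH, OW).  1x1 kernels take
    a channel-contraction fast path without materialising patch matrices.
    """
    N, C, H, W = x.data.shape
    F, C2, KH, KW = w.data.shape
    if C != C2:
        raise ValueError(f"conv2d: input has {C} channels, kernel expects {C2}")
    s, p = stride, padding
    if KH == 1 and KW == 1 and p == 0:
        return _conv1x1(x, w, b, s)
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    OH = (H + 2 * p - KH) // s + 1
    OW = (W + 2 * p - KW) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (KH, KW), axis=(2, 3))
    win = win[:, :, ::s, ::s]                       # N,C,OH,OW,KH,KW
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * OH * OW, C * KH * KW)
    wmat = w.data.reshape(F, C * KH * KW)
    out_flat = cols @ wmat.T
    if b is not None:
        out_flat = out_flat + b.data
    out_data = out_flat.reshape(N, OH, OW, F).transpose(0, 3, 1, 2)
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _prev=prev)

    def _bw(g):
        g2 = g.transpose(0, 2, 3, 1).reshape(N * OH * OW, F)
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=0))
        if w.requires_grad:
            w._accum((g2.T @ cols).reshape(F, C, KH, KW))
        if x.requires_grad:
            gcols = (g2 @ wmat).reshape(N, OH, OW, C, KH, KW)
            gxp = np.zeros((N, C, H + 2 * p, W + 2 * p))
            for i in range(KH):
                for j in range(KW):
                    gxp[:, :, i:i + s * OH:s, j:j + s * OW:s] += \
                        gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            x._accum(gxp[:, :, p:p + H, p:p + W] if p else gxp)

    out._backward = _bw
    return out


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None, s: int) -> Tensor:
    xs = x.data[:, :, ::s, ::s]
    wmat = w.data.reshape(w.data.shape[0], -1)            # (F, C)
    out_data = np.einsum("fc,nchw->nfhw", wmat, xs, optimize=True)
    if b is not None:
        out_data += b.data[None, :, None, None]
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, _prev=prev)

    def _bw(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.einsum("nfhw,nchw->fc", g, xs, optimize=True)
            w._accum(gw.reshape(w.data.shape))
        if x.requires_grad:
            gxs = np.einsum("fc,nfhw->nchw", wmat, g, optimize=True)
            if s == 1:
                x._accum(gxs)
            else:
                gx = np.zeros_like(x.data)
                gx[:, :, ::s, ::s] = gxs
                x._accum(gx)

    out._backward = _bw
    return out


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5
                ) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused batch normalisation over (N, H, W) with analytic backward.

    Returns (output, batch mean, batch variance); the statistics are plain
    arrays for the caller's running-average bookkeeping.
    """
    d = x.data
    mu = d.mean(axis=(0, 2, 3), keepdims=True)
    xc = d - mu
    var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
    ivar = 1.0 / np.sqrt(var + eps)
    xhat = xc * ivar
    gph = gamma.data.reshape(1, -1, 1, 1)
    out = Tensor(xhat * gph + beta.data.reshape(1, -1, 1, 1),
                 _prev=(x, gamma, beta))

    def _bw(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxhat = g * gph
            t1 = gxhat.mean(axis=(0, 2, 3), keepdims=True)
            t2 = (gxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
            x._accum(ivar * (gxhat - t1 - xhat * t2))

    out._backward = _bw
    return out, mu.ravel(), var.ravel()


def avg_pool2d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping k x k average pooling; H and W must be divisible by k."""
    N, C, H, W = x.data.shape
    if H % k or W % k:
        raise ValueError(f"avg_pool2d: spatial size {(H, W)} not divisible by {k}")
    out_data = x.data.reshape(N, C, H // k, k, W // k, k).mean(axis=(3, 5))
    out = Tensor(out_data, _prev=(x,))

    def _bw(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
            x._accum(gx)

    out._backward = _bw
    return out


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize of NCHW input to ``size`` (align_corners=False)."""
    N, C, H, W = x.data.shape
    H2, W2 = size
    r = np.clip((np.arange(H2) + 0.5) * H / H2 - 0.5, 0, H - 1)
    c = np.clip((np.arange(W2) + 0.5) * W / W2 - 0.5, 0, W - 1)
    r0 = np.floor(r).astype(np.intp)
    c0 = np.floor(c).astype(np.intp)
    r1 = np.minimum(r0 + 1, H - 1)
    c1 = np.minimum(c0 + 1, W - 1)
    wr = (r - r0)[:, None]
    wc = (c - c0)[None, :]
    d = x.data
    top = (1 - wc) * d[:, :, r0][:, :, :, c0] + wc * d[:, :, r0][:, :, :, c1]
    bot = (1 - wc) * d[:, :, r1][:, :, :, c0] + wc * d[:, :, r1][:, :, :, c1]
    out = Tensor((1 - wr) * top + wr * bot, _prev=(x,))

    def _bw(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        R0 = r0[:, None]
        R1 = r1[:, None]
        C0 = c0[None, :]
        C1 = c1[None, :]
        np.add.at(gx, (slice(None), slice(None), R0, C0), g * (1 - wr) * (1 - wc))
        np.add.at(gx, (slice(None), slice(None), R0, C1), g * (1 - wr) * wc)
        np.add.at(gx, (slice(None), slice(None), R1, C0), g * wr * (1 - wc))
        np.add.at(gx, (slice(None), slice(None), R1, C1), g * wr * wc)
        x._accum(gx)

    out._backward = _bw
    return out
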