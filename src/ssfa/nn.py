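"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the segmentation networks need: 3x3 and 1x1
convolutions, 2x2 max pooling, x2 bilinear upsampling, channel concatenation,
element-wise arithmetic, ReLU/tanh, group normalization, channel softmax and
reductions.  Everything is deterministic: no threading, no fused kernels, one
numpy RNG per parameter initializer.

Feature maps use NHWC layout (batch, height, width, channels): with channels
last, each spatial row is a contiguous (W, C) matrix and convolutions reduce
to nine batched BLAS matmuls over shifted views of the padded input — no
im2col materialization.

The engine is deliberately small.  A :class:`Tensor` wraps an ndarray,
records its parents and a backward closure; :meth:`Tensor.backward` runs a
topological sweep accumulating gradients into ``.grad`` of every tensor that
requires them.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "sub", "mul", "div", "scale", "shift",
    "relu", "tanh", "sum_all", "sum_axes",
    "conv2d", "conv1x1", "maxpool2", "upsample2", "concat_ch", "channel",
    "group_norm", "softmax_ch",
    "SGD",
]


class Tensor:
    """An ndarray node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        data = np.asarray(data)
        if data.dtype.kind in "iub":
            data = data.astype(np.float32)
        self.data = data
        self.grad = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in self.parents
        )

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) tensor w.r.t. the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # arithmetic sugar (constants are wrapped as non-grad tensors)
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, _wrap(other))


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------- arithmetic

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    out._backward = bw
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data - b.data, (a, b))

    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(-g, b.data.shape))

    out._backward = bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))

    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    out._backward = bw
    return out


def div(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data / b.data, (a, b))

    def bw(g):
        _accum(a, _unbroadcast(g / b.data, a.data.shape))
        _accum(b, _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    out._backward = bw
    return out


def scale(a: Tensor, c: float) -> Tensor:
    out = Tensor(a.data * c, (a,))
    out._backward = lambda g: _accum(a, g * c)
    return out


def shift(a: Tensor, c: float) -> Tensor:
    out = Tensor(a.data + c, (a,))
    out._backward = lambda g: _accum(a, g)
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, (a,))
    out._backward = lambda g: _accum(a, g * mask)
    return out


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)
    out = Tensor(y, (a,))
    out._backward = lambda g: _accum(a, g * (1.0 - y * y))
    return out


def sum_all(a: Tensor) -> Tensor:
    out = Tensor(np.asarray(a.data.sum()), (a,))
    out._backward = lambda g: _accum(a, np.broadcast_to(g, a.data.shape))
    return out


def sum_axes(a: Tensor, axes: tuple) -> Tensor:
    """Sum over ``axes`` with keepdims=True (so results broadcast back)."""
    out = Tensor(a.data.sum(axis=axes, keepdims=True), (a,))
    out._backward = lambda g: _accum(a, np.broadcast_to(g, a.data.shape))
    return out


# ------------------------------------------------------------- convolutions

def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3x3 convolution, stride 1, zero padding 1.

    x: (N, H, W, C); w: (3, 3, C, O); b: (O,).  Each tap is one batched
    matmul of a contiguous shifted view against (C, O).
    """
    N, H, W, C = x.data.shape
    O = w.data.shape[3]
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (0, 0)))
    y = np.zeros((N, H, W, O), dtype=x.data.dtype)
    for ki in range(3):
        for kj in range(3):
            y += np.matmul(xp[:, ki:ki + H, kj:kj + W, :], w.data[ki, kj])
    y += b.data
    out = Tensor(y, (x, w, b))

    def bw(g):
        if b.requires_grad:
            _accum(b, g.sum(axis=(0, 1, 2)))
        if w.requires_grad:
            gw = np.empty_like(w.data)
            for ki in range(3):
                for kj in range(3):
                    gw[ki, kj] = np.tensordot(
                        xp[:, ki:ki + H, kj:kj + W, :], g,
                        axes=([0, 1, 2], [0, 1, 2]))
            _accum(w, gw)
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for ki in range(3):
                for kj in range(3):
                    gxp[:, ki:ki + H, kj:kj + W, :] += np.matmul(
                        g, w.data[ki, kj].T)
            _accum(x, gxp[:, 1:-1, 1:-1, :])

    out._backward = bw
    return out


def conv1x1(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """1x1 convolution. x: (N, H, W, C); w: (C, O); b: (O,)."""
    y = np.matmul(x.data, w.data) + b.data
    out = Tensor(y, (x, w, b))

    def bw(g):
        if w.requires_grad:
            _accum(w, np.tensordot(x.data, g, axes=([0, 1, 2], [0, 1, 2])))
        if b.requires_grad:
            _accum(b, g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            _accum(x, np.matmul(g, w.data.T))

    out._backward = bw
    return out


# ------------------------------------------------------- pooling / sampling

def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2.  Ties resolve to the first element."""
    N, H, W, C = x.data.shape
    xr = x.data.reshape(N, H // 2, 2, W // 2, 2, C)
    flat = xr.transpose(0, 1, 3, 5, 2, 4).reshape(N, H // 2, W // 2, C, 4)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    out = Tensor(y, (x,))

    def bw(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(N, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        _accum(x, gx.reshape(N, H, W, C))

    out._backward = bw
    return out


_UP_CACHE: dict[int, np.ndarray] = {}


def _up_matrix(n_in: int) -> np.ndarray:
    """(2n, n) bilinear x2 interpolation matrix for one axis (align_corners=False)."""
    if n_in not in _UP_CACHE:
        src = (np.arange(2 * n_in) + 0.5) / 2.0 - 0.5
        i0 = np.clip(np.floor(src).astype(np.intp), 0, n_in - 1)
        i1 = np.clip(i0 + 1, 0, n_in - 1)
        f = np.clip(src - np.floor(src), 0.0, 1.0)
        f[src < 0] = 0.0
        U = np.zeros((2 * n_in, n_in), dtype=np.float32)
        U[np.arange(2 * n_in), i0] += 1.0 - f
        U[np.arange(2 * n_in), i1] += f
        _UP_CACHE[n_in] = U
    return _UP_CACHE[n_in]


def upsample2(x: Tensor) -> Tensor:
    """Bilinear upsampling by a factor of 2 in both spatial axes."""
    N, H, W, C = x.data.shape
    Ur = _up_matrix(H).astype(x.data.dtype)
    Uc = _up_matrix(W).astype(x.data.dtype)
    # rows: (2H,H) x (N,H,W,C) -> (N,2H,W,C); then columns likewise
    y = np.moveaxis(np.tensordot(Ur, x.data, axes=(1, 1)), 0, 1)
    y = np.moveaxis(np.tensordot(Uc, y, axes=(1, 2)), 0, 2)
    out = Tensor(np.ascontiguousarray(y), (x,))

    def bw(g):
        gx = np.moveaxis(np.tensordot(Uc.T, g, axes=(1, 2)), 0, 2)
        gx = np.moveaxis(np.tensordot(Ur.T, gx, axes=(1, 1)), 0, 1)
        _accum(x, np.ascontiguousarray(gx))

    out._backward = bw
    return out


def concat_ch(a: Tensor, b: Tensor) -> Tensor:
    na = a.data.shape[-1]
    out = Tensor(np.concatenate([a.data, b.data], axis=-1), (a, b))

    def bw(g):
        _accum(a, g[..., :na])
        _accum(b, g[..., na:])

    out._backward = bw
    return out


def channel(x: Tensor, idx: int) -> Tensor:
    """Select one channel, keeping the axis: (N,H,W,C) -> (N,H,W,1)."""
    out = Tensor(np.ascontiguousarray(x.data[..., idx:idx + 1]), (x,))

    def bw(g):
        gx = np.zeros_like(x.data)
        gx[..., idx:idx + 1] = g
        _accum(x, gx)

    out._backward = bw
    return out


# ------------------------------------------------------------ normalization

def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int,
               eps: float = 1e-5) -> Tensor:
    """Group normalization with per-channel affine parameters. x: (N,H,W,C)."""
    N, H, W, C = x.data.shape
    G = groups
    xg = x.data.reshape(N, H, W, G, C // G)
    mu = xg.mean(axis=(1, 2, 4), keepdims=True)
    var = xg.var(axis=(1, 2, 4), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * inv).reshape(N, H, W, C)
    y = xhat * gamma.data + beta.data
    out = Tensor(y, (x, gamma, beta))

    def bw(g):
        if gamma.requires_grad:
            _accum(gamma, (g * xhat).sum(axis=(0, 1, 2)))
        if beta.requires_grad:
            _accum(beta, g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            gy = (g * gamma.data).reshape(N, H, W, G, C // G)
            xh = xhat.reshape(N, H, W, G, C // G)
            gmean = gy.mean(axis=(1, 2, 4), keepdims=True)
            gxmean = (gy * xh).mean(axis=(1, 2, 4), keepdims=True)
            gx = inv * (gy - gmean - xh * gxmean)
            _accum(x, gx.reshape(N, H, W, C))

    out._backward = bw
    return out


def softmax_ch(x: Tensor) -> Tensor:
    """Softmax over the channel (last) axis of (N,H,W,C)."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(y, (x,))

    def bw(g):
        dot = (g * y).sum(axis=-1, keepdims=True)
        _accum(x, y * (g - dot))

    out._backward = bw
    return out


# ---------------------------------------------------------------- optimizer

class SGD:
    """Stochastic gradient descent with momentum and weight decay."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v = self._vel[k]
            v *= self.momentum
            v -= self.lr * g
            p.data = p.data + v
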