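"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Only the operations the segmentation network needs are implemented:
2-D convolution (stride 1, zero padding), 3x3/stride-2 max pooling,
batch normalization, nearest-neighbour 2x upsampling, channel
concatenation, element-wise add/multiply, ReLU, sigmoid, dense layers,
a global max-pool squeeze, and two fused losses (binary cross-entropy
on logits and soft Dice).  Feature maps are stored NHWC in float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "conv2d",
    "maxpool2d_s2",
    "upsample2x",
    "concat",
    "batchnorm2d",
    "global_maxpool",
    "bce_with_logits",
    "soft_dice_loss",
]


class Tensor:
    """An array node in the computation graph.

    ``backward()`` runs reverse-mode accumulation from a scalar output.
    Gradients are accumulated into ``.grad`` of every reachable tensor
    with ``requires_grad=True``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward_fn=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward_fn

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        if self.data.size != 1:
            raise ValueError("item() requires a single-element tensor")
        return float(self.data.ravel()[0])

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow recursion limits
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


def _needs(*tensors: Tensor) -> bool:
    return any(t.requires_grad for t in tensors)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, _needs(a, b), (a, b))

    def bw(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    out._backward = bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, _needs(a, b), (a, b))

    def bw(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    out._backward = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, _needs(a, b), (a, b))

    def bw(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    out._backward = bw
    return out


def relu(x: Tensor) -> Tensor:
    y = np.maximum(x.data, 0.0)
    out = Tensor(y, x.requires_grad, (x,))

    def bw(g):
        _accum(x, g * (x.data > 0))

    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(y, x.requires_grad, (x,))

    def bw(g):
        _accum(x, g * y * (1.0 - y))

    out._backward = bw
    return out


def _im2col(xp: np.ndarray, f: int) -> np.ndarray:
    """(N, Hp, Wp, C) -> (N, Ho, Wo, f*f*C) patch matrix, stride 1."""
    win = sliding_window_view(xp, (f, f), axis=(1, 2))  # (N, Ho, Wo, C, f, f)
    win = win.transpose(0, 1, 2, 4, 5, 3)  # (N, Ho, Wo, f, f, C)
    n, ho, wo = win.shape[:3]
    return np.ascontiguousarray(win).reshape(n, ho, wo, -1)


def _conv_raw(x: np.ndarray, w: np.ndarray, pad: int) -> np.ndarray:
    """Plain stride-1 cross-correlation, NHWC x (f, f, Cin, Cout)."""
    f = w.shape[0]
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x
    cols = _im2col(xp, f)
    return cols @ w.reshape(-1, w.shape[-1])


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 1) -> Tensor:
    """Stride-1 2-D convolution ("Same" for odd kernels with pad=(f-1)/2)."""
    f = w.data.shape[0]
    xp = np.pad(x.data, ((0, 0), (padding, padding), (padding, padding), (0, 0))) if padding else x.data
    cols = _im2col(xp, f)  # (N, Ho, Wo, f*f*Cin)
    y = cols @ w.data.reshape(-1, w.data.shape[-1])
    if b is not None:
        y = y + b.data
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, _needs(*parents), parents)

    def bw(g):
        n, ho, wo, co = g.shape
        gm = g.reshape(-1, co)
        if w.requires_grad:
            dw = cols.reshape(-1, cols.shape[-1]).T @ gm
            _accum(w, dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            _accum(b, gm.sum(axis=0))
        if x.requires_grad:
            # dX = full correlation of dY with the spatially flipped,
            # in/out-transposed kernel.
            w_rot = w.data[::-1, ::-1].transpose(0, 1, 3, 2)  # (f, f, Cout, Cin)
            dx = _conv_raw(g, np.ascontiguousarray(w_rot), f - 1 - padding)
            _accum(x, dx)

    out._backward = bw
    return out


def maxpool2d_s2(x: Tensor, window: int = 3) -> Tensor:
    """Max pooling, stride 2, symmetric padding 1 ("Same"): halves H and W."""
    n, h, w_, c = x.data.shape
    xp = np.pad(x.data, ((0, 0), (1, 1), (1, 1), (0, 0)), constant_values=-np.inf)
    win = sliding_window_view(xp, (window, window), axis=(1, 2))[:, ::2, ::2]
    winr = win.reshape(*win.shape[:4], window * window)  # (N, Ho, Wo, C, k*k)
    arg = winr.argmax(axis=-1)
    out_data = np.take_along_axis(winr, arg[..., None], axis=-1)[..., 0]
    out = Tensor(out_data, x.requires_grad, (x,))

    def bw(g):
        ho, wo = arg.shape[1:3]
        di, dj = arg // window, arg % window
        ii = (np.arange(ho) * 2)[None, :, None, None] + di
        jj = (np.arange(wo) * 2)[None, None, :, None] + dj
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, None, None, :]
        gxp = np.zeros((n, h + 2, w_ + 2, c), dtype=np.float32)
        np.add.at(gxp, (nn, ii, jj, cc), g)
        _accum(x, gxp[:, 1:-1, 1:-1, :])

    out._backward = bw
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Parameter-free nearest-neighbour doubling of H and W."""
    y = x.data.repeat(2, axis=1).repeat(2, axis=2)
    out = Tensor(y, x.requires_grad, (x,))

    def bw(g):
        n, h2, w2, c = g.shape
        _accum(x, g.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4)))

    out._backward = bw
    return out


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Channel concatenation (last axis) of two NHWC maps."""
    out = Tensor(np.concatenate([a.data, b.data], axis=-1), _needs(a, b), (a, b))
    ca = a.data.shape[-1]

    def bw(g):
        _accum(a, g[..., :ca])
        _accum(b, g[..., ca:])

    out._backward = bw
    return out


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Batch normalization over (N, H, W) per channel.

    Returns ``(out, batch_mean, batch_var)``; the caller maintains
    running statistics for inference.  Variance is the biased estimate.
    """
    axes = (0, 1, 2)
    m = x.data.mean(axis=axes)
    v = x.data.var(axis=axes)
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m) * inv
    y = gamma.data * xhat + beta.data
    out = Tensor(y, _needs(x, gamma, beta), (x, gamma, beta))
    count = x.data.shape[0] * x.data.shape[1] * x.data.shape[2]

    def bw(g):
        if gamma.requires_grad:
            _accum(gamma, (g * xhat).sum(axis=axes))
        if beta.requires_grad:
            _accum(beta, g.sum(axis=axes))
        if x.requires_grad:
            dxhat = g * gamma.data
            # standard batch-norm backward (biased variance)
            t1 = dxhat.sum(axis=axes)
            t2 = (dxhat * xhat).sum(axis=axes)
            dx = (dxhat - (t1 + xhat * t2) / count) * inv
            _accum(x, dx.astype(np.float32))

    out._backward = bw
    return out, m, v


def global_maxpool(x: Tensor) -> Tensor:
    """Squeeze (N, H, W, C) -> (N, C) by max over the spatial extent."""
    n, h, w_, c = x.data.shape
    xr = x.data.reshape(n, h * w_, c)
    arg = xr.argmax(axis=1)  # (N, C)
    out = Tensor(np.take_along_axis(xr, arg[:, None, :], axis=1)[:, 0, :], x.requires_grad, (x,))

    def bw(g):
        gx = np.zeros((n, h * w_, c), dtype=np.float32)
        np.put_along_axis(gx, arg[:, None, :], g[:, None, :], axis=1)
        _accum(x, gx.reshape(n, h, w_, c))

    out._backward = bw
    return out


def bce_with_logits(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of sigmoid(logits) against a 0/1 target.

    Fused with the sigmoid for numerical stability; the gradient is
    (p - t) / n_elements with p = sigmoid(z).
    """
    z = logits.data
    t = np.asarray(target, dtype=np.float32)
    loss = np.maximum(z, 0.0) - z * t + np.log1p(np.exp(-np.abs(z)))
    out = Tensor(loss.mean(), logits.requires_grad, (logits,))

    def bw(g):
        p = 1.0 / (1.0 + np.exp(-z))
        _accum(logits, g * (p - t) / z.size)

    out._backward = bw
    return out


def soft_dice_loss(logits: Tensor, target: np.ndarray, smooth: float = 1.0) -> Tensor:
    """1 - soft Dice of sigmoid(logits) vs. target, pooled over the batch."""
    z = logits.data
    t = np.asarray(target, dtype=np.float32)
    p = 1.0 / (1.0 + np.exp(-z))
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum())
    dice = (2.0 * inter + smooth) / (denom + smooth)
    out = Tensor(1.0 - dice, logits.requires_grad, (logits,))

    def bw(g):
        # d(dice)/dp, then chain through the sigmoid
        dp = (2.0 * t * (denom + smooth) - (2.0 * inter + smooth)) / (denom + smooth) ** 2
        _accum(logits, g * (-dp) * p * (1.0 - p))

    out._backward = bw
    return out
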