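"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains its networks on CPU with plain numpy, so this module
provides the small set of differentiable operations a convolutional
encoder--decoder needs: 2-D convolution (stride 1, "same" padding),
strided transposed convolution, 2x2 max pooling, nearest-neighbour
upsampling, channel concatenation, ReLU/sigmoid, batch normalisation,
elementwise averaging, and the two segmentation losses.

Tensors are float32 by default; float64 inputs are preserved, which the
test-suite uses for finite-difference gradient checks.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _as_float(data):
    a = np.asarray(data)
    if a.dtype not in (np.float32, np.float64):
        a = a.astype(np.float32)
    return a


class Tensor:
    """A numpy array plus the bookkeeping for reverse-mode autodiff."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_float(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- gradient plumbing ---------------------------------------------
    def accumulate_grad(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        """Backpropagate from this tensor through the recorded graph."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.accumulate_grad(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
                # free the closure (and any cached activations) eagerly
                node._backward = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward_builder):
    """Create an op output; record backward only when a parent needs grads."""
    out = Tensor(data)
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if grad_enabled() and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward_builder(out)
    return out


# ---------------------------------------------------------------------
# elementwise / shape ops
# ---------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def build(out):
        def _backward():
            g = out.grad
            if a.requires_grad:
                a.accumulate_grad(g)
            if b.requires_grad:
                b.accumulate_grad(g)
        return _backward
    return _node(a.data + b.data, (a, b), build)


def scale(a: Tensor, s: float) -> Tensor:
    def build(out):
        def _backward():
            if a.requires_grad:
                a.accumulate_grad(out.grad * s)
        return _backward
    return _node(a.data * s, (a,), build)


def mean_pair(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise (a + b) / 2 — the feature-fusion primitive."""
    if a.data.shape != b.data.shape:
        raise ValueError(
            f"mean_pair requires identical shapes, got {a.data.shape} and {b.data.shape}"
        )

    def build(out):
        def _backward():
            g = out.grad
            if a.requires_grad:
                a.accumulate_grad(0.5 * g)
            if b.requires_grad:
                b.accumulate_grad(0.5 * g)
        return _backward
    return _node((a.data + b.data) * 0.5, (a, b), build)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def build(out):
        def _backward():
            if x.requires_grad:
                x.accumulate_grad(out.grad * mask)
        return _backward
    return _node(np.where(mask, x.data, 0), (x,), build)


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable two-branch evaluation
    d = x.data
    s = np.empty_like(d)
    pos = d >= 0
    s[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    ex = np.exp(d[~pos])
    s[~pos] = ex / (1.0 + ex)

    def build(out):
        def _backward():
            if x.requires_grad:
                x.accumulate_grad(out.grad * s * (1.0 - s))
        return _backward
    return _node(s, (x,), build)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]

    def build(out):
        def _backward():
            g = out.grad
            if a.requires_grad:
                a.accumulate_grad(g[:, :ca])
            if b.requires_grad:
                b.accumulate_grad(g[:, ca:])
        return _backward
    return _node(np.concatenate([a.data, b.data], axis=1), (a, b), build)


# ---------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------

def _conv2d_forward(x: np.ndarray, w: np.ndarray, pad: int):
    """Stride-1 cross-correlation; returns output and the im2col matrix."""
    n, c, h, wd = x.shape
    o, _, kh, kw = w.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (n,c,H,W,kh,kw)
    hh, ww = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * hh * ww, c * kh * kw
    )
    out = cols @ w.reshape(o, -1).T
    return out.reshape(n, hh, ww, o).transpose(0, 3, 1, 2), cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, pad: int) -> Tensor:
    """2-D convolution, stride 1.  `pad = k // 2` gives "same" output."""
    need_grad = grad_enabled() and (
        x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    )
    out_data, cols = _conv2d_forward(x.data, w.data, pad)
    if b is not None:
        out_data += b.data[None, :, None, None]
    if not need_grad:
        return Tensor(out_data)
    cols_cache = cols if w.requires_grad else None

    def build(out):
        def _backward():
            g = out.grad
            o = w.data.shape[0]
            if w.requires_grad:
                gmat = g.transpose(0, 2, 3, 1).reshape(-1, o)
                w.accumulate_grad((gmat.T @ cols_cache).reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b.accumulate_grad(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                k = w.data.shape[2]
                w_flip = w.data.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
                dx, _ = _conv2d_forward(g, np.ascontiguousarray(w_flip), k - 1 - pad)
                x.accumulate_grad(dx)
        return _backward
    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, build)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (non-overlapping blocks).

    Weight layout is (C_in, C_out, 2, 2); output spatial size doubles.
    """
    n, c, h, wd = x.data.shape
    _, o, _, _ = w.data.shape
    out6 = np.einsum("nchw,coij->nohiwj", x.data, w.data, optimize=True)
    out_data = out6.reshape(n, o, 2 * h, 2 * wd)
    if b is not None:
        out_data += b.data[None, :, None, None]

    def build(out):
        def _backward():
            g = out.grad.reshape(n, o, h, 2, wd, 2)
            if w.requires_grad:
                w.accumulate_grad(
                    np.einsum("nchw,nohiwj->coij", x.data, g, optimize=True)
                )
            if b is not None and b.requires_grad:
                b.accumulate_grad(out.grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                x.accumulate_grad(
                    np.einsum("nohiwj,coij->nchw", g, w.data, optimize=True)
                )
        return _backward
    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, build)


def max_pool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2x2 needs even spatial dims, got {h}x{w}")
    h2, w2 = h // 2, w // 2
    blocks = x.data.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5)
    blocks = blocks.reshape(n, c, h2, w2, 4)
    idx = blocks.argmax(axis=-1)
    out_data = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def build(out):
        def _backward():
            if not x.requires_grad:
                return
            g = np.zeros((n, c, h2, w2, 4), dtype=x.data.dtype)
            np.put_along_axis(g, idx[..., None], out.grad[..., None], axis=-1)
            g = g.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            x.accumulate_grad(g.reshape(n, c, h, w))
        return _backward
    return _node(out_data, (x,), build)


def upsample_nearest2x(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def build(out):
        def _backward():
            if x.requires_grad:
                g = out.grad.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))
                x.accumulate_grad(g)
        return _backward
    return _node(out_data, (x,), build)


# ---------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------

def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out_data = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def build(out):
        def _backward():
            g = out.grad
            if gamma.requires_grad:
                gamma.accumulate_grad((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta.accumulate_grad(g.sum(axis=(0, 2, 3)))
            if not x.requires_grad:
                return
            gxhat = g * gamma.data[None, :, None, None]
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                sum_g = gxhat.sum(axis=(0, 2, 3), keepdims=True)
                sum_gx = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
                dx = (gxhat - sum_g / m - xhat * sum_gx / m) * inv_std[
                    None, :, None, None
                ]
            else:
                dx = gxhat * inv_std[None, :, None, None]
            x.accumulate_grad(dx)
        return _backward
    return _node(out_data, (x, gamma, beta), build)


# ---------------------------------------------------------------------
# losses (fused graph ops; clipped per the objectives-module contract)
# ---------------------------------------------------------------------

BCE_EPS = 1e-7


def bce_loss_graph(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean binary cross-entropy of probabilities against a binary target."""
    y = np.asarray(target, dtype=pred.data.dtype)
    p = np.clip(pred.data, BCE_EPS, 1.0 - BCE_EPS)
    n = p.size
    val = -(y * np.log(p) + (1.0 - y) * np.log1p(-p)).sum() / n

    def build(out):
        def _backward():
            if pred.requires_grad:
                dp = (p - y) / (p * (1.0 - p)) / n
                pred.accumulate_grad(out.grad * dp)
        return _backward
    return _node(val, (pred,), build)


def dice_loss_graph(pred: Tensor, target: np.ndarray, smooth: float = 1e-6) -> Tensor:
    """1 - soft Dice of probabilities against a binary target."""
    y = np.asarray(target, dtype=pred.data.dtype)
    p = pred.data
    num = 2.0 * (p * y).sum() + smooth
    den = (p * p).sum() + (y * y).sum() + smooth
    val = 1.0 - num / den

    def build(out):
        def _backward():
            if pred.requires_grad:
                dp = (2.0 * p * num / den - 2.0 * y) / den
                pred.accumulate_grad(out.grad * dp)
        return _backward
    return _node(val, (pred,), build)
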