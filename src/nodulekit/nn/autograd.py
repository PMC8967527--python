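"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine implements exactly the operations the segmentation networks
need: broadcast arithmetic, the activations (ReLU, sigmoid, tanh,
softplus, Mish), 2D convolution / transposed convolution, pooling,
nearest-neighbour upsampling, concatenation, cropping and reductions.
Everything is float32; gradients are validated against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

from . import convops


class Tensor:
    """A NumPy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph plumbing ------------------------------------------------

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).copy()
        else:
            self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this tensor (default seed gradient: ones)."""
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
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ------------------------------------------------

    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __truediv__(self, other):
        return div(self, _as_tensor(other))


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# -- arithmetic --------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(a.data * b.data, (a, b), backward)


def div(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.shape))

    return _make(a.data / b.data, (a, b), backward)


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.shape))

    return _make(out_data, (a,), backward)


def index(a: Tensor, idx) -> Tensor:
    """Basic (slice/integer) indexing with gradient scatter-back."""

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

    return _make(a.data[idx], (a,), backward)


# -- activations -------------------------------------------------------


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _make(a.data * mask, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    s = _sigmoid(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * s * (1.0 - s))

    return _make(s, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * (1.0 - t * t))

    return _make(t, (a,), backward)


def mish(a: Tensor) -> Tensor:
    """Mish activation x * tanh(softplus(x)), numerically stable."""
    sp = _softplus(a.data)
    t = np.tanh(sp)
    s = _sigmoid(a.data)

    def backward(g):
        if a.requires_grad:
            # d/dx [x tanh(sp(x))] = tanh(sp) + x * (1 - tanh^2(sp)) * sigmoid(x)
            a._accumulate(g * (t + a.data * (1.0 - t * t) * s))

    return _make(a.data * t, (a,), backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softplus(x: np.ndarray) -> np.ndarray:
    # log(1+e^x) = max(x,0) + log1p(e^{-|x|}) — no overflow for large |x|
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


# -- spatial ops (NCHW) ------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride: int = 1,
           dilation: int = 1, padding: int = 0) -> Tensor:
    out_data = convops.conv2d(x.data, w.data, stride=stride,
                              dilation=dilation, padding=padding)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if x.requires_grad:
            x._accumulate(convops.conv2d_bwd_input(
                g, w.data, x.data.shape[2:], stride=stride,
                dilation=dilation, padding=padding))
        if w.requires_grad:
            w._accumulate(convops.conv2d_bwd_weight(
                x.data, g, w.data.shape, stride=stride,
                dilation=dilation, padding=padding))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return _make(out_data, parents, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, *,
                     stride: int = 2, padding: int = 0) -> Tensor:
    """Transposed convolution; `w` has shape (C_in, C_out, kh, kw)."""
    kh = w.data.shape[2]
    out_h = (x.data.shape[2] - 1) * stride + kh - 2 * padding
    out_w = (x.data.shape[3] - 1) * stride + w.data.shape[3] - 2 * padding
    out_data = convops.conv2d_bwd_input(
        x.data, w.data, (out_h, out_w), stride=stride, dilation=1,
        padding=padding)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if x.requires_grad:
            x._accumulate(convops.conv2d(
                g, w.data, stride=stride, dilation=1, padding=padding))
        if w.requires_grad:
            w._accumulate(convops.conv2d_bwd_weight(
                g, x.data, w.data.shape, stride=stride, dilation=1,
                padding=padding))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return _make(out_data, parents, backward)


def avgpool2x(x: Tensor) -> Tensor:
    n, c, h, w = x.shape
    out_data = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(g):
        if x.requires_grad:
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
            x._accumulate(gx)

    return _make(out_data, (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    out_data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g):
        if x.requires_grad:
            n, c, h, w = x.shape
            x._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return _make(out_data, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _make(out_data, list(tensors), backward)


def crop2d(x: Tensor, top: int, left: int, height: int, width: int) -> Tensor:
    sl = (slice(None), slice(None), slice(top, top + height),
          slice(left, left + width))

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[sl] = g
            x._accumulate(full)

    return _make(x.data[sl], (x,), backward)


def soft_dice_loss(p: Tensor, target: np.ndarray, eps: float = 1.0) -> Tensor:
    """1 − 2Σpg / (Σp² + Σg² + ε), the Dice loss, as a graph node.

    ``target`` is a constant binary array of the same shape as ``p``.
    """
    g = np.asarray(target, dtype=np.float32)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs target {g.shape}")
    inter = float((p.data * g).sum())
    denom = float((p.data**2).sum() + (g**2).sum() + eps)
    loss = 1.0 - 2.0 * inter / denom

    def backward(gout):
        if p.requires_grad:
            # d/dp_i [−2 I/D] = −2 (g_i D − I·2p_i) / D²
            gp = -2.0 * (g * denom - inter * 2.0 * p.data) / denom**2
            p._accumulate(gout * gp)

    return _make(np.float32(loss), (p,), backward)
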