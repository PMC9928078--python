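"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the trajectory encoder needs: dense affine
maps, elementwise nonlinearities, row gather, segment (scatter) sums and
per-segment softmax for graph message passing and attention pooling, plus
the two task losses. Gradient correctness is verified against numerical
differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad=False, _prev=()):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            # adopt freshly-owned arrays, copy views (they may alias a
            # consumer's grad buffer that later accumulation would corrupt)
            self.grad = g if g.flags.owndata else g.copy()
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad:
                t._backward(t.grad)

    # ---- arithmetic -----------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    def __neg__(self):
        return self * Tensor(-1.0)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    __radd__ = __add__
    __rmul__ = __mul__

    def matmul(self, other):
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        out._backward = _bw
        return out

    __matmul__ = matmul

    def sum(self):
        out = Tensor(self.data.sum(), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(np.full_like(self.data, g))

        out._backward = _bw
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self._accumulate(np.full_like(self.data, g / n))

        out._backward = _bw
        return out


def affine(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    """Fused ``x @ W + b`` (bias row-broadcast); one op, fewer temporaries."""
    out = Tensor(x.data @ W.data + b.data, _prev=(x, W, b))

    def _bw(g):
        if x.requires_grad:
            x._accumulate(g @ W.data.T)
        if W.requires_grad:
            W._accumulate(x.data.T @ g)
        if b.requires_grad:
            b._accumulate(g.sum(axis=0, keepdims=True))

    out._backward = _bw
    return out


def _unbroadcast(grad, shape):
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


def relu(t: Tensor) -> Tensor:
    out = Tensor(np.maximum(t.data, 0.0), _prev=(t,))

    def _bw(g):
        if t.requires_grad:
            t._accumulate(g * (t.data > 0))

    out._backward = _bw
    return out


def tanh(t: Tensor) -> Tensor:
    y = np.tanh(t.data)
    out = Tensor(y, _prev=(t,))

    def _bw(g):
        if t.requires_grad:
            t._accumulate(g * (1.0 - y**2))

    out._backward = _bw
    return out


def sigmoid(t: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(t.data, -60, 60)))
    out = Tensor(y, _prev=(t,))

    def _bw(g):
        if t.requires_grad:
            t._accumulate(g * y * (1.0 - y))

    out._backward = _bw
    return out


def concat(tensors, axis=1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accumulate(g[tuple(sl)])

    out._backward = _bw
    return out


def gather(t: Tensor, idx) -> Tensor:
    """Select rows ``t[idx]``; backward scatter-adds into the source rows."""
    idx = np.asarray(idx, dtype=int)
    out = Tensor(t.data[idx], _prev=(t,))

    def _bw(g):
        if t.requires_grad:
            acc = np.zeros_like(t.data)
            np.add.at(acc, idx, g)
            t._accumulate(acc)

    out._backward = _bw
    return out


def segment_sum(t: Tensor, idx, num_segments: int) -> Tensor:
    """Sum rows of ``t`` into ``num_segments`` buckets given by ``idx``."""
    idx = np.asarray(idx, dtype=int)
    data = np.zeros((num_segments,) + t.data.shape[1:])
    np.add.at(data, idx, t.data)
    out = Tensor(data, _prev=(t,))

    def _bw(g):
        if t.requires_grad:
            t._accumulate(g[idx])

    out._backward = _bw
    return out


def segment_softmax(scores: Tensor, idx, num_segments: int) -> Tensor:
    """Softmax of ``scores`` (n, 1) within each segment (numerically stable)."""
    idx = np.asarray(idx, dtype=int)
    s = scores.data
    smax = np.full((num_segments,) + s.shape[1:], -np.inf)
    np.maximum.at(smax, idx, s)
    e = np.exp(s - smax[idx])
    denom = np.zeros((num_segments,) + s.shape[1:])
    np.add.at(denom, idx, e)
    y = e / denom[idx]
    out = Tensor(y, _prev=(scores,))

    def _bw(g):
        if scores.requires_grad:
            yg = y * g
            seg = np.zeros((num_segments,) + s.shape[1:])
            np.add.at(seg, idx, yg)
            scores._accumulate(yg - y * seg[idx])

    out._backward = _bw
    return out


def layer_norm(t: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-row normalization ``gamma * (t - mu) / sigma + beta``."""
    mu = t.data.mean(axis=1, keepdims=True)
    var = t.data.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (t.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data, _prev=(t, gamma, beta))

    def _bw(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=0, keepdims=True))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=0, keepdims=True))
        if t.requires_grad:
            gg = g * gamma.data
            t._accumulate(inv * (gg - gg.mean(axis=1, keepdims=True)
                                 - xhat * (gg * xhat).mean(axis=1, keepdims=True)))

    out._backward = _bw
    return out


def softmax_cross_entropy(logits: Tensor, labels) -> Tensor:
    """Mean cross-entropy of row-wise softmax(logits) against integer labels."""
    labels = np.asarray(labels, dtype=int)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = -np.mean(np.log(p[np.arange(n), labels] + 1e-300))
    out = Tensor(loss, _prev=(logits,))

    def _bw(g):
        if logits.requires_grad:
            dz = p.copy()
            dz[np.arange(n), labels] -= 1.0
            logits._accumulate(g * dz / n)

    out._backward = _bw
    return out


def masked_mse(pred: Tensor, target, mask) -> Tensor:
    """Mean squared error over rows where ``mask`` is true (0 if none)."""
    target = np.asarray(target, dtype=float).reshape(pred.data.shape)
    mask = np.asarray(mask, dtype=bool).reshape(pred.data.shape)
    n = max(int(mask.sum()), 1)
    diff = np.where(mask, pred.data - target, 0.0)
    out = Tensor(np.sum(diff**2) / n, _prev=(pred,))

    def _bw(g):
        if pred.requires_grad:
            pred._accumulate(g * 2.0 * diff / n)

    out._backward = _bw
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    """Plain NumPy row-wise softmax (for inference-time probabilities)."""
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
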