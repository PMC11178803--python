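"""Minimal reverse-mode automatic differentiation over numpy arrays.

The deep kernel is trained end to end by the Gaussian-process marginal
likelihood, which requires gradients of a Cholesky-based log density with
respect to every neural-network weight.  This module provides the small
tape-based engine used for that: a :class:`Tensor` wrapping a float64 numpy
array, a closed set of differentiable operations (enough for feed-forward
layers, gated recurrent units, message passing with segment reductions,
set2set attention, the Matern kernel and the GP log marginal likelihood),
and a topological-order backward pass.

Only what the package needs is implemented; this is not a general framework.
All arrays are float64 throughout — the GP linear algebra is ill-behaved in
single precision at the jitter levels used.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


class Tensor:
    """Node in the computation graph: a value, a gradient slot, a backward rule."""

    __slots__ = ("value", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, value, requires_grad: bool = False, name: str | None = None):
        self.value = _as_array(value)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()
        self.name = name

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.value)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        g = _as_array(g)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g is self.value else g
        else:
            self.grad = self.grad + g

    def backward(self, grad=None) -> None:
        """Reverse-mode sweep from this node; seeds with 1 for scalars."""
        if grad is None:
            if self.value.size != 1:
                raise ValueError("backward() without gradient only valid for scalars")
            grad = np.ones_like(self.value)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -------------------------------------------------------------- operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_wrap(other), -1.0))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return gather(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return mul(tsum(self, axis=axis, keepdims=keepdims), 1.0 / n)

    def reshape(self, *shape):
        return reshape(self, shape)

    @property
    def T(self):
        return transpose(self)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(value, parents, backward) -> Tensor:
    out = Tensor(value)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = True
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ------------------------------------------------------------------ primitives
def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _node(a.value + b.value, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        a._accumulate(_unbroadcast(g * b.value, a.shape))
        b._accumulate(_unbroadcast(g * a.value, b.shape))

    return _node(a.value * b.value, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _wrap(a)
    p = float(p)

    def backward(g):
        a._accumulate(g * p * np.power(a.value, p - 1.0))

    return _node(np.power(a.value, p), (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)

    def backward(g):
        ga = g @ np.swapaxes(b.value, -1, -2)
        gb = np.swapaxes(a.value, -1, -2) @ g
        a._accumulate(_unbroadcast(ga, a.shape))
        b._accumulate(_unbroadcast(gb, b.shape))

    return _node(a.value @ b.value, (a, b), backward)


def exp(a) -> Tensor:
    a = _wrap(a)
    out_val = np.exp(a.value)

    def backward(g):
        a._accumulate(g * out_val)

    return _node(out_val, (a,), backward)


def log(a) -> Tensor:
    a = _wrap(a)

    def backward(g):
        a._accumulate(g / a.value)

    return _node(np.log(a.value), (a,), backward)


def sqrt(a) -> Tensor:
    a = _wrap(a)
    out_val = np.sqrt(a.value)

    def backward(g):
        a._accumulate(g * 0.5 / out_val)

    return _node(out_val, (a,), backward)


def tanh(a) -> Tensor:
    a = _wrap(a)
    out_val = np.tanh(a.value)

    def backward(g):
        a._accumulate(g * (1.0 - out_val**2))

    return _node(out_val, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    out_val = expit(a.value)

    def backward(g):
        a._accumulate(g * out_val * (1.0 - out_val))

    return _node(out_val, (a,), backward)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.value > 0

    def backward(g):
        a._accumulate(g * mask)

    return _node(np.where(mask, a.value, 0.0), (a,), backward)


def softplus(a) -> Tensor:
    """log(1 + e^x), computed stably; maps the real line to (0, inf)."""
    a = _wrap(a)
    out_val = np.logaddexp(0.0, a.value)

    def backward(g):
        a._accumulate(g * expit(a.value))

    return _node(out_val, (a,), backward)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _wrap(a)

    def backward(g):
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.shape))
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape))

    return _node(a.value.sum(axis=axis, keepdims=keepdims), (a,), backward)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    old = a.shape

    def backward(g):
        a._accumulate(g.reshape(old))

    return _node(a.value.reshape(shape), (a,), backward)


def transpose(a) -> Tensor:
    a = _wrap(a)

    def backward(g):
        a._accumulate(np.swapaxes(g, -1, -2))

    return _node(np.swapaxes(a.value, -1, -2), (a,), backward)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _node(np.concatenate([t.value for t in tensors], axis=axis), tuple(tensors), backward)


def gather(a, idx) -> Tensor:
    """Row (or fancy-index) selection; gradient scatter-adds into the source."""
    a = _wrap(a)

    def backward(g):
        buf = np.zeros_like(a.value)
        np.add.at(buf, idx, g)
        a._accumulate(buf)

    return _node(a.value[idx], (a,), backward)


def segment_sum(a, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Sum rows of `a` into `num_segments` buckets given per-row bucket ids."""
    a = _wrap(a)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    out_val = np.zeros((num_segments,) + a.shape[1:], dtype=np.float64)
    np.add.at(out_val, segment_ids, a.value)

    def backward(g):
        a._accumulate(g[segment_ids])

    return _node(out_val, (a,), backward)


def segment_softmax(scores, segment_ids: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a score vector within each segment (used by set2set attention)."""
    scores = _wrap(scores)
    segment_ids = np.asarray(segment_ids, dtype=np.intp)
    # stability shift is constant within each segment -> no gradient needed
    seg_max = np.full(num_segments, -np.inf)
    np.maximum.at(seg_max, segment_ids, scores.value)
    shifted = add(scores, Tensor(-seg_max[segment_ids]))
    e = exp(shifted)
    denom = segment_sum(e, segment_ids, num_segments)
    return mul(e, power(gather(denom, segment_ids), -1.0))


def dropout(a, rate: float, rng: np.random.Generator | None) -> Tensor:
    """Inverted dropout; identity when rng is None (evaluation mode)."""
    if rng is None or rate <= 0.0:
        return _wrap(a)
    a = _wrap(a)
    mask = (rng.random(a.shape) >= rate) / (1.0 - rate)

    def backward(g):
        a._accumulate(g * mask)

    return _node(a.value * mask, (a,), backward)


def gaussian_lml(K_noisy, y: np.ndarray) -> Tensor:
    """Full Gaussian log marginal likelihood  -1/2 [yᵀ(K)⁻¹y + log|K| + n log 2π].

    `K_noisy` must already include the noise term on the diagonal.  The
    backward rule uses the closed form d lml / dK = 1/2 (ααᵀ − K⁻¹) with
    α = K⁻¹ y, so the Cholesky factorisation itself never enters the tape.
    """
    K = _wrap(K_noisy)
    y = _as_array(y).ravel()
    n = y.size
    c, low = cho_factor(K.value, lower=True, check_finite=False)
    alpha = cho_solve((c, low), y, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    val = -0.5 * (y @ alpha + logdet + n * np.log(2.0 * np.pi))

    def backward(g):
        Kinv = cho_solve((c, low), np.eye(n), check_finite=False)
        dK = 0.5 * (np.outer(alpha, alpha) - Kinv)
        K._accumulate(float(g) * dK)

    return _node(val, (K,), backward)
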