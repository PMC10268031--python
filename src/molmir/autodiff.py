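"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Every operation in this module dispatches on its arguments: called with plain
NumPy arrays it returns a plain array (cheap inference path), called with at
least one :class:`Tensor` it records the computation so that
:meth:`Tensor.backward` can later accumulate gradients into the leaves.

The op set is deliberately small — exactly what the molecule/sequence encoders
and the attention classifier need: broadcast-aware add/mul, matmul on 1-D/2-D
operands, relu, sigmoid, concat, reshape, row gather (embedding lookup),
segment sum (neighbor aggregation), sum/mean reductions and a fused
softmax/cross-entropy loss.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "concat",
    "reshape",
    "take",
    "segment_sum",
    "sum_",
    "mean",
    "softmax",
    "softmax_cross_entropy",
    "SGD",
]


class Tensor:
    """A node in the computation graph.

    Leaves are created directly by the user (trainable parameters);
    intermediate tensors are created by the ops below and carry closures that
    propagate the upstream gradient to each parent.
    """

    __slots__ = ("value", "grad", "_parents")

    def __init__(self, value, parents=()):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)  # pairs (parent Tensor, grad_fn)

    @property
    def shape(self):
        return self.value.shape

    def backward(self, seed=None):
        """Accumulate gradients of this (scalar) tensor w.r.t. all leaves."""
        if seed is None:
            if self.value.ndim != 0 and self.value.size != 1:
                raise ValueError("backward() without a seed requires a scalar")
            seed = np.ones_like(self.value)
        order = _topo_order(self)
        self.grad = np.asarray(seed, dtype=np.float64)
        for node in order:
            g = node.grad
            if g is None:
                continue
            for parent, grad_fn in node._parents:
                contrib = grad_fn(g)
                if parent.grad is None:
                    parent.grad = contrib
                else:
                    parent.grad = parent.grad + contrib

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, leaf={not self._parents})"


def _topo_order(root):
    """Reverse topological order of the graph reachable from ``root``."""
    order, seen = [], set()
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for parent, _ in node._parents:
            if id(parent) not in seen:
                stack.append((parent, False))
    return list(reversed(order))


def _val(x):
    return x.value if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


def _make(value, parents):
    tensor_parents = [(p, fn) for p, fn in parents if isinstance(p, Tensor)]
    if not tensor_parents:
        return value
    return Tensor(value, tensor_parents)


def add(a, b):
    va, vb = _val(a), _val(b)
    out = va + vb
    return _make(out, [
        (a, lambda g: _unbroadcast(g, va.shape)),
        (b, lambda g: _unbroadcast(g, vb.shape)),
    ])


def mul(a, b):
    va, vb = _val(a), _val(b)
    out = va * vb
    return _make(out, [
        (a, lambda g: _unbroadcast(g * vb, va.shape)),
        (b, lambda g: _unbroadcast(g * va, vb.shape)),
    ])


def matmul(a, b):
    va, vb = _val(a), _val(b)
    out = va @ vb
    if va.ndim == 2 and vb.ndim == 2:
        ga = lambda g: g @ vb.T
        gb = lambda g: va.T @ g
    elif va.ndim == 2 and vb.ndim == 1:
        ga = lambda g: np.outer(g, vb)
        gb = lambda g: va.T @ g
    elif va.ndim == 1 and vb.ndim == 2:
        ga = lambda g: vb @ g
        gb = lambda g: np.outer(va, g)
    elif va.ndim == 1 and vb.ndim == 1:
        ga = lambda g: g * vb
        gb = lambda g: g * va
    else:  # pragma: no cover - not used by the model
        raise ValueError("matmul supports 1-D and 2-D operands only")
    return _make(out, [(a, ga), (b, gb)])


def relu(x):
    vx = _val(x)
    out = np.maximum(vx, 0.0)
    mask = vx > 0
    return _make(out, [(x, lambda g: g * mask)])


def sigmoid(x):
    out = expit(_val(x))
    return _make(out, [(x, lambda g: g * out * (1.0 - out))])


def concat(parts, axis=0):
    vals = [_val(p) for p in parts]
    out = np.concatenate(vals, axis=axis)
    sizes = [v.shape[axis] for v in vals]
    offsets = np.cumsum([0] + sizes)

    def grad_fn_for(k):
        lo, hi = offsets[k], offsets[k + 1]
        sl = [slice(None)] * out.ndim
        sl[axis] = slice(lo, hi)
        sl = tuple(sl)
        return lambda g: g[sl]

    return _make(out, [(p, grad_fn_for(k)) for k, p in enumerate(parts)])


def reshape(x, shape):
    vx = _val(x)
    out = vx.reshape(shape)
    return _make(out, [(x, lambda g: g.reshape(vx.shape))])


def take(table, indices):
    """Row gather (embedding lookup); gradient scatter-adds into the table."""
    vt = _val(table)
    idx = np.asarray(indices, dtype=np.intp)
    out = vt[idx]

    def grad_fn(g):
        gt = np.zeros_like(vt)
        np.add.at(gt, idx, g)
        return gt

    return _make(out, [(table, grad_fn)])


def segment_sum(data, segment_ids, num_segments):
    """Sum rows of ``data`` into ``num_segments`` buckets by ``segment_ids``."""
    vd = _val(data)
    seg = np.asarray(segment_ids, dtype=np.intp)
    out = np.zeros((num_segments,) + vd.shape[1:], dtype=np.float64)
    np.add.at(out, seg, vd)
    return _make(out, [(data, lambda g: g[seg])])


def sum_(x, axis=None):
    vx = _val(x)
    out = vx.sum(axis=axis)

    def grad_fn(g):
        if axis is None:
            return np.broadcast_to(g, vx.shape).copy()
        return np.broadcast_to(np.expand_dims(g, axis), vx.shape).copy()

    return _make(out, [(x, grad_fn)])


def mean(x, axis=None):
    vx = _val(x)
    out = vx.mean(axis=axis)
    n = vx.size if axis is None else vx.shape[axis]

    def grad_fn(g):
        if axis is None:
            return np.broadcast_to(g / n, vx.shape).copy()
        return np.broadcast_to(np.expand_dims(g, axis) / n, vx.shape).copy()

    return _make(out, [(x, grad_fn)])


def softmax(logits):
    """Plain softmax (forward-only convenience; differentiable via the loss)."""
    z = _val(logits)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def softmax_cross_entropy(logits, label):
    """Fused softmax + negative log likelihood of ``label`` (0 or 1)."""
    z = _val(logits)
    if not np.all(np.isfinite(z)):
        raise FloatingPointError("non-finite logits in cross-entropy")
    zs = z - z.max()
    e = np.exp(zs)
    p = e / e.sum()
    loss = -np.log(max(p[label], 1e-300))
    onehot = np.zeros_like(p)
    onehot[label] = 1.0
    return _make(np.asarray(loss), [(logits, lambda g: g * (p - onehot))])


class SGD:
    """Stochastic gradient descent with classical momentum over leaf tensors."""

    def __init__(self, params, lr=1e-3, momentum=0.9):
        self.params = dict(params)
        self.lr = lr
        self.momentum = momentum
        self._velocity = {k: np.zeros_like(t.value) for k, t in self.params.items()}

    def zero_grad(self):
        for t in self.params.values():
            t.grad = None

    def step(self):
        for name, t in self.params.items():
            if t.grad is None:
                continue
            v = self._velocity[name]
            v *= self.momentum
            v -= self.lr * t.grad
            t.value += v
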