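"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package trains its neural networks (gated recurrent condition encoder,
cross-covariance attention denoiser) on CPU with this engine: a ``Tensor``
wraps an ``ndarray``, records its parents and a backward closure, and
``backward()`` runs the chain rule over the topologically sorted graph.
Only the operations the models need are implemented; all support the NumPy
broadcasting rules (gradients are summed back over broadcast axes).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "sigmoid", "tanh", "silu", "softmax_axis", "layer_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach its shape from `shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def T(self):
        return transpose(self)

    def item(self):
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_coerce(other), -1.0))

    def __rsub__(self, other):
        return add(_coerce(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _coerce(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_coerce(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean_(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)

    # ------------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None


def _coerce(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward_fn) -> Tensor:
    out = Tensor.__new__(Tensor)
    out.data = data
    out.grad = None
    out.requires_grad = any(p.requires_grad or p._backward is not None for p in parents)
    if out.requires_grad:
        out._parents = parents
        out._backward = backward_fn
    else:
        out._parents = ()
        out._backward = None
    return out


def _accum(t: Tensor, g: np.ndarray):
    if t.grad is None:
        t.grad = g.copy() if g.base is not None or g.flags.writeable is False else g
    else:
        t.grad = t.grad + g


# ----------------------------------------------------------------------
# primitive operations


def add(a, b) -> Tensor:
    a, b = _coerce(a), _coerce(b)
    out_data = a.data + b.data

    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = _coerce(a), _coerce(b)
    out_data = a.data * b.data

    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), bwd)


def power(a, p: float) -> Tensor:
    a = _coerce(a)
    out_data = a.data ** p

    def bwd(g):
        _accum(a, g * p * a.data ** (p - 1.0))

    return _make(out_data, (a,), bwd)


def matmul(a, b) -> Tensor:
    a, b = _coerce(a), _coerce(b)
    out_data = a.data @ b.data

    def bwd(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _make(out_data, (a, b), bwd)


def transpose(a) -> Tensor:
    a = _coerce(a)

    def bwd(g):
        _accum(a, g.T)

    return _make(a.data.T, (a,), bwd)


def reshape(a, shape) -> Tensor:
    a = _coerce(a)
    old = a.data.shape

    def bwd(g):
        _accum(a, g.reshape(old))

    return _make(a.data.reshape(shape), (a,), bwd)


def _is_basic_index(idx) -> bool:
    items = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(i, (int, np.integer, slice)) or i is Ellipsis for i in items)


def getitem(a, idx) -> Tensor:
    a = _coerce(a)
    out_data = a.data[idx]
    basic = _is_basic_index(idx)

    def bwd(g):
        full = np.zeros_like(a.data)
        if basic:
            full[idx] += g  # basic indexing never aliases
        else:
            np.add.at(full, idx, g)
        _accum(a, full)

    return _make(out_data, (a,), bwd)


def concat(tensors, axis=0) -> Tensor:
    tensors = [_coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    return _make(out_data, tuple(tensors), bwd)


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = _coerce(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.data.shape).copy())
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            _accum(a, np.broadcast_to(g, a.data.shape).copy())

    return _make(np.asarray(out_data), (a,), bwd)


def mean_(a, axis=None, keepdims=False) -> Tensor:
    a = _coerce(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / n)


def exp(a) -> Tensor:
    a = _coerce(a)
    out_data = np.exp(a.data)

    def bwd(g):
        _accum(a, g * out_data)

    return _make(out_data, (a,), bwd)


def log(a) -> Tensor:
    a = _coerce(a)

    def bwd(g):
        _accum(a, g / a.data)

    return _make(np.log(a.data), (a,), bwd)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def tanh(a) -> Tensor:
    a = _coerce(a)
    out_data = np.tanh(a.data)

    def bwd(g):
        _accum(a, g * (1.0 - out_data * out_data))

    return _make(out_data, (a,), bwd)


def sigmoid(a) -> Tensor:
    a = _coerce(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def bwd(g):
        _accum(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), bwd)


def silu(a) -> Tensor:
    """x * sigmoid(x) — smooth gating nonlinearity used in the denoiser."""
    a = _coerce(a)
    s = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * s

    def bwd(g):
        _accum(a, g * (s * (1.0 + a.data * (1.0 - s))))

    return _make(out_data, (a,), bwd)


def softmax_axis(a, axis: int) -> Tensor:
    """Numerically stable softmax along `axis` (max-shift is constant wrt grad)."""
    a = _coerce(a)
    shifted = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        _accum(a, out_data * (g - dot))

    return _make(out_data, (a,), bwd)


def layer_norm(a, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Row-wise layer normalization with learnable gain/bias (last axis)."""
    mu = mean_(a, axis=-1, keepdims=True)
    centered = add(a, mul(mu, -1.0))
    var = mean_(mul(centered, centered), axis=-1, keepdims=True)
    inv = power(add(var, eps), -0.5)
    return add(mul(mul(centered, inv), gain), bias)
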