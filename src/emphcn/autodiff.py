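"""Minimal reverse-mode automatic differentiation on numpy arrays.

The model is trained full-batch on dense matrices no larger than a few
hundred rows, so a small tape-based engine over dense numpy ops is all
that is needed: ``Tensor`` wraps an ``ndarray``, records its parents and
a backward closure, and ``backward()`` runs reverse topological
accumulation.  Broadcasting follows numpy semantics; gradients of
broadcast operands are summed back to the operand's shape.

Gradient correctness is pinned down by finite-difference checks in the
test suite rather than trusted by construction.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "mul",
    "matmul",
    "relu",
    "leaky_relu",
    "sigmoid",
    "log",
    "exp",
    "clip",
    "concat",
    "tensor_sum",
    "tensor_mean",
    "transpose",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph holding a float64 array."""

    __slots__ = ("value", "grad", "_parents", "_backward", "requires_grad", "name")

    def __init__(self, value, parents=(), backward=None, requires_grad=False, name=""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in self._parents
        )
        self.name = name

    # -- graph plumbing -------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    @property
    def T(self) -> "Tensor":
        return transpose(self)

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep at high epoch counts
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray):
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.value.shape)
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        return div(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return take(self, idx)

    def item(self) -> float:
        return float(self.value.reshape(-1)[0])

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, grad={'set' if self.grad is not None else 'none'})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# -- primitive operations ----------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.value + b.value, parents=(a, b))

    def backward(grad):
        if a.requires_grad:
            a._accum(grad)
        if b.requires_grad:
            b._accum(grad)

    out._backward = backward
    return out


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.value * b.value, parents=(a, b))

    def backward(grad):
        if a.requires_grad:
            a._accum(grad * b.value)
        if b.requires_grad:
            b._accum(grad * a.value)

    out._backward = backward
    return out


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.value / b.value, parents=(a, b))

    def backward(grad):
        if a.requires_grad:
            a._accum(grad / b.value)
        if b.requires_grad:
            b._accum(-grad * a.value / (b.value**2))

    out._backward = backward
    return out


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(a.value @ b.value, parents=(a, b))

    def backward(grad):
        if a.requires_grad:
            a._accum(grad @ b.value.T)
        if b.requires_grad:
            b._accum(a.value.T @ grad)

    out._backward = backward
    return out


def transpose(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.value.T, parents=(a,))

    def backward(grad):
        if a.requires_grad:
            a._accum(grad.T)

    out._backward = backward
    return out


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.value > 0
    out = Tensor(np.where(mask, a.value, 0.0), parents=(a,))

    def backward(grad):
        if a.requires_grad:
            a._accum(grad * mask)

    out._backward = backward
    return out


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    mask = a.value > 0
    out = Tensor(np.where(mask, a.value, slope * a.value), parents=(a,))

    def backward(grad):
        if a.requires_grad:
            a._accum(grad * np.where(mask, 1.0, slope))

    out._backward = backward
    return out


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # numerically stable logistic (no overflow for large |x|)
    s = np.where(a.value >= 0,
                 1.0 / (1.0 + np.exp(-np.abs(a.value))),
                 np.exp(-np.abs(a.value)) / (1.0 + np.exp(-np.abs(a.value))))
    out = Tensor(s, parents=(a,))

    def backward(grad):
        if a.requires_grad:
            a._accum(grad * s * (1.0 - s))

    out._backward = backward
    return out


def log(a) -> Tensor:
    a = as_tensor(a)
    out = Tensor(np.log(a.value), parents=(a,))

    def backward(grad):
        if a.requires_grad:
            a._accum(grad / a.value)

    out._backward = backward
    return out


def exp(a) -> Tensor:
    a = as_tensor(a)
    e = np.exp(a.value)
    out = Tensor(e, parents=(a,))

    def backward(grad):
        if a.requires_grad:
            a._accum(grad * e)

    out._backward = backward
    return out


def log_sigmoid(a) -> Tensor:
    """log(sigmoid(x)) = -softplus(-x), stable for large |x|; the
    gradient sigmoid(-x) never vanishes, unlike log(clip(sigmoid(x)))."""
    a = as_tensor(a)
    x = a.value
    out_val = np.where(x >= 0, -np.log1p(np.exp(-np.abs(x))),
                       x - np.log1p(np.exp(-np.abs(x))))
    out = Tensor(out_val, parents=(a,))
    grad_factor = np.where(x >= 0,
                           np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))),
                           1.0 / (1.0 + np.exp(-np.abs(x))))  # = sigmoid(-x)

    def backward(grad):
        if a.requires_grad:
            a._accum(grad * grad_factor)

    out._backward = backward
    return out


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through unclipped entries."""
    a = as_tensor(a)
    mask = (a.value >= lo) & (a.value <= hi)
    out = Tensor(np.clip(a.value, lo, hi), parents=(a,))

    def backward(grad):
        if a.requires_grad:
            a._accum(grad * mask)

    out._backward = backward
    return out


def take(a, idx) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.value[idx], parents=(a,))

    def backward(grad):
        if a.requires_grad:
            full = np.zeros_like(a.value)
            np.add.at(full, idx, grad)
            a._accum(full)

    out._backward = backward
    return out


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.value for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.value.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(grad[tuple(sl)])

    out._backward = backward
    return out


def tensor_sum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = Tensor(a.value.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def backward(grad):
        if not a.requires_grad:
            return
        g = np.asarray(grad)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis=axis)
        a._accum(np.broadcast_to(g, a.value.shape))

    out._backward = backward
    return out


def tensor_mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.value.size if axis is None else a.value.shape[axis]
    return mul(tensor_sum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def masked_row_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax restricted to ``mask`` (binary, constant).

    Rows of all-zero mask yield all-zero rows (no 0/0).  The row-max
    shift is detached, which leaves the softmax gradient exact.
    """
    mask = np.asarray(mask, dtype=np.float64)
    neg = (1.0 - mask) * (-1e30)
    shifted = add(scores, Tensor(neg))
    row_max = shifted.value.max(axis=1, keepdims=True)
    row_max = np.where(np.isfinite(row_max), row_max, 0.0)
    e = mul(exp(add(shifted, Tensor(-row_max))), Tensor(mask))
    denom = tensor_sum(e, axis=1, keepdims=True)
    has_nbr = (mask.sum(axis=1, keepdims=True) > 0).astype(np.float64)
    safe_denom = add(denom, Tensor(1.0 - has_nbr))
    return div(e, safe_denom)


class Adam:
    """Adam over a dict of named parameter Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 0.002,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.t = 0

    def zero_grad(self):
        for p in self.params.values():
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad**2
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
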