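"""Compact reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the contrastive model needs: broadcasting
arithmetic, matmul, reductions, reshape/transpose, exp/log/sqrt/tanh/softplus
and an elementwise floor against a constant. Gradients are accumulated by a
topological backward pass; correctness is pinned by numerical gradient checks
in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over the axes numpy broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # ---- construction helpers -------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(out_data, (self, other), backward)

    def pow(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1),)

        return self._make(out_data, (self,), backward)

    # ---- elementwise -----------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        # guarded denominator: callers clamp zero-norm branches with
        # maximum(), so the incoming gradient is already zero there
        safe = np.where(out_data > 0, out_data, 1.0)
        return self._make(out_data, (self,), lambda g: (g / (2.0 * safe),))

    def tanh(self):
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,), lambda g: (g * (1 - out_data**2),))

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)

        def backward(g):
            return (g / (1.0 + np.exp(-self.data)),)

        return self._make(out_data, (self,), backward)

    def maximum(self, floor: float):
        """Elementwise max against a constant (no gradient below the floor)."""
        out_data = np.maximum(self.data, floor)
        mask = (self.data >= floor).astype(float)
        return self._make(out_data, (self,), lambda g: (g * mask,))

    # ---- reductions / reshaping -----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            ax = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                for a in sorted(a % self.data.ndim for a in ax):
                    g = np.expand_dims(g, a)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        return self._make(
            out_data, (self,), lambda g: (g.reshape(self.data.shape),)
        )

    @property
    def T(self):
        return self._make(self.data.T, (self,), lambda g: (g.T,))

    # ---- autodiff driver -------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=float)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for p, pg in zip(t._parents, t._backward(g)):
                    if not p.requires_grad:
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = np.asarray(pg, dtype=float)
            else:
                # leaf: accumulate into .grad
                t.grad = g if t.grad is None else t.grad + g

    def item(self) -> float:
        return float(self.data)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def numerical_gradient(fn, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar function of an array."""
    x = np.asarray(x, dtype=float)
    grad = np.zeros_like(x)
    flat = x.ravel()
    gflat = grad.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = fn(x)
        flat[i] = orig - eps
        fm = fn(x)
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * eps)
    return grad


class Adam:
    """Standard Adam on a list of :class:`Parameter`."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
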