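"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

This is the numerical core used by the ZINB autoencoder and the classifier
heads.  It implements exactly the operations the model needs (dense affine
maps, ELU, exponential/log links, softplus, sigmoid, log-gamma, stable
log-add-exp and log-softmax) with analytically derived adjoints, and a plain
Adam optimizer.  Gradients are accumulated by topological traversal of the
expression graph, with broadcasting handled by summing adjoints over
broadcast axes.
"""

from __future__ import annotations

import numpy as np
from scipy.special import psi as _digamma


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were 1 in the original shape
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")
    __array_priority__ = 100  # keep numpy from hijacking binary ops

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    # -- utilities ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(grad)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            self._accum(g)
            other._accum(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, k: float):
        out = Tensor(self.data**k, _prev=(self,))

        def bw(g):
            self._accum(g * k * self.data ** (k - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = bw
        return out

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ---------------------------------------
    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _prev=(self,))
        out._backward = lambda g: self._accum(g * e)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    def softplus(self):
        out = Tensor(np.logaddexp(0.0, self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g / (1.0 + np.exp(-self.data)))
        return out

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        e = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out = Tensor(np.where(pos, self.data, e), _prev=(self,))
        out._backward = lambda g: self._accum(g * np.where(pos, 1.0, e + alpha))
        return out

    def lgamma(self):
        out = Tensor(_lgamma(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g * _digamma(self.data))
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through the unclipped region."""
        inside = (self.data >= lo) & (self.data <= hi)
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))
        out._backward = lambda g: self._accum(g * inside)
        return out


def _lgamma(x):
    from scipy.special import gammaln

    return gammaln(x)


def logaddexp(a: Tensor, b: Tensor) -> Tensor:
    """Stable log(exp(a) + exp(b)) with exact adjoints."""
    a, b = Tensor._lift(a), Tensor._lift(b)
    out = Tensor(np.logaddexp(a.data, b.data), _prev=(a, b))

    def bw(g):
        wa = 1.0 / (1.0 + np.exp(b.data - a.data))
        a._accum(g * wa)
        b._accum(g * (1.0 - wa))

    out._backward = bw
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Row-stable log-softmax with the exact softmax Jacobian adjoint."""
    m = x.data.max(axis=axis, keepdims=True)
    lse = m + np.log(np.exp(x.data - m).sum(axis=axis, keepdims=True))
    out = Tensor(x.data - lse, _prev=(x,))

    def bw(g):
        p = np.exp(out.data)
        x._accum(g - p * g.sum(axis=axis, keepdims=True))

    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
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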