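"""Minimal dense reverse-mode automatic differentiation.

Everything the graph attention autoencoder needs — broadcast arithmetic,
matmul, transpose, concatenation, reductions, the ELU / LeakyReLU / sigmoid
nonlinearities and a clip — on float64 numpy arrays, plus an Adam optimizer.
Cohort-scale graphs (a few hundred nodes) fit comfortably in dense matrices,
so there is no sparse path.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` back down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_children", "_backward")

    # make `ndarray <op> Tensor` fall through to our reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, _children=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(c.requires_grad for c in _children)
        self.grad = None
        self._children = _children
        self._backward = _backward

    # -- plumbing ----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs get deep over many layers
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for c in node._children:
                stack.append((c, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _children=(self, other))

        def _backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = _backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _children=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(-out.grad)

        out._backward = _backward
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _children=(self, other))

        def _backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = _backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, _children=(self, other))

        def _backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-out.grad * self.data / other.data**2, other.data.shape)
                )

        out._backward = _backward
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _children=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1))

        out._backward = _backward
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _children=(self, other))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = _backward
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, _children=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad.T)

        out._backward = _backward
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _children=(self,))

        def _backward():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ----------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), _children=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * out.data)

        out._backward = _backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), _children=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad / self.data)

        out._backward = _backward
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _children=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * out.data * (1.0 - out.data))

        out._backward = _backward
        return out

    def leaky_relu(self, negative_slope: float = 0.2):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, negative_slope * self.data), _children=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * np.where(mask, 1.0, negative_slope))

        out._backward = _backward
        return out

    def elu(self, alpha: float = 1.0):
        mask = self.data > 0
        ex = np.exp(np.minimum(self.data, 0.0))
        out = Tensor(np.where(mask, self.data, alpha * (ex - 1.0)), _children=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * np.where(mask, 1.0, alpha * ex))

        out._backward = _backward
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where un-clamped."""
        inside = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), _children=(self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * inside)

        out._backward = _backward
        return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _children=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(idx)])

    out._backward = _backward
    return out


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
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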