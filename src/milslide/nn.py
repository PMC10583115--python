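"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the numerical substrate for the MIL heads, the self-supervised losses
and the trainer. It deliberately covers only the operations those models need
(dense algebra, elementwise nonlinearities, reductions, slicing/concat, a
depthwise 2-D convolution for the convolutional positional encoding) and runs
in float64, which makes finite-difference gradient checks meaningful.

The API imitates the familiar tensor-library surface at small scale::

    x = nn.Tensor(np.ones((3, 2)), requires_grad=True)
    y = (x @ w).tanh().sum()
    y.backward()
    x.grad            # ndarray of dL/dx

Gradients accumulate into ``.grad`` (ndarray) of every tensor created with
``requires_grad=True``.
"""

from __future__ import annotations

import json
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "depthwise_conv2d",
    "softmax",
    "layer_norm",
    "Linear",
    "Module",
    "SGD",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach `grad.shape`."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents
        self._backward = _backward

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- graph construction -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def _make(self, data, parents, backward) -> "Tensor":
        if any(p.requires_grad for p in parents):
            return Tensor(data, _parents=parents, _backward=backward)
        return Tensor(data)

    # -- arithmetic ---------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            return (g * p * self.data ** (p - 1),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:          # inner product
                return (g * b, g * a)
            if a.ndim == 1:                          # (k,) @ (k,n) -> (n,)
                return (g @ b.T, np.outer(a, g))
            if b.ndim == 1:                          # (m,k) @ (k,) -> (m,)
                return (np.outer(g, b), a.T @ g)
            return (g @ b.swapaxes(-1, -2), a.swapaxes(-1, -2) @ g)

        return self._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities ----------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,), lambda g: (g * (1.0 - out_data ** 2),))

    def sigmoid(self):
        out_data = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable logistic
        return self._make(out_data, (self,),
                          lambda g: (g * out_data * (1.0 - out_data),))

    def relu(self):
        mask = self.data > 0

        def backward(g):
            return (g * mask,)

        return self._make(self.data * mask, (self,), backward)

    def softplus(self):
        out_data = np.logaddexp(0.0, self.data)
        sig = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        return self._make(out_data, (self,), lambda g: (g * sig,))

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    def max(self, axis=None):
        """Maximum; gradient flows to the first maximal element (ties -> lowest index)."""
        if axis is None:
            idx = np.unravel_index(int(np.argmax(self.data)), self.data.shape)
            out_data = self.data[idx]

            def backward(g):
                grad = np.zeros_like(self.data)
                grad[idx] = g
                return (grad,)

            return self._make(out_data, (self,), backward)
        raise NotImplementedError("axis-wise max is not needed by any model")

    # -- shape manipulation -------------------------------------------------
    def reshape(self, *shape):
        old_shape = self.shape
        return self._make(self.data.reshape(*shape), (self,),
                          lambda g: (g.reshape(old_shape),))

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.ndim)))
        inv = np.argsort(axes)
        return self._make(self.data.transpose(axes), (self,),
                          lambda g: (g.transpose(inv),))

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            grad = np.zeros_like(self.data)
            np.add.at(grad, idx, g)
            return (grad,)

        return self._make(out_data, (self,), backward)

    # -- backprop -----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:       # leaf
                if node.grad is None:
                    node.grad = np.zeros_like(node.data)
                node.grad += g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg


# -- free functions ---------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    if any(t.requires_grad for t in tensors):
        return Tensor(out_data, _parents=tuple(tensors), _backward=backward)
    return Tensor(out_data)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize over the last axis, then apply elementwise affine."""
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * gain + bias


def depthwise_conv2d(x: Tensor, w: Tensor) -> Tensor:
    """Per-channel 2-D convolution with 'same' zero padding.

    x: (C, H, W); w: (C, k, k) with odd k. Channel c of the output is the
    correlation of channel c of the input with kernel c.
    """
    x = Tensor._lift(x)
    w = Tensor._lift(w)
    C, H, W = x.shape
    k = w.shape[1]
    if w.shape != (C, k, k) or k % 2 == 0:
        raise ValueError("kernel must be (C, k, k) with odd k")
    pad = k // 2
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad)))
    out = np.zeros((C, H, W))
    for i in range(k):
        for j in range(k):
            out += w.data[:, i, j][:, None, None] * xp[:, i:i + H, j:j + W]

    def backward(g):
        dw = np.zeros_like(w.data)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                dw[:, i, j] = (xp[:, i:i + H, j:j + W] * g).sum(axis=(1, 2))
                dxp[:, i:i + H, j:j + W] += w.data[:, i, j][:, None, None] * g
        dx = dxp[:, pad:pad + H, pad:pad + W]
        return (dx, dw)

    if x.requires_grad or w.requires_grad:
        return Tensor(out, _parents=(x, w), _backward=backward)
    return Tensor(out)


# -- parameter containers and optimizers ------------------------------------

class Module:
    """Base class: any attribute that is a requires_grad Tensor or a Module
    contributes to :meth:`parameters`."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
                    elif isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # checkpoint plumbing: flat dict of arrays, in parameter order
    def state_arrays(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_arrays(self, arrays: Iterable[np.ndarray]) -> None:
        for p, a in zip(self.parameters(), arrays, strict=True):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data = np.asarray(a, dtype=np.float64).copy()


class Linear(Module):
    """Dense layer y = x W^T + b with Glorot-uniform init."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True):
        bound = np.sqrt(6.0 / (d_in + d_out))
        self.W = Tensor(rng.uniform(-bound, bound, (d_out, d_in)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W.T
        if self.b is not None:
            y = y + self.b
        return y


class SGD:
    def __init__(self, params: Sequence[Tensor], lr: float):
        self.params = list(params)
        self.lr = lr

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data = p.data - self.lr * p.grad


class Adam:
    """Adam with bias correction and optional decoupled weight decay."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

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
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay:
                p.data = p.data * (1.0 - self.lr * self.weight_decay)


def binary_cross_entropy_with_logit(logit: Tensor, label: float) -> Tensor:
    """Numerically stable BCE on a raw logit: softplus(l) - y*l."""
    return logit.softplus() - logit * float(label)


def numerical_gradient(f: Callable[[np.ndarray], float], x: np.ndarray,
                       eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function; test utility."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f(x)
        x[i] = orig - eps
        fm = f(x)
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def params_header(method: str, **meta) -> str:
    """JSON header stored inside model checkpoints."""
    return json.dumps({"method": method, **meta}, sort_keys=True)
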