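"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A small, vectorized tape-based engine sized for the transformer in this
package: float32 tensors, the dozen primitive ops a ViT needs (matmul,
broadcast add, layer norm, softmax, GELU, dropout masks, reshapes) and
an Adam optimizer with warmup plus cosine decay. Gradients are checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import math
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["Tensor", "Parameter", "Linear", "LayerNorm", "Adam",
           "gelu", "softmax", "dropout_mask"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a gradient down to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[], None]] = None
        self._prev: tuple = ()

    # -- graph plumbing ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, free_graph: bool = True):
        """Reverse-mode sweep from this (scalar) node.

        With ``free_graph`` (default) intermediate gradients, tape links
        and closures are released as soon as they have been consumed, so
        peak memory stays near one set of activations; leaf/parameter
        gradients survive.
        """
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            t, done = stack.pop()
            if done:
                topo.append(t)
                continue
            if id(t) in seen:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._prev:
                stack.append((p, False))

        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward()
            if free_graph:
                t._backward = None
                t._prev = ()
                if not isinstance(t, Parameter) and t is not self:
                    t.grad = None

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        out_data = self.data + other.data

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out = Tensor._make(out_data, (self, other), backward)
        return out

    def __sub__(self, other: "Tensor") -> "Tensor":
        return self + other.scale(-1.0)

    def scale(self, c: float) -> "Tensor":
        def backward():
            if self.requires_grad:
                self._accum(out.grad * np.float32(c))

        out = Tensor._make(self.data * np.float32(c), (self,), backward)
        return out

    def mul_mask(self, mask: np.ndarray) -> "Tensor":
        """Elementwise product with a constant array (dropout etc.)."""
        mask = np.asarray(mask, dtype=np.float32)

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * mask, self.shape))

        out = Tensor._make(self.data * mask, (self,), backward)
        return out

    def square(self) -> "Tensor":
        def backward():
            if self.requires_grad:
                self._accum(out.grad * 2.0 * self.data)

        out = Tensor._make(self.data * self.data, (self,), backward)
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self.data, other.data
        if b.ndim == 2 and a.ndim > 2:
            out_data = (a.reshape(-1, a.shape[-1]) @ b).reshape(
                *a.shape[:-1], b.shape[-1])
        else:
            out_data = a @ b

        def backward():
            g = out.grad
            if self.requires_grad:
                ga = g @ np.swapaxes(b, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                if b.ndim == 2:
                    gb = a.reshape(-1, a.shape[-1]).T @ g.reshape(-1, g.shape[-1])
                else:
                    gb = _unbroadcast(np.swapaxes(a, -1, -2) @ g, other.shape)
                other._accum(gb)

        out = Tensor._make(out_data, (self, other), backward)
        return out

    __matmul__ = matmul

    # -- shape ---------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        orig = self.shape

        def backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(orig))

        out = Tensor._make(self.data.reshape(*shape), (self,), backward)
        return out

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)

        def backward():
            if self.requires_grad:
                self._accum(out.grad.transpose(inv))

        out = Tensor._make(self.data.transpose(axes), (self,), backward)
        return out

    def mean(self, axis: Optional[int] = None) -> "Tensor":
        if axis is None:
            n = self.data.size

            def backward():
                if self.requires_grad:
                    self._accum(np.full_like(self.data, out.grad / n))

            out = Tensor._make(self.data.mean(), (self,), backward)
            return out
        n = self.shape[axis]

        def backward():
            if self.requires_grad:
                self._accum(np.repeat(np.expand_dims(out.grad / n, axis),
                                      n, axis=axis))

        out = Tensor._make(self.data.mean(axis=axis), (self,), backward)
        return out


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# -- nonlinearities and normalization ---------------------------------

_SQRT_2_OVER_PI = math.sqrt(2.0 / math.pi)


def gelu(x: Tensor) -> Tensor:
    """GELU with the tanh approximation."""
    d = x.data
    d3 = d * d * d  # explicit product: array powers hit a slow pow path
    inner = _SQRT_2_OVER_PI * (d + 0.044715 * d3)
    t = np.tanh(inner)
    out_data = 0.5 * d * (1.0 + t)

    def backward():
        if x.requires_grad:
            dinner = _SQRT_2_OVER_PI * (1.0 + 3 * 0.044715 * d * d)
            dgelu = 0.5 * (1.0 + t) + 0.5 * d * (1.0 - t * t) * dinner
            x._accum(out.grad * dgelu)

    out = Tensor._make(out_data, (x,), backward)
    return out


def softmax(x: Tensor) -> Tensor:
    """Softmax over the last axis."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=-1, keepdims=True)

    def backward():
        if x.requires_grad:
            g = out.grad
            x._accum(y * (g - (g * y).sum(axis=-1, keepdims=True)))

    out = Tensor._make(y, (x,), backward)
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis with affine parameters."""
    d = x.data
    mu = d.mean(axis=-1, keepdims=True)
    xc = d - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out_data = xhat * gamma.data + beta.data

    def backward():
        g = out.grad
        n = d.shape[-1]
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.shape))
        if x.requires_grad:
            gx = g * gamma.data
            x._accum(inv / n * (n * gx - gx.sum(axis=-1, keepdims=True)
                                - xhat * (gx * xhat).sum(axis=-1,
                                                         keepdims=True)))

    out = Tensor._make(out_data, (x, gamma, beta), backward)
    return out


def dropout_mask(shape, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Inverted-dropout multiplier: 0 with prob ``rate``, else 1/(1-rate)."""
    keep = 1.0 - rate
    u = rng.random(shape, dtype=np.float32)
    return (u < keep).astype(np.float32) / np.float32(keep)


# -- layers ------------------------------------------------------------

class Linear:
    """Dense layer ``y = x W + b`` with fan-in scaled init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        lim = math.sqrt(6.0 / (n_in + n_out))
        self.weight = Parameter(rng.uniform(-lim, lim, (n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias

    def parameters(self):
        return [self.weight, self.bias]


class LayerNorm:
    def __init__(self, dim: int):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)

    def parameters(self):
        return [self.gamma, self.beta]


class Adam:
    """Adam with linear warmup and cosine decay to zero."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 total_steps: int = 1000, warmup_frac: float = 0.05,
                 clip_norm: Optional[float] = 1.0):
        self.params = list(params)
        self.base_lr = lr
        self.betas = betas
        self.eps = eps
        self.clip_norm = clip_norm
        self.total_steps = max(total_steps, 1)
        self.warmup_steps = max(int(warmup_frac * self.total_steps), 1)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def current_lr(self) -> float:
        if self.t < self.warmup_steps:
            return self.base_lr * (self.t + 1) / self.warmup_steps
        frac = (self.t - self.warmup_steps) / max(
            self.total_steps - self.warmup_steps, 1)
        return self.base_lr * 0.5 * (1.0 + math.cos(math.pi * min(frac, 1.0)))

    def step(self):
        lr = self.current_lr()
        b1, b2 = self.betas
        if self.clip_norm is not None:
            total = math.sqrt(sum(float((p.grad * p.grad).sum())
                                  for p in self.params
                                  if p.grad is not None))
            if total > self.clip_norm:
                scale = np.float32(self.clip_norm / total)
                for p in self.params:
                    if p.grad is not None:
                        p.grad *= scale
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
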