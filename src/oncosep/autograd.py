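"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the package's small neural classifiers need
(dense, 2D convolution via patch extraction, LSTM cells, logistic loss).
Gradients are accumulated by a topological backward sweep; correctness is
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction ------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.requires_grad:
            self.grad = g if self.grad is None else self.grad + g

    # -- ops ---------------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (other * Tensor(-1.0))

    def matmul(self, other: "Tensor") -> "Tensor":
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def relu(self) -> "Tensor":
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            self._accum(g * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - t * t))

        return Tensor._make(t, (self,), backward)

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    def mean_over(self, axes: tuple[int, ...]) -> "Tensor":
        axes = tuple(axes)
        n = int(np.prod([self.data.shape[a] for a in axes]))
        out_data = self.data.mean(axis=axes)

        def backward(g):
            g_full = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g_full, self.data.shape) / n)

        return Tensor._make(out_data, (self,), backward)

    def pad2d(self, p: int) -> "Tensor":
        """Zero-pad the last two axes of an (N, C, H, W) tensor by ``p``."""
        out_data = np.pad(self.data, ((0, 0), (0, 0), (p, p), (p, p)))

        def backward(g):
            self._accum(g[:, :, p:-p, p:-p] if p else g)

        return Tensor._make(out_data, (self,), backward)

    def transpose_last2(self) -> "Tensor":
        def backward(g):
            self._accum(np.swapaxes(g, -1, -2))

        return Tensor._make(np.swapaxes(self.data, -1, -2), (self,), backward)

    def slice_cols(self, start: int, stop: int) -> "Tensor":
        def backward(g):
            gx = np.zeros_like(self.data)
            gx[..., start:stop] = g
            self._accum(gx)

        return Tensor._make(self.data[..., start:stop], (self,), backward)

    def gather_patches(self, index: np.ndarray) -> "Tensor":
        """Advanced-index gather along the flattened last dims (im2col).

        ``self`` has shape (N, D); ``index`` (P, K) selects columns, yielding
        (N, P, K).  Backward scatter-adds into the source.
        """
        out_data = self.data[:, index]

        def backward(g):
            gx = np.zeros_like(self.data)
            np.add.at(gx, (slice(None), index), g)
            self._accum(gx)

        return Tensor._make(out_data, (self,), backward)

    # -- loss --------------------------------------------------------------
    def bce_with_logits(self, targets: np.ndarray) -> "Tensor":
        """Mean binary cross-entropy of logits against 0/1 targets."""
        z = self.data
        y = np.asarray(targets, dtype=np.float64).reshape(z.shape)
        loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
        s = 1.0 / (1.0 + np.exp(-z))

        def backward(g):
            self._accum(g * (s - y) / z.size)

        return Tensor._make(loss, (self,), backward)

    # -- backward sweep ----------------------------------------------------
    def backward(self):
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
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)


def parameter(shape, rng: np.random.Generator, scale: float | None = None) -> Tensor:
    fan_in = shape[0] if len(shape) > 1 else max(shape[0], 1)
    scale = scale if scale is not None else 1.0 / np.sqrt(fan_in)
    return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)


class Adam:
    """Adam over a parameter list; state is per-parameter moment estimates."""

    def __init__(self, params: list[Tensor], lr=0.01, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
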