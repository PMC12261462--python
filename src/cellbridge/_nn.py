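"""Minimal reverse-mode autodiff on numpy arrays, plus MLPs and Adam.

The op set is exactly what the models in this package need: broadcasting
arithmetic, matmul, slicing, transpose, tanh/sigmoid/silu/softplus, exp/log,
abs, a straight-through unit-interval clamp, and sum/mean reductions.
Gradients accumulate in float64; everything is deterministic given the numpy
Generator streams passed in by callers.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "MLP", "Adam", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce `grad` back to `shape` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading added axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_children", "_backward")

    def __init__(self, data, requires_grad: bool = False, _children=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._children = _children
        self._backward = _backward

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
            for ch in node._children:
                if id(ch) not in seen:
                    stack.append((ch, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw():
            if self.requires_grad:
                self._accum(out.grad)
            if other.requires_grad:
                other._accum(out.grad)
        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * other.data)
            if other.requires_grad:
                other._accum(out.grad * self.data)
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1.0))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     (self, other))

        def bw():
            g = out.grad
            if self.requires_grad:
                self._accum(g @ other.data.T if other.data.ndim == 2
                            else np.outer(g, other.data))
            if other.requires_grad:
                other._accum(self.data.T @ g)
        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)
        out._backward = bw
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad.T)
        out._backward = bw
        return out

    # -- nonlinearities ---------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - y * y))
        out._backward = bw
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * y * (1.0 - y))
        out._backward = bw
        return out

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(self.data * s, self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * s * (1.0 + self.data * (1.0 - s)))
        out._backward = bw
        return out

    def softplus(self):
        out = Tensor(np.logaddexp(0.0, self.data), self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
                self._accum(out.grad * s)
        out._backward = bw
        return out

    def exp(self):
        y = np.exp(self.data)
        out = Tensor(y, self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * y)
        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad / self.data)
        out._backward = bw
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * np.sign(self.data))
        out._backward = bw
        return out

    def clamp01_st(self):
        """Clamp to [0, 1] with a straight-through gradient."""
        out = Tensor(np.clip(self.data, 0.0, 1.0), self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad)
        out._backward = bw
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bw():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def item(self) -> float:
        return float(self.data)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    req = any(t.requires_grad for t in tensors)
    out = Tensor(data, req, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bw():
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * data.ndim
                sl[axis] = slice(a, b)
                t._accum(out.grad[tuple(sl)])
    out._backward = bw
    return out


class MLP:
    """Fully connected net; weights are trainable Tensors.

    sizes = [in, h1, ..., out]; `activation` between hidden layers only.
    `zero_init_last` zeroes the output layer so an untrained net is the
    constant-zero map (used for drift fields).
    """

    def __init__(self, sizes, rng: np.random.Generator,
                 activation: str = "silu", zero_init_last: bool = False):
        self.sizes = list(sizes)
        self.activation = activation
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        for i, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            last = i == len(sizes) - 2
            if last and zero_init_last:
                w = np.zeros((fan_in, fan_out))
            else:
                w = rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)),
                               size=(fan_in, fan_out))
            self.weights.append(Tensor(w, requires_grad=True))
            self.biases.append(Tensor(np.zeros(fan_out), requires_grad=True))

    @property
    def params(self) -> list[Tensor]:
        return self.weights + self.biases

    def _act(self, x: Tensor) -> Tensor:
        if self.activation == "tanh":
            return x.tanh()
        if self.activation == "silu":
            return x.silu()
        raise ValueError(f"unknown activation {self.activation!r}")

    def forward(self, x: Tensor) -> Tensor:
        h = x
        n = len(self.weights)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < n - 1:
                h = self._act(h)
        return h

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(Tensor(x)).data

    def state(self) -> dict[str, np.ndarray]:
        d = {}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            d[f"W{i}"] = w.data.copy()
            d[f"b{i}"] = b.data.copy()
        return d

    def load_state(self, d: dict[str, np.ndarray]) -> None:
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            w.data = np.asarray(d[f"W{i}"], dtype=np.float64).copy()
            b.data = np.asarray(d[f"b{i}"], dtype=np.float64).copy()


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
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
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
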