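"""A compact reverse-mode automatic-differentiation engine over numpy arrays.

The trainable network in :mod:`acpnet.network` is small (one convolutional
layer per branch, one recurrent layer, one attention block, two dense layers),
so rather than depending on a heavyweight framework the model is expressed in
the handful of differentiable primitives below.  Every op stores its parents
and a closure that accumulates gradients; ``Tensor.backward`` runs a
topological sweep.  All arithmetic is float64.

Gradient correctness is asserted against central-difference numerical
gradients in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverses numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph mechanics -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- elementwise arithmetic ------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = backward
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(
            self.data / other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        out._backward = backward
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        out._backward = backward
        return out

    # -- linear algebra ---------------------------------------------------

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor(
            np.matmul(self.data, other.data),
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def backward(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                a = self.data
                if a.ndim == 1:
                    gb = np.outer(a, g) if g.ndim == 1 else np.matmul(a[:, None], g[None, :])
                else:
                    gb = np.matmul(np.swapaxes(a, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = backward
        return out

    __matmul__ = matmul

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a, b), requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))

        out._backward = backward
        return out

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        out._backward = backward
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = backward
        return out

    def take_last_axis(self, indices: np.ndarray) -> "Tensor":
        """Gather along the flattened last axis: used by im2col convolution.

        ``self`` has shape (..., M); ``indices`` any shape of ints < M; the
        result has shape (..., *indices.shape).
        """
        idx = np.asarray(indices)
        out_data = self.data[..., idx.ravel()].reshape(self.data.shape[:-1] + idx.shape)
        out = Tensor(out_data, requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                flat_g = g.reshape(self.data.shape[:-1] + (idx.size,))
                full = np.zeros_like(self.data)
                np.add.at(full, (..., idx.ravel()), flat_g)
                self._accum(full)

        out._backward = backward
        return out

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            requires_grad=self.requires_grad,
            parents=(self,),
        )

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.full_like(self.data, float(g)))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities ----------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = backward
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        out._backward = backward
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - t * t))

        out._backward = backward
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g * e)

        out._backward = backward
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = backward
        return out

    def clip(self, lo: float, hi: float) -> "Tensor":
        out = Tensor(np.clip(self.data, lo, hi), requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                inside = (self.data > lo) & (self.data < hi)
                self._accum(g * inside)

        out._backward = backward
        return out

    def softmax_last(self) -> "Tensor":
        """Numerically stable softmax over the last axis."""
        shifted = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(s, requires_grad=self.requires_grad, parents=(self,))

        def backward(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=-1, keepdims=True)
                self._accum(s * (g - dot))

        out._backward = backward
        return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        requires_grad=any(t.requires_grad for t in tensors),
        parents=tuple(tensors),
    )
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        pieces = np.split(g, splits, axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(piece)

    out._backward = backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(
        np.stack([t.data for t in tensors], axis=axis),
        requires_grad=any(t.requires_grad for t in tensors),
        parents=tuple(tensors),
    )

    def backward(g):
        pieces = np.split(g, len(tensors), axis=axis)
        for t, piece in zip(tensors, pieces):
            if t.requires_grad:
                t._accum(np.squeeze(piece, axis=axis))

    out._backward = backward
    return out


class Adam:
    """Adam optimizer over a dict of named parameter Tensors."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    """Glorot/Xavier uniform init: limit sqrt(6 / (fan_in + fan_out))."""
    if len(shape) == 1:
        fan_in = fan_out = shape[0]
    else:
        fan_in, fan_out = shape[-1], shape[-2]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)
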