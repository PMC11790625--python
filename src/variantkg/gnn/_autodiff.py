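"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for full-batch message-passing networks: dense
matmul, elementwise arithmetic with broadcasting, ReLU/sigmoid/exp/log,
reductions, row gather and segment-sum scatter (the two primitives that
express edge-list message passing), plus an Adam optimizer.  Backward
passes accumulate into ``.grad``; ``Tensor.backward()`` runs a
topological sweep from a scalar loss.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "spmm", "DTYPE", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager suppressing tape construction (inference passes)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False

#: working precision; single precision halves memory on edge-heavy graphs
DTYPE = np.float32


def _scatter_add(index: np.ndarray, values: np.ndarray, num_segments: int) -> np.ndarray:
    """out[s] += values[i] for index[i] == s, via a sparse selection
    matrix (orders of magnitude faster than an unbuffered ufunc on
    edge-sized arrays)."""
    from scipy import sparse

    flat = values.reshape(len(index), -1)
    sel = sparse.csr_matrix(
        (np.ones(len(index), dtype=values.dtype), (index, np.arange(len(index)))),
        shape=(num_segments, len(index)),
    )
    out = sel @ flat
    return np.asarray(out).reshape((num_segments,) + values.shape[1:])


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("value", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, value, requires_grad: bool = False):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(value, parents, backward, requires_grad=True):
        out = Tensor(value, requires_grad=requires_grad and _GRAD_ENABLED)
        if out.requires_grad:
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.value.shape)
        # never mutate in place: incoming grads may be shared between parents
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self) -> None:
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.value)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- ops ---------------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g)
            if other.requires_grad:
                other._accumulate(g)

        return Tensor._make(
            self.value + other.value, (self, other), backward,
            self.requires_grad or other.requires_grad,
        )

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._make(-self.value, (self,), backward, self.requires_grad)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * other.value)
            if other.requires_grad:
                other._accumulate(g * self.value)

        return Tensor._make(
            self.value * other.value, (self, other), backward,
            self.requires_grad or other.requires_grad,
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / other.value)
            if other.requires_grad:
                other._accumulate(-g * self.value / other.value**2)

        return Tensor._make(
            self.value / other.value, (self, other), backward,
            self.requires_grad or other.requires_grad,
        )

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.value.T)
            if other.requires_grad:
                other._accumulate(self.value.T @ g)

        return Tensor._make(
            self.value @ other.value, (self, other), backward,
            self.requires_grad or other.requires_grad,
        )

    __matmul__ = matmul

    def relu(self) -> "Tensor":
        mask = self.value > 0

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(self.value * mask, (self,), backward, self.requires_grad)

    def sigmoid(self) -> "Tensor":
        out_val = 1.0 / (1.0 + np.exp(-np.clip(self.value, -60, 60)))

        def backward(g):
            self._accumulate(g * out_val * (1 - out_val))

        return Tensor._make(out_val, (self,), backward, self.requires_grad)

    def exp(self) -> "Tensor":
        out_val = np.exp(np.clip(self.value, -80, 80))

        def backward(g):
            self._accumulate(g * out_val)

        return Tensor._make(out_val, (self,), backward, self.requires_grad)

    def log(self) -> "Tensor":
        def backward(g):
            self._accumulate(g / self.value)

        return Tensor._make(np.log(self.value), (self,), backward, self.requires_grad)

    def sqrt(self) -> "Tensor":
        out_val = np.sqrt(self.value)

        def backward(g):
            self._accumulate(g * 0.5 / np.maximum(out_val, 1e-30))

        return Tensor._make(out_val, (self,), backward, self.requires_grad)

    def sum(self, axis=None, keepdims=False) -> "Tensor":
        def backward(g):
            grad = np.asarray(g)
            if axis is not None and not keepdims:
                grad = np.expand_dims(grad, axis)
            self._accumulate(np.broadcast_to(grad, self.value.shape))

        return Tensor._make(
            self.value.sum(axis=axis, keepdims=keepdims), (self,), backward,
            self.requires_grad,
        )

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        count = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def gather(self, index: np.ndarray) -> "Tensor":
        """Select rows: out[i] = self[index[i]] (backward scatter-adds)."""
        index = np.asarray(index)
        n_rows = self.value.shape[0]

        def backward(g):
            self._accumulate(_scatter_add(index, np.asarray(g), n_rows))

        return Tensor._make(self.value[index], (self,), backward, self.requires_grad)

    def segment_sum(self, index: np.ndarray, num_segments: int) -> "Tensor":
        """out[s] = sum of self[i] where index[i] == s (backward gathers)."""
        index = np.asarray(index)
        out_val = _scatter_add(index, self.value, num_segments)

        def backward(g):
            self._accumulate(np.asarray(g)[index])

        return Tensor._make(out_val, (self,), backward, self.requires_grad)

    def reshape(self, *shape) -> "Tensor":
        old_shape = self.value.shape

        def backward(g):
            self._accumulate(np.asarray(g).reshape(old_shape))

        return Tensor._make(
            self.value.reshape(*shape), (self,), backward, self.requires_grad
        )

    # -- composites ---------------------------------------------------------

    def log_softmax(self) -> "Tensor":
        """Row-wise log-softmax (shift by a detached row max for stability)."""
        shift = Tensor(self.value.max(axis=-1, keepdims=True))
        z = self - shift
        return z - z.exp().sum(axis=-1, keepdims=True).log()

    def layer_norm(self, eps: float = 1e-5) -> "Tensor":
        mu = self.mean(axis=-1, keepdims=True)
        centered = self - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + eps).sqrt()


def spmm(a_sparse, x: Tensor) -> Tensor:
    """Product of a constant scipy sparse matrix with a Tensor.

    The sparse operand carries no gradient; backward is ``A.T @ g``.
    This is the memory-frugal aggregation path for fixed graphs (the
    per-edge gather/segment path is only needed when edge weights are
    themselves being learned).
    """

    def backward(g):
        x._accumulate((a_sparse.T @ np.asarray(g)).astype(DTYPE, copy=False))

    return Tensor._make(
        (a_sparse @ x.value).astype(DTYPE, copy=False), (x,), backward, x.requires_grad
    )


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

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
            m_hat = self.m[i] / (1 - self.b1**self.t)
            v_hat = self.v[i] / (1 - self.b2**self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
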