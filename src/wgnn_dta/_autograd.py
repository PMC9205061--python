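"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery to train the two-branch graph network on a CPU:
dense/sparse matrix products, broadcast elementwise arithmetic, the
activations used by the model, row gather/scatter (for edge-indexed
message passing and segment softmax/pooling), and an Adam optimizer.
Deliberately not a general framework — ops are added as the model needs
them.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "Parameter", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # -- graph construction helper ------------------------------------
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray, owned: bool = False) -> None:
        # `owned` promises the caller allocated `grad` freshly, so it can
        # be adopted without a defensive copy on first write
        if self.grad is None:
            if owned and grad.shape == self.data.shape:
                self.grad = grad
            else:
                self.grad = np.broadcast_to(grad, self.data.shape).astype(
                    np.float64
                )
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other) -> "Tensor":
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                ga = _unbroadcast(g, self.shape)
                self._accum(ga, owned=ga is not g)
            if other.requires_grad:
                gb = _unbroadcast(g, other.shape)
                other._accum(gb, owned=gb is not g)

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape), owned=True)
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape), owned=True)

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-self._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return self._coerce(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        return self * self._coerce(other).pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0), owned=True)

        return Tensor._make(self.data**exponent, (self,), bwd)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._coerce(other)

        def bwd(g):
            if self.requires_grad:
                self._accum(g @ other.data.T, owned=True)
            if other.requires_grad:
                other._accum(self.data.T @ g, owned=True)

        return Tensor._make(self.data @ other.data, (self, other), bwd)

    def __matmul__(self, other):
        return self.matmul(other)

    def sparse_matmul(self, mat: sp.spmatrix) -> "Tensor":
        """Left-multiply by a constant sparse matrix: ``mat @ self``."""
        mat = mat.tocsr()

        def bwd(g):
            if self.requires_grad:
                self._accum(mat.T @ g, owned=True)

        return Tensor._make(mat @ self.data, (self,), bwd)

    # -- activations ----------------------------------------------------
    def relu(self) -> "Tensor":
        mask = self.data > 0

        def bwd(g):
            if self.requires_grad:
                self._accum(g * mask, owned=True)

        return Tensor._make(self.data * mask, (self,), bwd)

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        factor = np.where(self.data > 0, 1.0, slope)

        def bwd(g):
            if self.requires_grad:
                self._accum(g * factor, owned=True)

        return Tensor._make(self.data * factor, (self,), bwd)

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s), owned=True)

        return Tensor._make(s, (self,), bwd)

    def exp(self) -> "Tensor":
        e = np.exp(np.clip(self.data, -700, 700))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * e, owned=True)

        return Tensor._make(e, (self,), bwd)

    def log(self) -> "Tensor":
        def bwd(g):
            if self.requires_grad:
                self._accum(g / self.data, owned=True)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def softplus(self) -> "Tensor":
        """log(1 + exp(x)), computed stably."""
        out = np.logaddexp(0.0, self.data)
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bwd(g):
            if self.requires_grad:
                self._accum(g * s, owned=True)

        return Tensor._make(out, (self,), bwd)

    # -- reductions & indexing ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.shape))

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd
        )

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    @staticmethod
    def _scatter_matrix(ids: np.ndarray, n_rows: int) -> sp.csr_matrix:
        """Sparse (n_rows, len(ids)) matrix summing entry k into row
        ids[k]; a csr product is much faster than np.add.at for wide
        per-row payloads."""
        k = ids.size
        return sp.csr_matrix(
            (np.ones(k), (ids, np.arange(k))), shape=(n_rows, k)
        )

    def gather_rows(self, index: np.ndarray) -> "Tensor":
        """Select rows by integer index (with repetition)."""
        index = np.asarray(index, dtype=np.int64)

        def bwd(g):
            if self.requires_grad:
                scat = Tensor._scatter_matrix(index, self.data.shape[0])
                self._accum(scat @ g, owned=True)

        return Tensor._make(self.data[index], (self,), bwd)

    def segment_sum(self, segment_ids: np.ndarray, num_segments: int) -> "Tensor":
        """Sum rows into ``num_segments`` buckets given per-row segment ids."""
        segment_ids = np.asarray(segment_ids, dtype=np.int64)
        scat = Tensor._scatter_matrix(segment_ids, num_segments)
        out = scat @ self.data

        def bwd(g):
            if self.requires_grad:
                self._accum(g[segment_ids], owned=True)

        return Tensor._make(out, (self,), bwd)

    @staticmethod
    def edge_aggregate(
        coeff: "Tensor",
        nodes: "Tensor",
        src: np.ndarray,
        dst: np.ndarray,
        num_out: int,
    ) -> "Tensor":
        """Fused message passing: out[i] = sum over edges (j -> i) of
        coeff_e * nodes[j], done as one sparse matrix product instead of
        gather / multiply / scatter (coeff is per-edge, shape (E,) or
        (E, 1))."""
        src = np.asarray(src, dtype=np.int64)
        dst = np.asarray(dst, dtype=np.int64)
        c = coeff.data.ravel()
        n_in = nodes.data.shape[0]
        A = sp.csr_matrix((c, (dst, src)), shape=(num_out, n_in))

        def bwd(g):
            if nodes.requires_grad:
                nodes._accum(A.T @ g, owned=True)
            if coeff.requires_grad:
                gc = np.einsum("ef,ef->e", g[dst], nodes.data[src])
                coeff._accum(gc.reshape(coeff.shape), owned=True)

        return Tensor._make(A @ nodes.data, (coeff, nodes), bwd)

    def concat(self, other: "Tensor", axis: int = 1) -> "Tensor":
        other = self._coerce(other)
        split = self.data.shape[axis]

        def bwd(g):
            ga, gb = np.split(g, [split], axis=axis)
            if self.requires_grad:
                self._accum(ga)
            if other.requires_grad:
                other._accum(gb)

        return Tensor._make(
            np.concatenate([self.data, other.data], axis=axis),
            (self, other),
            bwd,
        )

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)


class Parameter(Tensor):
    """Trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam optimizer (Kingma & Ba) over a list of Parameters."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
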