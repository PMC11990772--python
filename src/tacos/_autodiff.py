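"""Minimal reverse-mode automatic differentiation over numpy arrays.

The integration model only needs a handful of differentiable primitives
(dense/sparse matrix products, elementwise arithmetic, exp/log/sqrt, PReLU,
row gathering and reductions), so the engine is deliberately small: a
:class:`Tensor` records, for each operation, the parent tensors that require
gradients together with vector-Jacobian-product closures. ``backward`` walks
the graph in reverse topological order and accumulates gradients into leaf
tensors (the model parameters). Gradients of intermediate nodes live only in
a per-call dictionary, so calling ``backward`` on several loss components in
the same epoch accumulates into the leaves without double counting.

Every primitive is validated against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "as_tensor", "spmm", "prelu", "relu", "take_rows", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape."""

    __slots__ = ("data", "requires_grad", "grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) or bool(parents)
        self.grad = None  # populated on leaves by backward()
        # parents: tuple of (Tensor, vjp) for parents that require grad
        self._parents = tuple(parents)

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def zero_grad(self):
        self.grad = None

    # --------------------------------------------------------------- backward
    def backward(self):
        """Accumulate d(self)/d(leaf) into ``leaf.grad`` for every leaf.

        ``self`` must be a scalar. Safe to call multiple times on different
        roots sharing subgraphs: leaf gradients add up.
        """
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        grads: dict[int, np.ndarray] = {
            id(self): np.ones_like(self.data)
        }
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if not node._parents:
                if node.requires_grad:
                    if node.grad is None:
                        node.grad = np.zeros_like(node.data)
                    node.grad += _unbroadcast(g, node.data.shape)
                continue
            for parent, vjp in node._parents:
                pg = vjp(g)
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    # -------------------------------------------------------------- operators
    # Python scalars are kept unwrapped so float32 graphs are not promoted
    # to float64 by NumPy's array-scalar rules.
    def __add__(self, other):
        if isinstance(other, (int, float)):
            parents = [(self, lambda g: g)] if self.requires_grad else []
            return Tensor(self.data + other, parents=parents)
        other = as_tensor(other)
        out_data = self.data + other.data
        parents = []
        if self.requires_grad:
            sh = self.data.shape
            parents.append((self, lambda g, sh=sh: _unbroadcast(g, sh)))
        if other.requires_grad:
            sh = other.data.shape
            parents.append((other, lambda g, sh=sh: _unbroadcast(g, sh)))
        return Tensor(out_data, parents=parents)

    __radd__ = __add__

    def __neg__(self):
        parents = []
        if self.requires_grad:
            parents.append((self, lambda g: -g))
        return Tensor(-self.data, parents=parents)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            parents = [(self, lambda g, c=other: g * c)] if self.requires_grad else []
            return Tensor(self.data * other, parents=parents)
        other = as_tensor(other)
        out_data = self.data * other.data
        parents = []
        if self.requires_grad:
            sh = self.data.shape
            od = other.data
            parents.append((self, lambda g, od=od, sh=sh: _unbroadcast(g * od, sh)))
        if other.requires_grad:
            sh = other.data.shape
            sd = self.data
            parents.append((other, lambda g, sd=sd, sh=sh: _unbroadcast(g * sd, sh)))
        return Tensor(out_data, parents=parents)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = as_tensor(other)
        out_data = self.data / other.data
        parents = []
        if self.requires_grad:
            sh = self.data.shape
            od = other.data
            parents.append((self, lambda g, od=od, sh=sh: _unbroadcast(g / od, sh)))
        if other.requires_grad:
            sh = other.data.shape
            sd, od = self.data, other.data
            parents.append(
                (other, lambda g, sd=sd, od=od, sh=sh: _unbroadcast(-g * sd / (od * od), sh))
            )
        return Tensor(out_data, parents=parents)

    def __pow__(self, p):
        p = float(p)
        out_data = self.data ** p
        parents = []
        if self.requires_grad:
            sd = self.data
            parents.append((self, lambda g, sd=sd, p=p: g * p * sd ** (p - 1.0)))
        return Tensor(out_data, parents=parents)

    def __matmul__(self, other):
        other = as_tensor(other)
        out_data = self.data @ other.data
        parents = []
        if self.requires_grad:
            od = other.data
            parents.append((self, lambda g, od=od: g @ od.T))
        if other.requires_grad:
            sd = self.data
            parents.append((other, lambda g, sd=sd: sd.T @ g))
        return Tensor(out_data, parents=parents)

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    @property
    def T(self):
        parents = []
        if self.requires_grad:
            parents.append((self, lambda g: g.T))
        return Tensor(self.data.T, parents=parents)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        parents = []
        if self.requires_grad:
            sh = self.data.shape

            def vjp(g, sh=sh, axis=axis, keepdims=keepdims):
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                return np.ascontiguousarray(np.broadcast_to(g, sh))

            parents.append((self, vjp))
        return Tensor(out_data, parents=parents)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------ elementwise
    def exp(self):
        out_data = np.exp(self.data)
        parents = []
        if self.requires_grad:
            parents.append((self, lambda g, od=out_data: g * od))
        return Tensor(out_data, parents=parents)

    def log(self):
        out_data = np.log(self.data)
        parents = []
        if self.requires_grad:
            sd = self.data
            parents.append((self, lambda g, sd=sd: g / sd))
        return Tensor(out_data, parents=parents)

    def sqrt(self):
        out_data = np.sqrt(self.data)
        parents = []
        if self.requires_grad:
            parents.append((self, lambda g, od=out_data: g / (2.0 * od)))
        return Tensor(out_data, parents=parents)

    def relu(self):
        out_data = np.maximum(self.data, 0)
        parents = []
        if self.requires_grad:
            mask = (self.data > 0).astype(self.data.dtype)
            parents.append((self, lambda g, mask=mask: g * mask))
        return Tensor(out_data, parents=parents)

    def max(self):
        """Global maximum (0-d); gradient routes to the (first) argmax."""
        idx = np.unravel_index(np.argmax(self.data), self.data.shape)
        out_data = np.asarray(self.data[idx])
        parents = []
        if self.requires_grad:
            sh = self.data.shape

            def vjp(g, idx=idx, sh=sh):
                out = np.zeros(sh, dtype=g.dtype)
                out[idx] = g
                return out

            parents.append((self, vjp))
        return Tensor(out_data, parents=parents)

    def min(self):
        return -((-self).max())

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        parents = []
        if self.requires_grad:
            sh = self.data.shape
            parents.append((self, lambda g, sh=sh: g.reshape(sh)))
        return Tensor(out_data, parents=parents)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def relu(x: Tensor) -> Tensor:
    return as_tensor(x).relu()


def prelu(x: Tensor, slope: Tensor) -> Tensor:
    """Parametric ReLU with a learnable scalar slope for the negative part."""
    x = as_tensor(x)
    slope = as_tensor(slope)
    pos = x.data > 0
    s = float(slope.data)
    out_data = np.where(pos, x.data, s * x.data)
    parents = []
    if x.requires_grad:
        dgrad = np.where(pos, np.asarray(1.0, dtype=x.dtype), slope.data).astype(x.dtype)
        parents.append((x, lambda g, dgrad=dgrad: g * dgrad))
    if slope.requires_grad:
        neg_x = np.where(pos, 0.0, x.data)
        parents.append(
            (slope, lambda g, neg_x=neg_x: np.asarray((g * neg_x).sum(), dtype=slope.dtype))
        )
    return Tensor(out_data, parents=parents)


def spmm(A: sp.spmatrix, x: Tensor) -> Tensor:
    """Sparse-constant @ dense-tensor product; gradient flows to ``x`` only."""
    x = as_tensor(x)
    A = sp.csr_matrix(A)
    out_data = A @ x.data
    parents = []
    if x.requires_grad:
        AT = A.T.tocsr()
        parents.append((x, lambda g, AT=AT: AT @ g))
    return Tensor(out_data, parents=parents)


def take_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows of a 2-D tensor by integer index (repeats allowed)."""
    x = as_tensor(x)
    idx = np.asarray(idx, dtype=np.intp)
    out_data = x.data[idx]
    parents = []
    if x.requires_grad:
        sh = x.data.shape

        def vjp(g, idx=idx, sh=sh):
            out = np.zeros(sh, dtype=g.dtype)
            np.add.at(out, idx, g)
            return out

        parents.append((x, vjp))
    return Tensor(out_data, parents=parents)


class Adam:
    """Adam optimizer over a list of leaf :class:`Tensor` parameters."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * (g * g)
            mhat = m / b1t
            vhat = v / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
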