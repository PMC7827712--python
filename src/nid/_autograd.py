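"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the estimators in this package need:
broadcast add/multiply, (batched) matmul, relu, axis mean, embedding lookup
and a fused softmax cross-entropy.  Gradients flow through a dynamically
built graph; ``backward`` runs a topological sweep.  Everything is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam", "cross_entropy_sum", "relu", "embedding"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction --------------------------------------------
    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t: "Tensor") -> None:
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- ops ------------------------------------------------------------
    def __add__(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data + other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    def __mul__(self, other) -> "Tensor":
        if isinstance(other, (int, float)):
            out = Tensor(self.data * other, (self,))

            def bwd_s(g):
                if self.requires_grad:
                    self._accum(g * other)

            out._backward = bwd_s
            return out
        out = Tensor(self.data * other.data, (self, other))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(np.matmul(self.data, other.data), (self, other))

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bwd
        return out

    __matmul__ = matmul

    def mean(self, axis: int) -> "Tensor":
        n = self.data.shape[axis]
        out = Tensor(self.data.mean(axis=axis), (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(np.repeat(np.expand_dims(g / n, axis), n, axis=axis))

        out._backward = bwd
        return out

    def amax(self, axis: int) -> "Tensor":
        """Max pooling along one axis (ties broken towards the first index)."""
        idx = np.argmax(self.data, axis=axis)
        out = Tensor(np.take_along_axis(self.data, np.expand_dims(idx, axis), axis).squeeze(axis), (self,))

        def bwd(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.put_along_axis(full, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis)
                self._accum(full)

        out._backward = bwd
        return out

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        out._backward = bwd
        return out

    def broadcast_to(self, shape) -> "Tensor":
        orig = self.data.shape
        out = Tensor(np.broadcast_to(self.data, shape), (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, orig))

        out._backward = bwd
        return out

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), (self,))

        def bwd(g):
            if self.requires_grad:
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out


class Parameter(Tensor):
    """Trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), (x,))

    def bwd(g):
        if x.requires_grad:
            x._accum(g * (x.data > 0.0))

    out._backward = bwd
    return out


def embedding(table: Tensor, *index_arrays: np.ndarray) -> Tensor:
    """Advanced-indexing lookup ``table[idx...]`` with scatter-add backward."""
    idx = tuple(index_arrays)
    out = Tensor(table.data[idx], (table,))

    def bwd(g):
        if table.requires_grad:
            full = np.zeros_like(table.data)
            np.add.at(full, idx, g)
            table._accum(full)

    out._backward = bwd
    return out


def cross_entropy_sum(
    logits: Tensor, targets: np.ndarray, weights: np.ndarray | None = None
) -> Tensor:
    """Weighted sum over all leading axes of -log softmax(logits)[target].

    ``logits`` has shape ``(..., q)``, ``targets`` integer shape ``(...)``,
    ``weights`` broadcastable to ``targets`` (defaults to 1).  Returns a
    scalar tensor; the per-element NLL matrix is available via
    :func:`nll_matrix` for reporting.
    """
    nll, probs = _nll_forward(logits.data, targets)
    if weights is None:
        w = np.ones_like(nll)
    else:
        w = np.broadcast_to(np.asarray(weights, dtype=np.float64), nll.shape)
    out = Tensor((nll * w).sum(), (logits,))

    def bwd(g):
        if logits.requires_grad:
            grad = probs.copy()
            np.put_along_axis(
                grad,
                targets[..., None],
                np.take_along_axis(grad, targets[..., None], -1) - 1.0,
                -1,
            )
            logits._accum(grad * (g * w)[..., None])

    out._backward = bwd
    return out


def _nll_forward(logits: np.ndarray, targets: np.ndarray):
    z = logits - logits.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    nll = -np.take_along_axis(logp, targets[..., None], -1)[..., 0]
    return nll, np.exp(logp)


def nll_matrix(logits: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Per-element negative log-likelihoods (forward only, plain numpy)."""
    return _nll_forward(np.asarray(logits, dtype=np.float64), targets)[0]


class Adam:
    """Adam optimizer with optional global gradient-norm clipping."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, clip_norm=None):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.clip_norm = clip_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        grads = [
            p.grad if p.grad is not None else np.zeros_like(p.data)
            for p in self.params
        ]
        if self.clip_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
                grads = [g * scale for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
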