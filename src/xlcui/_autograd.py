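"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

This is a compact NN core sized for the small models in this package: dense
layers, character convolutions, LSTM cells and cosine-softmax classifiers over
a few thousand parameters. Tensors wrap float64 numpy arrays; gradients are
accumulated by a topological backward sweep. Broadcasting is supported for the
elementwise ops via gradient un-broadcasting.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "gather", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, prev, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(p for p in prev if p.requires_grad)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    # -- elementwise ----------------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return Tensor._make(out_data, (self, other), backward)

    # -- matmul ---------------------------------------------------------------
    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    # -- nonlinearities -------------------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def sigmoid(self):
        x = self.data
        out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                            np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            self._accum(g * (self.data > 0))

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    # -- reductions / shaping -------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis):
        out_data = self.data.max(axis=axis)
        argmax = self.data.argmax(axis=axis)

        def backward(g):
            full = np.zeros_like(self.data)
            idx = list(np.indices(out_data.shape))
            idx.insert(axis if axis >= 0 else self.data.ndim + axis, argmax)
            full[tuple(idx)] = g
            self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]
        basic = isinstance(key, (slice, int)) or (
            isinstance(key, tuple) and all(isinstance(k, (slice, int)) for k in key))

        def backward(g):
            full = np.zeros_like(self.data)
            if basic:  # basic indexing never aliases, += is exact
                full[key] += g
            else:
                np.add.at(full, key, g)
            self._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # -- fused losses ---------------------------------------------------------
    def bce_with_logits(self, targets: np.ndarray, pos_weight: float = 1.0) -> "Tensor":
        """Mean binary cross-entropy of sigmoid(self) against {0,1} targets.

        ``pos_weight`` scales the positive-class term (useful when positives
        are rare among enumerated candidates).
        """
        x = self.data
        t = np.asarray(targets, dtype=np.float64)
        # softplus(x) = max(x,0) + log(1+exp(-|x|)) is the stable core
        sp_neg = np.maximum(-x, 0) + np.log1p(np.exp(-np.abs(x)))   # softplus(-x)
        sp_pos = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))    # softplus(x)
        loss = pos_weight * t * sp_neg + (1.0 - t) * sp_pos
        n = x.size

        def backward(g):
            s = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                         np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
            grad = pos_weight * t * (s - 1.0) + (1.0 - t) * s
            self._accum(g * grad / n)

        return Tensor._make(loss.mean(), (self,), backward)

    def softmax_cross_entropy(self, labels: np.ndarray) -> "Tensor":
        """Mean cross-entropy of row-softmax(self) against integer labels."""
        x = self.data
        labels = np.asarray(labels)
        shifted = x - x.max(axis=1, keepdims=True)
        logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        logp = shifted - logz
        n = x.shape[0]
        loss = -logp[np.arange(n), labels].mean()

        def backward(g):
            p = np.exp(logp)
            p[np.arange(n), labels] -= 1.0
            self._accum(g * p / n)

        return Tensor._make(loss, (self,), backward)

    # -- backprop driver ------------------------------------------------------
    def backward(self):
        # topological order via iterative DFS post-ordering
        order: list[Tensor] = []
        seen2 = set()

        def visit(node):
            st = [(node, iter(node._prev))]
            while st:
                cur, it = st[-1]
                advanced = False
                for child in it:
                    if id(child) not in seen2:
                        seen2.add(id(child))
                        st.append((child, iter(child._prev)))
                        advanced = True
                        break
                if not advanced:
                    order.append(cur)
                    st.pop()

        seen2.add(id(self))
        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        parts = np.split(g, splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    return Tensor._make(out_data, tuple(tensors), backward)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def gather(t: Tensor, idx: np.ndarray) -> Tensor:
    """Row lookup t[idx] for an integer index array of any shape."""
    idx = np.asarray(idx)
    out_data = t.data[idx]

    def backward(g):
        full = np.zeros_like(t.data)
        np.add.at(full, idx, g)
        t._accum(full)

    return Tensor._make(out_data, (t,), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
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
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
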