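"""A compact reverse-mode automatic differentiation engine on numpy.

Sized for the models in this package: dense tensors, float64, a tape of
closures, and exactly the operations the vector-neuron encoder/decoders
need (broadcasted arithmetic, batched matmul, reductions, gather /
scatter-add for k-NN neighborhoods, cross products, piecewise-linear
activations). Gradients flow only through ``Tensor`` nodes created with
``requires_grad`` or derived from them.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concatenate", "cross", "gather_nodes", "where_mask"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # ----- construction helpers -------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ----- graph machinery ------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in t._backward(g):
                    if not parent.requires_grad:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg
            else:
                t.grad = g if t.grad is None else t.grad + g

    # ----- arithmetic ------------------------------------------------
    def __add__(self, other):
        o = Tensor.as_tensor(other)
        return self._make(
            self.data + o.data,
            (self, o),
            lambda g: [
                (self, _unbroadcast(g, self.data.shape)),
                (o, _unbroadcast(g, o.data.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: [(self, -g)])

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        o = Tensor.as_tensor(other)
        return self._make(
            self.data * o.data,
            (self, o),
            lambda g: [
                (self, _unbroadcast(g * o.data, self.data.shape)),
                (o, _unbroadcast(g * self.data, o.data.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = Tensor.as_tensor(other)
        return self._make(
            self.data / o.data,
            (self, o),
            lambda g: [
                (self, _unbroadcast(g / o.data, self.data.shape)),
                (o, _unbroadcast(-g * self.data / o.data**2, o.data.shape)),
            ],
        )

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)
        return self._make(
            self.data**e,
            (self,),
            lambda g: [(self, g * e * self.data ** (e - 1.0))],
        )

    def __matmul__(self, other):
        o = Tensor.as_tensor(other)

        def back(g):
            a, b = self.data, o.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return [
                (self, _unbroadcast(ga, a.shape)),
                (o, _unbroadcast(gb, b.shape)),
            ]

        return self._make(self.data @ o.data, (self, o), back)

    # ----- elementwise functions ------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: [(self, g * out_data)])

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(
            out_data, (self,), lambda g: [(self, g * 0.5 / np.maximum(out_data, 1e-300))]
        )

    def tanh(self):
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,), lambda g: [(self, g * (1 - out_data**2))])

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(
            out_data, (self,), lambda g: [(self, g * out_data * (1 - out_data))]
        )

    def abs(self):
        sign = np.sign(self.data)
        return self._make(np.abs(self.data), (self,), lambda g: [(self, g * sign)])

    def leaky_relu(self, alpha: float = 0.2):
        mask = np.where(self.data >= 0, 1.0, alpha)
        return self._make(self.data * mask, (self,), lambda g: [(self, g * mask)])

    def relu(self):
        return self.leaky_relu(alpha=0.0)

    # ----- reductions / shaping -------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return [(self, np.broadcast_to(g, self.data.shape).copy())]

        return self._make(out_data, (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return self._make(
            self.data.reshape(shape), (self,), lambda g: [(self, g.reshape(old))]
        )

    def swapaxes(self, a, b):
        return self._make(
            np.swapaxes(self.data, a, b),
            (self,),
            lambda g: [(self, np.swapaxes(g, a, b))],
        )

    def norm(self, axis=-1, keepdims=False, eps: float = 1e-12):
        """Euclidean norm along an axis, smoothed at zero by ``eps``."""
        return ((self * self).sum(axis=axis, keepdims=keepdims) + eps).sqrt()


class Parameter(Tensor):
    __slots__ = ()

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concatenate(tensors, axis=-1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        parts = np.split(g, splits, axis=axis)
        return list(zip(tensors, parts))

    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = back
    return out


def cross(a: Tensor, b: Tensor, axis: int = -1) -> Tensor:
    """Cross product of 3-vectors along ``axis``."""
    a = Tensor.as_tensor(a)
    b = Tensor.as_tensor(b)
    data = np.cross(a.data, b.data, axis=axis)

    def back(g):
        # d/da (a x b) . g = b x g ; d/db = g x a
        return [
            (a, _unbroadcast(np.cross(b.data, g, axis=axis), a.data.shape)),
            (b, _unbroadcast(np.cross(g, a.data, axis=axis), b.data.shape)),
        ]

    out = Tensor(data)
    if a.requires_grad or b.requires_grad:
        out.requires_grad = True
        out._parents = (a, b)
        out._backward = back
    return out


def gather_nodes(f: Tensor, idx: np.ndarray) -> Tensor:
    """Gather per-node neighbor features.

    f: (B, N, ...) tensor; idx: (B, N, k) integer array. Returns
    (B, N, k, ...) with out[b, n, j] = f[b, idx[b, n, j]].
    """
    f = Tensor.as_tensor(f)
    idx = np.asarray(idx)
    B = f.data.shape[0]
    batch = np.arange(B)[:, None, None]
    data = f.data[batch, idx]

    def back(g):
        grad = np.zeros_like(f.data)
        np.add.at(grad, (batch, idx), g)
        return [(f, grad)]

    out = Tensor(data)
    if f.requires_grad:
        out.requires_grad = True
        out._parents = (f,)
        out._backward = back
    return out


def neighbor_mean(f: Tensor, idx: np.ndarray) -> Tensor:
    """Mean of gathered neighbor features, fused to avoid materializing
    the (B, N, k, ...) block in the graph.

    f: (B, N, ...); idx: (B, N, k). Returns (B, N, ...) with
    out[b, n] = mean_j f[b, idx[b, n, j]].
    """
    f = Tensor.as_tensor(f)
    idx = np.asarray(idx)
    B, _, k = idx.shape
    batch = np.arange(B)[:, None, None]
    data = f.data[batch, idx].mean(axis=2)

    def back(g):
        grad = np.zeros_like(f.data)
        gk = np.repeat(np.expand_dims(g / k, 2), k, axis=2)
        np.add.at(grad, (batch, idx), gk)
        return [(f, grad)]

    out = Tensor(data)
    if f.requires_grad:
        out.requires_grad = True
        out._parents = (f,)
        out._backward = back
    return out


def where_mask(mask: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Select ``a`` where the (constant) boolean mask holds, else ``b``."""
    a = Tensor.as_tensor(a)
    b = Tensor.as_tensor(b)
    m = np.asarray(mask, dtype=bool)
    data = np.where(m, a.data, b.data)

    def back(g):
        return [
            (a, _unbroadcast(np.where(m, g, 0.0), a.data.shape)),
            (b, _unbroadcast(np.where(m, 0.0, g), b.data.shape)),
        ]

    out = Tensor(data)
    if a.requires_grad or b.requires_grad:
        out.requires_grad = True
        out._parents = (a, b)
        out._backward = back
    return out
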