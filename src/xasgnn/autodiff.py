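"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supplies exactly the operations the graph networks need: broadcast-aware
arithmetic, matmul, leaky ReLU, concatenation, row gathering and
segment-wise scatter sums (message passing and graph readout), and a
numerically safe segment softmax. Gradients accumulate into ``Tensor.grad``
after calling :meth:`Tensor.backward` on a scalar.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            return (_unbroadcast(g * other.data, self.shape),
                    _unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)

        def backward(g):
            return (_unbroadcast(g / other.data, self.shape),
                    _unbroadcast(-g * self.data / other.data ** 2, other.shape))

        return self._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    def square(self):
        return self._make(self.data ** 2, (self,), lambda g: (2.0 * g * self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return self._make(out_data, (self,), lambda g: (g / (2.0 * out_data),))

    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def leaky_relu(self, slope: float = 0.01):
        mask = np.where(self.data > 0, 1.0, slope)
        return self._make(self.data * mask, (self,), lambda g: (g * mask,))

    # -- indexing / structure -------------------------------------------------
    def gather_rows(self, index: np.ndarray):
        """Rows ``self[index]``; gradients scatter-add back."""
        index = np.asarray(index, dtype=int)

        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, index, g)
            return (out,)

        return self._make(self.data[index], (self,), backward)

    def reshape(self, *shape):
        old = self.shape
        return self._make(self.data.reshape(*shape), (self,),
                          lambda g: (g.reshape(old),))

    def detach_data(self) -> np.ndarray:
        return self.data

    # -- autodiff driver ------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, False)]
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

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:
                node.grad = g if node.grad is None else node.grad + g


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), backward)


def segment_sum(values: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of ``values`` into ``n_segments`` buckets given per-row ids."""
    segments = np.asarray(segments, dtype=int)
    out = np.zeros((n_segments,) + values.data.shape[1:])
    np.add.at(out, segments, values.data)

    def backward(g):
        return (g[segments],)

    return Tensor._make(out, (values,), backward)


def segment_mean(values: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    segments = np.asarray(segments, dtype=int)
    counts = np.bincount(segments, minlength=n_segments).astype(float)
    counts = np.maximum(counts, 1.0)
    summed = segment_sum(values, segments, n_segments)
    inv = (1.0 / counts).reshape((n_segments,) + (1,) * (summed.data.ndim - 1))
    return summed * Tensor(inv)


def segment_softmax(logits: Tensor, segments: np.ndarray, n_segments: int) -> Tensor:
    """Softmax of per-row logits normalized within each segment.

    The per-segment max is subtracted as a constant for numerical stability
    (its subgradient contribution cancels in exact arithmetic).
    """
    segments = np.asarray(segments, dtype=int)
    seg_max = np.full((n_segments,) + logits.data.shape[1:], -np.inf)
    np.maximum.at(seg_max, segments, logits.data)
    shifted = logits + Tensor(-seg_max[segments])
    exps = shifted.exp()
    denom = segment_sum(exps, segments, n_segments)
    return exps / denom.gather_rows(segments)
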