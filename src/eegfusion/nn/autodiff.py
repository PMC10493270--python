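"""Minimal reverse-mode automatic differentiation over numpy arrays.

Only the primitives needed by the transformer / graph-convolution stack are
implemented: broadcasting arithmetic, (batched) matmul, reductions, shape
ops, elementwise nonlinearities, fancy indexing and concatenation.
Gradients are validated against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

#: Large negative constant used for masking attention scores. exp() of it
#: underflows to exactly 0.0 in both float32 and float64.
NEG_INF = -1e30


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> "Tensor":
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # ensure numpy scalars/arrays defer to Tensor's reflected operators
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype.kind != "f":
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # ---- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __len__(self):
        return len(self.data)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        def bw(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape))
        return _node(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return _node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        other = as_tensor(other)
        def bw(g):
            return (_unbroadcast(g, self.data.shape), _unbroadcast(-g, other.data.shape))
        return _node(self.data - other.data, (self, other), bw)

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        other = as_tensor(other)
        def bw(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))
        return _node(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        def bw(g):
            return (_unbroadcast(g / other.data, self.data.shape),
                    _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape))
        return _node(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        def bw(g):
            return (g * p * self.data ** (p - 1),)
        return _node(self.data ** p, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        def bw(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            return (_unbroadcast(ga, self.data.shape), _unbroadcast(gb, other.data.shape))
        return _node(self.data @ other.data, (self, other), bw)

    # ---- elementwise ---------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return _node(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return _node(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return _node(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return _node(out_data, (self,), lambda g: (g * (1.0 - out_data ** 2),))

    def relu(self):
        mask = self.data > 0
        return _node(self.data * mask, (self,), lambda g: (g * mask,))

    # ---- shape ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        return _node(self.data.reshape(shape), (self,), lambda g: (g.reshape(orig),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return _node(self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),))

    def swapaxes(self, a: int, b: int):
        return _node(np.swapaxes(self.data, a, b), (self,),
                     lambda g: (np.swapaxes(g, a, b),))

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)
        return _node(self.data[idx], (self,), bw)

    # ---- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        orig = self.data.shape
        def bw(g):
            if axis is None:
                return (np.broadcast_to(g, orig).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return (np.broadcast_to(gg, orig).copy(),)
        return _node(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        elif isinstance(axis, tuple):
            n = int(np.prod([self.data.shape[a] for a in axis]))
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # ---- autodiff driver ----------------------------------------------
    def backward(self, grad=None) -> None:
        """Accumulate gradients of ``self`` into every reachable leaf's ``.grad``."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for p, pg in zip(node._parents, node._backward(g)):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]
    def bw(g):
        return tuple(np.split(g, splits, axis=axis))
    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)
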