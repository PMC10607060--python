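"""Reverse-mode automatic differentiation on numpy arrays.

A ``Tensor`` wraps a float64 ndarray and records, for each operation, a
closure that distributes the output gradient to its parents.  ``backward``
walks the tape in reverse topological order.  The engine is deliberately
small: only the operations the detector needs exist, and everything runs on
a single CPU.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "as_tensor"]


class Tensor:
    __slots__ = ("data", "grad", "parents", "_bwd", "requires_grad")

    def __init__(self, data, parents=(), bwd=None, requires_grad=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = tuple(parents)
        self._bwd = bwd
        if requires_grad is None:
            requires_grad = any(p.requires_grad for p in self.parents)
        self.requires_grad = requires_grad
        self.grad = None

    # -- introspection ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd ---------------------------------------------------------
    def accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.accumulate(grad)
        for node in reversed(topo):
            if node._bwd is not None and node.grad is not None:
                node._bwd(node.grad)

    # Lightweight operator sugar; the heavy ops live in functional.py.
    def __add__(self, other):
        from . import functional as F

        return F.add(self, other)

    def __mul__(self, other):
        from . import functional as F

        return F.mul(self, other)

    __radd__ = __add__
    __rmul__ = __mul__


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x, requires_grad=False)
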