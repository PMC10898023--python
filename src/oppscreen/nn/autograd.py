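"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and remembers the operation
that produced it as a closure mapping the output gradient to parent
gradients.  ``backward()`` walks the tape in reverse topological order.
Only what the segmentation / classification networks need is
implemented; this is not a general-purpose framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        if _GRAD_ENABLED:
            self._parents = tuple(parents)
            self._backward = backward
        else:
            self._parents = ()
            self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def make(data, parents, backward):
        """Result node: requires grad iff any parent does."""
        req = any(p.requires_grad for p in parents)
        if not (_GRAD_ENABLED and req):
            return Tensor(data)
        return Tensor(data, requires_grad=True, parents=parents, backward=backward)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def accumulate_grad(self, g) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free the closure so intermediate buffers are released
            node._backward = None
            if node._parents:
                node.grad = None

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"
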