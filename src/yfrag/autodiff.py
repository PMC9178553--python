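"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numeric core under the intensity model: a tape-based Tensor
supporting the handful of operations the network needs (broadcast
arithmetic, matrix products, gated-recurrent nonlinearities, softmax,
2-D convolution, gather/concat/stack).  Gradients are accumulated by a
topological backward pass; correctness is established by finite-difference
checks in the test suite.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=float)
            if self.grad.shape != self.data.shape:
                self.grad = np.broadcast_to(self.grad, self.data.shape).copy()
        else:
            self.grad += grad

    def backward(self) -> None:
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

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward=backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor(self.data ** exponent, parents=(self,), backward=backward)

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accumulate(
                    _unbroadcast(np.matmul(g, np.swapaxes(other.data, -1, -2)), self.shape)
                )
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(np.matmul(np.swapaxes(self.data, -1, -2), g), other.shape)
                )

        return Tensor(np.matmul(self.data, other.data), parents=(self, other), backward=backward)

    # -- nonlinearities ----------------------------------------------------

    def tanh(self):
        out = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (1 - out ** 2))

        return Tensor(out, parents=(self,), backward=backward)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out * (1 - out))

        return Tensor(out, parents=(self,), backward=backward)

    def relu(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > 0))

        return Tensor(np.maximum(self.data, 0.0), parents=(self,), backward=backward)

    def exp(self):
        out = np.exp(np.clip(self.data, -700, 700))

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out)

        return Tensor(out, parents=(self,), backward=backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out).sum(axis=axis, keepdims=True)
                self._accumulate(out * (g - dot))

        return Tensor(out, parents=(self,), backward=backward)

    # -- reductions & shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.full_like(self.data, 1.0) * g)
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.shape).copy())

        return Tensor(out, parents=(self,), backward=backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor(self.data.reshape(*shape), parents=(self,), backward=backward)

    def swapaxes(self, a: int, b: int):
        def backward(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))

        return Tensor(np.swapaxes(self.data, a, b), parents=(self,), backward=backward)

    def __getitem__(self, index):
        basic = isinstance(index, (int, slice)) or (
            isinstance(index, tuple)
            and all(isinstance(i, (int, slice)) for i in index)
        )

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                if basic:  # slices never alias, so direct assignment is safe
                    full[index] = g
                else:
                    np.add.at(full, index, g)
                self._accumulate(full)

        return Tensor(self.data[index], parents=(self,), backward=backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor(
        np.concatenate(datas, axis=axis), parents=tuple(tensors), backward=backward
    )


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor(
        np.stack([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward=backward,
    )


def conv2d(x: Tensor, kernel: Tensor, bias: Tensor | None = None, padding: int = 1) -> Tensor:
    """Stride-1 2-D convolution: x (B,C,H,W) * kernel (O,C,kh,kw) -> (B,O,H',W')."""
    B, C, H, W = x.shape
    O, C2, kh, kw = kernel.shape
    if C != C2:
        raise ValueError(f"channel mismatch: input {C} vs kernel {C2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Ho, Wo = H + 2 * padding - kh + 1, W + 2 * padding - kw + 1
    # im2col: (B, C*kh*kw, Ho*Wo), one slice per kernel offset
    cols = np.empty((B, C, kh * kw, Ho * Wo))
    for u in range(kh):
        for v in range(kw):
            cols[:, :, u * kw + v, :] = xp[:, :, u : u + Ho, v : v + Wo].reshape(B, C, -1)
    cols = cols.reshape(B, C * kh * kw, Ho * Wo)
    kmat = kernel.data.reshape(O, -1)  # (O, C*kh*kw)
    out = np.matmul(kmat, cols).reshape(B, O, Ho, Wo)
    if bias is not None:
        out = out + bias.data.reshape(1, O, 1, 1)

    def backward(g):
        gmat = g.reshape(B, O, Ho * Wo)
        if kernel.requires_grad:
            dk = np.einsum("boi,bci->oc", gmat, cols).reshape(kernel.shape)
            kernel._accumulate(dk)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.einsum("oc,boi->bci", kmat, gmat).reshape(B, C, kh * kw, Ho, Wo)
            dxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    dxp[:, :, u : u + Ho, v : v + Wo] += dcols[:, :, u * kw + v]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    parents = (x, kernel) if bias is None else (x, kernel, bias)
    return Tensor(out, parents=parents, backward=backward)
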