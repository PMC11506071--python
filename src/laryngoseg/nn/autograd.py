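"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Only the operations the segmentation network needs are implemented:
elementwise arithmetic, matmul, 2-D convolution (via im2col + BLAS),
nearest-neighbor ×2 upsampling, box filtering (for windowed SSIM), the
activations, and reductions.  Arrays are float32 NCHW throughout.

Gradients are accumulated by topological-order traversal from the output.
``no_grad()`` disables graph construction for cheap inference passes.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = ["Tensor", "no_grad", "concat", "conv2d", "upsample2x", "box_filter"]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Context manager: skip building the backward graph."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------
    @staticmethod
    def _result(data: np.ndarray, parents: Iterable["Tensor"]) -> "Tensor":
        parents = tuple(parents)
        track = _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=track)
        if track:
            out._prev = parents
        return out

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        """Backpropagate from this (typically scalar) tensor."""
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
            for parent in node._prev:
                if parent.requires_grad:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- shape helpers ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor._result(self.data.reshape(shape), (self,))
        if out.requires_grad:
            src_shape = self.data.shape

            def _bwd():
                self._accumulate(out.grad.reshape(src_shape))

            out._backward = _bwd
        return out

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = Tensor._coerce(other)
        out = Tensor._result(self.data + other.data, (self, other))
        if out.requires_grad:

            def _bwd():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad, other.data.shape))

            out._backward = _bwd
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = Tensor._coerce(other)
        out = Tensor._result(self.data * other.data, (self, other))
        if out.requires_grad:

            def _bwd():
                if self.requires_grad:
                    self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

            out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._coerce(other) + (-self)

    def __truediv__(self, other) -> "Tensor":
        return self * Tensor._coerce(other).pow(-1.0)

    def __rtruediv__(self, other) -> "Tensor":
        return Tensor._coerce(other) * self.pow(-1.0)

    def pow(self, exponent: float) -> "Tensor":
        out = Tensor._result(self.data**exponent, (self,))
        if out.requires_grad:

            def _bwd():
                self._accumulate(out.grad * exponent * self.data ** (exponent - 1.0))

            out._backward = _bwd
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor._result(self.data @ other.data, (self, other))
        if out.requires_grad:

            def _bwd():
                if self.requires_grad:
                    self._accumulate(out.grad @ other.data.T)
                if other.requires_grad:
                    other._accumulate(self.data.T @ out.grad)

            out._backward = _bwd
        return out

    __matmul__ = matmul

    # -- activations ------------------------------------------------------
    def relu(self) -> "Tensor":
        out = Tensor._result(np.maximum(self.data, 0.0), (self,))
        if out.requires_grad:

            def _bwd():
                self._accumulate(out.grad * (self.data > 0.0))

            out._backward = _bwd
        return out

    def sigmoid(self) -> "Tensor":
        sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))
        out = Tensor._result(sig, (self,))
        if out.requires_grad:

            def _bwd():
                self._accumulate(out.grad * sig * (1.0 - sig))

            out._backward = _bwd
        return out

    def softplus(self) -> "Tensor":
        # log(1 + e^x), stable for large |x|
        data = np.logaddexp(0.0, self.data)
        out = Tensor._result(data, (self,))
        if out.requires_grad:
            sig = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60.0, 60.0)))

            def _bwd():
                self._accumulate(out.grad * sig)

            out._backward = _bwd
        return out

    def exp(self) -> "Tensor":
        data = np.exp(np.clip(self.data, -60.0, 60.0))
        out = Tensor._result(data, (self,))
        if out.requires_grad:

            def _bwd():
                self._accumulate(out.grad * data)

            out._backward = _bwd
        return out

    def log(self) -> "Tensor":
        out = Tensor._result(np.log(self.data), (self,))
        if out.requires_grad:

            def _bwd():
                self._accumulate(out.grad / self.data)

            out._backward = _bwd
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor._result(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            src_shape = self.data.shape

            def _bwd():
                grad = out.grad
                if axis is not None and not keepdims:
                    grad = np.expand_dims(grad, axis)
                self._accumulate(np.broadcast_to(grad, src_shape))

            out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        count = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(count))

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor._result(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def _bwd():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * out.grad.ndim
                    sl[axis] = slice(lo, hi)
                    t._accumulate(out.grad[tuple(sl)])

        out._backward = _bwd
    return out


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation: x (N,C,H,W), weight (O,C,kh,kw) → (N,O,H',W').

    Evaluated as kh·kw shifted batched matmuls instead of im2col, which
    avoids materializing the 9× patch matrix for 3×3 kernels.
    """
    n, c, h, w = x.data.shape
    o, ci, kh, kw = weight.data.shape
    assert c == ci, f"channel mismatch: input {c}, weight {ci}"
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) if padding else x.data
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1

    def patch(arr, ki, kj):
        return arr[:, :, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride]

    y = np.zeros((n, o, ho * wo), dtype=np.float32)
    for ki in range(kh):
        for kj in range(kw):
            y += np.matmul(weight.data[:, :, ki, kj], patch(xp, ki, kj).reshape(n, c, ho * wo))
    y = y.reshape(n, o, ho, wo)
    if bias is not None:
        y += bias.data[None, :, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor._result(y, parents)
    if out.requires_grad:

        def _bwd():
            g = out.grad.reshape(n, o, ho * wo)
            if weight.requires_grad:
                gw = np.empty_like(weight.data)
                for ki in range(kh):
                    for kj in range(kw):
                        p = patch(xp, ki, kj).reshape(n, c, ho * wo)
                        gw[:, :, ki, kj] = np.matmul(g, p.transpose(0, 2, 1)).sum(axis=0)
                weight._accumulate(gw)
            if bias is not None and bias.requires_grad:
                bias._accumulate(g.sum(axis=(0, 2)))
            if x.requires_grad:
                gxp = np.zeros((n, c, hp, wp), dtype=np.float32)
                for ki in range(kh):
                    for kj in range(kw):
                        patch(gxp, ki, kj)[...] += np.matmul(
                            weight.data[:, :, ki, kj].T, g
                        ).reshape(n, c, ho, wo)
                if padding:
                    gxp = gxp[:, :, padding : hp - padding, padding : wp - padding]
                x._accumulate(gxp)

        out._backward = _bwd
    return out


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbor ×2 spatial upsampling of an NCHW tensor."""
    data = x.data.repeat(2, axis=2).repeat(2, axis=3)
    out = Tensor._result(data, (x,))
    if out.requires_grad:
        n, c, h, w = x.data.shape

        def _bwd():
            x._accumulate(out.grad.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        out._backward = _bwd
    return out


def box_filter(x: Tensor, size: int) -> Tensor:
    """Uniform ``size``×``size`` mean filter (zero padding) over H, W.

    Self-adjoint under zero padding, so the backward pass is the same filter
    applied to the incoming gradient.
    """
    footprint = (1,) * (x.data.ndim - 2) + (size, size)
    data = uniform_filter(x.data, size=footprint, mode="constant", cval=0.0)
    out = Tensor._result(data.astype(np.float32), (x,))
    if out.requires_grad:

        def _bwd():
            x._accumulate(uniform_filter(out.grad, size=footprint, mode="constant", cval=0.0))

        out._backward = _bwd
    return out
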