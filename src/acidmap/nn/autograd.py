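"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the pH-regression network needs —
broadcasting arithmetic, (batched) matrix products, 2-D convolution via
im2col, ReLU, softmax, reshape/transpose/concatenate and reductions — with
a topologically ordered backward pass. float32 throughout; gradients are
accumulated, so one tensor may feed several consumers (residual
connections, co-attention queries).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple["Tensor", ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(grad, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(grad, b.data.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(grad, a=self):
            if a.requires_grad:
                a._accumulate(-grad)

        return Tensor._from_op(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(grad, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(grad * b.data, a.data.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(grad * a.data, b.data.shape))

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(grad, a=self, b=other):
            bd, ad = b.data, a.data
            if a.requires_grad:
                ga = grad @ np.swapaxes(bd, -1, -2) if bd.ndim > 1 else (
                    np.expand_dims(grad, -1) * bd
                )
                a._accumulate(_unbroadcast(ga, ad.shape))
            if b.requires_grad:
                if ad.ndim > 1:
                    gb = np.swapaxes(ad, -1, -2) @ grad
                else:
                    gb = np.outer(ad, grad)
                b._accumulate(_unbroadcast(gb, bd.shape))

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    # -- nonlinearities and shape ops ------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(grad, a=self, mask=mask):
            if a.requires_grad:
                a._accumulate(grad * mask)

        return Tensor._from_op(self.data * mask, (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(grad, a=self, old=old):
            if a.requires_grad:
                a._accumulate(grad.reshape(old))

        return Tensor._from_op(self.data.reshape(*shape), (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(grad, a=self, inv=inv):
            if a.requires_grad:
                a._accumulate(grad.transpose(*inv))

        return Tensor._from_op(self.data.transpose(*axes), (self,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        def backward(grad, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            g = grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._from_op(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self):
        n = self.data.size

        def backward(grad, a=self, n=n):
            if a.requires_grad:
                a._accumulate(np.full(a.data.shape, grad / n, dtype=np.float32))

        return Tensor._from_op(self.data.mean(), (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out = e / e.sum(axis=axis, keepdims=True)

        def backward(grad, a=self, out=out, axis=axis):
            if a.requires_grad:
                dot = (grad * out).sum(axis=axis, keepdims=True)
                a._accumulate(out * (grad - dot))

        return Tensor._from_op(out, (self,), backward)

    @staticmethod
    def concat(tensors, axis: int = -1):
        tensors = [Tensor._wrap(t) for t in tensors]
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(grad, parts=tuple(tensors), splits=splits, axis=axis):
            pieces = np.split(grad, splits, axis=axis)
            for part, piece in zip(parts, pieces):
                if part.requires_grad:
                    part._accumulate(piece)

        return Tensor._from_op(
            np.concatenate([t.data for t in tensors], axis=axis),
            tensors,
            backward,
        )

    # -- tape ------------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        grad = np.asarray(grad, dtype=np.float32)
        self.grad = grad if self.grad is None else self.grad + grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if parent.requires_grad and id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) via im2col matrix products.

    ``x``: (N, C, H, W); ``weight``: (Cout, C, k, k); ``bias``: (Cout,).
    Returns (N, Cout, Hout, Wout).
    """
    n, c, h, w = x.data.shape
    cout, cin, k, _ = weight.data.shape
    if cin != c:
        raise ValueError(f"input has {c} channels, kernel expects {cin}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    hp, wp = xp.shape[2], xp.shape[3]
    hout = (hp - k) // stride + 1
    wout = (wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (N, C, Hout, Wout, k, k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, hout * wout, c * k * k)
    wmat = weight.data.reshape(cout, c * k * k)
    out = cols @ wmat.T + bias.data  # (N, Hout*Wout, Cout)
    out = out.transpose(0, 2, 1).reshape(n, cout, hout, wout)

    def backward(grad, x=x, weight=weight, bias=bias, cols=cols):
        gout = grad.reshape(n, cout, hout * wout).transpose(0, 2, 1)
        if bias.requires_grad:
            bias._accumulate(gout.sum(axis=(0, 1)))
        if weight.requires_grad:
            gw = np.einsum("npo,npk->ok", gout, cols, optimize=True)
            weight._accumulate(gw.reshape(weight.data.shape))
        if x.requires_grad:
            gcols = gout @ wmat  # (N, Hout*Wout, C*k*k)
            gcols = gcols.reshape(n, hout, wout, c, k, k).transpose(0, 3, 4, 5, 1, 2)
            gx = np.zeros((n, c, hp, wp), dtype=np.float32)
            for ki in range(k):
                for kj in range(k):
                    gx[
                        :,
                        :,
                        ki : ki + stride * hout : stride,
                        kj : kj + stride * wout : stride,
                    ] += gcols[:, :, ki, kj]
            if pad:
                gx = gx[:, :, pad:-pad, pad:-pad]
            x._accumulate(gx)

    return Tensor._from_op(out, (x, weight, bias), backward)
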