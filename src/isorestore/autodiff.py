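"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core behind the restoration networks: a small tape-based
autodiff engine supporting exactly the operations the architecture and the
losses need (elementwise arithmetic, reductions, LeakyReLU, and a GEMM-backed
2D convolution), plus an Adam optimizer.  Everything runs in float32; gradients
only flow where ``requires_grad`` is set, which is also how the two training
stages freeze each other's networks.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "_grad_shared")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self._grad_shared = False
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        # copy-on-write: the first accumulation may alias the caller's buffer
        if self.grad is None:
            self.grad = grad if grad.dtype == DTYPE else grad.astype(DTYPE)
            self._grad_shared = True
        elif self._grad_shared:
            self.grad = self.grad + grad
            self._grad_shared = False
        else:
            self.grad += grad

    # -- graph traversal ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, _prev=(self, other))
        na = self.requires_grad or bool(self._prev)
        nb = other.requires_grad or bool(other._prev)

        def _bw(g):
            if na:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if nb:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, _prev=(self, other))
        na = self.requires_grad or bool(self._prev)
        nb = other.requires_grad or bool(other._prev)

        def _bw(g):
            if na:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if nb:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, _prev=(self, other))
        na = self.requires_grad or bool(self._prev)
        nb = other.requires_grad or bool(other._prev)

        def _bw(g):
            if na:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if nb:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, _prev=(self,))

        def _bw(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        out._backward = _bw
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), _prev=(self,))

        def _bw(g):
            self._accumulate(g * 0.5 / out.data)

        out._backward = _bw
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # -- nonlinearity ---------------------------------------------------------
    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, slope * self.data), _prev=(self,))

        def _bw(g):
            self._accumulate(np.where(mask, g, slope * g))

        out._backward = _bw
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2D cross-correlation of an (N, C, H, W) batch with (F, C, kh, kw) filters.

    Zero padding, square stride.  Forward and backward are GEMM-backed
    (im2col / col2im), which is what makes CPU training practical.
    """
    n, c, h, wd = x.data.shape
    f, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, filters {c2}")
    s = int(stride)
    if pad:
        xp = np.zeros((n, c, h + 2 * pad, wd + 2 * pad), dtype=DTYPE)
        xp[:, :, pad : pad + h, pad : pad + wd] = x.data
    else:
        xp = x.data
    ho = (xp.shape[2] - kh) // s + 1
    wo = (xp.shape[3] - kw) // s + 1
    # im2col via kh*kw strided slice copies; GEMM is batched over n
    col = np.empty((n, c, kh, kw, ho, wo), dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            col[:, :, i, j] = xp[:, :, i : i + s * ho : s, j : j + s * wo : s]
    colmat = col.reshape(n, c * kh * kw, ho * wo)
    wmat = w.data.reshape(f, c * kh * kw)
    out_data = np.matmul(wmat, colmat).reshape(n, f, ho, wo)
    if b is not None:
        out_data += b.data[:, None, None]
    out = Tensor(out_data, _prev=(x, w) if b is None else (x, w, b))

    need_x = x.requires_grad or bool(x._prev)
    need_w = w.requires_grad or bool(w._prev)
    need_b = b is not None and (b.requires_grad or bool(b._prev))

    def _bw(g):
        dout = g.reshape(n, f, ho * wo)
        if need_w:
            w._accumulate(
                np.matmul(dout, colmat.transpose(0, 2, 1)).sum(axis=0).reshape(
                    w.data.shape
                )
            )
        if need_b:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if need_x:
            dcol = np.matmul(wmat.T, dout).reshape(n, c, kh, kw, ho, wo)
            dxp = np.zeros(xp.shape, dtype=DTYPE)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcol[
                        :, :, i, j
                    ]
            x._accumulate(dxp[:, :, pad : pad + h, pad : pad + wd] if pad else dxp)

    out._backward = _bw
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-4,
                 betas: Sequence[float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.step_count = 0  # number of calls to step(); used by schedule audits

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        self.step_count += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
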