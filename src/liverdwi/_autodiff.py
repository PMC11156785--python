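"""Compact reverse-mode automatic differentiation over numpy arrays.

Provides exactly the operator set the correction network and its composite
loss need: broadcasting arithmetic, elementwise nonlinearities, reductions,
matrix multiplication, 2-D convolution (stride 1, zero padding, implemented as
an im2col matrix product), 2x2 max pooling, nearest-neighbour 2x upsampling
and channel concatenation.  Gradients flow through a dynamically built tape;
``Tensor.backward()`` runs a topological sweep.

Dtypes are preserved: the network trains in float32 for speed; gradient-check
tests run the same code in float64.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "conv2d", "maxpool2", "upsample2", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node of the autodiff tape."""

    __slots__ = ("data", "grad", "_backward", "_prev")

    def __init__(self, data, _prev: tuple = ()):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._prev = _prev

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    def _coerce(self, other) -> "Tensor":
        """Wrap a constant operand, keeping this tensor's dtype."""
        if isinstance(other, Tensor):
            return other
        return Tensor(np.asarray(other, dtype=self.data.dtype))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _acc(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, (self, other))

        def back():
            self._acc(out.grad)
            other._acc(out.grad)

        out._backward = back
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda: self._acc(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, (self, other))

        def back():
            self._acc(out.grad * other.data)
            other._acc(out.grad * self.data)

        out._backward = back
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data / other.data, (self, other))

        def back():
            self._acc(out.grad / other.data)
            other._acc(-out.grad * self.data / (other.data * other.data))

        out._backward = back
        return out

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, (self,))

        def back():
            self._acc(out.grad * exponent * self.data ** (exponent - 1))

        out._backward = back
        return out

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)
        out = Tensor(self.data @ other.data, (self, other))

        def back():
            self._acc(out.grad @ other.data.T)
            other._acc(self.data.T @ out.grad)

        out._backward = back
        return out

    # -- elementwise ----------------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0), (self,))
        out._backward = lambda: self._acc(out.grad * (self.data > 0))
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), (self,))
        out._backward = lambda: self._acc(out.grad * np.sign(self.data))
        return out

    def sqrt(self):
        out = Tensor(np.sqrt(self.data), (self,))
        out._backward = lambda: self._acc(out.grad * 0.5 / out.data)
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), (self,))
        out._backward = lambda: self._acc(out.grad * out.data)
        return out

    def softplus(self, beta: float = 1.0):
        """Numerically stable ``log(1 + exp(beta x)) / beta``."""
        z = self.data * beta
        val = np.where(z > 30, z, np.log1p(np.exp(np.minimum(z, 30)))) / beta
        out = Tensor(val.astype(self.data.dtype, copy=False), (self,))

        def back():
            sig = 1.0 / (1.0 + np.exp(np.clip(-z, -60, 60)))
            self._acc(out.grad * sig)

        out._backward = back
        return out

    # -- reductions -----------------------------------------------------------
    def sum(self):
        out = Tensor(np.asarray(self.data.sum()), (self,))
        out._backward = lambda: self._acc(
            np.broadcast_to(out.grad, self.data.shape)
        )
        return out

    def mean(self):
        return self.sum() * (1.0 / self.data.size)

    def masked_mean(self, mask: np.ndarray):
        """Mean over a fixed boolean mask (mask is a constant, not a node)."""
        mask = np.asarray(mask, dtype=self.data.dtype)
        return (self * mask).sum() * (1.0 / float(mask.sum()))

    # -- autodiff driver ------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()
        # break the closure reference cycles so the tape frees by refcount
        for node in topo:
            node._backward = None
            node._prev = ()


# ---------------------------------------------------------------------------
# structured ops


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(B, C, H, W) zero-padded to same size -> (B*H*W, C*kh*kw)."""
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # B,C,H,W,kh,kw
    b, c, h, w = x.shape
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        b * h * w, c * kh * kw
    )


def _conv_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Raw same-size stride-1 correlation, (B,C,H,W) x (F,C,kh,kw) -> (B,F,H,W)."""
    b, c, h, wd = x.shape
    f, _, kh, kw = w.shape
    cols = _im2col(x, kh, kw)
    out = cols @ w.reshape(f, -1).T
    return out.reshape(b, h, wd, f).transpose(0, 3, 1, 2)


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-size stride-1 2-D convolution with bias.

    ``x``: (B, C, H, W); ``w``: (F, C, kh, kw) with odd kh, kw; ``b``: (F,).
    """
    bs, c, h, wd = x.data.shape
    f, cin, kh, kw = w.data.shape
    if cin != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cin}")
    cols = _im2col(x.data, kh, kw)
    out_mat = cols @ w.data.reshape(f, -1).T + b.data
    out = Tensor(
        out_mat.reshape(bs, h, wd, f).transpose(0, 3, 1, 2), (x, w, b)
    )

    def back():
        g = out.grad  # (B,F,H,W)
        g_mat = g.transpose(0, 2, 3, 1).reshape(-1, f)
        w._acc((g_mat.T @ cols).reshape(w.data.shape))
        b._acc(g_mat.sum(axis=0))
        # dX: full correlation of grad with spatially flipped, transposed kernel
        w_flip = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C,F,kh,kw)
        x._acc(_conv_raw(g, w_flip))

    out._backward = back
    return out


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; H and W must be even."""
    b, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {h}x{w}")
    blocks = x.data.reshape(b, c, h // 2, 2, w // 2, 2)
    out_data = blocks.max(axis=(3, 5))
    out = Tensor(out_data, (x,))

    def back():
        # (b, c, h2, 2, w2, 2) -> (b, c, h2, w2, 4), one group per pooling block
        flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
        winner = flat == out_data[..., None]
        # break ties toward the first maximum within each 2x2 block
        idx = winner.argmax(axis=4)
        g4 = np.zeros_like(flat)
        np.put_along_axis(g4, idx[..., None], 1.0, axis=4)
        g4 = g4 * out.grad[..., None]
        g = (
            g4.reshape(b, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, h, w)
        )
        x._acc(g)

    out._backward = back
    return out


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out = Tensor(x.data.repeat(2, axis=2).repeat(2, axis=3), (x,))

    def back():
        b, c, h, w = x.data.shape
        g = out.grad.reshape(b, c, h, 2, w, 2).sum(axis=(3, 5))
        x._acc(g)

    out._backward = back
    return out


def concat(a: Tensor, b: Tensor, axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([a.data, b.data], axis=axis), (a, b))
    na = a.data.shape[axis]

    def back():
        ga, gb = np.split(out.grad, [na], axis=axis)
        a._acc(ga)
        b._acc(gb)

    out._backward = back
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
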