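"""Minimal reverse-mode automatic differentiation over numpy arrays.

The multilevel assignment network and the contrastive patch encoder are
small enough that a compact tape-based engine covers every operation they
need: dense/sparse matrix products, elementwise arithmetic with
broadcasting, stable softmax / log-softmax, straight-through hard-max row
masking, and a strided 2-D convolution.  Arrays are kept in float64 so that
seeded runs are bit-reproducible across platforms.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as _sp

__all__ = ["Tensor", "Adam", "spmm", "conv2d", "concat", "relu", "elu",
           "row_softmax", "log_row_softmax", "hard_max_rows", "dropout"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64, copy=True)
        else:
            self.grad += grad

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- arithmetic ------------------------------------------------------
    @staticmethod
    def _wrap(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accumulate(-g)
        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(
                    -g * self.data / (other.data ** 2), other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)

        return Tensor._result(out_data, (self, other), backward)

    def pow(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._result(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._result(out_data, (self,), backward)

    def log(self, eps: float = 0.0):
        out_data = np.log(self.data + eps)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / (self.data + eps))

        return Tensor._result(out_data, (self,), backward)

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(g, self.data.shape))

        return Tensor._result(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        return Tensor._result(out_data, (self,), backward)

    @property
    def T(self):
        out_data = self.data.T

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.T)

        return Tensor._result(out_data, (self,), backward)

    # -- autodiff --------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def item(self) -> float:
        return float(self.data)


# -- free functions -------------------------------------------------------

def concat(tensors, axis=0):
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return Tensor._result(out_data, tuple(tensors), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor._result(out_data, (x,), backward)


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    neg = x.data <= 0
    expm = alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0)
    out_data = np.where(neg, expm, x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * np.where(neg, expm + alpha, 1.0))

    return Tensor._result(out_data, (x,), backward)


def row_softmax(x: Tensor) -> Tensor:
    """Numerically stable softmax along the last axis."""
    z = x.data - x.data.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * p).sum(axis=-1, keepdims=True)
            x._accumulate(p * (g - dot))

    return Tensor._result(p, (x,), backward)


def log_row_softmax(x: Tensor) -> Tensor:
    z = x.data - x.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    out_data = z - lse
    p = np.exp(out_data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g - p * g.sum(axis=-1, keepdims=True))

    return Tensor._result(out_data, (x,), backward)


def hard_max_rows(s: Tensor) -> Tensor:
    """Per row keep only the maximal entry (ties: lowest index).

    Forward is the hard selection; backward uses the straight-through
    convention and passes gradients as if the masking were the identity,
    so the soft assignment keeps receiving a learning signal.
    """
    idx = np.argmax(s.data, axis=-1)
    mask = np.zeros_like(s.data)
    np.put_along_axis(mask, idx[..., None], 1.0, axis=-1)
    out_data = s.data * mask

    def backward(g):
        if s.requires_grad:
            s._accumulate(g)

    return Tensor._result(out_data, (s,), backward)


def spmm(a, x: Tensor) -> Tensor:
    """Sparse constant matrix times dense tensor: ``a @ x``."""
    a = _sp.csr_matrix(a)
    out_data = a @ x.data

    def backward(g):
        if x.requires_grad:
            x._accumulate(a.T @ g)

    return Tensor._result(out_data, (x,), backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator,
            training: bool = True) -> Tensor:
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p) / (1.0 - p)
    return x * Tensor(keep)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    b, h, w, c = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    sb, sh, sw, sc = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, shape=(b, ho, wo, kh, kw, c),
        strides=(sb, sh * stride, sw * stride, sh, sw, sc))
    return cols.reshape(b, ho, wo, kh * kw * c)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, stride: int = 1) -> Tensor:
    """Valid-mode 2-D convolution, NHWC layout; weight (kh, kw, cin, cout)."""
    kh, kw, cin, cout = weight.data.shape
    cols = _im2col(x.data, kh, kw, stride)  # (b, ho, wo, kh*kw*cin)
    wmat = weight.data.reshape(kh * kw * cin, cout)
    out_data = cols @ wmat + bias.data

    def backward(g):
        b, ho, wo, _ = g.shape
        gmat = g.reshape(-1, cout)
        if weight.requires_grad:
            weight._accumulate(
                (cols.reshape(-1, kh * kw * cin).T @ gmat).reshape(weight.data.shape))
        if bias.requires_grad:
            bias._accumulate(gmat.sum(axis=0))
        if x.requires_grad:
            gcols = (gmat @ wmat.T).reshape(b, ho, wo, kh, kw, cin)
            gx = np.zeros_like(x.data)
            for i in range(kh):
                for j in range(kw):
                    gx[:, i:i + ho * stride:stride,
                       j:j + wo * stride:stride, :] += gcols[:, :, :, i, j, :]
            x._accumulate(gx)

    return Tensor._result(out_data, (x, weight, bias), backward)


class Adam:
    """Adam optimizer over a list of ``Tensor`` parameters."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = [p for p in params if p.requires_grad]
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
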