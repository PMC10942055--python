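"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the capsule network needs: broadcasting
arithmetic, reductions, reshapes/concatenation, batched matmul, padding and
strided patch extraction (the primitive behind convolution), plus the usual
pointwise nonlinearities.  Everything is float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concatenate", "matmul", "im2col", "pad2d", "softmax"]


def _as_f32(x):
    a = np.asarray(x)
    if a.dtype != np.float32:
        a = a.astype(np.float32)
    return a


def _unbroadcast(g, shape):
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


class Tensor:
    """A numpy array plus the tape entry needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False):
        self.data = _as_f32(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _accum(t, g):
        if not t.requires_grad:
            return
        if t.grad is None:
            t.grad = g.astype(np.float32, copy=True)
        else:
            t.grad += g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = _as_f32(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads/graph references eagerly
                if node is not self:
                    node.grad = None
                node._backward = None
                node._parents = ()

    # -- basic info --------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self):
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data + other.data

        def backward(g, a=self, b=other):
            Tensor._accum(a, _unbroadcast(g, a.data.shape))
            Tensor._accum(b, _unbroadcast(g, b.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            Tensor._accum(a, -g)

        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data * other.data

        def backward(g, a=self, b=other):
            Tensor._accum(a, _unbroadcast(g * b.data, a.data.shape))
            Tensor._accum(b, _unbroadcast(g * a.data, b.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other)
        out_data = self.data / other.data

        def backward(g, a=self, b=other):
            Tensor._accum(a, _unbroadcast(g / b.data, a.data.shape))
            Tensor._accum(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._coerce(other) / self

    def __pow__(self, exponent):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def backward(g, a=self, e=exponent):
            Tensor._accum(a, g * e * a.data ** (e - 1))

        return Tensor._result(out_data, (self,), backward)

    # -- pointwise ---------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, o=out_data):
            Tensor._accum(a, g * o)

        return Tensor._result(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g, a=self, o=out_data):
            Tensor._accum(a, g * 0.5 / o)

        return Tensor._result(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g, a=self, m=mask):
            Tensor._accum(a, g * m)

        return Tensor._result(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self, o=out_data):
            Tensor._accum(a, g * o * (1.0 - o))

        return Tensor._result(out_data, (self,), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, ax=axis, kd=keepdims):
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            Tensor._accum(a, np.broadcast_to(g, a.data.shape).astype(np.float32))

        return Tensor._result(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward(g, a=self):
            Tensor._accum(a, g.reshape(a.data.shape))

        return Tensor._result(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g, a=self, inv=tuple(inv)):
            Tensor._accum(a, g.transpose(inv))

        return Tensor._result(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g, a=self, idx=idx):
            full = np.zeros_like(a.data)
            full[idx] = g
            Tensor._accum(a, full)

        return Tensor._result(out_data, (self,), backward)

    def __matmul__(self, other):
        return matmul(self, other)


def matmul(a, b):
    """Batched matrix multiply with numpy broadcasting over leading axes."""
    a = Tensor._coerce(a)
    b = Tensor._coerce(b)
    out_data = a.data @ b.data

    def backward(g, a=a, b=b):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        Tensor._accum(a, _unbroadcast(ga, a.data.shape))
        Tensor._accum(b, _unbroadcast(gb, b.data.shape))

    return Tensor._result(out_data, (a, b), backward)


def concatenate(tensors, axis=-1):
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, ts=tuple(tensors), ax=axis, sp=tuple(splits)):
        for t, piece in zip(ts, np.split(g, sp, axis=ax)):
            Tensor._accum(t, piece)

    return Tensor._result(out_data, tensors, backward)


def pad2d(x, pad_h, pad_w):
    """Zero-pad the two spatial axes of an NHWC tensor."""
    x = Tensor._coerce(x)
    out_data = np.pad(x.data, ((0, 0), (pad_h, pad_h), (pad_w, pad_w), (0, 0)))

    def backward(g, a=x, ph=pad_h, pw=pad_w):
        H, W = a.data.shape[1:3]
        Tensor._accum(a, g[:, ph:ph + H, pw:pw + W, :])

    return Tensor._result(out_data, (x,), backward)


def im2col(x, kernel, stride):
    """Extract sliding (kh, kw) patches from an NHWC tensor.

    Returns a tensor of shape (N, OH, OW, C*kh*kw) whose last axis is laid
    out channel-major: index = c*kh*kw + i*kw + j.
    """
    x = Tensor._coerce(x)
    kh, kw = kernel
    sh, sw = stride
    N, H, W, C = x.data.shape
    if kh > H or kw > W:
        raise ValueError(f"kernel ({kh}x{kw}) larger than input ({H}x{W})")
    win = sliding_window_view(x.data, (kh, kw), axis=(1, 2))[:, ::sh, ::sw]
    OH, OW = win.shape[1:3]
    out_data = np.ascontiguousarray(win).reshape(N, OH, OW, C * kh * kw)

    def backward(g, a=x, kh=kh, kw=kw, sh=sh, sw=sw, OH=OH, OW=OW, C=C):
        g = g.reshape(g.shape[0], OH, OW, C, kh, kw)
        dx = np.zeros_like(a.data)
        for i in range(kh):
            for j in range(kw):
                dx[:, i:i + OH * sh:sh, j:j + OW * sw:sw, :] += g[:, :, :, :, i, j]
        Tensor._accum(a, dx)

    return Tensor._result(out_data, (x,), backward)


def softmax(x, axis=-1):
    """Numerically stabilized softmax built from primitive ops."""
    x = Tensor._coerce(x)
    shifted = x - x.data.max(axis=axis, keepdims=True)  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)
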