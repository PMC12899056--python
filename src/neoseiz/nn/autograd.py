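"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations needed by the seizure-detection network:
broadcast arithmetic, matmul, pointwise nonlinearities, reductions, shape
manipulation, 2-D convolution/pooling, dropout and gradient reversal.
Gradients are accumulated on leaf tensors with ``requires_grad=True``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "concatenate",
    "stack",
    "conv2d",
    "max_pool2d",
    "adaptive_avg_pool2d",
    "dropout",
    "grad_reverse",
    "softmax",
    "log_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing broadcast dimensions."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other))

    def _wrap_like(self, other) -> "Tensor":
        """Wrap ``other``, casting 0-d scalars to this tensor's float dtype so
        Python-float constants do not upcast float32 graphs to float64."""
        if isinstance(other, Tensor):
            return other
        arr = np.asarray(other)
        if (arr.ndim == 0 and np.issubdtype(self.data.dtype, np.floating)
                and arr.dtype != self.data.dtype):
            arr = arr.astype(self.data.dtype)
        return Tensor(arr)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype)
        self.grad += g

    # -- graph plumbing -------------------------------------------------------
    def _make(self, data: np.ndarray, parents: tuple["Tensor", ...], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._prev for p in parents):
            out.requires_grad = True
            out._prev = parents
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            pending = [p for p in node._prev if id(p) not in seen]
            if pending:
                stack_.extend(pending)
            else:
                seen.add(id(node))
                topo.append(node)
                stack_.pop()
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node._accumulate(g)
            if node._backward is not None:
                for parent, pg in node._backward(g):
                    if pg is None:
                        continue
                    if parent.requires_grad and parent._backward is None:
                        parent._accumulate(pg)
                    elif parent._prev or parent._backward is not None:
                        if id(parent) in grads:
                            grads[id(parent)] = grads[id(parent)] + pg
                        else:
                            grads[id(parent)] = pg

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap_like(other)
        out_data = self.data + other.data

        def bwd(g):
            return ((self, _unbroadcast(g, self.data.shape)),
                    (other, _unbroadcast(g, other.data.shape)))

        return self._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            return ((self, -g),)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._wrap_like(other))

    def __rsub__(self, other):
        return self._wrap_like(other) + (-self)

    def __mul__(self, other):
        other = self._wrap_like(other)
        out_data = self.data * other.data

        def bwd(g):
            return ((self, _unbroadcast(g * other.data, self.data.shape)),
                    (other, _unbroadcast(g * self.data, other.data.shape)))

        return self._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap_like(other)
        out_data = self.data / other.data

        def bwd(g):
            return ((self, _unbroadcast(g / other.data, self.data.shape)),
                    (other, _unbroadcast(-g * self.data / other.data ** 2,
                                         other.data.shape)))

        return self._make(out_data, (self, other), bwd)

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bwd(g):
            return ((self, g * p * self.data ** (p - 1)),)

        return self._make(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data
        a, b = self.data, other.data

        def bwd(g):
            if a.ndim == 1 or b.ndim == 1:
                raise NotImplementedError("matmul backward requires >=2-D operands")
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return ((self, _unbroadcast(ga, a.shape)),
                    (other, _unbroadcast(gb, b.shape)))

        return self._make(out_data, (self, other), bwd)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def bwd(g):
            return ((self, g * mask),)

        return self._make(out_data, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g):
            return ((self, g * (1.0 - out_data ** 2)),)

        return self._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            return ((self, g * out_data * (1.0 - out_data)),)

        return self._make(out_data, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g):
            return ((self, g * out_data),)

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g):
            return ((self, g / self.data),)

        return self._make(np.log(self.data), (self,), bwd)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            if axis is None:
                return ((self, np.broadcast_to(g, self.data.shape).copy()),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            return ((self, np.broadcast_to(gg, self.data.shape).copy()),)

        return self._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ----------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape

        def bwd(g):
            return ((self, g.reshape(old)),)

        return self._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def bwd(g):
            return ((self, g.transpose(inv)),)

        return self._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, key):
        # basic indexing only (ints/slices) — indices never repeat
        out_data = self.data[key]

        def bwd(g):
            full = np.zeros_like(self.data, dtype=g.dtype)
            full[key] += g
            return ((self, full),)

        return self._make(out_data, (self,), bwd)


# -- free functions -----------------------------------------------------------

def concatenate(tensors, axis=0):
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        parts = np.split(g, splits, axis=axis)
        return tuple(zip(tensors, parts))

    out = Tensor(out_data)
    if any(t.requires_grad or t._prev for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = bwd
    return out


def stack(tensors, axis=0):
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bwd(g):
        parts = np.split(g, len(tensors), axis=axis)
        return tuple((t, p.squeeze(axis)) for t, p in zip(tensors, parts))

    out = Tensor(out_data)
    if any(t.requires_grad or t._prev for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = bwd
    return out


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    # xp: (N, C, Hp, Wp) -> (N, OH, OW, C, kh, kw)
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::sh, ::sw].transpose(0, 2, 3, 1, 4, 5)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation. x: (N,C,H,W), w: (O,C,kh,kw), b: (O,)."""
    xd, wd = x.data, w.data
    n, c, h, wdt = xd.shape
    o, _, kh, kw = wd.shape
    sh = sw = stride
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    cols6 = _im2col(xp, kh, kw, sh, sw)            # (N, OH, OW, C, kh, kw)
    oh, ow = cols6.shape[1], cols6.shape[2]
    cols = np.ascontiguousarray(cols6).reshape(n * oh * ow, c * kh * kw)
    wmat = wd.reshape(o, -1)
    out = cols @ wmat.T
    if b is not None:
        out = out + b.data
    out_data = out.reshape(n, oh, ow, o).transpose(0, 3, 1, 2)

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * oh * ow, o)
        gw = (gmat.T @ cols).reshape(wd.shape)
        gb = g.sum(axis=(0, 2, 3)) if b is not None else None
        dcols = (gmat @ wmat).reshape(n, oh, ow, c, kh, kw)
        dcols = np.ascontiguousarray(dcols.transpose(0, 3, 1, 2, 4, 5))  # (N,C,OH,OW,kh,kw)
        dxp = np.zeros_like(xp, dtype=g.dtype)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + oh * sh:sh, j:j + ow * sw:sw] += dcols[:, :, :, :, i, j]
        if padding:
            dx = dxp[:, :, padding:padding + h, padding:padding + wdt]
        else:
            dx = dxp
        res = [(x, dx), (w, gw)]
        if b is not None:
            res.append((b, gb))
        return tuple(res)

    parents = (x, w) + ((b,) if b is not None else ())
    return x._make(out_data, parents, bwd)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    xd = x.data
    n, c, h, w = xd.shape
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf)
    win = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    oh, ow = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, oh, ow, kernel * kernel)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        dxp = np.zeros_like(xp, dtype=g.dtype)
        ni, ci, ohi, owi = np.indices((n, c, oh, ow))
        hh = ohi * stride + idx // kernel
        ww = owi * stride + idx % kernel
        np.add.at(dxp, (ni, ci, hh, ww), g)
        if padding:
            return ((x, dxp[:, :, padding:padding + h, padding:padding + w]),)
        return ((x, dxp),)

    return x._make(out_data, (x,), bwd)


def adaptive_avg_pool2d(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """PyTorch-style adaptive average pooling with floor/ceil bin edges."""
    xd = x.data
    n, c, h, w = xd.shape
    oh, ow = out_hw
    hs = [(int(np.floor(i * h / oh)), int(np.ceil((i + 1) * h / oh))) for i in range(oh)]
    ws = [(int(np.floor(j * w / ow)), int(np.ceil((j + 1) * w / ow))) for j in range(ow)]
    out_data = np.empty((n, c, oh, ow), dtype=xd.dtype)
    for i, (h0, h1) in enumerate(hs):
        for j, (w0, w1) in enumerate(ws):
            out_data[:, :, i, j] = xd[:, :, h0:h1, w0:w1].mean(axis=(2, 3))

    def bwd(g):
        dx = np.zeros_like(xd, dtype=g.dtype)
        for i, (h0, h1) in enumerate(hs):
            for j, (w0, w1) in enumerate(ws):
                cnt = (h1 - h0) * (w1 - w0)
                dx[:, :, h0:h1, w0:w1] += g[:, :, i:i + 1, j:j + 1] / cnt
        return ((x, dx),)

    return x._make(out_data, (x,), bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return x * Tensor(mask)


def grad_reverse(x: Tensor, lam: float) -> Tensor:
    """Identity in the forward pass; scales gradients by ``-lam`` in the backward pass."""
    if lam < 0:
        raise ValueError("gradient-reversal coefficient must be non-negative")

    def bwd(g):
        return ((x, -lam * g),)

    return x._make(x.data.copy(), (x,), bwd)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant: exact for softmax
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()
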