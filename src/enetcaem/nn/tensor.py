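"""Reverse-mode automatic differentiation over numpy arrays.

A small define-by-run engine: every operation builds a node holding its
inputs and a closure that accumulates gradients into them. ``backward()``
runs a topological sort from the output and applies the closures in
reverse order. All arrays are float32; broadcasting follows numpy rules,
with gradients summed back over broadcast axes.

Only the operations the network needs are provided: elementwise
arithmetic, matmul, reductions (sum / mean / max), shape ops, sigmoid /
relu / exp / log, grouped dilated 2-D convolution, 1-D convolution over a
channel sequence, and average / max pooling.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "conv1d",
    "avg_pool2d",
    "max_pool2d",
    "log_softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 stretched by broadcasting
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = _prev

    # ---- bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs exceed recursion limits
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
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float32).copy()
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- elementwise arithmetic --------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        out._backward = _bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data**p, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad or self._prev:
                self._accumulate(g @ other.data.T)
            if other.requires_grad or other._prev:
                other._accumulate(self.data.T @ g)

        out._backward = _bw
        return out

    # ---- nonlinearities ----------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * out.data * (1.0 - out.data))
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * (self.data > 0))
        return out

    def swish(self):
        """x * sigmoid(x)."""
        return self * self.sigmoid()

    # ---- reductions --------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))
        shape = self.data.shape

        def _bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, shape).astype(np.float32))
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, shape).astype(np.float32))

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to the first argmax."""
        out_data = self.data.max(axis=axis, keepdims=True)
        mask = self.data == out_data
        # route gradient only to the first maximal entry per slice
        first = np.cumsum(mask, axis=axis) == 1
        mask = mask & first
        out = Tensor(out_data if keepdims else np.squeeze(out_data, axis=axis), _prev=(self,))

        def _bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(mask * g)

        out._backward = _bw
        return out

    # ---- shape ops ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), _prev=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, axes):
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def broadcast_to(self, shape):
        out = Tensor(np.broadcast_to(self.data, shape).copy(), _prev=(self,))
        out._backward = lambda g: self._accumulate(_unbroadcast(g, self.data.shape))
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list, axis: int) -> Tensor:
    """Concatenate along ``axis``, splitting the gradient back."""
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._accumulate(g[tuple(idx)])

    out._backward = _bw
    return out


# ---- convolution -----------------------------------------------------


def _conv_out_size(n: int, k: int, s: int, p: int, d: int) -> int:
    return (n + 2 * p - d * (k - 1) - 1) // s + 1


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
    groups: int = 1,
) -> Tensor:
    """Grouped dilated 2-D cross-correlation (the CNN convention).

    x: (B, Cin, H, W); weight: (Cout, Cin/groups, kh, kw); bias: (Cout,).
    Forward uses an im2col view + einsum; the input gradient is a
    per-kernel-tap scatter into the padded input (vectorised over space).
    """
    B, Cin, H, W = x.data.shape
    Cout, Cg, kh, kw = weight.data.shape
    if Cin % groups or Cout % groups or Cg != Cin // groups:
        raise ValueError("channel counts incompatible with groups")
    s, p, d = int(stride), int(padding), int(dilation)
    Ho = _conv_out_size(H, kh, s, p, d)
    Wo = _conv_out_size(W, kw, s, p, d)
    if Ho < 1 or Wo < 1:
        raise ValueError("kernel does not fit inside the (padded) input")

    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    eh, ew = d * (kh - 1) + 1, d * (kw - 1) + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (eh, ew), axis=(2, 3))
    win = win[:, :, ::s, ::s, ::d, ::d]  # (B, Cin, Ho, Wo, kh, kw)

    # (g, B*Ho*Wo, Cg*kh*kw) x (g, Cg*kh*kw, Cout/g) -> (g, B*Ho*Wo, Cout/g)
    col = win.reshape(B, groups, Cg, Ho, Wo, kh, kw)
    col = col.transpose(1, 0, 3, 4, 2, 5, 6).reshape(groups, B * Ho * Wo, Cg * kh * kw)
    wcol = weight.data.reshape(groups, Cout // groups, Cg * kh * kw)
    out_data = np.einsum("gnk,gok->gno", col, wcol, optimize=True)
    out_data = (
        out_data.reshape(groups, B, Ho, Wo, Cout // groups)
        .transpose(1, 0, 4, 2, 3)
        .reshape(B, Cout, Ho, Wo)
    )
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, Cout, 1, 1)

    prev = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, _prev=prev)

    def _bw(g):
        go = (
            g.reshape(B, groups, Cout // groups, Ho, Wo)
            .transpose(1, 0, 3, 4, 2)
            .reshape(groups, B * Ho * Wo, Cout // groups)
        )
        if weight.requires_grad or weight._prev:
            gw = np.einsum("gno,gnk->gok", go, col, optimize=True)
            weight._accumulate(gw.reshape(Cout, Cg, kh, kw))
        if bias is not None and (bias.requires_grad or bias._prev):
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._prev:
            gcol = np.einsum("gno,gok->gnk", go, wcol, optimize=True)
            gcol = gcol.reshape(groups, B, Ho, Wo, Cg, kh, kw)
            gcol = gcol.transpose(1, 0, 4, 2, 3, 5, 6).reshape(B, Cin, Ho, Wo, kh, kw)
            gx = np.zeros((B, Cin, H + 2 * p, W + 2 * p), dtype=np.float32)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i * d : i * d + Ho * s : s, j * d : j * d + Wo * s : s] += gcol[
                        :, :, :, :, i, j
                    ]
            if p:
                gx = gx[:, :, p:-p, p:-p]
            x._accumulate(gx)

    out._backward = _bw
    return out


def conv1d(x: Tensor, weight: Tensor, bias: Tensor | None = None, padding: int = 0) -> Tensor:
    """1-D convolution over (B, C, L) via the 2-D kernel with H=1.

    Padding applies along L only (conv2d would pad the dummy H axis too).
    """
    B, C, L = x.data.shape
    Cout, Cin, k = weight.data.shape
    if padding:
        orig = x
        xp = Tensor(np.pad(x.data, ((0, 0), (0, 0), (padding, padding))), _prev=(x,))

        def _bw(g):
            orig._accumulate(g[:, :, padding:-padding])

        xp._backward = _bw
        x, L = xp, L + 2 * padding
    out = conv2d(x.reshape(B, C, 1, L), weight.reshape(Cout, Cin, 1, k), bias=bias)
    return out.reshape(B, Cout, out.data.shape[-1])


# ---- pooling ---------------------------------------------------------


def avg_pool2d(x: Tensor, kernel: int, stride: int | None = None) -> Tensor:
    """Average pooling (no padding); gradient spreads uniformly per window."""
    s = stride or kernel
    B, C, H, W = x.data.shape
    k = kernel
    if k > H or k > W:
        raise ValueError("pooling window larger than input")
    Ho, Wo = (H - k) // s + 1, (W - k) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(x.data, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    out = Tensor(win.mean(axis=(4, 5)), _prev=(x,))

    def _bw(g):
        gx = np.zeros_like(x.data)
        gshare = g / (k * k)
        for i in range(k):
            for j in range(k):
                gx[:, :, i : i + Ho * s : s, j : j + Wo * s : s] += gshare
        x._accumulate(gx)

    out._backward = _bw
    return out


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None) -> Tensor:
    """Max pooling (no padding); gradient routes to the first argmax."""
    s = stride or kernel
    B, C, H, W = x.data.shape
    k = kernel
    if k > H or k > W:
        raise ValueError("pooling window larger than input")
    Ho, Wo = (H - k) // s + 1, (W - k) // s + 1
    win = np.lib.stride_tricks.sliding_window_view(x.data, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    flat = win.reshape(B, C, Ho, Wo, k * k)
    arg = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0], _prev=(x,))

    def _bw(g):
        gx = np.zeros_like(x.data)
        bi, ci, oi, oj = np.indices((B, C, Ho, Wo))
        ii = oi * s + arg // k
        jj = oj * s + arg % k
        np.add.at(gx, (bi, ci, ii, jj), g)
        x._accumulate(gx)

    out._backward = _bw
    return out


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable log-softmax (max shift is a constant)."""
    shift = x - x.data.max(axis=axis, keepdims=True)
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()
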