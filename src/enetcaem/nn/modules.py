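"""Neural-network modules built on the autograd tensor.

Conventions follow the compact-CNN literature: convolutions that feed a
batch-norm layer carry no bias, batch norm uses momentum 0.1 / eps 1e-5,
and Swish means x * sigmoid(x). Every module takes an explicit
``numpy.random.Generator`` at construction so that two builds from the
same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, avg_pool2d, conv1d, conv2d, max_pool2d

__all__ = [
    "Module",
    "Sequential",
    "Conv2d",
    "Conv1d",
    "BatchNorm2d",
    "Linear",
    "Dropout",
    "ReLU",
    "Swish",
    "Identity",
    "GlobalAvgPool",
]

# active MAC trace (list appended to by parametric layers), or None
_MAC_TRACE: list | None = None


def _record_macs(n: int):
    if _MAC_TRACE is not None:
        _MAC_TRACE.append(int(n))


class Module:
    """Base class: parameter registration, train/eval mode, state dicts."""

    def __init__(self):
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._parameters.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # buffers (running stats) are exposed via _buffers on the subclasses
    def named_buffers(self, prefix: str = ""):
        for name, b in getattr(self, "_buffers", {}).items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def state_dict(self) -> dict:
        out = {k: p.data.copy() for k, p in self.named_parameters()}
        out.update({k: b.copy() for k, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for k, v in state.items():
            if k in own:
                if own[k].data.shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}")
                own[k].data[...] = v
            elif k in bufs:
                bufs[k][...] = v
            else:
                raise KeyError(f"unexpected key {k}")

    def __call__(self, x):
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _param(rng: np.random.Generator, shape, std: float) -> Tensor:
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32), requires_grad=True)


class Conv2d(Module):
    """Grouped dilated 2-D convolution with He-normal init."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        groups: int = 1,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = in_channels // groups * k * k
        self.weight = _param(rng, (out_channels, in_channels // groups, k, k), np.sqrt(2.0 / fan_in))
        self.bias = (
            Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True) if bias else None
        )
        self.stride, self.padding, self.dilation, self.groups = stride, padding, dilation, groups
        self.in_channels, self.out_channels, self.kernel_size = in_channels, out_channels, k

    def forward(self, x: Tensor) -> Tensor:
        out = conv2d(
            x,
            self.weight,
            bias=self.bias,
            stride=self.stride,
            padding=self.padding,
            dilation=self.dilation,
            groups=self.groups,
        )
        _record_macs(
            out.data.shape[0]
            * out.data.shape[1]
            * out.data.shape[2]
            * out.data.shape[3]
            * (self.in_channels // self.groups)
            * self.kernel_size
            * self.kernel_size
        )
        return out


class Conv1d(Module):
    """1-D convolution over a channel sequence (B, C, L)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size
        self.weight = _param(rng, (out_channels, in_channels, kernel_size), np.sqrt(2.0 / fan_in))
        self.bias = (
            Tensor(np.zeros(out_channels, dtype=np.float32), requires_grad=True) if bias else None
        )
        self.padding = padding
        self.in_channels, self.out_channels, self.kernel_size = (
            in_channels,
            out_channels,
            kernel_size,
        )

    def forward(self, x: Tensor) -> Tensor:
        out = conv1d(x, self.weight, bias=self.bias, padding=self.padding)
        _record_macs(
            out.data.shape[0]
            * out.data.shape[1]
            * out.data.shape[2]
            * self.in_channels
            * self.kernel_size
        )
        return out


class BatchNorm2d(Module):
    """Batch normalisation over (B, H, W) per channel.

    Training mode normalises with batch statistics and updates running
    estimates; eval mode uses the running estimates. Works on (B, C, 1, 1)
    inputs too (the channel-attention bottlenecks), where it degenerates
    to per-channel batch statistics.
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(num_features, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features, dtype=np.float32), requires_grad=True)
        self.momentum, self.eps = momentum, eps
        object.__setattr__(
            self,
            "_buffers",
            {
                "running_mean": np.zeros(num_features, dtype=np.float32),
                "running_var": np.ones(num_features, dtype=np.float32),
            },
        )

    def forward(self, x: Tensor) -> Tensor:
        C = x.data.shape[1]
        g = self.gamma.reshape(1, C, 1, 1)
        b = self.beta.reshape(1, C, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu.data.reshape(C)
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var.data.reshape(C)
            xhat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = self._buffers["running_mean"].reshape(1, C, 1, 1)
            sd = np.sqrt(self._buffers["running_var"] + self.eps).reshape(1, C, 1, 1)
            xhat = (x - mu) * (1.0 / sd)
        return xhat * g + b


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.weight = _param(rng, (in_features, out_features), np.sqrt(2.0 / in_features))
        self.bias = (
            Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True) if bias else None
        )
        self.in_features, self.out_features = in_features, out_features

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        _record_macs(x.data.shape[0] * self.in_features * self.out_features)
        return out


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Seeded via set_rng()."""

    def __init__(self, p: float = 0.2):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self._rng = np.random.default_rng(0)

    def set_rng(self, rng: np.random.Generator):
        object.__setattr__(self, "_rng", rng)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self._rng.random(x.data.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Swish(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.swish()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class GlobalAvgPool(Module):
    """(B, C, H, W) -> (B, C, 1, 1)."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3), keepdims=True)


class _MacTraceContext:
    """Context manager that collects MAC counts from parametric layers."""

    def __enter__(self):
        global _MAC_TRACE
        self._saved = _MAC_TRACE
        _MAC_TRACE = []
        return _MAC_TRACE

    def __exit__(self, *exc):
        global _MAC_TRACE
        _MAC_TRACE = self._saved
        return False


def mac_trace() -> _MacTraceContext:
    return _MacTraceContext()
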