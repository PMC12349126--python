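"""Module base class and the layer zoo used by the network."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import init
from .autograd import Tensor
from .conv import conv2d, conv_transpose2d
from .functional import add_macs, gelu, relu, sigmoid, silu


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Minimal parameter container with registration by attribute assignment."""

    def __init__(self):
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def forward(self, *args, **kwargs):
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal -----------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._parameters.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    # -- (de)serialisation ----------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for name, p in self._parameters.items():
            out[prefix + name] = p.data
        for name, b in self._buffers.items():
            out[prefix + name] = b
        for name, m in self._modules.items():
            out.update(m.state_dict(prefix + name + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = ""):
        for name, p in self._parameters.items():
            src = state[prefix + name]
            if src.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {prefix + name}: "
                                 f"{src.shape} vs {p.data.shape}")
            p.data = src.astype(p.data.dtype)
        for name in self._buffers:
            self._buffers[name] = state[prefix + name].copy()
            object.__setattr__(self, name, self._buffers[name])
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")

    def to_dtype(self, dtype):
        """Convert parameters and buffers in place (float64 for grad checks)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for m in self.modules():
            for name in m._buffers:
                m._buffers[name] = m._buffers[name].astype(dtype)
                object.__setattr__(m, name, m._buffers[name])
        return self


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


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return relu(x)


class GELU(Module):
    def forward(self, x):
        return gelu(x)


class SiLU(Module):
    def forward(self, x):
        return silu(x)


class Sigmoid(Module):
    def forward(self, x):
        return sigmoid(x)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True):
        super().__init__()
        if in_ch % groups or out_ch % groups:
            raise ValueError("channels must be divisible by groups")
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel_size, self.stride = kernel_size, stride
        self.padding, self.groups = padding, groups
        fan_in = (in_ch // groups) * kernel_size ** 2
        self.weight = Parameter(init.kaiming_normal(
            (out_ch, in_ch // groups, kernel_size, kernel_size), fan_in))
        self.bias = Parameter(init.zeros(out_ch)) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding, groups=self.groups)


class ConvTranspose2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel_size: int = 4,
                 stride: int = 2, padding: int = 1, bias: bool = True):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = Parameter(init.kaiming_normal(
            (in_ch, out_ch, kernel_size, kernel_size), in_ch * kernel_size ** 2))
        self.bias = Parameter(init.zeros(out_ch)) if bias else None

    def forward(self, x):
        return conv_transpose2d(x, self.weight, self.bias,
                                stride=self.stride, padding=self.padding)


class Linear(Module):
    """Affine map over the trailing axis; init follows transformer practice
    (truncated normal, std 0.02)."""

    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.weight = Parameter(init.trunc_normal((in_features, out_features)))
        self.bias = Parameter(init.zeros(out_features)) if bias else None

    def forward(self, x):
        out = x @ self.weight
        add_macs(int(np.prod(x.shape[:-1])) * self.weight.shape[0]
                 * self.weight.shape[1])
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(init.ones(num_features))
        self.bias = Parameter(init.zeros(num_features))
        self.register_buffer("running_mean", init.zeros(num_features))
        self.register_buffer("running_var", init.ones(num_features))

    def forward(self, x):
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"]
                + m * mu.data.reshape(c))
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"]
                + m * var.data.reshape(c))
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(1, c, 1, 1))
            var = Tensor(self._buffers["running_var"].reshape(1, c, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.weight.reshape(1, c, 1, 1) \
            + self.bias.reshape(1, c, 1, 1)


class LayerNorm2d(Module):
    """LayerNorm over the channel axis of NCHW input (per spatial location)."""

    def __init__(self, num_features: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(init.ones(num_features))
        self.bias = Parameter(init.zeros(num_features))

    def forward(self, x):
        c = x.shape[1]
        mu = x.mean(axis=1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=1, keepdims=True)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.weight.reshape(1, c, 1, 1) \
            + self.bias.reshape(1, c, 1, 1)
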