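"""Module system and neural-network layers on top of the autodiff engine."""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from . import tensor as T
from .tensor import Tensor


class Parameter(Tensor):
    """A leaf tensor that an optimizer updates."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)
        # parameters stay trainable even when created inside no_grad()
        self.requires_grad = True


class Module:
    def __init__(self):
        self._parameters: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_parameters", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for n, p in self._parameters.items():
            yield f"{prefix}{n}", p
        for n, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{n}.")

    def parameters(self) -> Iterator[Parameter]:
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for n, b in self._buffers.items():
            yield f"{prefix}{n}", b
        for n, m in self._modules.items():
            yield from m.named_buffers(f"{prefix}{n}.")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        state.update({f"buffer::{n}": b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, value in state.items():
            if name.startswith("buffer::"):
                self._set_buffer_by_path(name[len("buffer::"):], value)
            else:
                if name not in params:
                    raise KeyError(f"unexpected parameter {name!r} in state dict")
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name!r}")
                params[name].data = value.astype(np.float32).copy()

    def _set_buffer_by_path(self, path: str, value: np.ndarray) -> None:
        mod = self
        parts = path.split(".")
        for part in parts[:-1]:
            mod = mod._modules[part]
        mod.register_buffer(parts[-1], value.copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def count_parameters(module: Module) -> int:
    """Number of trainable scalar parameters."""
    return int(sum(p.data.size for p in module.parameters()))


# ---------------------------------------------------------------------

class Identity(Module):
    def forward(self, x):
        return x


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        bound = np.sqrt(6.0 / (in_features + out_features))
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        y = T.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    """3x3/1x1/7x7 convolution with optional weight standardization.

    Weight standardization (zero-mean, unit-variance kernels at forward
    time) mirrors the StdConv layers of the big-transfer ResNetV2 stem;
    it changes no parameter shapes.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True,
                 weight_standardized: bool = False):
        super().__init__()
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, (out_ch, in_ch, kernel, kernel)))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride = stride
        self.padding = padding
        self.weight_standardized = weight_standardized

    def forward(self, x):
        w = self.weight
        if self.weight_standardized:
            mu = T.mean(w, axis=(1, 2, 3), keepdims=True)
            var = T.mean((w - mu) ** 2.0, axis=(1, 2, 3), keepdims=True)
            w = (w - mu) / T.sqrt(var + 1e-5)
        return T.conv2d(x, w, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        if self.training:
            mu = T.mean(x, axis=(0, 2, 3), keepdims=True)
            var = T.mean((x - mu) ** 2.0, axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
            self._buffers["running_mean"] = self.running_mean
            self._buffers["running_var"] = self.running_var
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xn = (x - mu) / T.sqrt(var + self.eps)
        w = T.reshape(self.weight, (1, -1, 1, 1))
        b = T.reshape(self.bias, (1, -1, 1, 1))
        return xn * w + b


class GroupNorm(Module):
    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        super().__init__()
        if num_channels % num_groups:
            raise ValueError("channels must divide evenly into groups")
        self.num_groups = num_groups
        self.weight = Parameter(np.ones(num_channels))
        self.bias = Parameter(np.zeros(num_channels))
        self.eps = eps

    def forward(self, x):
        n, c, h, w = x.shape
        g = self.num_groups
        xg = T.reshape(x, (n, g, c // g, h, w))
        mu = T.mean(xg, axis=(2, 3, 4), keepdims=True)
        var = T.mean((xg - mu) ** 2.0, axis=(2, 3, 4), keepdims=True)
        xn = T.reshape((xg - mu) / T.sqrt(var + self.eps), (n, c, h, w))
        return xn * T.reshape(self.weight, (1, -1, 1, 1)) + T.reshape(self.bias, (1, -1, 1, 1))


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x):
        mu = T.mean(x, axis=-1, keepdims=True)
        var = T.mean((x - mu) ** 2.0, axis=-1, keepdims=True)
        return (x - mu) / T.sqrt(var + self.eps) * self.weight + self.bias


class Dropout(Module):
    def __init__(self, p: float, rng: Optional[np.random.Generator] = None):
        super().__init__()
        self.p = p
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def forward(self, x):
        return T.dropout(x, self.p, self.rng, self.training)


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: Optional[int] = None, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride or kernel, padding

    def forward(self, x):
        return T.max_pool2d(x, self.kernel, self.stride, self.padding)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._modules[str(i)] = layer

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class GELU(Module):
    def forward(self, x):
        return T.gelu(x)
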