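"""Layer abstractions: parameter containers, convolutions, normalization,
linear maps and dropout, in the spirit of the usual ``nn.Module`` pattern.

Modules own a ``training`` flag (propagated by :meth:`Module.train` /
:meth:`Module.eval`) and an optional RNG used for dropout so that whole-model
forward passes are reproducible from a single seed.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv3d",
    "PointwiseConv3d",
    "Linear",
    "BatchNorm3d",
    "LayerNorm",
    "Dropout",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64))
        # trainable regardless of any enclosing no_grad() (lazy construction)
        self.requires_grad = True


class Module:
    def __init__(self):
        self._params: "OrderedDict[str, Parameter]" = OrderedDict()
        self._modules: "OrderedDict[str, Module]" = OrderedDict()
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", OrderedDict())[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for name, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{name}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_buffers():
            state[name] = m.copy()
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for name, value in state.items():
            if name in params:
                params[name].data = np.asarray(value, dtype=params[name].dtype)
            elif name in buffers:
                buffers[name][...] = value
            else:
                raise KeyError(f"unknown parameter {name!r} in state dict")

    def _named_buffers(self, prefix: str = ""):
        for attr in ("running_mean", "running_var"):
            buf = self.__dict__.get(attr)
            if isinstance(buf, np.ndarray):
                yield f"{prefix}{attr}", buf
        for name, m in self._modules.items():
            yield from m._named_buffers(f"{prefix}{name}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv3d(Module):
    """Stride-1 "same" 3D convolution (odd kernel)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.kernel = kernel
        self.weight = Parameter(_kaiming(rng, (c_out, c_in, kernel, kernel, kernel), c_in * kernel**3))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x):
        return F.conv3d(x, self.weight, self.bias)


class PointwiseConv3d(Module):
    """1x1x1 convolution implemented as a channel-wise linear map."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (c_out, c_in), c_in))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x):
        n, c, h, w, d = x.shape
        flat = x.reshape(n, c, h * w * d).transpose(0, 2, 1)  # (N, V, C)
        out = flat @ self.weight.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias
        return out.transpose(0, 2, 1).reshape(n, self.weight.shape[0], h, w, d)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, (d_out, d_in), d_in))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def forward(self, x):
        out = x @ self.weight.transpose(1, 0)
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm3d(Module):
    """Channel-wise batch normalization over (N, H, W, D)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x):
        axes = (0, 2, 3, 4)
        shape = (1, -1, 1, 1, 1)
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class LayerNorm(Module):
    """Normalization over the trailing feature dimension (token layout)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x):
        return F.dropout(x, self.rate, self.rng, self.training)
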