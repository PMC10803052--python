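"""Neural-network modules built on the autodiff tensor.

Feature maps use channel-last layout throughout: (N, H, W, C).
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from .tensor import (Parameter, Tensor, conv3x3, maxpool2x2,
                     upsample_bilinear2)

__all__ = ["Module", "Dense", "Conv3x3", "BatchNorm", "LayerNorm", "Dropout",
           "ConvBlock"]


class Module:
    """Base class with parameter registration and train/eval mode."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        object.__setattr__(self, "training", mode)
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Parameters plus buffers (running statistics) as a flat dict."""
        out = {name: p.data for name, p in self.named_parameters()}
        for name, mod, buf in self._named_buffers():
            out[name] = buf
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=p.data.dtype)
        for name, mod, buf in self._named_buffers():
            buf[...] = state[name]

    def _named_buffers(self, prefix: str = ""):
        for attr in getattr(self, "_buffer_names", ()):
            yield prefix + attr, self, getattr(self, attr)
        for name, mod in self._modules.items():
            yield from mod._named_buffers(prefix + name + ".")


class Dense(Module):
    """Per-position linear projection on the last axis, with bias."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        limit = math.sqrt(6.0 / (cin + cout))
        self.weight = Parameter(rng.uniform(-limit, limit, (cin, cout)).astype(dtype))
        self.bias = Parameter(np.zeros(cout, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        shape = x.shape
        flat = x.reshape(-1, shape[-1]) @ self.weight
        return (flat + self.bias).reshape(*shape[:-1], self.weight.shape[1])


class Conv3x3(Module):
    """3x3 'same' convolution without bias (batch norm follows)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        std = math.sqrt(2.0 / (9 * cin))
        self.weight = Parameter(rng.normal(0.0, std, (3, 3, cin, cout)).astype(dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return conv3x3(x, self.weight)


class BatchNorm(Module):
    """Batch normalization over (N, H, W) per channel, with affine terms."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.momentum = momentum
        self.eps = eps
        object.__setattr__(self, "running_mean", np.zeros(channels, dtype=dtype))
        object.__setattr__(self, "running_var", np.ones(channels, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 1, 2), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 1, 2), keepdims=True)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var[...] = (1 - m) * self.running_var + m * var.data.ravel()
            inv = (var + self.eps) ** -0.5
            return xc * inv * self.gamma + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        scale = Tensor(inv.astype(x.dtype))
        shift = Tensor((-self.running_mean * inv).astype(x.dtype))
        return (x * scale + shift) * self.gamma + self.beta


class LayerNorm(Module):
    """Layer normalization over the channel axis at each spatial position."""

    def __init__(self, channels: int, eps: float = 1e-6, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout driven by an explicit generator (reproducible)."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * Tensor(mask)


class ConvBlock(Module):
    """Conv 3x3 -> batch norm -> ReLU; spatial dimensions preserved."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.conv = Conv3x3(cin, cout, rng, dtype)
        self.bn = BatchNorm(cout, dtype=dtype)
        self.cin = cin
        self.cout = cout

    def __call__(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()

    def macs(self, h: int, w: int) -> int:
        """Multiply-accumulates of one forward pass at spatial size h x w."""
        return 9 * self.cin * self.cout * h * w


def downsample2(x: Tensor) -> Tensor:
    """Halve spatial resolution by 2x2 max pooling."""
    return maxpool2x2(x)


def upsample2(x: Tensor) -> Tensor:
    """Double spatial resolution by bilinear interpolation."""
    return upsample_bilinear2(x)
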