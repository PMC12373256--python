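"""Neural-network building blocks on top of :mod:`btformer.autodiff`.

Provides the layer types the segmentation network is assembled from
(2D convolution, batch normalisation, pooling, bilinear upsampling),
a ``Module`` container with named parameter/buffer traversal for
checkpointing, and an Adam optimizer with the poly learning-rate policy
handled by the training loop.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    """A trainable tensor (``requires_grad=True``)."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


class Module:
    """Base class with recursive parameter/buffer discovery."""

    def __init__(self):
        self.training = True

    # -- traversal -------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Parameter):
                        yield f"{full}.{i}", item
                    elif isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, np.ndarray):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_buffers(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")

    def modules(self) -> Iterator["Module"]:
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    # -- train/eval mode -------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state dict ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"buffer:{name}": b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name]).astype(p.data.dtype).copy()
        for name, b in self.named_buffers():
            b[...] = state[f"buffer:{name}"]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class MaxPool2x2(Module):
    def forward(self, x):
        return ad.maxpool2x2(x)


def kaiming_normal(rng: np.random.Generator, shape: tuple, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2d(Module):
    """Stride-1 convolution; ``same`` padding for odd kernels by default."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, padding: int | None = None,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 dtype=np.float64):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(kaiming_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in, dtype))
        self.bias = Parameter(np.zeros(out_ch, dtype=dtype)) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float64):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (var.data.reshape(-1) - self.running_var)
            inv = (var + self.eps) ** -0.5
            xhat = centered * inv
        else:
            mu = self.running_mean[None, :, None, None]
            inv = 1.0 / np.sqrt(self.running_var + self.eps)[None, :, None, None]
            xhat = (x - mu) * inv
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xhat * g + b


class ConvBNReLU(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3,
                 rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, kernel, rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(out_ch, dtype=dtype)

    def forward(self, x):
        return ad.relu(self.bn(self.conv(x)))


class UpsampleBilinear2x(Module):
    """Separable ×2 bilinear upsampling (half-pixel centre alignment)."""

    def forward(self, x: Tensor) -> Tensor:
        for axis in (-2, -1):
            n = x.shape[axis]
            src = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
            i0 = np.clip(np.floor(src).astype(int), 0, n - 1)
            i1 = np.clip(i0 + 1, 0, n - 1)
            w1 = np.clip(src - np.floor(src), 0.0, 1.0)
            w1[src < 0] = 0.0
            shape = [1] * x.ndim
            shape[axis] = 2 * n
            w1b = w1.reshape(shape)
            x = ad.take(x, i0, axis=x.ndim + axis) * (1.0 - w1b) + \
                ad.take(x, i1, axis=x.ndim + axis) * w1b
        return x


class UpsampleNearest2x(Module):
    def forward(self, x: Tensor) -> Tensor:
        for axis in (-2, -1):
            idx = np.repeat(np.arange(x.shape[axis]), 2)
            x = ad.take(x, idx, axis=x.ndim + axis)
        return x


class TransposedConvUp2x(Module):
    """×2 upsampling as nearest-neighbour expansion followed by a 3×3 conv."""

    def __init__(self, channels: int, rng=None, dtype=np.float64):
        super().__init__()
        self.up = UpsampleNearest2x()
        self.conv = Conv2d(channels, channels, 3, rng=rng, dtype=dtype)

    def forward(self, x):
        return self.conv(self.up(x))


class Adam:
    """Adam with optional coupled L2 weight decay (decay added to the gradient)."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
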