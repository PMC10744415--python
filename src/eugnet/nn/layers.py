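"""Layers built on the autograd core: convolutions, group normalization,
activations, pooling/upsampling and a parameter-tracking Module base."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, conv2d, log_softmax, max_pool2d, upsample_nearest2  # noqa: F401

__all__ = [
    "Module", "Conv2d", "DepthwiseSeparableConv2d", "GroupNorm",
    "ReLU", "Sigmoid", "Sequential",
]


class Module:
    """Base class; children registered as attributes are discovered."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        named: list[tuple[str, Tensor]] = []
        for k, v in self.__dict__.items():
            key = f"{prefix}{k}"
            if isinstance(v, Tensor) and v.requires_grad:
                named.append((key, v))
            elif isinstance(v, Module):
                named.extend(v.named_parameters(prefix=key + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        named.extend(item.named_parameters(prefix=f"{key}.{i}."))
        return named

    def parameter_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    """Same-padded stride-1 convolution, He-initialized."""

    def __init__(self, cin: int, cout: int, k: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.dilation = k, dilation
        self.weight = Tensor(_he_init(rng, (cout, cin, k, k), cin * k * k),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, dilation=self.dilation)


class DepthwiseSeparableConv2d(Module):
    """Per-channel k x k spatial convolution followed by a 1x1 pointwise mix.

    Parameter count k^2*Cin + Cin*Cout (+ biases) versus k^2*Cin*Cout for a
    standard convolution — the efficiency device used throughout the
    encoder/decoder when the separable flag is on.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.k, self.dilation = k, dilation
        self.dw_weight = Tensor(_he_init(rng, (cin, 1, k, k), k * k),
                                requires_grad=True)
        self.pw_weight = Tensor(_he_init(rng, (cout, cin, 1, 1), cin),
                                requires_grad=True)
        self.bias = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        y = conv2d(x, self.dw_weight, dilation=self.dilation, depthwise=True)
        return conv2d(y, self.pw_weight, self.bias)


class GroupNorm(Module):
    """Group normalization (batch-size independent, hence deterministic at
    evaluation without running statistics)."""

    def __init__(self, channels: int, groups: int | None = None, eps: float = 1e-5):
        self.groups = min(groups or 8, channels)
        while channels % self.groups:
            self.groups -= 1
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        g = self.groups
        xg = x.reshape(n, g, c // g * h * w)
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        yn = xc * (var + self.eps).pow(-0.5)
        y = yn.reshape(n, c, h, w)
        gamma = self.gamma.reshape(1, c, 1, 1)
        beta = self.beta.reshape(1, c, 1, 1)
        return y * gamma + beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class SGD:
    """Stochastic gradient descent with classical momentum."""

    def __init__(self, params: list[Tensor], momentum: float = 0.9):
        self.params = params
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v -= lr * p.grad
            p.data += v
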