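"""Layer modules built on the autodiff engine.

Feature maps are (C, D, H, W); all convolutions use "same" padding.
"""

from __future__ import annotations

import numpy as np

from ..autodiff import (
    Module,
    Parameter,
    Tensor,
    conv3d,
    dropout,
    instance_norm,
    kaiming_conv_weight,
    linear,
)
from ..volumes import InvalidInputError


class Conv3d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        dilation: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        negative_slope: float = 0.01,
    ):
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.dilation = dilation
        self.weight = Parameter(
            kaiming_conv_weight(rng, out_channels, in_channels, kernel_size, negative_slope)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        if self.stride > 1 and any(n % self.stride for n in x.shape[1:]):
            raise InvalidInputError(
                f"spatial shape {x.shape[1:]} not divisible by stride {self.stride}"
            )
        return conv3d(x, self.weight, self.bias, stride=self.stride, dilation=self.dilation)


class InstanceNorm3d(Module):
    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.gamma, self.beta, self.eps)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, size=(out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        return linear(x, self.weight, self.bias)


class ConvNormAct(Module):
    """Conv -> InstanceNorm -> LeakyReLU."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        dilation: int = 1,
        negative_slope: float = 0.01,
        rng: np.random.Generator | None = None,
    ):
        self.conv = Conv3d(
            in_channels, out_channels, kernel_size, stride, dilation,
            rng=rng, negative_slope=negative_slope,
        )
        self.norm = InstanceNorm3d(out_channels)
        self.negative_slope = negative_slope

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x)).leaky_relu(self.negative_slope)


class ResidualBlock(Module):
    """Two 3x3x3 conv/IN/LeakyReLU stages plus an identity or 1x1x1
    projection shortcut; spatial shape preserved."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        negative_slope: float = 0.01,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv3d(in_channels, out_channels, 3, rng=rng, negative_slope=negative_slope)
        self.norm1 = InstanceNorm3d(out_channels)
        self.conv2 = Conv3d(out_channels, out_channels, 3, rng=rng, negative_slope=negative_slope)
        self.norm2 = InstanceNorm3d(out_channels)
        self.negative_slope = negative_slope
        self.shortcut = (
            None
            if in_channels == out_channels
            else Conv3d(in_channels, out_channels, 1, bias=False, rng=rng)
        )

    def __call__(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).leaky_relu(self.negative_slope)
        h = self.norm2(self.conv2(h))
        identity = x if self.shortcut is None else self.shortcut(x)
        return (h + identity).leaky_relu(self.negative_slope)


class Downsample(Module):
    """Stride-2 3x3x3 convolution halving each spatial dim, followed by
    dropout."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        dropout_rate: float = 0.0,
        negative_slope: float = 0.01,
        rng: np.random.Generator | None = None,
        dropout_seed: int = 0,
    ):
        self.block = ConvNormAct(
            in_channels, out_channels, 3, stride=2, negative_slope=negative_slope, rng=rng
        )
        self.dropout_rate = dropout_rate
        self._rng = np.random.default_rng(dropout_seed)

    def __call__(self, x: Tensor) -> Tensor:
        if any(n % 2 for n in x.shape[1:]):
            raise InvalidInputError(f"spatial dims must be even for downsampling, got {x.shape[1:]}")
        h = self.block(x)
        return dropout(h, self.dropout_rate, self._rng, self.training)
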