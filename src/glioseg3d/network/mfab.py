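"""Multi-scale fusion attention block for skip connections.

The decoder-side (high-dimensional, semantically rich) map is first aligned
to the encoder-side (low-dimensional, edge-rich) map by 1x1x1 and 3x3x3
convolutions.  Global average pooling of both maps yields per-channel
statistics which pass through two independent fully connected bottlenecks
(inner ReLU); their sum is squashed by a sigmoid into per-channel scales
that recalibrate the encoder map before it is superposed onto the decoder
map.  Two final 3x3x3 convolutions refine the fused features.
"""

from __future__ import annotations

import numpy as np

from ..autodiff import Module, Tensor
from ..volumes import InvalidInputError
from .layers import ConvNormAct, Linear


class _ChannelBottleneck(Module):
    """Two fully connected layers, ReLU between them, on a (C,) statistic."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        hidden = max(channels // reduction, 1)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)

    def __call__(self, s: Tensor) -> Tensor:
        return self.fc2(self.fc1(s).relu())


class MFAB(Module):
    def __init__(
        self,
        low_channels: int,
        high_channels: int,
        reduction: int = 4,
        negative_slope: float = 0.01,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.low_channels = low_channels
        # alignment of the raw high-dimensional map: 1x1x1 then 3x3x3
        self.align_1x1 = ConvNormAct(high_channels, low_channels, 1, rng=rng,
                                     negative_slope=negative_slope)
        self.align_3x3 = ConvNormAct(low_channels, low_channels, 3, rng=rng,
                                     negative_slope=negative_slope)
        self.bottleneck_low = _ChannelBottleneck(low_channels, reduction, rng)
        self.bottleneck_high = _ChannelBottleneck(low_channels, reduction, rng)
        self.refine1 = ConvNormAct(low_channels, low_channels, 3, rng=rng,
                                   negative_slope=negative_slope)
        self.refine2 = ConvNormAct(low_channels, low_channels, 3, rng=rng,
                                   negative_slope=negative_slope)
        #: force all channel scales to exactly 1 (attention bypass)
        self.bypass_attention = False

    def channel_scales(self, x_low: Tensor, x_high: Tensor) -> Tensor:
        s_low = x_low.mean(axis=(1, 2, 3))    # (C,)
        s_high = x_high.mean(axis=(1, 2, 3))  # (C,)
        z = self.bottleneck_low(s_low) + self.bottleneck_high(s_high)
        return z.sigmoid()

    def __call__(self, x_low: Tensor, x_high_raw: Tensor) -> Tensor:
        x_high = self.align_3x3(self.align_1x1(x_high_raw))
        if x_high.shape != x_low.shape:
            raise InvalidInputError(
                f"aligned high-dim map {x_high.shape} does not match low-dim map {x_low.shape}"
            )
        if self.bypass_attention:
            fused = x_high + x_low
        else:
            beta = self.channel_scales(x_low, x_high)           # (C,) in (0,1)
            scaled = x_low * beta.reshape(self.low_channels, 1, 1, 1)
            fused = x_high + scaled
        return self.refine2(self.refine1(fused))
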