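"""Atrous spatial pyramid pooling over a 3D feature map.

Five parallel branches — a 1x1x1 convolution, three 3x3x3 atrous convolutions
with configurable dilation rates (default 6/12/18), and global average
pooling restored by a 1x1x1 convolution and broadcast — concatenated on the
channel axis and projected back to the requested width by a final 1x1x1
convolution.  Spatial shape is preserved.
"""

from __future__ import annotations

import numpy as np

from ..autodiff import Module, Tensor, concat, resize_trilinear
from ..volumes import InvalidSpecError
from .layers import Conv3d, ConvNormAct


class ASPP(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        rates: tuple[int, ...] = (6, 12, 18),
        negative_slope: float = 0.01,
        rng: np.random.Generator | None = None,
    ):
        if not rates:
            raise InvalidSpecError("ASPP needs at least one dilation rate")
        rng = rng or np.random.default_rng(0)
        branch_ch = max(out_channels // 4, 4)
        self.rates = tuple(int(r) for r in rates)
        self.branch_1x1 = ConvNormAct(in_channels, branch_ch, 1, rng=rng,
                                      negative_slope=negative_slope)
        self.branches_atrous = [
            ConvNormAct(in_channels, branch_ch, 3, dilation=r, rng=rng,
                        negative_slope=negative_slope)
            for r in self.rates
        ]
        # plain conv on the pooled 1x1x1 statistic: instance norm would be
        # degenerate on a single voxel
        self.branch_pool = Conv3d(in_channels, branch_ch, 1, rng=rng,
                                  negative_slope=negative_slope)
        n_branches = 2 + len(self.rates)
        self.project = ConvNormAct(n_branches * branch_ch, out_channels, 1, rng=rng,
                                   negative_slope=negative_slope)
        self.branch_channels = branch_ch
        self.negative_slope = negative_slope

    def branch_outputs(self, x: Tensor) -> list[Tensor]:
        spatial = x.shape[1:]
        outs = [self.branch_1x1(x)]
        outs += [b(x) for b in self.branches_atrous]
        pooled = x.mean(axis=(1, 2, 3), keepdims=True)  # (C,1,1,1)
        pooled = self.branch_pool(pooled).leaky_relu(self.negative_slope)
        outs.append(resize_trilinear(pooled, spatial))
        return outs

    def __call__(self, x: Tensor) -> Tensor:
        return self.project(concat(self.branch_outputs(x), axis=0))
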