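"""The improved 3D U-Net segmentation model.

Residual encoder with strided downsampling, ASPP at the bottleneck,
attention-gated (MFAB) skip fusion in the decoder, and deep supervision:
1x1x1 heads at every decoder resolution, trilinearly interpolated to full
resolution and combined by element-wise summation before the softmax.
A 128-voxel input reaches an 8-voxel bottleneck (16x smaller per axis at
the default depth of 4).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from ..autodiff import Module, Tensor, no_grad, resize_trilinear, softmax
from ..volumes import (
    InvalidInputError,
    InvalidSpecError,
    MultimodalVolume,
    ProbabilityVolume,
)
from .aspp import ASPP
from .layers import Conv3d, ConvNormAct, Downsample, ResidualBlock
from .mfab import MFAB


@dataclass
class NetworkConfig:
    in_channels: int = 4
    num_classes: int = 4
    base_channels: int = 16
    depth: int = 4
    aspp_rates: tuple[int, ...] = (6, 12, 18)
    dropout_rate: float = 0.1
    negative_slope: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.num_classes < 2:
            raise InvalidSpecError("num_classes must be >= 2")
        if self.depth < 1:
            raise InvalidSpecError("depth must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise InvalidSpecError("dropout_rate must lie in [0, 1)")
        self.aspp_rates = tuple(int(r) for r in self.aspp_rates)
        if not self.aspp_rates:
            raise InvalidSpecError("aspp_rates must be non-empty")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["aspp_rates"] = list(self.aspp_rates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**{**d, "aspp_rates": tuple(d.get("aspp_rates", (6, 12, 18)))})


class UNet3D(Module):
    def __init__(self, cfg: NetworkConfig | None = None):
        cfg = cfg or NetworkConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        ns = cfg.negative_slope
        ch = [cfg.base_channels * (2 ** i) for i in range(cfg.depth + 1)]
        self.channels = ch

        self.stem = ResidualBlock(cfg.in_channels, ch[0], ns, rng)
        self.down_blocks = []
        self.enc_blocks = []
        for i in range(1, cfg.depth + 1):
            self.down_blocks.append(
                Downsample(ch[i - 1], ch[i], cfg.dropout_rate, ns, rng, dropout_seed=cfg.seed + i)
            )
            self.enc_blocks.append(ResidualBlock(ch[i], ch[i], ns, rng))

        self.aspp = ASPP(ch[cfg.depth], ch[cfg.depth], cfg.aspp_rates, ns, rng)

        # decoder: one level per downsampling, deepest first
        self.up_conv3 = []
        self.up_conv1 = []
        self.skip_fusion = []
        self.heads = []
        for i in range(cfg.depth - 1, -1, -1):
            self.up_conv3.append(ConvNormAct(ch[i + 1], ch[i], 3, rng=rng, negative_slope=ns))
            self.up_conv1.append(ConvNormAct(ch[i], ch[i], 1, rng=rng, negative_slope=ns))
            self.skip_fusion.append(MFAB(ch[i], ch[i], rng=rng, negative_slope=ns))
            self.heads.append(Conv3d(ch[i], cfg.num_classes, 1, rng=rng))

    # -- forward -------------------------------------------------------------

    def _check_input(self, x: Tensor) -> None:
        if x.ndim != 4 or x.shape[0] != self.cfg.in_channels:
            raise InvalidInputError(
                f"expected ({self.cfg.in_channels}, D, H, W) input, got {x.shape}"
            )
        factor = 2 ** self.cfg.depth
        for axis, n in enumerate(x.shape[1:]):
            if n % factor:
                raise InvalidInputError(
                    f"spatial axis {axis} has size {n}, not divisible by 2^depth = {factor}"
                )

    def encode(self, x: Tensor) -> list[Tensor]:
        """Encoder features from full resolution down to the bottleneck input."""
        self._check_input(x)
        feats = [self.stem(x)]
        for down, block in zip(self.down_blocks, self.enc_blocks):
            feats.append(block(down(feats[-1])))
        return feats

    def forward_logits(self, x: Tensor) -> Tensor:
        """Deep-supervision-fused logits at full resolution."""
        feats = self.encode(x)
        full_shape = x.shape[1:]
        h = self.aspp(feats[-1])
        fused_logits: Tensor | None = None
        for lvl, i in enumerate(range(self.cfg.depth - 1, -1, -1)):
            skip = feats[i]
            h = resize_trilinear(h, skip.shape[1:])
            h = self.up_conv1[lvl](self.up_conv3[lvl](h))
            h = self.skip_fusion[lvl](skip, h)
            head = self.heads[lvl](h)
            head_full = resize_trilinear(head, full_shape)
            fused_logits = head_full if fused_logits is None else fused_logits + head_full
        return fused_logits

    def __call__(self, x: Tensor) -> Tensor:
        """Per-voxel class probabilities (num_classes, D, H, W)."""
        return softmax(self.forward_logits(x), axis=0)

    def bottleneck_shape(self, spatial_shape: tuple[int, int, int]) -> tuple[int, int, int]:
        factor = 2 ** self.cfg.depth
        return tuple(n // factor for n in spatial_shape)


def model_forward(vol: MultimodalVolume, cfg: NetworkConfig | None = None,
                  model: UNet3D | None = None) -> ProbabilityVolume:
    """Run a (possibly freshly initialised) model over a multimodal volume
    in inference mode and wrap the result."""
    net = model if model is not None else UNet3D(cfg)
    net.eval()
    with no_grad():
        probs = net(Tensor(vol.data.astype(np.float32)))
    return ProbabilityVolume(probs.data, spacing=vol.spacing, affine=vol.affine)
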