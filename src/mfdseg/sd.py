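"""Spatial-channel decoupled (SD) downsampling.

Standard strided convolutions compress space and remix channels in one step,
which smears the faint high-frequency detail (canopy edges, thin branches)
that small-object segmentation depends on.  The SD module decouples the two
jobs — "preserve first, compress later":

1. channel adaptation: 1x1 convolution (stride 1) + BN + SiLU, which changes
   only the channel count;
2. spatial reduction: KxK *depthwise* strided convolution + BN, with groups
   equal to the output channel count, which changes only the resolution.

No activation follows the second BN (a flag exposes one for ablation).
Convolutions are bias-free, as everywhere a BN follows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError
from .mfe import silu
from .reparam import BNStats, ConvTensor, conv_forward

__all__ = ["SDConfig", "SDState", "init_sd_state", "sd_forward", "sd_param_count"]


@dataclass(frozen=True)
class SDConfig:
    in_channels: int
    out_channels: int
    kernel: int = 3
    stride: int = 2
    act_after_bn2: bool = False

    def __post_init__(self):
        if min(self.in_channels, self.out_channels, self.stride) < 1:
            raise ValueError("channels and stride must be >= 1")

    @property
    def padding(self) -> int:
        return self.kernel // 2


@dataclass
class SDState:
    pointwise: ConvTensor
    bn1: BNStats
    depthwise: ConvTensor
    bn2: BNStats


def init_sd_state(cfg: SDConfig, rng: np.random.Generator | None = None) -> SDState:
    rng = np.random.default_rng() if rng is None else rng
    c1, c2, k = cfg.in_channels, cfg.out_channels, cfg.kernel

    def bn(d):
        return BNStats(mean=np.zeros(d), std=np.ones(d), gamma=np.ones(d), beta=np.zeros(d))

    pw = ConvTensor(
        weights=rng.normal(0.0, np.sqrt(2.0 / c1), size=(c2, c1, 1, 1)),
        bias=np.zeros(c2),
    )
    dw = ConvTensor(
        weights=rng.normal(0.0, np.sqrt(2.0 / (k * k)), size=(c2, 1, k, k)),
        bias=np.zeros(c2),
        stride=cfg.stride,
        padding=(cfg.padding, cfg.padding),
        groups=c2,
    )
    return SDState(pointwise=pw, bn1=bn(c2), depthwise=dw, bn2=bn(c2))


def sd_forward(cfg: SDConfig, state: SDState, x: np.ndarray) -> np.ndarray:
    """Pointwise channel adaptation, then depthwise strided compression."""
    x = np.asarray(x, dtype=float)
    if x.shape[-3] != cfg.in_channels:
        raise DimensionError(f"input has {x.shape[-3]} channels, expected {cfg.in_channels}")
    x1 = silu(state.bn1.apply(conv_forward(state.pointwise, x)))
    out = state.bn2.apply(conv_forward(state.depthwise, x1))
    return silu(out) if cfg.act_after_bn2 else out


def sd_param_count(cfg: SDConfig) -> int:
    """Trainable parameters: bias-free convs + two affine BNs."""
    c1, c2, k = cfg.in_channels, cfg.out_channels, cfg.kernel
    return c1 * c2 + 2 * c2 + k * k * c2 + 2 * c2
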