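"""The four-branch multi-scale feature-extraction (MFE) block.

At training time the block runs four parallel branches over the same input —

* a KxK convolution + BN (mid-scale structure, the main branch),
* a 1x1 convolution + BN (local fine-grained detail),
* KxK average pooling, then a 1x1 convolution + BN (smoothed global context),
* a 1x1 -> KxK sequential pair, each with BN (expanded receptive field),

sums them element-wise and applies SiLU.  Because every branch is linear up
to the sum, the whole structure collapses exactly to a single KxK convolution
for deployment (:func:`mfe_fuse`); the SiLU sits outside the sum and is kept
outside the fused convolution, so fusion is lossless.

The residual/identity path is deliberately *not* part of this block: the
aggregation stage that hosts MFE blocks adds its own residual connection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, ModeError
from .reparam import (
    BNStats,
    ConvTensor,
    avg_pool2d,
    avgpool_as_conv,
    conv_forward,
    fuse_conv_bn,
    merge_parallel_sum,
    merge_seq_1x1_kxk,
    merge_seq_kxk_1x1,
    pad_kernel_to_target,
)

__all__ = ["MFEConfig", "MFEState", "init_mfe_state", "mfe_forward_train", "mfe_fuse", "mfe_param_counts", "silu"]


def silu(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class MFEConfig:
    """Hyperparameters of one MFE block.

    ``alpha`` scales the intermediate channel count of the sequential branch:
    ``c_mid = round(alpha * in_channels)`` (round half up), at least 1.
    """

    in_channels: int
    out_channels: int
    kernel: int = 3
    alpha: float = 1.0

    def __post_init__(self):
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ValueError("MFE kernel size must be odd")
        if self.c_mid < 1:
            raise ValueError("expansion alpha gives an empty intermediate stage")

    @property
    def c_mid(self) -> int:
        return int(np.floor(self.alpha * self.in_channels + 0.5))

    @property
    def padding(self) -> int:
        return self.kernel // 2


@dataclass
class MFEState:
    """Trainable parameters of an MFE block plus its train/deploy mode."""

    main: ConvTensor
    main_bn: BNStats
    pointwise: ConvTensor
    pointwise_bn: BNStats
    pool_pw: ConvTensor
    pool_bn: BNStats
    seq1: ConvTensor
    seq1_bn: BNStats
    seq2: ConvTensor
    seq2_bn: BNStats
    mode: str = "train"
    deployed_conv: ConvTensor | None = None


def init_mfe_state(cfg: MFEConfig, rng: np.random.Generator | None = None) -> MFEState:
    """He-style random initialization; BN starts as identity statistics."""
    rng = np.random.default_rng() if rng is None else rng
    k, cin, cout, cmid = cfg.kernel, cfg.in_channels, cfg.out_channels, cfg.c_mid

    def conv(d, c, ksz, pad):
        std = np.sqrt(2.0 / (c * ksz * ksz))
        return ConvTensor(
            weights=rng.normal(0.0, std, size=(d, c, ksz, ksz)),
            bias=np.zeros(d),
            stride=1,
            padding=(pad, pad),
        )

    def bn(d):
        return BNStats(mean=np.zeros(d), std=np.ones(d), gamma=np.ones(d), beta=np.zeros(d))

    return MFEState(
        main=conv(cout, cin, k, cfg.padding),
        main_bn=bn(cout),
        pointwise=conv(cout, cin, 1, 0),
        pointwise_bn=bn(cout),
        pool_pw=conv(cout, cin, 1, 0),
        pool_bn=bn(cout),
        seq1=conv(cmid, cin, 1, 0),
        seq1_bn=bn(cmid),
        seq2=conv(cout, cmid, k, cfg.padding),
        seq2_bn=bn(cout),
    )


def mfe_forward_train(cfg: MFEConfig, state: MFEState, x: np.ndarray) -> np.ndarray:
    """Branch-by-branch training-mode forward: SiLU(base + 1x1 + pool + seq)."""
    if state.mode != "train":
        raise ModeError("training forward requested on a deployed block")
    x = np.asarray(x, dtype=float)
    if x.shape[-3] != cfg.in_channels:
        raise DimensionError(f"input has {x.shape[-3]} channels, expected {cfg.in_channels}")
    f_base = state.main_bn.apply(conv_forward(state.main, x))
    f_1x1 = state.pointwise_bn.apply(conv_forward(state.pointwise, x))
    pooled = avg_pool2d(x, cfg.kernel, stride=1, padding=cfg.padding)
    f_pool = state.pool_bn.apply(conv_forward(state.pool_pw, pooled))
    f_seq = state.seq2_bn.apply(_seq_stage2(state, cfg, x))
    return silu(f_base + f_1x1 + f_pool + f_seq)


def _seq_stage2(state: MFEState, cfg: MFEConfig, x: np.ndarray) -> np.ndarray:
    """Sequential branch up to (but excluding) the second BN.

    The intermediate map is padded with the first stage's *zero-input
    response* — what stage 1 would produce on the zero-padding ring of the
    input — rather than with zeros.  Zero-padding the intermediate map would
    make the branch inequivalent to its fused form at image borders whenever
    the first stage's BN shifts zero; padding with the zero response keeps
    the 1x1 -> KxK merge exact everywhere.
    """
    mid = state.seq1_bn.apply(conv_forward(state.seq1, x))
    p = cfg.padding
    if p == 0:
        return conv_forward(state.seq2, mid)
    zero_resp = state.seq1_bn.apply(
        state.seq1.bias.reshape(-1, 1, 1) * np.ones((1, 1, 1))
    ).reshape(-1)
    pad_spec = [(0, 0)] * (mid.ndim - 2) + [(p, p), (p, p)]
    mid_p = np.pad(mid, pad_spec)
    mid_p[..., :p, :] = zero_resp.reshape(-1, 1, 1)
    mid_p[..., -p:, :] = zero_resp.reshape(-1, 1, 1)
    mid_p[..., :, :p] = zero_resp.reshape(-1, 1, 1)
    mid_p[..., :, -p:] = zero_resp.reshape(-1, 1, 1)
    inner = ConvTensor(
        weights=state.seq2.weights, bias=state.seq2.bias, stride=1, padding=(0, 0)
    )
    return conv_forward(inner, mid_p)


def mfe_fuse(cfg: MFEConfig, state: MFEState) -> ConvTensor:
    """Collapse the four branches into one KxK convolution.

    Plan: (a) main: conv-BN fusion; (b) pointwise: conv-BN fusion then central
    zero-padding to KxK; (c) pooling: the pooling window as a KxK convolution
    with the BN-fused 1x1 folded in behind it; (d) sequential: both conv-BN
    pairs fused, then the 1x1 factor contracted into the KxK kernel; finally
    the four same-geometry kernels are summed.
    """
    if state.mode != "train":
        raise ModeError("block is already deployed")
    k = cfg.kernel
    a = fuse_conv_bn(state.main, state.main_bn)
    b = pad_kernel_to_target(fuse_conv_bn(state.pointwise, state.pointwise_bn), k)
    pool = avgpool_as_conv(cfg.in_channels, k, stride=1, padding=cfg.padding)
    c = merge_seq_kxk_1x1(pool, fuse_conv_bn(state.pool_pw, state.pool_bn))
    d = merge_seq_1x1_kxk(
        fuse_conv_bn(state.seq1, state.seq1_bn),
        fuse_conv_bn(state.seq2, state.seq2_bn),
    )
    return merge_parallel_sum([a, b, c, d])


def deploy(cfg: MFEConfig, state: MFEState) -> MFEState:
    """Return a deployed copy of the state holding only the fused convolution."""
    fused = mfe_fuse(cfg, state)
    out = MFEState(**{f: getattr(state, f) for f in state.__dataclass_fields__})
    out.mode = "deployed"
    out.deployed_conv = fused
    return out


def mfe_forward_deploy(cfg: MFEConfig, state: MFEState, x: np.ndarray) -> np.ndarray:
    if state.mode != "deployed" or state.deployed_conv is None:
        raise ModeError("block has not been fused")
    return silu(conv_forward(state.deployed_conv, x))


def mfe_param_counts(cfg: MFEConfig) -> tuple[int, int]:
    """(train, deployed) trainable-parameter counts.

    Convolutions feeding a BN carry no independent bias; each BN contributes
    two trainable vectors (gamma, beta).  The deployed form is one biased
    KxK convolution.
    """
    k, cin, cout, cmid = cfg.kernel, cfg.in_channels, cfg.out_channels, cfg.c_mid
    train = (
        cout * cin * k * k + 2 * cout          # main + BN
        + cout * cin + 2 * cout                # 1x1 + BN
        + cout * cin + 2 * cout                # pool 1x1 + BN
        + cmid * cin + 2 * cmid                # seq 1x1 + BN
        + cout * cmid * k * k + 2 * cout       # seq KxK + BN
    )
    deploy_count = cout * (cin * k * k + 1)
    return train, deploy_count
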