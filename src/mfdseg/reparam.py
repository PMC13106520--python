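"""Structural re-parameterization algebra.

Multi-branch convolutional structures used at training time can be folded,
exactly, into a single convolution for inference.  This module implements the
six equivalence transforms that make that possible:

I.   conv + batch-norm       -> conv            (``fuse_conv_bn``)
II.  parallel branches, sum  -> conv            (``merge_parallel_sum``)
III. 1x1 conv then KxK conv  -> KxK conv        (``merge_seq_1x1_kxk``)
IV.  branches, channel concat-> conv            (``merge_branch_concat``)
V.   KxK average pooling     -> KxK conv        (``avgpool_as_conv``)
VI.  small kernel -> KxK kernel by zero-padding (``pad_kernel_to_target``)

plus the KxK-then-1x1 composition (``merge_seq_kxk_1x1``) needed to fuse an
average-pooling branch followed by a pointwise convolution.

Everything here is a pure function of :class:`ConvTensor` / :class:`BNStats`
values; ``conv_forward`` and ``avg_pool2d`` are the reference forward
evaluations the equivalences are stated (and tested) against.

Conventions
-----------
* Weight layout is ``[D, C, kh, kw]`` — output channel, input channel (per
  group), kernel row, kernel column; kernel indices are 0-based.
* Average pooling always divides by ``K**2`` regardless of border clipping
  (zero padding is counted in the divisor).  Only this convention makes
  transform V exact at image borders; it deviates from the
  ``count_include_pad=False`` default of some libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    DimensionError,
    InvalidStatisticsError,
    UnsupportedCompositionError,
)

__all__ = [
    "ConvTensor",
    "BNStats",
    "conv_forward",
    "avg_pool2d",
    "fuse_conv_bn",
    "merge_parallel_sum",
    "merge_seq_1x1_kxk",
    "merge_seq_kxk_1x1",
    "merge_branch_concat",
    "avgpool_as_conv",
    "pad_kernel_to_target",
]


@dataclass(frozen=True)
class ConvTensor:
    """A convolution as data: weights, bias and geometry.

    ``weights[d, c, i, j]`` with ``d`` the output channel, ``c`` the input
    channel *within the group*, and ``(i, j)`` the kernel position.
    """

    weights: np.ndarray
    bias: np.ndarray
    stride: int = 1
    padding: tuple[int, int] = (0, 0)
    groups: int = 1

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        b = np.asarray(self.bias, dtype=float)
        if w.ndim != 4:
            raise DimensionError(f"weights must be 4-D, got shape {w.shape}")
        if b.ndim != 1 or b.shape[0] != w.shape[0]:
            raise DimensionError(
                f"bias length {b.shape} does not match {w.shape[0]} output channels"
            )
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
            raise InvalidStatisticsError("non-finite convolution parameters")
        if self.stride < 1:
            raise DimensionError("stride must be a positive integer")
        if self.groups < 1 or w.shape[0] % self.groups:
            raise DimensionError("output channels must be divisible by groups")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "bias", b)
        object.__setattr__(self, "padding", tuple(int(p) for p in self.padding))

    @property
    def out_channels(self) -> int:
        return self.weights.shape[0]

    @property
    def in_channels(self) -> int:
        """Total input channels (per-group channels times groups)."""
        return self.weights.shape[1] * self.groups

    @property
    def kernel_size(self) -> tuple[int, int]:
        return self.weights.shape[2], self.weights.shape[3]


@dataclass(frozen=True)
class BNStats:
    """Per-channel batch-normalization statistics and affine parameters.

    ``std`` already contains the numerical stabilizer: ``std = sqrt(var + eps)``.
    """

    mean: np.ndarray
    std: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    eps: float = 1e-3

    def __post_init__(self):
        vecs = {}
        for name in ("mean", "std", "gamma", "beta"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.ndim != 1:
                raise DimensionError(f"{name} must be a vector")
            vecs[name] = v
        n = {v.shape[0] for v in vecs.values()}
        if len(n) != 1:
            raise DimensionError("BN vectors must share one length")
        if np.any(vecs["std"] <= 0) or not np.all(np.isfinite(vecs["std"])):
            raise InvalidStatisticsError("BN std must be finite and > 0")
        for name, v in vecs.items():
            object.__setattr__(self, name, v)

    @property
    def channels(self) -> int:
        return self.mean.shape[0]

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Normalize a ``[..., C, H, W]`` feature map channel-wise."""
        shape = (-1, 1, 1)
        return (x - self.mean.reshape(shape)) / self.std.reshape(shape) * self.gamma.reshape(
            shape
        ) + self.beta.reshape(shape)


# ---------------------------------------------------------------------------
# reference forwards
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: tuple[int, int]) -> np.ndarray:
    """Lower a padded [C,H,W] map to columns of shape [C*kh*kw, Ho*Wo]."""
    c, h, w = x.shape
    ph, pw = pad
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw)))
    ho = (h + 2 * ph - kh) // stride + 1
    wo = (w + 2 * pw - kw) // stride + 1
    cols = np.empty((c, kh * kw, ho * wo), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            patch = xp[:, i : i + stride * ho : stride, j : j + stride * wo : stride]
            cols[:, i * kw + j, :] = patch.reshape(c, -1)
    return cols.reshape(c * kh * kw, ho * wo)


def conv_forward(conv: ConvTensor, x: np.ndarray) -> np.ndarray:
    """Direct evaluation of a convolution on a ``[C, H, W]`` (or ``[N, C, H, W]``) map."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 4:
        return np.stack([conv_forward(conv, xi) for xi in x])
    if x.ndim != 3:
        raise DimensionError("feature map must be [C,H,W] or [N,C,H,W]")
    if x.shape[0] != conv.in_channels:
        raise DimensionError(
            f"input has {x.shape[0]} channels, convolution expects {conv.in_channels}"
        )
    kh, kw = conv.kernel_size
    d = conv.out_channels
    g = conv.groups
    cg = conv.weights.shape[1]
    dg = d // g
    outs = []
    for gi in range(g):
        cols = _im2col(x[gi * cg : (gi + 1) * cg], kh, kw, conv.stride, conv.padding)
        wmat = conv.weights[gi * dg : (gi + 1) * dg].reshape(dg, cg * kh * kw)
        outs.append(wmat @ cols)
    out = np.concatenate(outs, axis=0)
    ph, pw = conv.padding
    ho = (x.shape[1] + 2 * ph - kh) // conv.stride + 1
    wo = (x.shape[2] + 2 * pw - kw) // conv.stride + 1
    return out.reshape(d, ho, wo) + conv.bias.reshape(-1, 1, 1)


def avg_pool2d(x: np.ndarray, k: int, stride: int = 1, padding: int = 0) -> np.ndarray:
    """KxK average pooling with divisor ``k**2`` everywhere (padding counted)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 4:
        return np.stack([avg_pool2d(xi, k, stride, padding) for xi in x])
    c = x.shape[0]
    box = ConvTensor(
        weights=np.broadcast_to(np.eye(c).reshape(c, c, 1, 1) / k**2, (c, c, k, k)).copy(),
        bias=np.zeros(c),
        stride=stride,
        padding=(padding, padding),
    )
    return conv_forward(box, x)


# ---------------------------------------------------------------------------
# the transforms
# ---------------------------------------------------------------------------


def fuse_conv_bn(conv: ConvTensor, bn: BNStats) -> ConvTensor:
    """Transform I: fold a following batch-norm into the convolution.

    Per output channel ``j``:  ``F'_j = (gamma_j / std_j) * F_j`` and
    ``b'_j = beta_j + (b_j - mean_j) * gamma_j / std_j``; with a bias-free
    convolution this reduces to the familiar ``beta - gamma * mean / std``.
    """
    if bn.channels != conv.out_channels:
        raise DimensionError(
            f"BN has {bn.channels} channels, convolution outputs {conv.out_channels}"
        )
    scale = bn.gamma / bn.std
    return replace(
        conv,
        weights=conv.weights * scale.reshape(-1, 1, 1, 1),
        bias=bn.beta + (conv.bias - bn.mean) * scale,
    )


def _require_same_geometry(branches: list[ConvTensor], *, same_out: bool = True) -> None:
    ref = branches[0]
    for b in branches[1:]:
        same = (
            b.in_channels == ref.in_channels
            and b.kernel_size == ref.kernel_size
            and b.stride == ref.stride
            and b.padding == ref.padding
            and b.groups == ref.groups
        )
        if same_out:
            same = same and b.out_channels == ref.out_channels
        if not same:
            raise DimensionError("branch geometries differ")


def merge_parallel_sum(branches: list[ConvTensor]) -> ConvTensor:
    """Transform II: branches whose outputs are summed merge by adding kernels."""
    if not branches:
        raise ValueError("need at least one branch")
    _require_same_geometry(branches)
    return replace(
        branches[0],
        weights=sum(b.weights for b in branches),
        bias=sum(b.bias for b in branches),
    )


def merge_seq_1x1_kxk(first: ConvTensor, second: ConvTensor) -> ConvTensor:
    """Transform III: a pointwise convolution followed by a KxK one.

    The pointwise factor mixes input channels; folding it in amounts to
    contracting the KxK kernel's input-channel axis with the 1x1 matrix:
    ``F'[d,c,i,j] = sum_e F2[d,e,i,j] * F1[e,c,0,0]``.  The first stage's bias
    feeds through the second kernel, so
    ``b'_d = b2_d + sum_{e,i,j} F2[d,e,i,j] * b1_e``.
    """
    if first.kernel_size != (1, 1):
        raise UnsupportedCompositionError("first factor must be a 1x1 convolution")
    if first.stride != 1 or first.padding != (0, 0):
        raise UnsupportedCompositionError("1x1 factor must have stride 1 and no padding")
    if first.groups != 1 or second.groups != 1:
        raise UnsupportedCompositionError("grouped sequential merges are not supported")
    if first.out_channels != second.in_channels:
        raise DimensionError(
            f"stage-1 outputs {first.out_channels} channels, stage-2 expects {second.in_channels}"
        )
    w1 = first.weights[:, :, 0, 0]  # [mid, Cin]
    weights = np.einsum("deij,ec->dcij", second.weights, w1)
    bias = second.bias + np.einsum("deij,e->d", second.weights, first.bias)
    return replace(second, weights=weights, bias=bias)


def merge_seq_kxk_1x1(first: ConvTensor, second: ConvTensor) -> ConvTensor:
    """Fold a trailing pointwise convolution into a KxK one.

    Needed for the pooling branch, whose order is 'KxK (pooling) conv then
    1x1 conv'.  The 1x1 matrix acts on the KxK kernel's output-channel axis:
    ``F'[d,c,:,:] = sum_e W[d,e] * F[e,c,:,:]`` and
    ``b'_d = b2_d + sum_e W[d,e] * b1_e``.
    """
    if second.kernel_size != (1, 1):
        raise UnsupportedCompositionError("second factor must be a 1x1 convolution")
    if second.stride != 1 or second.padding != (0, 0):
        raise UnsupportedCompositionError("1x1 factor must have stride 1 and no padding")
    if first.groups != 1 or second.groups != 1:
        raise UnsupportedCompositionError("grouped sequential merges are not supported")
    if second.in_channels != first.out_channels:
        raise DimensionError(
            f"stage-1 outputs {first.out_channels} channels, stage-2 expects {second.in_channels}"
        )
    w2 = second.weights[:, :, 0, 0]  # [D, mid]
    weights = np.einsum("de,ecij->dcij", w2, first.weights)
    bias = second.bias + w2 @ first.bias
    return replace(first, weights=weights, bias=bias)


def merge_branch_concat(branches: list[ConvTensor]) -> ConvTensor:
    """Transform IV: branches concatenated along the output-channel axis."""
    if not branches:
        raise ValueError("need at least one branch")
    _require_same_geometry(branches, same_out=False)
    return replace(
        branches[0],
        weights=np.concatenate([b.weights for b in branches], axis=0),
        bias=np.concatenate([b.bias for b in branches]),
    )


def avgpool_as_conv(channels: int, k: int, stride: int = 1, padding: int = 0) -> ConvTensor:
    """Transform V: express KxK average pooling as a convolution.

    Each output channel's kernel is ``1/K**2`` on its own input channel at
    every kernel position and zero on every other channel, so the forward is
    exactly ``avg_pool2d`` with the divisor-``K**2`` border convention.
    """
    if channels < 1 or k < 1:
        raise ValueError("channels and kernel size must be >= 1")
    if k % 2 == 0:
        raise ValueError("even pooling windows are not supported (no centered kernel)")
    eye = np.eye(channels).reshape(channels, channels, 1, 1)
    weights = np.broadcast_to(eye / k**2, (channels, channels, k, k)).copy()
    return ConvTensor(weights=weights, bias=np.zeros(channels), stride=stride, padding=(padding, padding))


def pad_kernel_to_target(conv: ConvTensor, k: int) -> ConvTensor:
    """Transform VI: embed a small kernel centrally in a KxK kernel of zeros.

    Requires matching parity so the embedding is centered; a forward with the
    padded kernel at spatial padding ``p`` equals the original's at ``p - Hp``.
    """
    kh, kw = conv.kernel_size
    if k < kh or k < kw:
        raise ValueError(f"target size {k} smaller than kernel {conv.kernel_size}")
    if (k - kh) % 2 or (k - kw) % 2:
        raise ValueError("target and kernel size must have equal parity for centered padding")
    hp, wp = (k - kh) // 2, (k - kw) // 2
    weights = np.zeros(conv.weights.shape[:2] + (k, k))
    weights[:, :, hp : hp + kh, wp : wp + kw] = conv.weights
    return replace(
        conv,
        weights=weights,
        padding=(conv.padding[0] + hp, conv.padding[1] + wp),
    )
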