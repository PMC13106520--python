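"""Network building blocks.

The blocks mirror the efficient layer-aggregation (GELAN/CSP) family that the
segmentation backbone is built from, plus the two blocks this package is
about: the trainable four-branch :class:`MFEConv` (fusible to one
convolution) and the spatial-channel decoupled :class:`SDDown` downsampler.
All blocks run on the NumPy autodiff engine in :mod:`mfdseg.nn`.

Shared conventions: convolutions in front of a batch norm are bias-free; the
default activation is SiLU; ``k=1`` convolutions use no padding and ``k=3``
use padding 1.
"""

from __future__ import annotations

import math

import numpy as np

from . import nn
from .errors import ModeError
from .mfe import MFEConfig, MFEState, mfe_fuse
from .reparam import BNStats, ConvTensor

__all__ = [
    "Conv", "RepConvN", "RepNBottleneck", "RepNCSP", "RepNCSPELAN4", "ADown",
    "SPPELAN", "Upsample", "Concat", "Silence", "CBLinear", "CBFuse",
    "MFEConv", "FusedMFEConv", "SDDown", "ASFF3", "Proto", "DualDSegment",
    "Segment", "make_divisible",
]


def make_divisible(x: float, divisor: int) -> int:
    return int(math.ceil(x / divisor) * divisor)


class Conv(nn.Module):
    """conv -> BN -> SiLU (the standard unit)."""

    def __init__(self, c1, c2, k=1, s=1, p=None, g=1, act=True, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, s, p, g, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(c2)
        self.act = act

    def forward(self, x):
        y = self.bn(self.conv(x))
        return y.silu() if self.act else y


class RepConvN(nn.Module):
    """Two-branch re-parameterizable conv (3x3 + 1x1, no identity branch)."""

    def __init__(self, c1, c2, k=3, s=1, rng=None):
        super().__init__()
        self.conv1 = Conv(c1, c2, k, s, act=False, rng=rng)
        self.conv2 = Conv(c1, c2, 1, s, p=0, act=False, rng=rng)

    def forward(self, x):
        return (self.conv1(x) + self.conv2(x)).silu()


class RepNBottleneck(nn.Module):
    """Residual bottleneck; ``mfe`` upgrades its convolutions to MFE blocks.

    The shortcut around the (possibly MFE-transformed) convolutions is the
    residual connection that adds the transformed output back to the input.
    """

    def __init__(self, c1, c2, shortcut=True, e=1.0, rng=None, mfe="none", mfe_alpha=1.0):
        super().__init__()
        c_ = int(c2 * e)
        if mfe in ("bottl", "all"):
            self.cv1 = MFEConv(c1, c_, 3, alpha=mfe_alpha, rng=rng)
            self.cv2 = MFEConv(c_, c2, 3, alpha=mfe_alpha, rng=rng)
        elif mfe == "repconv":
            self.cv1 = MFEConv(c1, c_, 3, alpha=mfe_alpha, rng=rng)
            self.cv2 = Conv(c_, c2, 3, 1, rng=rng)
        else:
            self.cv1 = RepConvN(c1, c_, 3, 1, rng=rng)
            self.cv2 = Conv(c_, c2, 3, 1, rng=rng)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class RepNCSP(nn.Module):
    def __init__(self, c1, c2, n=1, shortcut=True, e=0.5, rng=None, mfe="none", mfe_alpha=1.0):
        super().__init__()
        c_ = int(c2 * e)
        self.cv1 = Conv(c1, c_, 1, 1, rng=rng)
        self.cv2 = Conv(c1, c_, 1, 1, rng=rng)
        self.cv3 = Conv(2 * c_, c2, 1, rng=rng)
        self.m = [
            RepNBottleneck(c_, c_, shortcut, e=1.0, rng=rng, mfe=mfe, mfe_alpha=mfe_alpha)
            for _ in range(n)
        ]

    def forward(self, x):
        y = self.cv1(x)
        for b in self.m:
            y = b(y)
        return self.cv3(nn.concat([y, self.cv2(x)], 1))


class RepNCSPELAN4(nn.Module):
    """CSP-ELAN aggregation stage with a configurable MFE conversion policy.

    ``mfe`` selects which internal convolution units become four-branch MFE
    blocks: ``"none"`` (plain stage), ``"repconv"`` (only the
    re-parameterizable bottleneck convolution), ``"bottl"`` (both bottleneck
    convolutions) or ``"all"`` (bottleneck convolutions plus the two
    stage-level 3x3 convolutions).
    """

    def __init__(self, c1, c2, c3, c4, n=1, rng=None, mfe="none", mfe_alpha=1.0):
        super().__init__()
        if mfe is True:
            mfe = "all"
        if mfe is False or mfe is None:
            mfe = "none"
        self.c = c3 // 2

        def stage_conv(cin, cout):
            if mfe == "all":
                return MFEConv(cin, cout, 3, alpha=mfe_alpha, rng=rng)
            return Conv(cin, cout, 3, 1, rng=rng)

        self.cv1 = Conv(c1, c3, 1, 1, rng=rng)
        self.cv2 = nn.Sequential(
            RepNCSP(c3 // 2, c4, n, rng=rng, mfe=mfe, mfe_alpha=mfe_alpha),
            stage_conv(c4, c4),
        )
        self.cv3 = nn.Sequential(
            RepNCSP(c4, c4, n, rng=rng, mfe=mfe, mfe_alpha=mfe_alpha),
            stage_conv(c4, c4),
        )
        self.cv4 = Conv(c3 + 2 * c4, c2, 1, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        y1 = y[:, : self.c]
        y2 = y[:, self.c :]
        y3 = self.cv2(y2)
        y4 = self.cv3(y3)
        return self.cv4(nn.concat([y1, y2, y3, y4], 1))


class ADown(nn.Module):
    """The baseline's hybrid average/max-pool downsampler."""

    def __init__(self, c1, c2, rng=None):
        super().__init__()
        self.c = c2 // 2
        self.cv1 = Conv(c1 // 2, self.c, 3, 2, 1, rng=rng)
        self.cv2 = Conv(c1 // 2, self.c, 1, 1, 0, rng=rng)

    def forward(self, x):
        x = nn.avg_pool2d(x, 2, 1, 0)
        half = x.shape[1] // 2
        x1, x2 = x[:, :half], x[:, half:]
        x1 = self.cv1(x1)
        x2 = self.cv2(nn.max_pool2d(x2, 3, 2, 1))
        return nn.concat([x1, x2], 1)


class SPPELAN(nn.Module):
    """Spatial pyramid pooling in ELAN form (three chained 5x5 max-pools)."""

    def __init__(self, c1, c2, c3, rng=None):
        super().__init__()
        self.cv1 = Conv(c1, c3, 1, 1, rng=rng)
        self.cv5 = Conv(4 * c3, c2, 1, 1, rng=rng)

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(nn.max_pool2d(y[-1], 5, 1, 2))
        return self.cv5(nn.concat(y, 1))


class Upsample(nn.Module):
    def __init__(self, scale=2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return nn.upsample_nearest2(x, self.scale)


class Concat(nn.Module):
    def forward(self, xs):
        return nn.concat(xs, 1)


class Silence(nn.Module):
    def forward(self, x):
        return x


class CBLinear(nn.Module):
    """1x1 projection split into per-scale routing channels."""

    def __init__(self, c1, c2s, rng=None):
        super().__init__()
        self.c2s = list(c2s)
        self.conv = nn.Conv2d(c1, sum(c2s), 1, bias=True, rng=rng)

    def forward(self, x):
        y = self.conv(x)
        outs, start = [], 0
        for c in self.c2s:
            outs.append(y[:, start : start + c])
            start += c
        return outs


class CBFuse(nn.Module):
    """Sum routed feature slices (upsampled to the last input's size)."""

    def __init__(self, idx):
        super().__init__()
        self.idx = list(idx)

    def forward(self, xs):
        target = xs[-1]
        th = target.shape[2]
        out = target
        for i, x in enumerate(xs[:-1]):
            piece = x[self.idx[i]]
            scale = th // piece.shape[2]
            if scale > 1:
                piece = nn.upsample_nearest2(piece, scale)
            out = out + piece
        return out


# ---------------------------------------------------------------------------
# the two blocks under study
# ---------------------------------------------------------------------------


class MFEConv(nn.Module):
    """Trainable four-branch multi-scale feature block (stride 1).

    Branches: KxK conv+BN; 1x1 conv+BN; KxK avg-pool then 1x1 conv+BN;
    1x1 conv+BN then KxK conv+BN.  Outputs are summed and SiLU-activated.
    The sequential branch pads its intermediate map with the first stage's
    zero-input response so the block fuses *exactly* into one KxK
    convolution (:meth:`fuse`).
    """

    def __init__(self, c1, c2, k=3, alpha=1.0, rng=None):
        super().__init__()
        self.cfg = MFEConfig(c1, c2, k, alpha)
        p = self.cfg.padding
        cm = self.cfg.c_mid
        self.main = nn.Conv2d(c1, c2, k, 1, p, bias=False, rng=rng)
        self.main_bn = nn.BatchNorm2d(c2)
        self.pw = nn.Conv2d(c1, c2, 1, 1, 0, bias=False, rng=rng)
        self.pw_bn = nn.BatchNorm2d(c2)
        self.pool_pw = nn.Conv2d(c1, c2, 1, 1, 0, bias=False, rng=rng)
        self.pool_bn = nn.BatchNorm2d(c2)
        self.seq1 = nn.Conv2d(c1, cm, 1, 1, 0, bias=False, rng=rng)
        self.seq1_bn = nn.BatchNorm2d(cm, track_zero_response=True)
        self.seq2 = nn.Conv2d(cm, c2, k, 1, 0, bias=False, rng=rng)  # pads manually
        self.seq2_bn = nn.BatchNorm2d(c2)
        # ring mask marking the padding border, built lazily per input size
        self._mask_cache: dict[tuple[int, int], np.ndarray] = {}

    def forward(self, x):
        k, p = self.cfg.kernel, self.cfg.padding
        f = nn.conv2d(x, self.main.weight, None, 1, p)
        f = self.main_bn(f)
        f = f + self.pw_bn(nn.conv2d(x, self.pw.weight, None, 1, 0))
        pooled = nn.avg_pool2d(x, k, 1, p)
        f = f + self.pool_bn(nn.conv2d(pooled, self.pool_pw.weight, None, 1, 0))
        mid = self.seq1_bn(nn.conv2d(x, self.seq1.weight, None, 1, 0))
        midp = nn.pad2d(mid, p)
        if p > 0:
            h, w = midp.shape[2], midp.shape[3]
            mask = self._mask_cache.get((h, w))
            if mask is None:
                mask = np.ones((1, 1, h, w), dtype=np.float32)
                mask[:, :, p:-p, p:-p] = 0.0
                self._mask_cache[(h, w)] = mask
            zr = self.seq1_bn.zero_response().reshape(1, -1, 1, 1)
            midp = midp + zr * nn.Tensor(mask)
        f = f + self.seq2_bn(nn.conv2d(midp, self.seq2.weight, None, 1, 0))
        return f.silu()

    def _bnstats(self, bn: nn.BatchNorm2d) -> BNStats:
        return BNStats(
            mean=bn.running_mean.astype(float),
            std=np.sqrt(bn.running_var.astype(float) + bn.eps),
            gamma=bn.gamma.data.astype(float),
            beta=bn.beta.data.astype(float),
            eps=bn.eps,
        )

    def _conv(self, conv: nn.Conv2d, padding: int) -> ConvTensor:
        w = conv.weight.data.astype(float)
        return ConvTensor(
            weights=w, bias=np.zeros(w.shape[0]), stride=1, padding=(padding, padding)
        )

    def fuse(self) -> "FusedMFEConv":
        """Fold the four branches into a single biased KxK convolution."""
        p = self.cfg.padding
        state = MFEState(
            main=self._conv(self.main, p),
            main_bn=self._bnstats(self.main_bn),
            pointwise=self._conv(self.pw, 0),
            pointwise_bn=self._bnstats(self.pw_bn),
            pool_pw=self._conv(self.pool_pw, 0),
            pool_bn=self._bnstats(self.pool_bn),
            seq1=self._conv(self.seq1, 0),
            seq1_bn=self._bnstats(self.seq1_bn),
            seq2=ConvTensor(
                weights=self.seq2.weight.data.astype(float),
                bias=np.zeros(self.cfg.out_channels),
                stride=1,
                padding=(p, p),
            ),
            seq2_bn=self._bnstats(self.seq2_bn),
        )
        fused = mfe_fuse(self.cfg, state)
        return FusedMFEConv(fused)


class FusedMFEConv(nn.Module):
    """Deployed form of an MFE block: one biased KxK convolution + SiLU."""

    def __init__(self, fused: ConvTensor):
        super().__init__()
        k = fused.kernel_size[0]
        c2, c1 = fused.out_channels, fused.in_channels
        self.padding = fused.padding[0]
        self.weight = nn.Parameter(fused.weights)
        self.bias = nn.Parameter(fused.bias)
        self.cfg_shape = (c2, c1, k)

    def forward(self, x):
        return nn.conv2d(x, self.weight, self.bias, 1, self.padding).silu()

    def fuse(self):
        raise ModeError("block is already deployed")


class SDDown(nn.Module):
    """Spatial-channel decoupled downsampler (see :mod:`mfdseg.sd`).

    1x1 conv + BN + SiLU for channel adaptation, then KxK depthwise strided
    conv + BN (no activation) for spatial compression.
    """

    def __init__(self, c1, c2, k=3, s=2, rng=None):
        super().__init__()
        self.pw = Conv(c1, c2, 1, 1, 0, rng=rng)
        self.dw = nn.Conv2d(c2, c2, k, s, k // 2, g=c2, bias=False, rng=rng)
        self.dw_bn = nn.BatchNorm2d(c2)

    def forward(self, x):
        return self.dw_bn(nn.conv2d(self.pw(x), self.dw.weight, None, self.dw.stride,
                                    self.dw.padding, self.dw.groups))


class ASFF3(nn.Module):
    """Adaptively spatial feature fusion over three pyramid levels.

    Every source level is resized to the target level's resolution and
    channel width (1x1 projection where widths differ), a per-level 1x1
    projection produces spatial weight logits, and a softmax across levels
    yields per-pixel convex weights; the output is the weighted sum.
    """

    def __init__(self, chans: list[int], target: int, wch: int = 8, expand: str = "none", rng=None):
        super().__init__()
        self.target = target
        self.nlev = len(chans)
        ct = chans[target]
        self.resize = [
            None if c == ct else Conv(c, ct, 1, 1, 0, rng=rng) for c in chans
        ]
        self.wconv = [nn.Conv2d(ct, wch, 1, bias=True, rng=rng) for _ in chans]
        self.wmerge = nn.Conv2d(wch * self.nlev, self.nlev, 1, bias=True, rng=rng)
        if expand == "3x3":
            self.expand = Conv(ct, ct, 3, 1, rng=rng)
        elif expand == "3x3g4":
            self.expand = Conv(ct, ct, 3, 1, g=4, rng=rng)
        elif expand == "1x1":
            self.expand = Conv(ct, ct, 1, 1, 0, rng=rng)
        else:
            self.expand = None

    def forward(self, xs):
        if len(xs) == 1:
            return xs[0]
        th = xs[self.target].shape[2]
        feats = []
        for i, x in enumerate(xs):
            if self.resize[i] is not None:
                x = self.resize[i](x)
            h = x.shape[2]
            if h < th:
                x = nn.upsample_nearest2(x, th // h)
            elif h > th:
                x = nn.max_pool2d(x, h // th, h // th, 0)
            feats.append(x)
        logits = nn.concat([self.wconv[i](f) for i, f in enumerate(feats)], 1)
        w = nn.softmax(self.wmerge(logits), axis=1)
        out = feats[0] * w[:, 0:1]
        for i in range(1, self.nlev):
            out = out + feats[i] * w[:, i : i + 1]
        if self.expand is not None:
            out = self.expand(out)
        return out


# ---------------------------------------------------------------------------
# heads
# ---------------------------------------------------------------------------


class Proto(nn.Module):
    """Prototype-mask generator at 1/4 input resolution.

    ``pre``/``post`` control how many 3x3 refinement convolutions run before
    and after the learned 2x upsampling.  The lead head uses a deeper stack
    (2/2) — it is the one used at inference — while the auxiliary head keeps
    the minimal 1/1 form, serving only as deep supervision during training.
    """

    def __init__(self, c1, c_=256, c2=32, pre=1, post=1, rng=None):
        super().__init__()
        convs = [Conv(c1, c_, 3, rng=rng)]
        convs += [Conv(c_, c_, 3, rng=rng) for _ in range(pre - 1)]
        self.pre = convs
        self.upsample = nn.ConvTranspose2dS2(c_, c_, rng=rng)
        self.post = [Conv(c_, c_, 3, rng=rng) for _ in range(post)]
        self.out = Conv(c_, c2, 1, rng=rng)

    def forward(self, x):
        for c in self.pre:
            x = c(x)
        x = self.upsample(x)
        for c in self.post:
            x = c(x)
        return self.out(x)


class _Tower(nn.Module):
    """Two 3x3 convs (second optionally grouped) and a 1x1 prediction conv."""

    def __init__(self, cin, cmid, cout, g2=1, gout=1, rng=None):
        super().__init__()
        self.seq = nn.Sequential(
            Conv(cin, cmid, 3, rng=rng),
            Conv(cmid, cmid, 3, g=g2, rng=rng),
            nn.Conv2d(cmid, cout, 1, g=gout, bias=True, rng=rng),
        )

    def forward(self, x):
        return self.seq(x)


class _DetBranch(nn.Module):
    """One scale's decoupled towers: box distribution, class, mask-coeff."""

    def __init__(self, cin, cbox, ccls, cmask, reg_max, nc, nm,
                 gbox=4, gcls=4, rng=None):
        super().__init__()
        self.box = _Tower(cin, cbox, 4 * reg_max, g2=gbox, gout=gbox, rng=rng)
        self.cls = _Tower(cin, ccls, nc, g2=gcls, gout=1, rng=rng)
        self.mask = _Tower(cin, cmask, nm, g2=1, gout=1, rng=rng)

    def forward(self, x):
        return self.box(x), self.cls(x), self.mask(x)


class Segment(nn.Module):
    """Single-path decoupled segmentation head over three scales.

    Per scale: class logits (sigmoid at inference), a discretized box
    distribution (``reg_max`` bins per side, decoded by expectation), and
    mask coefficients; plus one shared prototype map at 1/4 input resolution.
    """

    def __init__(self, nc, nm, npr, ch, reg_max=16, rng=None):
        super().__init__()
        self.nc, self.nm, self.reg_max = nc, nm, reg_max
        self.nl = len(ch)
        cbox = ccls = make_divisible(max(ch[0] // 2, reg_max * 4), 4)
        cmask = max(ch[0] // 4, nm)
        self.proto = Proto(ch[0], npr, nm, pre=2, post=2, rng=rng)
        self.branches = [
            _DetBranch(c, cbox, ccls, cmask, reg_max, nc, nm, rng=rng) for c in ch
        ]
        # frozen distribution-expectation bins (not a trainable parameter)
        self.dfl_bins = np.arange(reg_max, dtype=np.float32)

    def forward(self, xs):
        protos = self.proto(xs[0])
        outs = [self.branches[i](x) for i, x in enumerate(xs)]
        return {"scales": outs, "protos": protos}


class DualDSegment(nn.Module):
    """Dual-branch segmentation head (auxiliary + lead).

    Takes six feature maps: three from the auxiliary reversible branch and
    three from the lead branch; each triplet gets its own decoupled towers
    and prototype generator, and only the lead outputs survive at inference.
    Tower widths: box/cls/mask towers at half their branch's P3 width
    (grouped second convolutions), except the auxiliary box towers, which
    keep full width — they carry the deep box supervision.
    """

    def __init__(self, nc, nm, npr, ch, reg_max=16, rng=None):
        super().__init__()
        self.nc, self.nm, self.reg_max = nc, nm, reg_max
        self.nl = len(ch) // 2
        ch_aux, ch_lead = ch[: self.nl], ch[self.nl :]
        cl = make_divisible(max(ch_lead[0] // 2, reg_max * 4), 4)
        cm_aux = max(ch_aux[0] // 2, nm)
        cm_lead = max(ch_lead[0] // 2, nm)
        self.proto_aux = Proto(ch_aux[0], npr, nm, pre=1, post=1, rng=rng)
        self.proto_lead = Proto(ch_lead[0], npr, nm, pre=2, post=2, rng=rng)
        self.aux = [
            _DetBranch(c, ch_aux[0], cl, cm_aux, reg_max, nc, nm,
                       gbox=4, gcls=4, rng=rng)
            for c in ch_aux
        ]
        self.lead = [
            _DetBranch(c, cl, cl, cm_lead, reg_max, nc, nm, gbox=4, gcls=4, rng=rng)
            for c in ch_lead
        ]
        self.dfl_bins = np.arange(reg_max, dtype=np.float32)

    def forward(self, xs):
        xs_aux, xs_lead = xs[: self.nl], xs[self.nl :]
        return {
            "aux": {
                "scales": [self.aux[i](x) for i, x in enumerate(xs_aux)],
                "protos": self.proto_aux(xs_aux[0]),
            },
            "scales": [self.lead[i](x) for i, x in enumerate(xs_lead)],
            "protos": self.proto_lead(xs_lead[0]),
        }
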