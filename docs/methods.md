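# Methods

## The re-parameterization algebra

The package's central object is the equivalence between a multi-branch
convolutional structure and a single convolution. All six transforms in
`mfdseg.reparam` are exact identities of linear algebra, not approximations;
the test suite asserts them to 1e-9 in double precision over random
geometries, and the block- and model-level checks hold to float32 rounding.

Numerical and semantic choices that make the algebra exact everywhere
(including image borders):

- **BN epsilon.** The batch-norm standard deviation is defined as
  `sqrt(var + eps)` with `eps = 1e-3` throughout (training, inference and
  fusion). Fusion correctness only requires the *same* sigma on both sides,
  so the value is a free parameter; 1e-3 is the convention of the detector
  family this backbone descends from.
- **Bias-free convolutions before BN.** Every convolution followed by a BN
  carries no independent bias; `fuse_conv_bn` still accepts one for
  generality.
- **Average pooling divides by K² everywhere.** Only this border convention
  makes the pooling-as-convolution transform exact; it deviates from the
  `count_include_pad=False` default of some libraries and is applied
  consistently in the trainable blocks too.
- **Sequential-branch border semantics.** Folding a biased 1×1 stage into a
  following K×K convolution is exact in the interior but not under naive
  zero-padding of the intermediate map: the padding ring must carry the
  first stage's *zero-input response* (what that stage would produce on the
  zero-padded input), not zeros. The trainable MFE block pads its
  intermediate map with exactly that per-channel constant — which is why its
  batch norm there keeps batch statistics differentiable — so the fused and
  multi-branch forwards agree at every pixel. The printed bias rule for this
  merge in some descriptions (summing the *first* factor's kernel) does not
  reproduce the staged forward; the implementation uses the rule forced by
  forward equivalence: `b'_d = b2_d + Σ_{e,i,j} F2[d,e,i,j] · b1_e`.
- **Pooling-as-convolution kernel.** A K×K average-pooling window is the
  diagonal convolution with every kernel entry `1/K²` on the matching
  channel. (A center-only kernel with weight `1/(H·W)` would implement
  *global* average pooling instead and is not what the pooling branch does.)
  Even pooling windows are rejected — there is no centered embedding for
  them.
- Kernel indices are 0-based; the centered index of an odd K×K kernel is
  `K//2`.

## The MFE block

`MFEConfig(in_channels, out_channels, kernel=3, alpha=1.0)`; the sequential
branch's intermediate width is `round(alpha * in_channels)` (half-up, at
least 1). The block is stride-1 by design; downsampling is the SD module's
job. The identity/residual path deliberately sits *outside* the block — the
bottleneck that hosts it adds its own shortcut — so the fused form stays a
single convolution. Fusion uses inference (running) BN statistics; fusing
mid-batch statistics is undefined and an already-deployed block refuses to
fuse again (`ModeError`).

Parameter accounting (per block, K=3, alpha=1, C_in=C_out=C): training form
`21C² + 10C`, deployed form `C(9C + 1)` — the deployed cost is exactly that
of the plain convolution it replaces (plus bias).

## The SD module

1×1 convolution + BN + SiLU (channels only), then K×K depthwise strided
convolution + BN with groups equal to the output channel count (space only).
No activation follows the second BN, matching the structure it was designed
with; a flag exposes one for ablation. For every C₁ ≥ 2 the module is
cheaper than a standard strided 3×3 convolution + BN (swept exhaustively
over C₁, C₂ ≤ 256 in the tests).

## Architecture variants and their accounting

The four bundled configs (`zoo/*.yaml`) encode, stage by stage, the
dual-branch segmentation baseline and the three variants built from it
(MFE-only, SD-only, full model). The backbone/neck/auxiliary-branch layout
follows the public GELAN/CSP dual-branch design, which reproduces the
published complexity of its detection form to within 0.1%. The head
internals and the exact MFE/SD placements are not published anywhere in
reusable form; where a choice was open, this package fixes it by requiring
the *reported complexity budget* of each variant to be met, and records the
result explicitly in the config files so every placement is auditable:

- lead head towers at half the P3 width with grouped (g=4) second
  convolutions; auxiliary box towers at full width; mask-coefficient towers
  at half width; prototype generators with `npr=256`, a learned 2× upsample,
  a minimal (1 conv before / 1 after) stack on the auxiliary side and a
  deeper (2/2) stack on the lead side — the branch actually used at
  inference;
- MFE conversion: bottleneck-level in the first backbone stage and the P4
  neck stage, full-stage in the deepest lead stage and throughout the
  auxiliary branch (`alpha = 1`);
- SD at all six hybrid downsampling positions plus the first neck
  downsampler; ASFF fusion of the three lead scales with weight-projection
  width 4 and a 3×3 expand convolution per scale (grouped at P5).

With these choices the baseline counts 57.47 M parameters / 365.7 GFLOPs,
the MFE-only form 65.59 M, the SD-only form 59.29 M / 390.0 GFLOPs, and the
deployed full model 59.14 M / 389.4 GFLOPs. One bookkeeping identity is
worth stating: since a fused MFE block has strictly fewer parameters than
the unit it replaces, the deployed full model is necessarily *lighter* than
the SD-only variant; a deployed count above it is not realizable under
lossless fusion.

**FLOP convention.** One multiply–accumulate counts as two operations; only
convolutions (including transposed ones, at their true MAC cost) are
counted. Normalization, activations and resampling contribute well under
0.1% and are omitted. Profiling propagates one forward at a reduced probe
resolution and rescales spatially — exact here because every feature map's
extent scales with the input side.

## Training protocol

Defaults mirror the reference protocol: SGD (momentum 0.937, weight decay
5e-4), initial learning rate 0.01 under cosine annealing with a short
warmup, 200 epochs, batch 8, image size 640, mask downsampling ratio 4, no
augmentation, seed 42, early-stopping patience 50, and n=3 repeats
(seeds 42/43/44) for mean ± half-range reporting.

Label assignment is task-aligned: anchors inside a truth box compete by
`score^0.5 · IoU^6`, each truth keeps its top-10 candidates, and soft class
targets are the per-truth-normalized alignment scaled by the best IoU. The
composite loss weighs `7.5·(1−IoU) + 1.5·DFL + 0.5·BCE(cls) + 2.5·BCE(mask)`;
box sides are discretized over 16 bins and decoded by expectation; the mask
term is evaluated at 1/4 input resolution, cropped to the truth box and
normalized by box area. The operating point for reported precision/recall
is the maximum-F1 confidence along the PR sweep, and AP50 uses all-point
(continuous) interpolation — stated because comparability between
implementations hinges on it. Greedy matching breaks IoU ties toward the
lower truth index, so evaluation is deterministic.

## Desk-scale experiment

Full-scale training of a 57–67 M-parameter model is far outside CPU budgets,
so trainability is demonstrated with the `tiny` config (0.52 M parameters:
same design vocabulary — MFE stages, SD downsamplers, ASFF fusion,
prototype-mask head — at a fraction of width/depth) on 200 synthetic
160×160 scenes cycling the four regimes, split 7:3, 40 epochs from scratch
(~8 CPU-minutes). It reaches box mAP50 ≈ 0.93 and mask mAP50 ≈ 0.85 on the
held-out split. Problem sizes were chosen so the whole experiment is a
routine test-suite run.

## What the synthetic scenes do and do not show

The generator emulates the *structure* of UAV orchard frames: textured
elliptical canopies over a soil/grass background, density/occlusion/scale
regimes, instance masks consistent with their polygons, full determinism
under a seed. It does not emulate real foliage texture statistics,
illumination changes, perspective distortion, inter-tree shadowing or
sensor noise. Passing the training criterion therefore shows that the
pipeline (assignment, losses, mask assembly, evaluation) can fit and
generalize within a controlled distribution — not that the model reaches
any particular accuracy on real orchards. The historical split convention
(seven of every ten shuffled items to train) is kept because it reproduces
the 700/298 partition of a 998-frame survey exactly.

## Known limitations

- The re-parameterization plan covers the MFE block only; the two-branch
  `RepConvN` units and SD modules are left in their training form at
  deployment (fusing RepConvN would be routine; SD is nonlinear between its
  two convolutions and cannot fuse).
- The autodiff engine is single-threaded NumPy; it is meant for correctness
  and desk-scale training, not throughput.
- Even pooling windows and dilated or strided 1×1 merge factors are outside
  the supported algebra (not needed by the fusion plan).
- Mask quality at very small object sizes is limited by the 1/4-resolution
  prototype grid.
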