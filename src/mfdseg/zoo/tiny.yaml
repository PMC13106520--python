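# Reduced-depth desk-scale model: same design vocabulary (MFE stages, SD
# downsamplers, ASFF fusion, decoupled segmentation head with prototypes)
# at a fraction of the width/depth, single-path head.  Intended for CPU
# training on small synthetic scenes (e.g. 160x160).
nc: 1

stages:
  - [-1, 1, Conv, [8, 3, 2]]                    # 0  P1/2
  - [-1, 1, Conv, [16, 3, 2]]                   # 1  P2/4
  - [-1, 1, RepNCSPELAN4, [24, 16, 8, 1, bottl]]   # 2
  - [-1, 1, SDDown, [32]]                       # 3  P3/8
  - [-1, 1, RepNCSPELAN4, [32, 32, 16, 1, bottl]]  # 4
  - [-1, 1, SDDown, [48]]                       # 5  P4/16
  - [-1, 1, RepNCSPELAN4, [48, 48, 24, 1, bottl]]  # 6
  - [-1, 1, SDDown, [64]]                       # 7  P5/32
  - [-1, 1, RepNCSPELAN4, [64, 64, 32, 1, bottl]]  # 8
  - [-1, 1, SPPELAN, [64, 32]]                  # 9

  - [-1, 1, Upsample, [2]]                      # 10
  - [[-1, 6], 1, Concat, [1]]                   # 11
  - [-1, 1, RepNCSPELAN4, [48, 48, 24, 1]]      # 12  P4
  - [-1, 1, Upsample, [2]]                      # 13
  - [[-1, 4], 1, Concat, [1]]                   # 14
  - [-1, 1, RepNCSPELAN4, [32, 32, 16, 1]]      # 15  P3
  - [-1, 1, SDDown, [32]]                       # 16
  - [[-1, 12], 1, Concat, [1]]                  # 17
  - [-1, 1, RepNCSPELAN4, [48, 48, 24, 1]]      # 18  P4'
  - [-1, 1, SDDown, [48]]                       # 19
  - [[-1, 9], 1, Concat, [1]]                   # 20
  - [-1, 1, RepNCSPELAN4, [64, 64, 32, 1]]      # 21  P5'

  - [[15, 18, 21], 1, ASFF3, [0, 4, none]]      # 22  fused P3
  - [[15, 18, 21], 1, ASFF3, [1, 4, none]]      # 23  fused P4
  - [[15, 18, 21], 1, ASFF3, [2, 4, none]]      # 24  fused P5

  - [[22, 23, 24], 1, Segment, [1, 8, 16]]      # 25  head (nm=8, npr=16)
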