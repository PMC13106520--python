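# Full MFD model: multi-branch MFE blocks inside the aggregation stages
# (fusible to single convolutions for deployment), spatial-channel decoupled
# downsamplers at the high-resolution positions, and adaptively weighted
# (ASFF) fusion of the three lead scales.
nc: 1

stages:
  # backbone
  - [-1, 1, Silence, []]                        # 0
  - [-1, 1, Conv, [64, 3, 2]]                   # 1  P1/2
  - [-1, 1, Conv, [128, 3, 2]]                  # 2  P2/4
  - [-1, 1, RepNCSPELAN4, [256, 128, 64, 1, repconv]] # 3
  - [-1, 1, SDDown, [256]]                      # 4  P3/8
  - [-1, 1, RepNCSPELAN4, [512, 256, 128, 1]]   # 5
  - [-1, 1, SDDown, [512]]                      # 6  P4/16
  - [-1, 1, RepNCSPELAN4, [512, 512, 256, 1]]   # 7
  - [-1, 1, SDDown, [512]]                      # 8  P5/32
  - [-1, 1, RepNCSPELAN4, [512, 512, 256, 1]]   # 9

  # neck (top-down then bottom-up)
  - [-1, 1, SPPELAN, [512, 256]]                # 10
  - [-1, 1, Upsample, [2]]                      # 11
  - [[-1, 7], 1, Concat, [1]]                   # 12
  - [-1, 1, RepNCSPELAN4, [512, 512, 256, 1]]   # 13
  - [-1, 1, Upsample, [2]]                      # 14
  - [[-1, 5], 1, Concat, [1]]                   # 15
  - [-1, 1, RepNCSPELAN4, [256, 256, 128, 1]]   # 16  lead P3/8
  - [-1, 1, SDDown, [256]]                      # 17
  - [[-1, 13], 1, Concat, [1]]                  # 18
  - [-1, 1, RepNCSPELAN4, [512, 512, 256, 1, repconv]] # 19  lead P4/16
  - [-1, 1, Conv, [512, 3, 2]]                  # 20
  - [[-1, 10], 1, Concat, [1]]                  # 21
  - [-1, 1, RepNCSPELAN4, [512, 512, 256, 1, all]]    # 22  lead P5/32

  # adaptively weighted cross-scale fusion of the lead pyramid
  - [[16, 19, 22], 1, ASFF3, [0, 4, 3x3]]       # 23  fused P3
  - [[16, 19, 22], 1, ASFF3, [1, 4, 3x3]]       # 24  fused P4
  - [[16, 19, 22], 1, ASFF3, [2, 4, 3x3g4]]     # 25  fused P5

  # auxiliary reversible branch
  - [5, 1, CBLinear, [[256]]]                   # 26
  - [7, 1, CBLinear, [[256, 512]]]              # 27
  - [9, 1, CBLinear, [[256, 512, 512]]]         # 28
  - [0, 1, Conv, [64, 3, 2]]                    # 29  P1/2
  - [-1, 1, Conv, [128, 3, 2]]                  # 30  P2/4
  - [-1, 1, RepNCSPELAN4, [256, 128, 64, 1, all]]     # 31
  - [-1, 1, SDDown, [256]]                      # 32  P3/8
  - [[26, 27, 28, -1], 1, CBFuse, [[0, 0, 0]]]  # 33
  - [-1, 1, RepNCSPELAN4, [512, 256, 128, 1, all]]    # 34  aux P3
  - [-1, 1, SDDown, [512]]                      # 35  P4/16
  - [[27, 28, -1], 1, CBFuse, [[1, 1]]]         # 36
  - [-1, 1, RepNCSPELAN4, [512, 512, 256, 1, all]]    # 37  aux P4
  - [-1, 1, SDDown, [512]]                      # 38  P5/32
  - [[28, -1], 1, CBFuse, [[2]]]                # 39
  - [-1, 1, RepNCSPELAN4, [512, 512, 256, 1, all]]    # 40  aux P5

  # dual decoupled segmentation head: aux (34,37,40) + fused lead (23,24,25)
  - [[34, 37, 40, 23, 24, 25], 1, DualDSegment, [1, 32, 256]]  # 41
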