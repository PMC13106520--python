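# MFE-only ablation: multi-branch MFE blocks inside selected aggregation stages
# (the re-parameterizable bottleneck convolution in the first backbone stage and
# the P4 neck stage; full-stage conversion in the deepest lead stage and
# throughout the auxiliary branch); downsampling unchanged.
# Rows: [from, repeats, module, args]
nc: 1

stages:
  # backbone
  - [-1, 1, Silence, []]                        # 0
  - [-1, 1, Conv, [64, 3, 2]]                   # 1  P1/2
  - [-1, 1, Conv, [128, 3, 2]]                  # 2  P2/4
  - [-1, 1, RepNCSPELAN4, [256, 128, 64, 1, repconv]] # 3
  - [-1, 1, ADown, [256]]                       # 4  P3/8
  - [-1, 1, RepNCSPELAN4, [512, 256, 128, 1]]   # 5
  - [-1, 1, ADown, [512]]                       # 6  P4/16
  - [-1, 1, RepNCSPELAN4, [512, 512, 256, 1]]   # 7
  - [-1, 1, ADown, [512]]                       # 8  P5/32
  - [-1, 1, RepNCSPELAN4, [512, 512, 256, 1]]   # 9

  # neck (top-down then bottom-up)
  - [-1, 1, SPPELAN, [512, 256]]                # 10
  - [-1, 1, Upsample, [2]]                      # 11
  - [[-1, 7], 1, Concat, [1]]                   # 12
  - [-1, 1, RepNCSPELAN4, [512, 512, 256, 1]]   # 13
  - [-1, 1, Upsample, [2]]                      # 14
  - [[-1, 5], 1, Concat, [1]]                   # 15
  - [-1, 1, RepNCSPELAN4, [256, 256, 128, 1]]   # 16  lead P3/8
  - [-1, 1, Conv, [256, 3, 2]]                  # 17
  - [[-1, 13], 1, Concat, [1]]                  # 18
  - [-1, 1, RepNCSPELAN4, [512, 512, 256, 1, repconv]] # 19  lead P4/16
  - [-1, 1, Conv, [512, 3, 2]]                  # 20
  - [[-1, 10], 1, Concat, [1]]                  # 21
  - [-1, 1, RepNCSPELAN4, [512, 512, 256, 1, all]]    # 22  lead P5/32

  # auxiliary reversible branch
  - [5, 1, CBLinear, [[256]]]                   # 23
  - [7, 1, CBLinear, [[256, 512]]]              # 24
  - [9, 1, CBLinear, [[256, 512, 512]]]         # 25
  - [0, 1, Conv, [64, 3, 2]]                    # 26  P1/2
  - [-1, 1, Conv, [128, 3, 2]]                  # 27  P2/4
  - [-1, 1, RepNCSPELAN4, [256, 128, 64, 1, all]]     # 28
  - [-1, 1, ADown, [256]]                       # 29  P3/8
  - [[23, 24, 25, -1], 1, CBFuse, [[0, 0, 0]]]  # 30
  - [-1, 1, RepNCSPELAN4, [512, 256, 128, 1, all]]    # 31  aux P3
  - [-1, 1, ADown, [512]]                       # 32  P4/16
  - [[24, 25, -1], 1, CBFuse, [[1, 1]]]         # 33
  - [-1, 1, RepNCSPELAN4, [512, 512, 256, 1, all]]    # 34  aux P4
  - [-1, 1, ADown, [512]]                       # 35  P5/32
  - [[25, -1], 1, CBFuse, [[2]]]                # 36
  - [-1, 1, RepNCSPELAN4, [512, 512, 256, 1, all]]    # 37  aux P5

  # dual decoupled segmentation head: aux (31,34,37) + lead (16,19,22)
  - [[31, 34, 37, 16, 19, 22], 1, DualDSegment, [1, 32, 256]]  # 38
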