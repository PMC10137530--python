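# YOLOv5s baseline: Focus entry, C3 stages, SPP(5,9,13), standard PAN head.
# Nominal channels; the "s" scale applies depth 0.33 / width 0.50 multiples.
nc: 20
depth_multiple: 0.33
width_multiple: 0.50
anchors:
  - [10, 13, 16, 30, 33, 23]        # P3/8
  - [30, 61, 62, 45, 59, 119]       # P4/16
  - [116, 90, 156, 198, 373, 326]   # P5/32
backbone:
  - [-1, 1, Focus, [64, 3]]         # 0
  - [-1, 1, Conv, [128, 3, 2]]      # 1
  - [-1, 3, C3, [128]]              # 2
  - [-1, 1, Conv, [256, 3, 2]]      # 3
  - [-1, 9, C3, [256]]              # 4
  - [-1, 1, Conv, [512, 3, 2]]      # 5
  - [-1, 9, C3, [512]]              # 6
  - [-1, 1, Conv, [1024, 3, 2]]     # 7
  - [-1, 1, SPP, [1024, [5, 9, 13]]]  # 8
  - [-1, 3, C3, [1024, false]]      # 9
head:
  - [-1, 1, Conv, [512, 1, 1]]      # 10
  - [-1, 1, Upsample, [null, 2, nearest]]  # 11
  - [[-1, 6], 1, Concat, [1]]       # 12
  - [-1, 3, C3, [512, false]]       # 13
  - [-1, 1, Conv, [256, 1, 1]]      # 14
  - [-1, 1, Upsample, [null, 2, nearest]]  # 15
  - [[-1, 4], 1, Concat, [1]]       # 16
  - [-1, 3, C3, [256, false]]       # 17
  - [-1, 1, Conv, [256, 3, 2]]      # 18
  - [[-1, 14], 1, Concat, [1]]      # 19
  - [-1, 3, C3, [512, false]]       # 20
  - [-1, 1, Conv, [512, 3, 2]]      # 21
  - [[-1, 10], 1, Concat, [1]]      # 22
  - [-1, 3, C3, [1024, false]]      # 23
  - [[17, 20, 23], 1, Detect, [nc, anchors]]  # 24
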