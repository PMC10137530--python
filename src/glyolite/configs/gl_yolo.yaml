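# GL-YOLO: YOLOv5s with CoT3 stages in the backbone (layers 2/4/6/9), a
# SimAM gate after the last head stage, and k-means++ anchors.
nc: 20
depth_multiple: 0.33
width_multiple: 0.50
anchors:
  - [137, 119, 190, 224, 304, 155]  # small scale
  - [223, 377, 331, 288, 459, 219]  # medium scale
  - [359, 459, 513, 358, 549, 545]  # large scale
backbone:
  - [-1, 1, Focus, [64, 3]]         # 0
  - [-1, 1, Conv, [128, 3, 2]]      # 1
  - [-1, 3, CoT3, [128]]            # 2
  - [-1, 1, Conv, [256, 3, 2]]      # 3
  - [-1, 9, CoT3, [256]]            # 4
  - [-1, 1, Conv, [512, 3, 2]]      # 5
  - [-1, 9, CoT3, [512]]            # 6
  - [-1, 1, Conv, [1024, 3, 2]]     # 7
  - [-1, 1, SPP, [1024, [5, 9, 13]]]  # 8
  - [-1, 3, CoT3, [1024, false]]    # 9
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
  - [-1, 1, SimAM, [1024]]          # 24
  - [[17, 20, 24], 1, Detect, [nc, anchors]]  # 25
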