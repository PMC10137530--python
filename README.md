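# glyolite

Config-driven implementations of a lightweight fallen-person detector
family — a YOLOv5s baseline, **GL-YOLO** (contextual-transformer backbone +
parameter-free attention), and **GL-YOLO-Lite** (stem entry, re-parameterisable
rep blocks, lightweight 128-channel head) — in pure NumPy, for researchers and
engineers who want to study, verify and rank these architectures at desk
scale: exact parameter/FLOP accounting, certified structural
re-parameterisation, k-means++ anchors, the BCE/CIoU training objective,
detection metrics, and TOPSIS composite ranking.

Falls are a leading cause of serious injury among the elderly, and
camera-based fall detection needs models that are simultaneously accurate
and cheap enough for real-time and mobile use. The networks here are
single-stage anchor-based detectors: an image letterboxed to 640×640 passes
a backbone and PAN-style head, and three detection scales regress offsets
against anchor priors. The distinctive ingredients:

- **CoT3 stages** replace CSP bottleneck convs with contextual-transformer
  attention: keys pass a k×k group conv (static context K_static), the
  attention matrix A = [K_static, Q]·W_θ·W_δ is produced by two 1×1 convs on
  the concatenated stack, and the dynamic context is the local matrix
  multiplication K_dynamic = V ⊛ A (softmax-weighted aggregation of values
  over each k×k neighbourhood); the block outputs K_static + K_dynamic.
- **SimAM** gates every neuron by the logistic of its inverse minimal
  energy e\*, computed in closed form from its channel's statistics —
  three-dimensional attention with zero added parameters.
- **Stem & rep blocks**: the space-to-depth focus entry (whose conv costs
  ~3.9× a plain stride-2 conv: 3488 vs 896 parameters, 357.2M vs 91.8M
  FLOPs) is replaced by a stride-4 stem of standard conv units; backbone
  downsampling convs become multi-branch rep blocks that collapse at deploy
  time into single 3×3 convolutions with *certified* output equivalence.
- **Model selection** uses TOPSIS over (mAP@0.5, FPS, parameters, GFLOPs)
  with weights (0.4, 0.2, 0.2, 0.2).

Everything — including the autograd engine behind training — is NumPy;
there is no deep-learning framework dependency.

## Worked example

Profile the deployed (re-parameterised) GL-YOLO-Lite at 20 classes:

```
$ glyolite profile --cfg gl_yolo_lite --classes 20 --deploy
...
  23 C3                22912        2252800
  24 SimAM                 0              0
  25 Detect            14625       10080000
total: 4419073 params (4.42 M), 3.4 GFLOPs @ 640
```

4.42 M parameters and 3.4 GFLOPs (two ops per multiply-accumulate at
640×640) — against 7.11 M / 16.4 for the YOLOv5s baseline at the same class
count (`glyolite profile --cfg yolov5s --classes 20`): a 38 % parameter and
79 % compute reduction. Rank the nine models of the bundled fall-detection
benchmark table on the four weighted criteria:

```
$ glyolite rank --bundled fpdd
method,closeness,rank
YOLOv5-mbv3-small,0.435585,7
...
YOLOv5s-Ghost,0.537934,2
GL-YOLO,0.507247,3
GL-YOLO-Lite,0.578998,1
```

GL-YOLO-Lite's closeness to the ideal point (0.579) ranks it first —
closest to the best achievable trade-off of accuracy, speed and cost.

An end-to-end run on synthetic data (generate → cluster anchors → train a
narrow variant → evaluate) takes about two minutes on one CPU:

```bash
glyolite gen-data ds --n-images 50 --image-size 320 --seed 11
glyolite train ds --out-dir runs/demo --img 320 --epochs 40 \
    --batch-size 10 --width-multiple 0.125
glyolite evaluate runs/demo/checkpoint.npz ds --split train
{"precision": 0.975, "recall": 0.975, "f1": 0.975, "map50": 0.967}
```

`glyolite export runs/demo/checkpoint.npz --deploy` collapses the rep
blocks and writes a JSON equivalence report (max abs deviation, parameters
before/after).

See `docs/methods.md` for the model conventions, calibration choices and
limitations.

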