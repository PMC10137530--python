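# Methods

`glyolite` implements a family of single-stage, anchor-based fallen-person
detectors — a YOLOv5s baseline, GL-YOLO (contextual-transformer backbone plus
a parameter-free attention gate), and GL-YOLO-Lite (stem entry, rep blocks,
lightweight head) — together with the surrounding method stack: k-means++
anchor generation, the BCE/CIoU training objective, detection metrics, an
analytic parameter/FLOP calculus, structural re-parameterisation, and TOPSIS
composite ranking. This note records the model assumptions, the design
choices made where the architecture description left freedom, the numerical
conventions, and what the synthetic-data experiments do and do not show.

## Network assembly

Every network is a declarative layer table (YAML rows `[from, number,
module, args]`) mirroring the published architecture tables; the builder
applies depth multiple 0.33 and width multiple 0.50 (the "s" scale, channels
rounded to multiples of 8) to the tables' nominal values. The block
vocabulary is:

- **Conv** — Conv2d (no bias) + BatchNorm (eps 1e-3, momentum 0.03) + SiLU.
- **Focus** — space-to-depth slicing (fixed lattice order even/even,
  odd/even, even/odd, odd/odd — any fixed order is valid since a conv
  follows) + a conv unit; an exact bijection before the conv, asserted by a
  reconstruction test.
- **Stem** — the focus replacement, overall stride 4: a 3×3/s2 conv, then a
  dual branch (1×1 → 3×3/s2 conv path ‖ 2×2/s2 max-pool), concatenated and
  projected by a 1×1 conv. The wiring is described only in words in the
  source material; this realisation was selected because it reproduces the
  published ablation cell (7.09 M parameters, 4.5 GFLOPs) — in particular
  the ~4× GFLOPs drop forces the stride-4 reading, under which detection
  strides double to 16/32/64 and anchors are re-assigned to scales by
  ascending area.
- **C3 / CoT3** — the CSP split/merge stage; in CoT3 the bottleneck's 3×3
  conv is replaced by a contextual-transformer (CoT) block.
- **CoT** — keys pass a 3×3 group conv (groups 4, BN+ReLU) giving the static
  context; the attention matrix comes from two 1×1 convs (reduction factor
  4; ReLU after the first only) applied to the channel-concatenated
  (static, query) stack; the value embedding is a plain linear 1×1 map (no
  norm, no bias); values are aggregated per position over the 3×3
  neighbourhood with softmax weights (one head); static and dynamic context
  fuse by addition. The unstated internals (groups, reduction, the absence
  of norm/bias on the value and attention-expansion maps, additive fusion)
  were calibrated so that whole-model parameter counts reproduce the
  published 7.08 M / 4.42 M / 4.41 M cells; the vectorised aggregation is
  tested against a naive per-position loop at 1e-5.
- **SimAM** — parameter-free attention. Each neuron's gate is the logistic
  of its inverse minimal separation energy, computed with *exact
  leave-one-out* channel statistics (vectorised from channel sums, so still
  O(HW)). We use the exact form rather than the common shared-statistics
  approximation because the closed form then matches independent numerical
  minimisation of the energy to better than 1e-6 even on tiny channels;
  for large H·W the two coincide. λ defaults to 1e-4 and is exposed.
- **SPP** — parallel max-pools (5, 9, 13, stride 1, same padding) plus
  identity, concatenated and projected.
- **Rep** — train-time 3×3+BN and 1×1+BN branches (plus an identity BN
  branch only when input channels = output channels and stride 1 — the
  backbone's stride-2 rep blocks therefore have two branches), SiLU after
  the sum. Deploy mode collapses the block to a single 3×3 conv with bias;
  equivalence is pre-activation and exact algebraically, asserted at 1e-5
  per block and 1e-4 for the whole model on a 640×640 input in single
  precision (accumulation across ~25 layers).
- **Detect** — one 1×1 conv per scale to 3·(5+nc) channels; grid decode
  `xy = (2σ(t)−0.5+cell)·stride`, `wh = (2σ(t))²·anchor`; confidence
  σ(obj)·σ(cls) with a strict `>` threshold; per-class NMS at IoU 0.45.
  The class term is trained even for a single class so the decoded product
  confidence is calibrated.

## Counting conventions

Parameters of a bare conv are `n·(h·w·c+1)`; convention-A FLOPs are
`H·W·n·(h·w·c+1)` on the output map (one op per multiply-accumulate plus the
bias add). The whole-model profiler (convention B, used for the GFLOPs
tables at 640×640) counts two ops per multiply-accumulate over conv kernels
*and* the CoT neighbourhood aggregation (a genuine k²·C-MAC-per-position
contraction), with normalisation, activations, pooling, softmax and
upsampling at zero — the convention under which every published
parameter/GFLOPs table cell reproduces exactly (7.11/16.4, 7.08/16.4,
7.09/4.5, 4.42/3.4, 4.41/3.3). Models containing rep blocks are reported in
deploy (fused) form, which is the only reading consistent with the
published ablation (adding rep branches leaves the printed count unchanged).
The published tables themselves carry one internal inconsistency (7.08 vs
7.07 for the same configuration; our exact count is 7,083,649) which the
profiler does not attempt to force.

## Anchors

k-means++ (D²-sampled seeding, then Lloyd iterations; seed 0, max 300
iterations, tolerance 1e-6) on absolute (w, h) pairs at the network input
scale with Euclidean distance — deliberately not the IoU distance some YOLO
tools use, since plain k-means++ is the stated method and the published
anchors are in input pixels. Normalised label dimensions are multiplied by
the input size; whether the original pipeline clustered raw-pixel or
letterboxed-scale dimensions is unstated, and the letterboxed input scale is
chosen here. Inertia is non-increasing across iterations (asserted); on
small well-separated instances the result matches exhaustive-assignment
enumeration, and on larger instances it cross-checks against scikit-learn.

## Loss and training

Classification and objectness use natural-log BCE (probability clamp 1e-7;
on logits, the stable softplus form); the box term is complete IoU with the
baseline framework's conventions: anchor matching by wh ratio < 4 with
up-to-two neighbour-cell duplication, objectness targets equal to the
(clipped, detached) CIoU of the matched prediction, per-scale objectness
balance 4.0/1.0/0.4, and component weights box 0.05 / obj 1.0 / cls 0.5.
Training uses Adam with the published recipe defaults — initial learning
rate 0.01, first-moment coefficient 0.937 (the recipe lists "momentum"
alongside Adam; it is read as β₁), weight decay 5e-4, 300 epochs nominal.

Because the stack holds ~60 batch-norm layers trained with small batches,
the momentum-averaged running statistics lag the final weights enough that
eval-mode outputs can collapse even when train-mode predictions are
confident. The loop therefore ends with a precise-BN recalibration pass:
running statistics are replaced by a cumulative average of batch statistics
over two forward sweeps of the training set under the final weights.

## Synthetic data

The generator emulates the *structure* of the single-class fallen-person
dataset: one class ("fall", id 0), about one labelled box per image, YOLO
txt labels, and an 80/16/4 train/test/val split (deterministic under a
seed; partitions disjoint and exhaustive, sizes within one file of the
ratios). Images are textured low-frequency noise backgrounds with one
high-contrast rotated bar or ellipse per target — orientation jitter
included, human subjects deliberately not. Targets span roughly 18–45 % of
the frame. The contract is "a small detector can learn them": passing the
end-to-end test shows the loss, assignment, decode, NMS and metric pipeline
is self-consistent; it says nothing about accuracy on photographs of fallen
people, which requires the real dataset and full-scale training.

Desk-scale problem sizes: the end-to-end training check uses 50 images at
320 px (vs the published 640), 40 epochs, batch 10, on a width-0.125
variant of the lightweight model with anchors re-clustered on the generated
labels; it reaches train-split mAP@0.5 ≈ 0.98 in about two minutes on one
CPU. Unit fixtures use 64–128 px inputs. Note the deepest detection scale
has stride 64, so inputs must be at least 128 px for the attention gate to
be defined.

## Metrics and ranking

Precision/recall/F1 follow the standard confusion arithmetic (F1 = 0 when
P+R = 0; all-zero counts flagged); matching is greedy by descending
confidence at IoU ≥ 0.5, one detection per ground-truth box. AP integrates
the precision envelope at 101 recall points, evaluated as "max precision at
recall ≥ r" so that detections identical to the ground truth score exactly
1.0; the 11-point variant is exposed via the `points` argument.

TOPSIS ranks models on (mAP@0.5, FPS, parameters, GFLOPs) with weights
(0.4, 0.2, 0.2, 0.2), the first two benefit and the last two cost criteria,
FPS-GPU by default. The published description does not pin the
normalisation chain, and the published 6-decimal score vectors are not
reproducible by any standard formulation we tested (vector/sum/max/min-max/
z-score normalisations × cost re-orientations × L1/L2/L∞/weighted
distances × either FPS column, including freely fitted weights — best
attainable deviation ≈ 0.07 on some row). The shipped default is the
closest coherent chain found: min-max re-orientation per criterion, vector
normalisation, weighting, and weighted-Euclidean distances; it reproduces
the top-ranked model's published closeness to within 1 % (0.578998 vs
0.573961; 0.566097 vs 0.563583) and its first-place rank on both bundled
tables. The classic vector-normalisation chain and the plain min-max chain
remain available (`variant="vector" | "minmax"`); regression tests pin the
shipped variant's outputs, and the unresolved gap to the printed 6-decimal
scores is asserted honestly in the acceptance suite rather than papered
over.

## Degenerate inputs and numerics

Focus rejects odd spatial dims; Stem rejects dims not divisible by 4; SimAM
requires ≥ 2 neurons per channel and positive λ; SPP and CoT reject even
kernels; rep collapse rejects non-positive BN variance; k-means++ rejects
k above the number of distinct boxes and all-identical boxes; label parsing
reports file and line for malformed or out-of-range rows; VOC boxes
(1-based inclusive) convert to 0-based half-open pixel coordinates.
Everything runs in float32; equivalence tolerances are stated above; BCE
clamps probabilities at 1e-7; max-pool padding uses −∞; ties in max-pool
backward route to the first maximum.

## Known limitations

- No GPU path and no im2col caching: full-scale (640 px, width-0.5)
  training is out of reach; the package trains reduced variants only.
- No augmentation (mosaic, HSV, flips) and no EMA; the training loop is a
  minimal faithful objective, not a performance recipe.
- Published mAP/FPS/latency figures require the external datasets, GPU
  training and specific hardware; they are inputs to the ranking stage
  here, never reproduced quantities.
- The letterbox resize uses bilinear interpolation via Pillow; sub-pixel
  differences from other resize kernels are irrelevant at the tested
  tolerances but would matter for weight-porting, which is unsupported.
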