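# Methods

## Scope

The package reconstructs a lightweight single-stage instance segmenter for
crop heads and the full methodology used to evaluate it: the three
architecture modules (deformable-attention C2f, ADown, small-object pyramid),
hardware-independent profiling, the dataset pipeline, and the metric suite.
Training is deliberately out of scope: the original field dataset is not
public, and every claim the package verifies — the parameter/FLOP ablation
ladder, the structural behaviour of each block, the correctness of the metric
implementations — is reachable without fitting weights. Forward passes run on
deterministically seeded (untrained) weights unless user weights are loaded.

## Baseline reconstruction

The baseline is the nano variant of the standard one-stage segmentation
architecture: depth multiple 1/3, width multiple 1/4, channel plan
16/32/64/128/256, CSP backbone (stem, four stages of strided conv + C2f,
SPPF), PAFPN neck (two top-down, two bottom-up paths), decoupled anchor-free
heads at strides 8/16/32 with a 16-bin box-side distribution (DFL), one class
logit, 32 mask coefficients, and a stride-4 prototype branch (64 hidden
channels, transposed-conv upsampling, 32 prototype maps).

Counting conventions, chosen so the closed forms close against the published
profile and verified against an independent enumeration of materialized
tensors in every test run:

* convolutions followed by a norm carry no bias (the norm absorbs it);
* a norm layer owns 2·C learnable parameters; running statistics are not
  learnable and are not counted;
* the frozen DFL projection (16 fixed weights) is excluded from the
  learnable-parameter total (it moves no rounding either way);
* FLOPs are multiply-accumulates × 2 at a square input, with one bias
  operation per output element for genuinely biased layers. Transposed
  convolutions are counted kernel-per-*output*-element — four times their true
  MACs — because that is the convention of the standard profilers behind
  published model tables (it reproduces both the 8.7 G detection profile and
  the 12.6 G / 80-class segmentation profile of the reference family);
  pooling, activations, nearest upsampling and concatenation count zero.
  FFT-based branches are counted at 5·N·log2(N) per channel per transform,
  and attention from its constituent projections, sampling and logit/weighted
  sums.

With one class this yields 3,263,795 parameters (3.26 M) and 11.97 G → 12.0
GFLOPs at 640×640.

## Deformable attention (C2f-DAttention)

The deepest backbone C2f block (the 256-channel stage) is the "final C2f"
that carries attention; the operator acts on the 128-channel hidden bottleneck
branch with a residual connection and the block's fuse convolution serving as
the output projection. Design, with reconstruction choices flagged:

* q/k/v 1×1 projections, no separate output projection (3·dim² weights);
* offset network: 5×5 depthwise conv (stride = grid stride) → channel
  LayerNorm → GELU → 1×1 conv to 2 channels per offset group; offsets are
  tanh-bounded and scaled by `offset_range_factor` (default 1.0) in units of
  the reference-grid spacing;
* reference grid: centres of 2×2 cells (grid stride 2); keys/values are
  bilinearly sampled at grid + offset;
* 4 heads, 1 offset group (never stated in the source material — a
  reconstruction);
* a per-head relative-position-bias table sized for the nominal 20×20 grid
  (the stride-32 map at the 640 working resolution) and bilinearly
  interpolated at other resolutions, so the parameter count is independent of
  input size.

The added cost is 3·128² + 3,712 (offset net) + 4·39² (bias tables) = 58,948
parameters, giving 3,322,743 → 3.32 M, and ≈0.04 GFLOPs (12.0 G unchanged at
1 dp). With offsets forced to zero the operator provably reduces to attention
over the uniform downsampled grid; the test suite asserts this against an
independent loop-based oracle to 1e-5.

## ADown placement

ADown (average-pool 2×2 stride 1 → channel split → {3×3 stride-2 conv,
3×3 stride-2 max-pool + 1×1 conv} → concat) replaces the three deepest
backbone stage transitions (strides 8, 16, 32) and both neck bottom-up
downsampling convolutions. The first post-stem transition stays a plain
strided conv: replacing all four backbone transitions would save 416,000
parameters but 0.85 GFLOPs, which is inconsistent with the published ladder;
the five-site placement (−412,672 parameters, −0.68 G) reproduces both
printed columns (2.91 M, 11.3 G) and is the package's calibrated resolution
of a placement the source diagrams leave ambiguous. ADown is strictly cheaper
than the strided conv it replaces for every channel pair (asserted over a
grid in the tests).

## Small Object Enhance Pyramid

SPD-Conv folds the stride-4 backbone map (P2, 32 channels) to stride 8 by a
factor-2 space-to-depth rearrangement — a bijection, exactly invertible, so no
pixel is discarded — followed by a stride-1 3×3 CBS to 88 channels. Its output
is concatenated with the top-down feature (128 ch) and the backbone P3 (64 ch)
and aggregated by a CSP-OmniKernel block replacing the P3 fusion C2f; the
P4/P5 aggregation blocks, downstream paths and the three heads are unchanged.

CSP-OmniKernel splits the 280-channel concat in half; one half bypasses, the
other passes an OmniKernel mixer (dim 140), and a 1×1 CBS fuses back to 64
channels. The mixer has a 1×1 (+GELU) in-projection and three parallel
branches summed with the identity before a 1×1 out-projection:

* local: depthwise 1×1;
* large: depthwise 31×31 plus 1×11 and 11×1 strip convolutions;
* global: 1×1 projection → dual-domain channel attention (DCAM) → a
  frequency-based spatial gate (FSAM).

DCAM and FSAM are named but not defined in the source material; the package's
declared reconstructions are: DCAM = sigmoid channel gate from two
reduction-4 squeeze-excite MLPs reading a global-average descriptor and a mean
Fourier-magnitude descriptor; FSAM = sigmoid spatial gate from a 1×1
(C→1) conv over the high-pass-filtered feature map (Fourier coefficients
below relative frequency 1/8 removed). Channel widths (SPD width 88, mixer
dim 140, reduction 4) are calibrated so that the full model reproduces the
published +0.30 M / +3.8 G deltas: 3,209,704 → 3.21 M and 15.09 → 15.1 G.

## Post-processing

Class scores are sigmoids of the logits; boxes decode from the softmax
expectation of the 16-bin side distributions at anchor centres (i+0.5)·stride.
NMS is class-agnostic (one class), greedy by descending confidence with ties
broken by instance index. Instance masks are the sigmoid of the
coefficient-weighted prototype sum, bilinearly upsampled, letterbox-inverted
(symmetric padding, fill 114), thresholded at 0.5 and cropped to the box.
Confidence 0.25 / NMS IoU 0.7 are declared defaults — the thresholds behind
the published result tables are not stated anywhere, so none were inferred.

## Metric suite

Overlap metrics are exact pixel counts: IoU = TP/(TP+FP+FN),
Dice = 2TP/(2TP+FP+FN) (= F1 on the same counts), PA = (TP+TN)/total.
Boundaries for the Hausdorff distance are 8-connected erosion residues;
distances are Euclidean in pixels (`scipy` directed Hausdorff both ways).
Undefined ratios (zero denominators, two empty masks) are flagged and
reported as NaN, never silently 0; aggregates treat them as 0 and count the
skips.

Two deliberately distinct matchers: detection-style AP uses greedy matching
by descending confidence with each ground truth claimed once; the
universal-metric protocol (for comparisons with promptable segmenters that
need their outputs matched to targets first) uses the optimal one-to-one
assignment maximizing total IoU (`scipy` Hungarian solver, verified against
exhaustive permutation search for small instance counts). Because the
aggregation of per-pair IoU/Dice is ambiguous in published comparisons, both
per-instance means and dataset-pooled pixel counts are implemented and the
choice is an explicit report field.

AP: the all-point mode integrates the monotonized precision envelope exactly.
The 101-point mode samples the envelope on the 0:0.01:1 recall grid and
averages the 100 positive-recall samples; dropping the recall-0 sample from
the mean makes the estimator a guaranteed lower bound of the all-point area
(an Abel-summation argument: Σ floor(100·r_j)/100·Δp_j ≤ Σ r_j·Δp_j), whereas
averaging all 101 samples can exceed it when recall jumps align with the
grid. The difference from the common implementation is below (p_max − AP)/101
< 0.01. Size-stratified AP follows the ignore semantics of the COCO protocol:
out-of-range ground truth is ignored rather than removed, detections matched
to it leave the ranking, and unmatched out-of-range detections are never
false positives (small = area < 32² px at the working resolution).

## Synthetic scenes

The generator emulates the statistical structure the pipeline must survive,
not the photometry of real fields: superellipse head instances (random
aspect, exponent and orientation, radial vein-like shading) over leaf-like
clutter and smooth illumination gradients; a two-component diameter mixture
with 30% mass below 32 px (uniform 8–30 px) and a log-normal bulk (median
90 px, log-sd 0.4, clipped to 48–240 px); depth-ordered occlusion in which
later instances occlude earlier ones and annotations trace the *visible*
region only (instances reduced below 16 visible pixels are dropped). Polygons
are half-pixel contour traces whose even-odd rasterization reproduces the
mask exactly, including hole contours of occlusion rings; the YOLO-seg
writer stitches multi-segment instances into keyhole polygons. Everything is
deterministic under the recipe seed (byte-identical images and annotations).

What passing tests on these scenes shows: format conversions, matching,
aggregation and the perfect-predictor identities are implemented correctly at
realistic instance statistics. What it does not show: anything about
segmentation accuracy on real crops — the scenes carry none of the texture,
colour confusion between heads and leaves, or lighting pathology that makes
the real task hard.

## Numerical and procedural choices

* Splits sort ids before shuffling (order-invariant), allocate val/test by
  floor and give the remainder to train; 10,000 ids at 6:2:2 → 6000/2000/2000.
* Letterboxing scales by min(target/h, target/w) and pads symmetrically with
  fill 114; the inverse transform is recorded on the sample.
* Coordinates are 0-based pixels, x right / y down; polygon vertices live in
  [0, w]×[0, h]; COCO boxes are [x, y, w, h]; rasterization places pixel
  centres at integer coordinates (the scikit-image convention).
* Weight materialization is per-node seeded (He-normal convs, unit norms), so
  any graph is reproducible from one root seed.
* Profiling sizes: parameters are input-size-independent; FLOPs are reported
  at 640×640. Tests run forward passes at 64–256 px and the perfect-predictor
  identity on 200 scenes at 640 px — sizes chosen to exercise every code path
  at desk scale.

## Known limitations

* No training loop, loss, or label assigner; predictions from seeded weights
  are structurally valid but meaningless. Published accuracy numbers
  (mask precision/recall/mAP on the field dataset) are therefore outside the
  verified surface; the profiling ladder and the metric/property suites are
  the verification targets.
* DCAM/FSAM and the attention head/group counts are declared reconstructions
  constrained by the printed parameter/FLOP deltas, not by released code.
* Frames-per-second is wall-clock of the NumPy forward pass and is orders of
  magnitude below a GPU deployment; it is exposed (`measure_fps`) but never a
  comparison surface.
* The large-kernel depthwise convolution uses an FFT path whose output can
  differ from direct convolution at ~1e-4 relative tolerance.
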