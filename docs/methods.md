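# Methods

`ratpose` estimates nine anatomical landmarks of a rat filmed from the side
during treadmill locomotion — nose tip, eye, ear, front claw wrist, front
claw tip, back claw ankle, back claw palm, back claw tip, tail — and
derives joint-motion quantities (heights, gait phases, stride period) from
the tracked coordinates.  Knee and hip are deliberately excluded: under fur
they cannot be labelled reliably.  This note documents the models, the
numerical choices and the synthetic data the package is validated on.

## Cascade networks

Two structures share a *basic feature extraction* backbone operating on RGB
input: repeated blocks of two 3x3 convolutions followed by a downsampling
layer (a stride-2 3x3 convolution), then five same-size convolutions.  With
three downsamplings the feature map is 1/8 of the input (11 convolution
layers + 3 downsampling layers); the stride-4 variant drops one block
(9 + 2), trading compute for heatmap resolution.  Channel width doubles at
each downsampling from `base_channels`, capped at `max_channels` (default
4x base).  The cap, the 24-channel stage blocks of the reference
configuration, 3x3 kernels, ReLU activations and batch normalisation after
each convolution are this package's choices: cascade pose architectures in
the literature leave these free, and the widths were picked so the
reference experiment trains on one CPU.

**CCN** (cascade convolution network): four refinement stages of nine 3x3
convolutions.  Stage 1 consumes the backbone features; each later stage
consumes the channel-concatenation of the backbone features and the
previous stage's prediction, merged by a 1x1 feature-fusion convolution.
**CHN** (cascade hourglass network): two stages, each an hourglass with two
max-pool downsamplings, two nearest-neighbour upsamplings and residual
skip connections at each resolution.  Hourglass stages do not share
weights.  All stages carry their own prediction head; training supervises
every stage (*intermediate supervision*), inference reads only the last.

Under FCR (below) the previous stage's prediction is a coordinate vector,
which cannot be concatenated spatially; the stage's pre-head feature map is
fused instead.

The networks run on a small NumPy automatic-differentiation engine inside
the package (`ratpose.autodiff`).  Feature maps are channels-last; 3x3
stride-1 convolutions are lowered onto the flattened padded image so each
kernel tap is one GEMM on a contiguous slice, and every backward pass is
hand-derived and verified against central finite differences in the test
suite.  Float32 throughout training; float64 in gradient-contract tests.

## Coordinate decoders

* **FCR** — fully connected regression: one linear layer on the flattened
  stage features regresses 18 values, interpreted as coordinates
  normalised to [0, 1] by input size.  Loss: smooth L1 on coordinates.
* **HMP** — heatmap maximum position: each stage predicts 9 score maps;
  labels are Gaussian bumps and the loss is mean squared error on the
  maps.  At decode time the map is bicubically upsampled to input
  resolution and the integer argmax taken (ties: first in row-major
  order).  Accuracy is bounded by quantisation at the map stride.
* **HIR** — heatmap integral regression: softmax is applied jointly over
  each predicted map, the marginal column/row sums are weighted by their
  indices (soft-argmax), and the expected index times the stride gives
  sub-pixel input coordinates.  Differentiable end to end; loss is smooth
  L1 on the decoded coordinates of every stage.

Coordinate losses for FCR and HIR are both computed in input-pixel units so
the two decoders see the same loss scale.

### Gaussian label encoding

The label bump is `A * exp(-((x-xc)^2/(2*sx) + (y-yc)^2/(2*sy)))` with
`A = 1` and `sx = sy = 3` by default.  The width parameters enter the
denominator as `2*s` — they are used directly as variances, not squared —
which is the convention this package standardises on; anyone comparing
against kernels parameterised by a standard deviation should note the
difference.  Map and input coordinates are related by `x_map = x_in /
stride` with no half-pixel offset, making encode/decode round trips exactly
invertible for grid-aligned centres.

A softmax-based decode of an amplitude-1 bump is dominated by the uniform
background (every cell contributes `exp(0)`), so HIR round-trip properties
are stated for *sharp logits*: amplitude ~12 concentrates the softmax mass
on the bump while still spanning several cells.  Larger amplitudes snap to
the grid (quantisation), smaller ones drift to the map centroid; the test
suite pins amplitude 12, where round trips recover interior landmarks to
<0.5 input px at stride 8.  A trained HIR network is free to choose its own
logit scale, which is precisely what the coordinate loss optimises.

### Bicubic dialect

HMP upsampling uses the Keys cubic convolution kernel with `a = -0.5`
(Catmull-Rom), replicated edges, implemented as two separable interpolation
matrices.  The kernel parameter is pinned for reproducibility and checked
against a direct per-pixel evaluation oracle.

## Evaluation criterion

Pixel error is not comparable across images of differently sized or
differently distant animals.  Each landmark's error is therefore divided by
the labelled nose-eye distance of the same image (in the spirit of
head-normalised PCKh):

    error_i = dist(pred_i, label_i) / dist(nose, eye) - p,   p = 0.1

A prediction is correct iff `error_i <= 0`; the boundary case counts as
correct (the non-strict inequality is pinned deliberately — the strict
variant differs only on a measure-zero event).  Per-landmark accuracy is
the percentage of correct predictions; the report's Total is the
arithmetic mean of the nine per-landmark accuracies, rounded to one
decimal for display.  Images with non-positive nose-eye distance are
excluded and counted in the report.

## Training

Adam (lr 2e-3), batch size 4, seed-controlled shuffling and HSV colour
jitter (hue +/-0.05 turns, saturation/value +/-0.2), all configurable.
The optimiser and its settings are the package's own: with ~320 training
images an epoch is only ~80 updates, so the recipe favours many small
steps at a moderately high rate; no learning-rate schedule is used.
Inputs keep their natural unequal aspect (direct anisotropic resize, no
padding), e.g. 1056x720 acquisition frames to a 512x256 network input;
landmark targets are scaled per axis by the same factors.  Every
`eval_every_epochs` (default 2) all stages are decoded and scored on the
test set, giving per-stage accuracy curves.  Divergence (non-finite loss)
raises an error naming the epoch.

## Synthetic data

The generator renders an articulated rat silhouette in side view: capsule/
ellipse segments with distinct tones per segment (torso, head, snout, ear,
fore/hind limb segments, tail) on a flat or belt-textured background, with
Gaussian pixel noise.  Kinematics are closed-form in the gait phase:
claw tips follow a stance/swing cycle with duty factor 0.6 (stance height
exactly at ground level, swing height a half-sine of amplitude 14 px),
hind stride 36 px vs fore stride 22 px, limbs half a cycle out of phase,
ankle leading palm leading tip slightly in lift-off, and a small
double-frequency torso bob.  At the nominal 100 frames/s the default
24-frame period is ~4 strides/s — a realistic treadmill rate for a young
rat — and the nose-eye distance is ~22.5 px in the default 256x128 scene
(~0.14 of the body length).  Datasets sample random phases, positions
(+/-12 px) and body scales (+/-5%); videos advance the phase by
2*pi/period per frame.  All randomness flows from one explicit seed; the
same seed reproduces a dataset byte-for-byte.

What the generator does *not* emulate: fur texture, lighting variation,
motion blur, occlusions, multi-animal scenes, annotation disagreement
between human labellers.  Passing tests on this data therefore demonstrate
the correctness of the pipeline and the relative behaviour of the
structures/decoders, not absolute real-world accuracy.

## Gait quantification

Heights are `image_height - y` in pixels (no camera calibration).  Phase
segmentation smooths the reference joint's height (moving average, window
5), labels a frame *lifting* where the first difference is positive and
*falling* otherwise (stance frames, where height is flat, count as
falling), and merges runs shorter than 2 frames.  Stride peaks use
prominence-based peak detection (prominence 0.2x series range, minimum
separation half the autocorrelation period estimate); the period is the
median inter-peak gap.  These procedures are the package's own — the
observable they quantify (alternating stance/swing with the hind limb
out-travelling the forelimb during its falling phase) is standard treadmill
locomotion.

## Reference experiment (desk scale)

The original rat dataset (1,613 labelled frames) is not public and the
published networks' channel widths are unspecified, so the package pins its
own scaled-down stand-in (`ratpose.benchmark`): 400 synthetic 256x128
frames, 80/20 split, a reduced CCN (4 stages, stride 8, base 16 channels,
24-channel stage blocks, 224k parameters) trained with HIR decoding for 12
epochs, evaluated at p = 0.1.  Problem sizes were chosen so the run
completes in minutes on one CPU.  A further-reduced "mini" protocol (140
frames, half-resolution input, 8 epochs) supports seed-replicated property
checks: HIR beating FCR at matched budgets, and the final cascade stage
scoring at least the first.

## Known limitations

* The NumPy engine is single-threaded GEMM-bound; training beyond desk
  scale is out of scope.
* The hourglass (CHN) path and the stride-4 variant are functionally
  complete and shape-audited, but the reference accuracy experiment is run
  with the CCN at stride 8 only.
* Peak counts on real fore-claw trajectories (double-peaked protrusion)
  are exposed via `detect_strides` but no specific count is asserted —
  that observation is qualitative.
* FCR regresses normalised coordinates with a single linear layer; it is
  intentionally the weakest decoder and serves as the comparison baseline.
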