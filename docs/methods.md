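# Methods

## Supervision model

The atomic supervision unit is a set of points marking finding centers on a
preprocessed radiograph. A point carries no scale information, so the
package converts points to disks: mask pixel (i, j) is 1 iff the Euclidean
distance from its center to any annotation point is at most *s*, with union
semantics for overlapping disks. The boundary is inclusive (distance ≤ s)
and measured to pixel centers; coordinates are x = column, y = row, 0-based,
origin top-left, points at pixel centers — one convention used everywhere.

Defaults: *s* = 75 px at the 1024 px working resolution, scaled
proportionally for smaller inputs (`MaskConfig.for_input_size`), e.g.
9.375 px at 128. The disk is deliberately generous: it is a noisy target
whose job is to bias saliency toward the finding, not to segment it.

Because the true spatial scale of a finding is ambiguous, every point
supervises every pyramid level. The full-resolution mask is reduced to each
level by **block max-pooling** (an output pixel is 1 iff any pixel of its
block is 1). Max-pooling is positive-preserving: a 75 px disk survives to
the 32×32 level regardless of its position, which an area-threshold
reduction does not guarantee. The alternative (`downsample="area_threshold"`,
block mean ≥ 0.5) is available for sensitivity analyses.

## Network

The detector maps a square grayscale image (side divisible by 32) to four
saliency logit grids of sides input/32 … input/4, coarse to fine. Two
encoders satisfy this contract:

* `densenet169_fpn` — dense blocks with channel concatenation, 1×1
  transitions and 2× downsampling, feeding a 256-channel top-down path.
  The default growth rate (8) and block depths (2, 4, 4, 4) are compact so
  that a 1024 px forward pass costs seconds on one CPU; both are
  configurable upward. The published DenseNet-169 depth is not reproduced,
  and ImageNet initialization is supported only by supplying an explicit
  weights file (`pretrained=True` + `weights_path`); no weights are
  bundled.
* `tiny_fpn` — a six-convolution encoder (widths 6–32) with a 16-channel
  top-down path, for desk-scale training experiments.

Shared top-down design: 1×1 lateral projections; nearest-neighbour 2×
upsampling with additive fusion starting from the coarsest level; one 3×3
smoothing convolution and a 1×1 single-channel head per level. Convolutions
use 'same' zero padding and He-normal initialization from a seeded
generator; head biases start at −2 (a background prior — most pixels are
negative). Instance normalization (per-sample, per-channel spatial
standardization, no affine) follows every non-head convolution by default
(`norm="instance"`); it is what makes short CPU training schedules converge
reliably, and can be disabled for analyses that need exact translation
covariance (normalization couples pixels globally).

**Output level.** The source design is ambiguous about whether the deployed
heatmap is the coarsest (32×32) or finest (256×256) map, and both readings
appear. The package exposes `output_level` with default `"coarsest"`
(matching the 32×32 output description and the max-pixel image score);
`"finest"` is used in the desk-scale experiments because at 128 px input the
coarsest map is only 4×4 — too coarse to resolve a 9 px localization disk.
The image-level probability is always max over pixels of sigmoid(logit) on
the designated level.

## Training

The objective is the sum over levels of the per-level pixel-mean binary
cross-entropy between logits and masks, computed in the log-sum-exp form
max(z,0) − z·t + log(1+exp(−|z|)). The printed form of the objective in
some descriptions ("log σ(1 − P)") does not vanish for confident true
negatives and is treated as a typo for log(1 − σ(P)). The public
`multiscale_bce_loss` evaluates in float64 (tests compare it to a per-pixel
arithmetic oracle at 1e-10 relative); the training path uses the same
formula inside the float32 autodiff graph.

Augmentation (per training image, each field uniform over its range):
translation ±100 px at 1024 (scaled linearly with input size), rescale
[0.9, 1.1], horizontal flip p = 0.5, rotation ±15°, brightness and contrast
[0.75, 1.25]. The spatial part is a single affine (flip, then
rescale+rotate about the center, then translate) applied identically to the
image (bilinear, zero fill) and to the annotation points; points leaving
the canvas are dropped with a logged count. Brightness is multiplicative
and contrast pivots at 0.5, then values clip to [0, 1]. Masks are rebuilt
from the transformed points, not warped.

Cross-validation uses label-stratified folds (positives and negatives
round-robined after independent shuffles), which the source describes only
as "random and even" — stratification is required at desk scale so every
validation fold contains both classes; a single-class fold is an error.
After each epoch the validation AUROC of the image-level score (single
model, no TTA, un-augmented images) is recorded and the best epoch's
parameters are kept. Optimizer: Adam, batch 8; full-scale defaults are 100
epochs at learning rate 1e-5; the desk-scale preset
(`TrainConfig.desk_scale`) uses 20 epochs at 3e-3 with global gradient-norm
clipping at 10 — the narrow backbone and the short schedule need the larger
step, and clipping removes occasional divergence spikes observed mid-run.
All randomness derives from one master seed through named SeedSequence
streams (per fold, per epoch), so runs are bit-reproducible.

The annotation-size ablation trains on nested subsets (a smaller fraction
is a prefix of the same seeded permutation), runs the full cross-validation
per fraction and evaluates the resulting ensemble on a held-out manifest;
fraction 1.0 is identical to plain cross-validation under the same seed.

## Ensemble inference

Five fold models × five predefined test-time augmentations (default:
identity, horizontal flip, rotation ±10°, contrast 1.15 — only flip,
rotation and contrast families are allowed, all spatially invertible). The
exact five combinations are not recoverable from the source and are
configuration; none of the package's guarantees depend on them. Member maps
are taken at the output level in sigmoid space. p is the mean of member
maxima; the localization map is the mean of members after applying each
spec's inverse flip/rotation at map resolution (bilinear), with
out-of-support pixels filled by the member map's minimum so rotated-in
borders do not imitate confident negatives.

One subtlety: "mirror the input ⇒ members permute" holds only for TTA sets
closed under composition with the flip, and no odd-sized set can be closed
(specs pair up). The property test uses a 4-spec closed set; with the
default 5-spec set, p moves slightly under input mirroring.

## Statistics

AUROC is the Mann–Whitney concordance probability (ties half-credit);
AUPRC the area under the PR step curve — both via scikit-learn, each tested
against a brute-force oracle (O(n²) pair scan; exhaustive threshold sweep).
Confidence intervals are percentile bootstrap over case resampling, 2000
replicates by default, seeded; resamples on which a metric is undefined are
redrawn and logged. (Whether the clinical analyses used the percentile
variant is unstated; percentile matches the common default.) The Youden-J
cutoff is selected over midpoints between consecutive distinct scores plus
one candidate beyond each extreme, ties broken toward the higher threshold
(higher specificity); score ≥ cutoff ⇒ positive call, stated explicitly
because midpoint thresholds make the convention observable only at tied
scores. McNemar's test compares correctness indicators: exact two-sided
binomial when the discordant count is below 25, chi-square with continuity
correction otherwise. The reader study evaluates each fracture class
one-vs-rest on its 100 relevant cases (50 target + 50 normal), reports
accuracy/sensitivity/specificity, three-class balanced accuracy (mean
per-class recall), a McNemar p against the model on the same cases, and
misdiagnoses-detected (reader missed, model called).

## Synthetic phantoms

The generator emulates the *structure* of a trauma PXR cohort, not its
appearance: a bright pelvic-ring annulus plus two femur primitives on a
darker background, Gaussian blur (σ = 1.5 px), additive Gaussian noise
(σ = 0.02), and small seeded geometry jitter so images differ. Positive
images carry 1–7 lesions (median 1, mean ≈ 1.6, matching the annotated-point
statistics of the clinical training cohort); the positive fraction is
configurable, 0.5 by default for the recovery experiments (the clinical
development set is ≈ 60% positive, the clinical test set ≈ 33%). Each of
the five finding categories has one distinguishable local appearance (dark
polyline, dark band with displaced bright edge, bright rim with dark core,
bright bar with adjacent dark line, straight dark shaft line), confined to
a disk of radius 16·(size/256) px around the anchor; the annotation point
is exactly the anchor. Negative images are pixel-identical to their
lesion-free phantom.

What passing these tests shows: the pipeline can learn point-supervised
localization and classification end to end, and every arithmetic contract
holds. What it does not show: performance on real radiographs — phantom
lesions are high-contrast, anatomically unstructured, and free of the
projection, exposure and hardware variation of clinical PXRs.

## Experiment sizes

Desk-scale experiments use 200 training phantoms at 128 px with fivefold
cross-validation for up to 20 epochs and an 80-image held-out set; the
ablation compares the 20% subset (40 images) with the full set. These sizes
make the recovery experiment a minutes-scale CPU run while keeping at least
~20 positives per validation fold.

## Known limitations

* The NumPy network trains small models happily but is not suited to
  full-scale (1024 px, 100-epoch) training; the full-size configuration is
  exercised at inference.
* `densenet169_fpn` keeps the name of its design family but is a compact
  variant; no pretrained weights ship with the package.
* Bootstrap CIs are percentile-only (no BCa); PR curves are not smoothed.
* The phantom makes no claim of anatomical realism, and per-category
  appearances are stand-ins chosen for distinguishability.
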