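# Methods

## Model

AID-U-Net generalizes the U-Net encoder–decoder by splitting its depth
budget between a *direct* path of depth `K` and a nested *sub-path*
excursion of depth `d`, with `0 ≤ d ≤ K`. Execution order over depth
levels (level 0 = full resolution, filter count `2^(N_f + level)`):

1. **Direct contracting path**, levels `0 → K`. Each block applies two
   same-padded convolutions of kernel extent 3 (the first followed by batch
   normalization), each with ReLU, then dropout. Blocks are connected by
   2× max-pooling.
2. **Sub-expansive path**, levels `K → K−d`. Each block up-samples with a
   stride-2, kernel-2 transposed convolution, concatenates the same-level
   direct contracting block's output along the channel axis, then applies
   the two-convolution recipe.
3. **Sub-contracting path**, levels `K−d → K`, structured like the direct
   contracting blocks (max-pool connections).
4. **Direct expansive path**, levels `K → 0`, structured like the
   sub-expansive blocks, starting from the sub-contracting output at level
   `K`. With `d = 0` there is no excursion and the decoder starts at the
   bottleneck: the planner then emits exactly a conventional U-Net of depth
   `K`.
5. **Head**: a kernel-1 convolution to `num_classes` channels followed by a
   per-pixel softmax. (Binary problems could equivalently use a
   single-channel sigmoid; the two-channel softmax is used throughout for
   uniformity.)

Merging is by concatenation, never addition: concatenating feature maps
preserves each channel's variance, whereas adding two independent maps
doubles it, so concatenation keeps decoder activations on the same scale as
the encoder features they join. This is asserted numerically in the test
suite.

Worst-case complexity orders are the geometric sums
`2^(depth+1) − 1` (conventional) and
`S1 + S2 = 2^(K+2) − 2^(K−d) − 1` (nested); for equal total depth and
`d ≥ 1` the nested order is strictly smaller (checked exhaustively for
`K ≤ 10`).

### Design choices where the architecture was genuinely open

- **One excursion.** The sub-expansive and sub-contracting paths are paired
  one-to-one; exactly one excursion is instantiated. Supporting repeated
  excursions would change none of the per-block recipes.
- **Skip endpoints.** Direct contracting level `ℓ` feeds its output to the
  concatenation of *both* the sub-expansive and the direct expansive block
  at level `ℓ`. The decoder's input at level `K` is the sub-contracting
  output alone (the bottleneck reaches the decoder through the excursion,
  not through an extra concat). Every concatenation therefore joins exactly
  two sources of identical spatial extent.
- **Normalization placement.** Batch normalization follows the *first*
  convolution of each block only. Together with the skip-endpoint choice
  above, this convention reproduces the published reference counts for the
  two flagship 2D configurations at base `2^5` filters — 3,386,882
  ("3.4 M") for AID-U-Net(3,1) and 924,130 ("924 K") for AID-U-Net(2,2) —
  which is why it was frozen. A depth-4 conventional U-Net under the same
  convention counts 7,763,074; no convention we could construct reaches the
  occasionally quoted 4.0 M for that baseline, so only the strict ordering
  U-Net(4) > AID(3,1) > AID(2,2) is asserted.
- **Parameter-count rules.** Trainable scalars are convolution and
  transposed-convolution kernels and biases plus one (γ, β) pair per
  normalized channel; running statistics are excluded. Counts are reported
  raw; for comparison against published magnitudes they are rounded to two
  significant figures.
- **Up-sampling** is a kernel-2, stride-2 transposed convolution; because
  kernel equals stride, output blocks never overlap and the operator is an
  exact per-voxel linear expansion.
- **The in-block cropping layer** is realized as the identity: patch
  extents are required to be divisible by `2^K`, so all concatenations
  already align (the shape validator rejects configurations where they
  would not).

## Training

Hand-written backprop in NumPy (float32). Convolutions are evaluated by
shift-and-multiply — one batched channel-mixing matmul per kernel offset —
identical in 2D and 3D; layer gradients are verified in the tests against
brute-force sliding-window/scatter oracles.

Defaults: Adam with learning rate 1e-3 (no schedule), batch size 8,
generalized dice loss on softmax probabilities, He/fan-in weight
initialization from the run seed, dropout rate 0.5 inside blocks
(configurable per run). Softmax cross-entropy is available as an
alternative loss. Identical seed, configuration and data order reproduce
the training history bitwise on one machine; a non-finite loss aborts with
the offending epoch and batch.

The generalized dice loss uses inverse-squared-area class weights
`w_i = 1/Σ_j G_ij²` (for one-hot truth, the reciprocal of the class pixel
count), computed per batch; absent classes get weight 0. A smoothing
constant ε = 1e-5 is added to numerator and denominator; on the 4-element
hand-evaluated fixture in the tests it shifts the loss by < 1e-4. The loss
gradient is derived analytically through the softmax and checked against
finite differences.

## Preprocessing

Patch planning is per-axis: an axis divisible by the patch extent is tiled
directly; otherwise a crop window of size `floor(extent/patch)·patch` is
centred on the foreground-mask centroid (image centre if no mask), clamped
to bounds, ties toward the lower coordinate — maximizing object
containment reproducibly. Foreground pixels clipped by the crop are
reported as a warning with their count. If the foreground bounding box is
larger than a patch on some axis, no crop can keep the object inside one
patch; on such axes the full extent is kept and covered by the minimal
number of overlapping patches with evenly spread origins (`overlap_flag`
set). An explicit crop override is available in the run configuration for
datasets whose crop should be tuned separately.

Augmentation applies quarter-turn rotations (in the trailing image plane),
per-axis reflections and bounded integer-pixel translations
(reflection-padded) to image and mask identically; all transforms are
interpolation-free, so label sets are preserved exactly. Patches are
augmented after extraction.

## Synthetic data

The generator emulates the statistics that make biomedical segmentation
hard — a few compact objects against a textured background with heavy
class imbalance — without claiming photorealism. Per sample: 1–3
superellipse blobs (exponent 1.5–3, random orientation and elongation,
low-frequency radial perturbation up to 12%; ellipsoids in 3D), radius
6–20% of the short axis, rendered at +0.3–0.5 intensity contrast over a
flat, gradient or speckle background, plus Gaussian noise of sd 0.05 on a
unit intensity scale. Mask foreground fractions are held in 1–15% by
rejection sampling. Each sample derives its RNG stream from
`(seed, index)`, so datasets are bitwise reproducible, also under partial
regeneration.

What passing tests on these fixtures show: the full pipeline — planning,
building, training, stitching, scoring — is correct and convergent on
imbalanced blob-like targets. What they do not show: performance on real
endoscopy/microscopy/CT appearance (specular highlights, texture inside
lesions, anisotropic voxels, annotation noise), which requires real data
and longer training.

## Evaluation

Per mask pair: per-class precision, recall, F1 (= dice), IoU; global
accuracy; mean accuracy (mean per-class recall); mean IoU; weighted IoU
(ground-truth-frequency weights); mean BF score. Boundaries are foreground
pixels with a face-connected background neighbour (array edges count as
background); the BF score matches boundary pixels within a Euclidean
tolerance defaulting to 0.75% of the mask diagonal — a widespread
convention, exposed as a knob since published variants differ. Classes
absent from both masks are excluded from means rather than scored 0, so
fixtures with missing classes stay comparable. Confusion overlays color
TP cyan, FP magenta, FN yellow, TN black. Per-volume dice distributions
are summarized boxplot-style (median, quartiles, whiskers at the most
extreme non-outliers under the 1.5·IQR rule).

For binary masks both the foreground-class IoU and the mean IoU are
emitted; prose in this repository quotes the foreground IoU.

## Desk-scale study conditions

The end-to-end check trains AID-U-Net(2,1) on 64 synthetic 64×64 RGB blob
images for 10 epochs (batch 8, Adam 1e-3, generalized dice, seed 7,
validation fraction 0.25) and requires held-out foreground IoU above 0.5
and above the all-background baseline. `N_f = 4` (base 16 filters) and
dropout 0 are the package's choices for this configuration: blob targets
need no heavier trunk, and dropout's regularization has nothing to offer a
ten-epoch run on homogeneous synthetic data. The run completes in well
under a minute on one CPU and reaches IoU ≈ 0.96.

## Known limitations

- Batch normalization uses per-batch statistics with momentum-0.9 running
  estimates; very small batches give noisy validation scores in early
  epochs (visible as transient IoU dips before the running statistics
  settle).
- Pure-NumPy training is desk-scale: minutes for small fixtures, not
  suitable for full-resolution clinical datasets or pre-trained backbones.
- The search for the best `(K, d)` per dataset is out of scope; depths are
  user-chosen.
- No intensity augmentation or elastic deformation; geometric transforms
  only.
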