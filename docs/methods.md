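# Methods

This note records the scientific and numerical choices behind milslide: the
models, their assumptions, the parameters that matter, what the synthetic
generators do and do not emulate, and the package's known limitations.

## Problem setting

A whole-slide image (WSI) is stored as a multi-resolution pyramid whose level
0 may span billions of pixels. Molecular labels (here: a continuous marker
such as FPKM gene expression, binarized at the cohort median) exist once per
slide. Multiple instance learning (MIL) treats the slide as a bag of patch
instances with a single bag label; the learning problem is to aggregate
instance evidence into a bag decision when the informative instances — the
"witnesses" — may be a small minority and are never individually labeled.

## Slide reading

All geometry uses 0-based, half-open pixel intervals; region origins are in
the level-0 frame, region sizes in the target-level frame (the dominant
slide-reader convention). Reads return 3-channel 8-bit color; alpha is
composited over white, encoding the glass-background assumption. Backends
are adapters with four members (`open`, `level_dims`, `level_downsamples`,
`read_region`); pyramid metadata is validated on open (dims non-increasing,
downsamples strictly increasing and within 1 % of the width ratios). When an
analysis level finer than a size budget does not exist, a virtual level is
synthesized by block-mean downsampling of the coarsest stored level and
flagged as virtual.

## Tissue masking and patching

Assumption: stained tissue is darker than glass. Pixels are converted to
grayscale with Rec. 601 luma weights (0.299/0.587/0.114) and cut at the
threshold maximizing between-class variance on the 256-bin histogram;
foreground is strictly below the cut, and among tied maximizers the smallest
cut is chosen so the contract is deterministic. A constant image has no
separable classes and raises a degenerate-input error rather than returning
an arbitrary mask.

The mask is computed at the coarsest stored level whose larger dimension is
at most `mask_max_dim` (default 4096 px) — coarse levels are where
segmentation is cheap and stain contrast is stable. Cleanup order: remove
objects < `min_object_area` (256 px), fill holes < `min_hole_area` (64 px),
morphological closing with a disk of radius 2 px; both area thresholds are
strict and expressed in mask-level pixels.

Patch candidates start at (0, 0) of the patch level and advance with stride
`step` (default = patch size, 224 px — the canonical input size of
ImageNet-era backbones). Each candidate's tissue coverage is the exact
area-weighted fraction of its footprint on the mask level (fractional border
pixels are weighted by overlap, not re-thresholded), and candidates are kept
when coverage ≥ `tissue_threshold` (default 0.5, exposed as a flag since no
canonical value exists). Raising the threshold can only shrink the grid.
Pen marks and blur are *not* detected automatically; heavily marked slides
are expected to be excluded at the cohort level via the min-patch-count
filter, mirroring the manual curation such datasets receive in practice.

Color normalization is Reinhard-style: per-channel mean/std matching in
CIELAB (a decorrelated space in which H&E stain variation is approximately
affine), with zero-variance channels passed through under a warning.

## Encoders and self-supervision

Feature extraction is a pre-processing step: each retained patch is read
once, normalized with fixed constants ((x/255 − 0.5)/0.25), and embedded;
the N×d float32 matrix is persisted beside the grid. Every feature bag
stores an `encoder_fingerprint` (hash of the spec plus a weight checksum) so
cohorts cannot silently mix encoders. The bundled `tiny` encoder is a small
randomly initialized conv net (block-mean to 32×32, two 3×3 conv/ReLU/pool
stages, global average pooling, linear head), a deterministic pure function
of its seed; production backbones plug in through `register_encoder`.

The NT-Xent (SimCLR) loss uses the pairing convention that rows (2k, 2k+1)
are one augmentation pair, L2-normalizes embeddings internally, excludes
self-similarity, and averages over all 2N anchors; it requires at least two
pairs (otherwise no negatives exist). MoCo keeps a FIFO queue of K
unit-normalized key embeddings (default 4096), temperature 0.07 and momentum
0.999 (the cited conventions); the key encoder receives its momentum update
*before* encoding keys, and only the query encoder receives gradients.
Augmentations are flips, 90° rotations and color jitter; aggressive cropping
is deliberately excluded because a patch is already a small crop of the
slide and further cropping can remove the tissue context entirely.

## MIL heads

All heads compute logits internally and emit probabilities only at the
output boundary. Initialization is Glorot-uniform for dense layers; the
transformer attention projections use the small-normal transformer
convention (std 0.02) so attention starts near uniform and sharpens during
training — this also makes the Nyström landmark approximation faithful at
initialization, where attention kernels are smooth.

- **ABMIL** (gated attention): instance scores are the attention weights,
  which are nonnegative and sum to 1; the bag probability is invariant to
  instance permutation.
- **DSMIL**: critical-instance ties break to the lowest index; attention
  uses raw dot products `qᵢ·q_c` (no scaling), and the final logit is the
  unweighted mean of the max instance score and the bag-classifier score.
  Both choices are the simplest members of their design families and are
  kept fixed rather than configurable-by-default.
- **TransMIL**: tokens = ReLU(linear projection of instances); sequence
  squaring pads to the next perfect square by re-appending the first tokens;
  the positional-encoding stage adds depthwise convolutions (kernels 7, 5, 3
  plus identity) over the √M×√M token grid between two pre-norm
  self-attention blocks, which is what breaks permutation invariance and
  injects patch-neighborhood structure. Per-patch scores are the class
  token's attention over the original N tokens in the final block, averaged
  over heads and renormalized (head-mean is a choice; no canonical reduction
  exists). Exact softmax attention is used up to 4096 tokens; beyond that a
  Nyström approximation with segment-mean landmarks (default 64) and a
  6-iteration Newton–Schulz pseudo-inverse is available. The approximate
  path is inference-only.
- **TL baseline**: every instance inherits the bag label (pseudo-labels);
  the loss is the mean instance cross-entropy and the bag score the mean
  instance probability. This is the paradigm MIL is meant to beat when
  witnesses are rare, because pseudo-labels are mostly wrong on positive
  bags.

## Training contract

Whole bags do not batch, so the trainer fixes batch size at 1 bag and
accumulates gradients over `accumulate_grad_batches` bags (default 8),
scaling each bag loss by the window size so one optimizer step equals a step
on the mean loss — the equivalence is exact and is asserted to 1e-6 in the
tests. The optimizer is Adam (default lr 1e-4, configurable; optional
decoupled weight decay). With a validation set, validation AUROC is computed
every epoch, early stopping triggers after `early_stop_patience`
non-improving epochs, and the best-epoch parameters are restored; without
one the full epoch budget runs. An optional per-bag instance sampler
(uniform, without replacement, order-preserving) caps bag size. A non-finite
loss aborts with the epoch and slide named.

Splits are stratified by label and grouped by patient (no patient spans
splits); the test set takes round(0.2 × stratum) groups per class, K-fold
mode deals groups round-robin. Site-based grouping is available via the
group column. The median-split tie policy is strict: label 1 iff the marker
exceeds the median. AUROC is the Mann–Whitney rank statistic with half
credit for ties, computed from average ranks.

## Synthetic data: what it emulates, what it does not

`make_slide` reproduces the *geometry and contrast* of an H&E scan — bright
glass (230 ± 10 gray), dark elliptical blobs with a pink/purple channel
tint, optional saturated pen stroke, a 3-level block-mean pyramid — together
with exact ground-truth masks. It does not attempt realistic H&E texture,
stain variation, focus artifacts or compression; passing mask/patch tests
therefore validates the geometry and thresholding contracts, not robustness
to real staining variability.

`make_bags` is the classic witness construction: background instances are
standard normal in d dimensions; positive bags receive
round(witness_rate × instances_per_bag) witnesses (minimum 1; round half to
even, so the default 0.05 × 50 gives 2) shifted by `shift` background
standard deviations along one fixed random unit direction. The frozen
benchmark used throughout the docs and the acceptance script is 200 bags ×
50 instances, d = 32, witness_rate 0.05, shift 1.5, balanced labels, seeds
{0, 1, 2}. This construction isolates the aggregation problem from the
encoder; its Gaussian instances do not emulate feature correlations of real
patch embeddings. Note that at the frozen signal strength the task is
intrinsically hard: the exact likelihood-ratio statistic — the
Neyman–Pearson-optimal bag scorer — sits near AUROC 0.68 under these
conditions, so desk-scale trained models are expected to land between
chance and that ceiling, and the benchmark should be read as a relative
comparison of aggregators, not as a calibration of absolute performance.

`make_texture_patches` builds the self-supervision test bed: two clusters
that differ only in grating frequency with a random phase per patch, under a
strong brightness/channel-gain nuisance. Random phase makes the class a
power-spectrum (quadratic) feature that linear probes on raw or randomly
projected pixels cannot read, while the nuisance is exactly what the
color-jitter augmentations remove — so contrastive pre-training, and only
it, renders the clusters linearly separable.

## Benchmark protocol and problem sizes

The witness benchmark trains each method on the 80 % stratified remainder
with a fixed per-method budget (ABMIL: 20 epochs, hidden 64, weight decay
1e-3; DSMIL: 10 epochs, q = 32, wd 1e-2; TransMIL: 25 epochs, token_dim 64,
wd 1e-2; TL: 10 epochs, wd 1e-2; all lr 1e-3, accumulation 8) and no
validation carve-out: at 160 training bags a 10 % validation split yields an
AUROC too granular (increments of ~1/64) to select checkpoints by, so
checkpoint selection on it is effectively random and fixed budgets are more
reproducible. Early stopping on validation AUROC remains the default
contract of `train_model` whenever a validation set is supplied. These
sizes keep a full 4-method × 3-seed benchmark (plus its shift-0 null) in a
few CPU-minutes.

## Numerical choices

- All training mathematics runs in float64 on an in-repo reverse-mode
  autodiff; every model's loss gradient is verified against central finite
  differences at 1e-4 relative tolerance.
- Softmax and log-sum-exp are computed with detached max-shifts; the
  logistic function uses the tanh form; binary cross entropy is evaluated on
  logits via softplus.
- Otsu ties break to the smallest threshold; DSMIL argmax ties to the lowest
  index; the gradient of a hard max flows to its first maximizer.
- Degenerate inputs raise typed errors rather than returning silent
  defaults: constant images (no separable tissue), identical marker values
  (empty label class), single-class AUROC, empty bags.
- Heatmaps min-max normalize per slide (a constant map renders at the
  colormap midpoint); a raw mode exists for cross-slide comparability.
  Colors come from the perceptually uniform purple→yellow ramp, and cells
  without patches keep the original slide pixels.

## Limitations

- The bundled encoders are deliberately small; results with them demonstrate
  pipeline correctness, not state-of-the-art representation quality. Real
  backbones (e.g. a pre-trained ResNet through any framework) attach via
  `register_encoder`.
- The Nyström attention path does not carry gradients; training always uses
  exact attention.
- Only binary slide-level classification is supported (median-split labels);
  survival, regression and multi-class heads are out of scope.
- No vendor color-profile handling, DICOM-WSI, or Java-based readers; pen
  marks are not segmented away automatically.
- MoCo is implemented for the trainable MLP encoder; momentum updates for
  arbitrary registered encoders would require those encoders to expose their
  parameters in the autodiff format.
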