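# milslide

Multiple-instance-learning (MIL) pipelines for whole-slide histopathology
images, for computational pathologists and biomedical researchers who want to
predict slide-level molecular labels (e.g. "high" vs "low" expression of a
gene) from H&E-stained tissue without pixel-level annotations.

A whole-slide image (WSI) is a gigapixel pyramid; a classifier cannot see it
whole, and a molecular label exists only per slide. MIL resolves this by
treating the slide as a *bag* X = {h_1, ..., h_N} of patch-feature
*instances*: only the bag carries a label y ∈ {0, 1}, and an aggregation
function must decide which (possibly very few) instances carry the evidence.
milslide covers the full desk-to-model workflow:

- **`slide_io`** — backend-agnostic slide reading (pyramidal/plain TIFF, PNG,
  in-memory arrays; custom readers via `register_backend`) with a uniform
  scale-pyramid and region-read contract.
- **`preprocess`** — Otsu tissue masking (foreground = tissue darker than the
  between-class-variance-maximizing gray cut) with morphological cleanup,
  raster patch-grid extraction with exact area-weighted tissue coverage,
  Reinhard-style color normalization, HDF5 per-slide stores, and a
  multi-process collector whose results are invariant to worker count.
- **`encode`** — patch-feature encoders behind a registry (a deterministic
  tiny conv net and a trainable MLP are bundled), plus self-supervised
  pre-training: the SimCLR NT-Xent loss and MoCo momentum/queue updates with
  flip/rotation/color-jitter augmentations.
- **`mil`** — four bag classifiers:
  - **ABMIL**: gated attention `a = softmax(wᵀ(tanh(V h) ⊙ σ(U h)))`,
    bag embedding `z = Σ aᵢ hᵢ`;
  - **DSMIL**: a max-pooled instance stream picks the critical instance, a
    second stream attends to it (`Uᵢ = softmax(qᵢ·q_c)`) — bag logit is the
    mean of the two streams;
  - **TransMIL**: class token + sequence squaring to `M = ⌈√N⌉²` tokens +
    pyramid positional encoding (depthwise conv 7/5/3 on the √M×√M token
    grid) between two self-attention blocks (exact softmax attention, or a
    Nyström landmark approximation for very long bags);
  - **TL**: the transfer-learning baseline — a patch classifier trained on
    pseudo-labels copied from the slide label, bag score = mean patch
    probability.
- **`experiment`** — median-split label derivation (label 1 iff marker
  strictly above the cohort median), >min-patch cohort filtering, stratified
  patient-grouped 80/20 or K-fold splits, a trainer with batch size fixed at
  1 bag, gradient accumulation, and early stopping on validation AUROC, and
  rank-based (Mann–Whitney) AUROC.
- **`viz`** — per-patch attention/probability heatmaps blended over the slide
  with the perceptual purple→yellow ramp.
- **`fixtures`** — synthetic generators with planted ground truth: pyramidal
  pseudo-slides (glass + tissue blobs + optional pen marks) and witness
  feature bags (positive bags contain a few instances shifted along a hidden
  direction), so the whole pipeline is testable without any download.

All neural components run on a small NumPy reverse-mode autodiff
(`milslide.nn`) in float64; every model's gradients are finite-difference
checked in the test suite.

## Worked example

```python
import numpy as np
from milslide import (SlideSpec, make_slide, MaskParams, compute_tissue_mask,
                      extract_patch_grid, EncoderSpec, encode_bag)
from milslide.fixtures import BagSpec, make_bags
from milslide.experiment import TrainConfig, train_model, evaluate, split_bags

# 1. preprocess a synthetic slide
handle, truth = make_slide(SlideSpec(width=1024, height=1024, seed=0))
mask = compute_tissue_mask(handle, MaskParams())
grid = extract_patch_grid(handle, mask, patch_size=224, step=224,
                          tissue_threshold=0.5)
print(f"otsu threshold {mask.otsu_threshold}, "
      f"tissue fraction {mask.foreground_fraction:.3f}")
print(f"retained patches: {len(grid)}")

# 2. encode patches into a feature bag
bag = encode_bag(handle, grid, EncoderSpec(name="tiny", embed_dim=32))
print(f"feature bag: {bag.features.shape}")

# 3. train gated-attention MIL on separable witness bags
bags, _, _ = make_bags(BagSpec(seed=0, shift=3.0, witness_rate=0.3))
train, val, test = split_bags(bags, 0.2, 0.15, seed=0)
cfg = TrainConfig(method="abmil", seed=0, max_epochs=30,
                  early_stop_patience=30, learning_rate=1e-3,
                  model_kwargs={"hidden": 64})
res = train_model(train, val, cfg)
scores, test_auroc = evaluate(res.model, test)
print(f"best val AUROC {res.best_val_auroc:.3f} at epoch {res.best_epoch}; "
      f"test AUROC {test_auroc:.3f}")
```

prints

```
otsu threshold 175, tissue fraction 0.208
retained patches: 3
feature bag: (3, 32)
best val AUROC 1.000 at epoch 14; test AUROC 1.000
```

The Otsu cut (175) separates the dark tissue blobs from bright glass; three
224-px patches clear the 50 % tissue-coverage threshold on this sparse slide.
With witnesses shifted 3 σ the classes are cleanly separable and gated
attention reaches perfect validation AUROC by epoch 14 (AUROC 0.5 = chance,
1.0 = every positive bag outscores every negative). Inspecting a positive
test bag, the model concentrates attention ~16× above uniform on its most
informative instances; `milslide.viz.render_heatmap` projects such scores
back onto slide coordinates.

A `milslide` console script wraps the same library surface
(`milslide info|preprocess|encode|ssl|train|evaluate|heatmap|fixtures`; see
`milslide --help`).

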