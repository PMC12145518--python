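# Methods

## Problem and approach

Fungiform papillae (FPs) are the mushroom-shaped, taste-bud-bearing
structures on the anterior tongue. After staining with blue food dye they
appear as lighter, roughly circular spots inside the darker-stained region,
against a background of darker filiform papillae. This package detects and
counts FPs in such photographs by *heatmap regression*: instead of a binary
mask, the networks predict a continuous map with a peak of probability at
each papilla center that decays smoothly toward its border. Point
annotations are converted into training targets by placing a unit-peak
isotropic Gaussian `exp(-d² / 2σ²)` at every annotated center; predicted
maps are converted back into coordinates by local peak detection; predicted
and annotated point sets are compared by one-to-one matching within a
declared radius.

## Pipeline

1. **Preprocessing** (`papillae.preprocess`). The stained region is
   segmented by projecting RGB onto a stain-contrast axis (default blue
   dominance, weights −0.5, −0.5, 1.0), thresholding with Otsu, closing
   small gaps, and keeping the largest connected component (≥ 1 % of the
   image, else a detection error). An ellipse is fitted from the
   component's second-order moments: for a filled ellipse the semi-axes
   equal twice the principal standard deviations, so `a, b = 2√λ₁, 2√λ₂`.
   A square of side `2(1+margin)·max(a,b)` (margin 0.05) centered on the
   ellipse is cropped, resized bilinearly to 250 × 250, and contrast-
   normalized with CLAHE. CLAHE runs on the L channel of CIELAB by default
   (per-channel optional); the clip limit follows scikit-image's normalized
   convention (default 0.01, roughly the common OpenCV clip limit of 2 with
   256-bin tiles). Annotations are mapped analytically through the recorded
   crop/scale transforms, never resampled; points leaving the crop are
   dropped and counted.

2. **Targets and peaks** (`papillae.heatmap`). σ defaults to 3 px at
   250 × 250, matching the apparent FP radius at that resolution.
   Overlapping Gaussians combine by pixelwise maximum (not sum) so the
   regression target stays in [0, 1] under crowding; an additive density
   mode is available. Peak detection reports integer-pixel local maxima of
   a `(2d+1)²` neighborhood (d = 3 by default) that reach 20 % of the map
   maximum and an absolute floor of 0.05 (suppressing noise peaks on
   near-empty predictions); among candidates closer than d, the higher
   (then lexicographically smaller) one wins. No sub-pixel refinement is
   performed — the matching radius absorbs quantization.

3. **Networks** (`papillae.models`). Three encoder–decoder variants, all
   ending in a linear 1 × 1 single-channel regression head:
   * *Classic U-Net*: widths 64/128/256/512, middle 1024, plain skip
     concatenation; ≈ 31.0 M parameters at 3-channel input.
   * *Optimized U-Net*: widths 64/64/128/256, middle 512, BatchNorm after
     every convolution, Dropout in each block (0.2; 0.5 in the middle
     block); ≈ 7.9 M parameters.
   * *MultiResUNet*: MultiRes blocks (three chained 3 × 3 convolutions,
     concatenated, plus a 1 × 1 residual) with the usual width plan
     W = α·32·2^level, α = 1.67, and residual skip paths of length 4/3/2/1;
     ≈ 7.3 M parameters.
   Hidden activations are ReLU (the final layer is linear). Downsampling is
   2 × 2 max pooling, upsampling 2 × 2 transposed convolution. Inputs whose
   sides are not divisible by 16 are reflection-padded up and the output is
   center-cropped back, preserving the 250 × 250 interface. Weights are
   He-normal with a seeded generator, so instantiation is deterministic.

   The networks run on a small NumPy computation-graph engine
   (`papillae.nn`): declarative layer DAGs executed with im2col
   convolutions over BLAS sgemm in float32, explicit reverse-mode
   backpropagation, and Adam. Parameter counts are computed from the
   declarative graph without allocating weights and are asserted to match
   the instantiated arrays.

4. **Training** (`papillae.training`). 5-fold cross-validation; each fold
   trains 500 epochs with batch size 2, MSE loss, MAE monitoring, Adam at
   lr 1e-3 (no schedule, no early stopping; final-epoch weights are kept).
   Augmentation applies, with probability 0.5 per sample per epoch, a
   random quarter-turn, a free rotation within ±15° (bilinear, reflect
   padding), horizontal/vertical flips, and a photometric jitter
   (multiplicative 0.9–1.1, additive ±0.05, image only); geometric
   transforms are applied identically to image and target so peak positions
   stay aligned. One master seed derives the fold, initialization, and
   augmentation streams. Per-epoch training MSE/MAE are accumulated over
   the optimization steps (training mode); validation metrics are computed
   after each epoch in inference mode.

5. **Evaluation** (`papillae.evaluation`). MAE; SSIM with the standard
   constants (Gaussian window σ 1.5, width 11, C1 = (0.01 L)², C2 =
   (0.03 L)², L = 1); Dice on maps binarized at 0.5 of the unit target
   amplitude (both-empty defined as 1). Predicted peaks are matched
   one-to-one to annotations by a linear-sum assignment restricted to pairs
   within the radius (maximum cardinality, then minimum total distance) —
   deterministic and order-independent, unlike greedy nearest-first.
   Matched peaks are TPs; unmatched predictions UPs; unmatched annotations
   UNs, giving TP rate = TP/GT·100 %, accurate count = TP/(TP+UP)·100 %,
   and complete accuracy = TP/(TP+UP+UN)·100 %. The matching radius
   (default 5 px at 250 × 250 ≈ FP radius plus peak quantization) is
   recorded in every report, since the rates are meaningless without it.
   Zero-denominator rates surface as explicit `None` markers, never silent
   zeros that would corrupt fold averages. Fold rates normalize summed
   counts by the fold's real papilla count; cross-fold aggregation reports
   mean ± SD over folds, and a per-image count table is exported for
   external statistics (ANOVA/post-hoc comparisons are deliberately out of
   scope).

## Synthetic scenes

`papillae.synthetic` renders the structure the detector relies on: a
blue-tinted soft-edged stain ellipse (auto-placed near the image center)
on a lighter tissue-colored background; Poisson-placed darker speckle
inside the stain emulating filiform papillae (the main distractor class);
and 5–40 lighter anisotropic Gaussian "mushroom" spots per scene (radius
3–6 px, eccentricity up to 1.5, contrast 0.15–0.35 at 250 × 250), placed
uniformly in the ellipse with a minimum pairwise separation (8 px) and
emitted at integer pixel centers, like pixel-accurate manual clicks. An
illumination ramp and Gaussian sensor noise (σ 0.02) are added last. The
uniform 5–40 count range brackets the density reported for real stained
regions (mean ≈ 17 ± 8).

What the scenes do **not** emulate: real filiform texture (ours is
isotropic speckle, not elongated threads), 3-D tongue curvature and
specular highlights, staining inhomogeneity, motion blur, and the
inter-observer ambiguity of real annotations. Passing the end-to-end tests
therefore demonstrates that the pipeline's machinery — target
construction, optimization, peak extraction, matching — works and can
recover known spots through realistic nuisances; it does not certify
performance on real photographs.

## Problem sizes and presets

Two bundled profiles fix the study conditions:

* `standard`: 250 × 250 scenes, σ = 3 targets, full-width networks, k = 5,
  500 epochs — the full-scale protocol.
* `desk`: 128 × 128 scenes (spot radius 2–4 px, separation 6 px), σ = 2
  targets (papilla radius scales with resolution), networks at 1/8 width
  (encoder 8/8/16/32, middle 64), 50 epochs. This is the package's chosen
  desk-scale working point for CPU-only runs; with the NumPy engine one
  batch-2 optimization step at 128 × 128 costs ≈ 0.15 s at 1/8 width
  (≈ 1 s at 1/2 width), and 1/8 width proved sufficient for the spot
  detection task. The desk profile is a documented scaled-down surrogate
  and is never silently substituted for the standard one.

The single-sample overfit check uses a width-halved network with
`dropout_rate=0`: memorization tests conventionally disable stochastic
regularization, whose injected noise otherwise floors the training loss
(measured ≈ 2e-3) above the 1e-3 memorization criterion.

## Numerical choices and degenerate inputs

* Coordinates are (row, col), 0-based, pixel centers at integer positions;
  annotation files are `row,col` CSV (header) or JSON `[row, col]` lists.
  Sub-pixel annotations are accepted.
* Images are float32 in [0, 1]; heatmaps persist losslessly as 32-bit
  float TIFF; 8/16-bit image round trips are exact to one quantization
  step.
* Gaussian kernels are truncated at 4σ; empty point sets give all-zero
  maps; all-zero maps give empty peak sets.
* Matching uses a large sentinel cost for out-of-radius pairs, so the
  assignment maximizes matched count before minimizing distance.
* A constant image passes CLAHE unchanged (flat histogram); constant-map
  SSIM follows the zero-variance closed form.
* Training aborts with a diagnostic naming the epoch if the loss becomes
  non-finite; k > n fold requests and empty training sets are rejected.

## Known limitations

* The NumPy engine is single-device and unaccelerated; full-width,
  full-resolution, 500-epoch training is out of reach on one CPU — the
  numbers produced at desk scale characterize the pipeline, not the
  full-scale study.
* Peak positions are integer-valued; sub-pixel localization error up to
  ~0.7 px is absorbed by the matching radius.
* Ellipse detection assumes one dominant stain-consistent component;
  multiple disjoint stained regions keep only the largest.
* MultiResUNet filter budgets follow the cited α = 1.67 plan; matching its
  budget to the Classic U-Net instead is possible via `multires_base`.
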