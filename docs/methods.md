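# Methods

`patchscreen` implements one-class anomaly screening for square grayscale
radiograph-like images. Training uses normal images only; an image is
flagged abnormal when it deviates from the learned model of normality.
This note records the model, its assumptions, the parameters that matter,
and the design decisions taken where more than one reasonable choice
existed.

## Model overview

For a predefined set of patch sizes {s₁, …, s_k} (all dividing the resized
image side), each resolution gets:

1. **A contrastive patch encoder D(sᵢ).** SimCLR-style training on the
   normal patches of that size: two stochastic views per patch (random
   crop retaining a fixed area fraction, resized back, plus a small random
   rotation), encoder `f` and projection head `g`, NT-Xent loss

   l_{i,j} = −log [ exp(cos(z_i, z_j)/τ) / Σ_{k≠i} exp(cos(z_i, z_k)/τ) ],

   averaged over all 2N ordered positives of a batch of N patches. After
   training `g` is discarded and `h = f(x)` is the stored representation.
2. **A reference database.** Every patch of every normal training image is
   embedded and stored as the tuple (patch size, grid x, grid y, image id,
   h), plus one pooled covariance model per size for Mahalanobis scoring.
3. **Locality-constrained nearest-reference scoring.** A query patch at
   grid cell (gx, gy) is compared only against reference records whose
   grid location lies within Chebyshev radius d(sᵢ) of (gx, gy), clipped
   at grid borders; its anomaly score is the minimum distance in that
   neighborhood. Supported distances: Euclidean, Manhattan,
   1 − cosine, and Mahalanobis under the shrinkage-regularized pooled
   covariance. Larger always means more anomalous; expressing "inverse
   similarity" as a distance is ranking-equivalent to any strictly
   decreasing transform of similarity and numerically stable.
4. **Per-resolution anomaly maps and fusion.** Patch scores are broadcast
   to their pixels (maps are piecewise-constant per grid). Each map is
   rescaled by calibration quantiles (1st/99th percentiles of patch scores
   on held-out normal validation images), floored at ε = 1e-6, and the
   fused map is the weighted geometric mean

   A_final = Πᵢ A(sᵢ)^{wᵢ / Σw}.

   The image score is the maximum pixel of A_final; the image is abnormal
   iff that score strictly exceeds the threshold (default 0.5).

## Assumptions

- Inputs are single-channel, resized (bilinear, no intensity rescaling) to
  a square side divisible by every configured patch size.
- Anatomy is roughly registered across images: corresponding grid cells
  contain corresponding content up to a few cells of displacement, which
  is what the locality radius d absorbs.
- Normal appearance at each grid location is well covered by the training
  set; abnormality manifests as a patch embedding far from all local
  references.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| patch sizes | {16, 32, 64, 128} on 128-px images | desk-scale mirror of {128, 256, 512, 1024} on 1024-px inputs; grid shapes (8×8 … 1×1) are identical |
| locality d | 2 (8×8 grid), 1 (4×4), 0 (coarser) | same grid-to-radius mapping as the full-scale setting |
| similarity | mahalanobis | the best-performing kind in the full-scale experiments; all four are available |
| fusion weights | (0.1, 1.2, 1.2, 1.0), smallest→largest patch | the best-performing full-scale weight vector; the smallest resolution contributes little and is down-weighted |
| fusion mode | geometric | see design decisions |
| threshold | 0.5 | fixed decision threshold on the calibrated [0,1] fused score |
| covariance shrinkage λ | 0.1 | (1−λ)S + λ·(mean variance)·I keeps S positive definite even when feature dim exceeds record count |
| NT-Xent τ | 0.5 | standard contrastive-learning default; not reported in the full-scale setting |
| crop fraction / rotation | 0.5 / ±5° | the augmentation family of the full-scale setting ("random cropping (50%)" read as retained area at a uniform position) |
| encoder | pooled-pixel MLP, h ∈ R⁶⁴, z ∈ R³², hidden 128, 16×16 pooling | CPU-trainable backbone; see below |
| optimizer | Adam 1e-3, cosine decay | stable for small batches; LARS at lr 4.8 is tied to batch-256 ResNet-50 training and is recorded in `PAPER_PROFILE` only |
| epochs / batch / per-epoch cap | 6 / 64 pairs / 256 patches | minutes-scale training on one CPU with a visibly decreasing loss curve |

## The encoder backbone

The method is backbone-agnostic: anything that maps a patch to a feature
vector works, and the training loop accepts any implementation of the
`ContrastiveNet` interface. The default backbone average-pools the patch
to a 16×16 raster, flattens, and applies a two-layer MLP (ReLU) to produce
`h`, with a second two-layer MLP as the projection head. Forward and
backward passes are written explicitly in NumPy; the analytic NT-Xent
gradient (through the cosine normalization) is verified against finite
differences in the test suite. A full-scale profile (ResNet-50, h ∈
R²⁰⁴⁸, z ∈ R¹²⁸, LARS, batch 256, 100 epochs) is recorded as data for
provenance; it is not the default and is not required by any part of the
pipeline.

Pixel intensities are divided by the 16-bit white level inside the network
only; stored images and resizing never rescale intensities.

## Calibration and normalization

Raw nearest-reference distances live on unrelated scales across
resolutions, so fusion needs a common scale. Two normalizations were
deliberately rejected: per-image min–max (it forces every image's maximum
to 1 and makes a fixed threshold vacuous) and literal scalar weighting
with global rescaling (the scalar product Πwᵢ is a global constant that
cancels, making weights irrelevant). Instead, per-resolution scores are
mapped through quantiles of the normal validation score distribution, and
weights act as exponents in a weighted geometric mean. This keeps A_final
in [0, 1], preserves cross-image comparability, reduces to the plain
product + k-th root when all weights are 1, makes the weight vector
genuinely ranking-relevant, and is exactly invariant to rescaling all
weights by a common constant. The literal mode (scalar weights, k-th
root, clipped) is retained for fidelity experiments.

The ε floor before fusion prevents one perfectly matched resolution from
annihilating anomalies visible at other resolutions.

## Synthetic phantoms

The generator emulates the gross geometry of a frontal chest radiograph:
a bright body ellipse on a dark background, two darker lung-field
ellipses, sinusoidal rib banding inside the lungs, per-image uniform
jitter of centers/axes (±0.02 of the side), Gaussian smoothing (σ = 1.5 px)
and additive pixel noise (σ = 0.01 on a [0, 1] scale). Anomalies are
bright or dark blobs with a truncated-Gaussian profile (support confined
to twice the nominal radius) or a local radial deformation, with diameter
8–48 px and |contrast| 0.15–0.45 — the diameter range deliberately spans
several patch scales. Datasets mirror the one-class protocol: normal-only
training, balanced labeled validation/test, per-image seeds in a manifest
for bit-identical regeneration.

What the phantoms do *not* emulate: radiographic physics, anatomical
variability beyond affine-ish jitter, texture-level pathology, acquisition
artifacts. Passing tests therefore demonstrate the mechanics of the method
(representation learning, locality search, fusion, calibration), not
clinical performance.

A known and expected limitation visible on phantoms: the
locality-constrained nearest-reference search is largely blind to small
*geometric deformations*, because a deformed patch resembles a normal
patch at a neighboring grid location, which the radius-d search happily
matches. Intensity anomalies (blobs) are detected reliably; deformations
need either d = 0 everywhere (at the cost of jitter robustness) or a
different scoring principle. The full-scale method shares this trait —
localization weakness is a recognized limitation of patch-broadcast
scoring.

## Numerical choices

- Resampling: bilinear for resize and crop-resize, linear interpolation
  for rotations (nearest-edge padding); all deterministic.
- The Euclidean distance uses the same reduction arithmetic as the
  Mahalanobis quadratic form, so Mahalanobis with identity covariance
  coincides bit-for-bit with Euclidean.
- Mahalanobis uses a cached Cholesky factorization of the regularized
  covariance; negative quadratic forms from rounding are clamped at 0.
- Ties in the nearest-reference search keep the first record in insertion
  order; fusion accumulates maps in ascending patch-size order — both make
  results independent of iteration order.
- Degenerate cases: zero-variance calibration spans fall back to an
  identity scale; an all-zero covariance (duplicated features) is kept
  positive definite by the shrinkage ridge; a batch with a single patch
  pair has zero contrastive loss by construction.
- Cross-validation folds the pooled normal images only (train/val
  rotation) with a fixed labeled test pool — the only folding scheme
  compatible with one-class training — and retrains encoders per fold.

## Problem sizes

The default experiment uses 60 normal training images, 20 + 20 validation
and 20 + 20 test images at 128² with patch sizes {16, 32, 64, 128}; four
encoders train in under half a minute on one CPU and the full experiment
(train → calibrate → score → metrics) completes in well under a minute.
These sizes were chosen as the smallest configuration in which every grid
shape of the full-scale setting (8×8 down to 1×1) is represented and the
anomaly diameter range straddles at least two patch scales.
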