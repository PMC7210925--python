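# Methods

This document describes the models and algorithms implemented in
`octenhance`, the default parameter choices and why they were made, the
scope of the synthetic data generator, and the numerical decisions that
shape the results.

## Problem setting

A single optical coherence tomography (OCT) B-scan is dominated by
speckle: multiplicative-looking interference noise that obscures retinal
layer boundaries. The clinical remedy is frame averaging — acquire N
B-scans at the same position and average them — which raises the window
signal-to-noise ratio by a factor of √N when the per-frame noise is
independent, at the cost of N-fold acquisition time and sensitivity to
fixation drift. The package trains a convolutional network to map a
single noisy B-scan to its N-frame-averaged counterpart, so that
averaged-quality images can be produced from single acquisitions.

## Synthetic phantom generator (`octenhance.phantom`)

Real OCT volumes cannot ship with the package, so training and
evaluation run on procedurally generated retinal phantoms:

- A stack of smooth, non-crossing layer boundaries (cosine-mixture
  curves with bounded curvature and lateral wiggle), each layer with its
  own reflectivity; the deepest band is bright (retinal pigment
  epithelium analogue) and is followed by an exponentially attenuating
  choroid-like region.
- Optional vessel shadows: Gaussian-profile attenuation columns below a
  superficial boundary.
- Noise models: additive Gaussian (default σ = 0.1 at study conditions)
  or Rayleigh speckle-like noise; optional inter-frame correlation (a
  shared noise field mixed as √c·S + √(1−c)·I so the per-frame marginal
  variance is preserved) and integer-pixel fixation jitter.
- `simulate_averaged_scan(truth, n, noise, seed)` draws n noisy frames
  and returns the first frame as the "single acquisition" together with
  the frame average — exactly the pairing used for supervision.

Scope and limitations: the phantom is a layered-tissue caricature. It
reproduces the statistics that matter for this package — piecewise-smooth
anatomy, depth attenuation, controllable noise with a known ground truth
— but it does not model real speckle's spatial correlation within a
frame, pathology (fluid pockets, drusen geometry), or scanner-specific
artifacts. Conclusions about relative method behavior transfer;
absolute quality numbers do not.

Default phantom size is 64×64. This is a desk-scale choice: every
property being tested (noise estimation, the √N law, training descent,
ensemble exactness) is scale-free, and 64×64 keeps a full train/evaluate
cycle in CPU-minutes.

## Enhancement networks (`octenhance.networks`, `octenhance._engine`)

Four comparison families are implemented, all encoder–decoder pyramids
with 3×3 convolutions, ReLU activations, 2×2 average-pool downsampling,
and a final 1×1 convolution clamped to [0, 1]:

- `unet` with transposed-convolution upsampling and concatenation skips;
- `unet` with bilinear upsampling;
- `brunet`: sum skips, pyramid injection of the downsampled input image
  at every encoder level, one convolution block per level;
- `brunet94`: the primary model — like `brunet` but with two
  back-to-back convolution blocks per level on both paths and an extra
  horizontal block at the coarsest level.

Sum skips require the decoder and encoder channel counts to match; the
builder verifies this and raises a `ConstructionError` on mismatch
(testable via the `up_channels` override). Channel widths double per
level from `base_channels`. Inputs whose sides are not divisible by
2^(levels−1) are reflect-padded and cropped back, so arbitrary B-scan
shapes are supported.

No deep-learning framework is available in the target environment, so
the package includes a small reverse-mode automatic differentiation
engine (`_engine.py`): tensors with recorded operations and an iterative
topological-order backward pass. Convolutions use im2col with einsum;
bilinear upsampling and reflect-boundary Gaussian filtering are
expressed as cached dense per-axis matrices whose adjoints are exact
transposes. Gradients were validated against central finite differences
(relative error ~5e-8).

## Training (`octenhance.training`)

- Loss: mean absolute error plus the SSIM complement, `MAE + (1 −
  SSIM)`. The SSIM term is a differentiable re-implementation of the
  reference configuration (Gaussian windows, σ = 1.5, radius 5,
  no sample-covariance correction, K1 = 0.01, K2 = 0.03, data range 1,
  border crop 5) and matches `skimage.metrics.structural_similarity`
  to machine precision on numpy inputs.
- Optimizer: Adam. Full-scale defaults are 500 epochs at learning rate
  1e-4; the desk-scale schedule used in tests and the acceptance script
  is 15 epochs at 1e-3 with batch size 8, which is enough to show
  unambiguous enhancement on 64×64 phantoms within the CPU budget.
- Augmentation (`octenhance.augment`), each applied independently with
  probability 0.5 per mini-batch: additive Gaussian (σ = 0.5) or
  Rayleigh (σ = 0.2) noise; intensity transform a·x^g + b with a, b, g
  drawn from [0.5, 1.5]; joint rotation ±45° and scaling 50–150%;
  Gaussian blur σ = 1.0. Corruptions (noise, intensity, blur) hit only
  the input; geometric transforms are applied jointly to input and
  target. Tiered configurations (none / noise+intensity / all) support
  the distillation grid.
- Distillation (`distill_synthetic_set`): a grid of networks over
  architectures × datasets × noise models × augmentation tiers is
  trained, and the mean of their predictions on a base set becomes the
  synthetic target of a distilled training set. All cells share the
  grid seed, so cells that differ only in a label are bit-identical —
  the mean of equal predictions equals either one, which is the
  correctness anchor used in tests.

## Test-time ensemble (`octenhance.ensemble`)

An ensemble of up to four trained members enhances each image twice —
once raw and once histogram-equalized (`skimage.exposure.equalize_hist`,
256 bins) — and averages the up-to-eight predictions, clipping to
[0, 1]. The implementation is an exact arithmetic mean; tests compare it
against an explicit brute-force accumulation.

## Objective quality metrics (`octenhance.metrics`)

- Noise: Immerkaer's fast estimator — the absolute response to the
  3×3 Laplacian-difference mask, scaled by √(π/2)/6 and averaged over
  valid pixels. It is exactly zero on constant and planar images and
  recovers planted Gaussian σ within a few percent.
- Window SNR: mean of a signal window divided by the sample standard
  deviation of a disjoint noise window (half-open index windows,
  ≥16 pixels each, validated for disjointness). `default_windows`
  places the noise window in the dark vitreous-like top rows and the
  signal window on the brightest band.
- SSIM and MAE against the noiseless phantom when ground truth exists.
- Paired statistics: two-sided paired t-test (`scipy.stats.ttest_rel`)
  over per-image metric differences; degenerate (constant-difference)
  inputs are rejected rather than reported with an infinite statistic.

## Intergrader agreement (`octenhance.agreement`)

Grading records carry ten binary biomarkers (IRF, SRF, ERM, Drusen,
RPD, GA, iRORA, PED, HE, SCAR_FIB) and a 1–10 quality score per image,
grader, and condition (original vs enhanced), for exactly two graders.

- Cohen's kappa per biomarker and condition, computed from the 2×2
  contingency table; cross-checked against scikit-learn.
- Wilcoxon signed-rank test on quality (original vs enhanced) per
  grader. Zero differences are dropped and midranks used. For n ≤ 25 the
  two-sided p-value is exact, computed by dynamic-programming
  convolution over doubled ranks (valid under ties, where the standard
  exact tables are not); larger n uses the tie-corrected normal
  approximation.
- `simulate_grading_records` provides a planted-truth generator: each
  grader's label is the true biomarker flipped independently with
  probability q, which gives the closed-form agreement
  κ = (p_o − p_e)/(1 − p_e) with p_o = (1−q)² + q², used as the oracle
  in tests (`flip_model_kappa`).

## Numerical choices

- All images are float64 in [0, 1]; file I/O (8/16-bit PNG and TIFF)
  scales linearly with round-half-to-even.
- Seeds are propagated through `numpy.random.SeedSequence` and reduced
  modulo 2³¹, so every artifact is reproducible from one integer.
- Noise is additive and clipped to [0, 1] after corruption; with the
  default background level 0.15 and σ = 0.1 the clipping bias is small
  enough that the √N averaging law holds within the tested 15%.
- Training batches are stacked only when shapes agree; augmentation
  draws are keyed by (epoch seed, batch index) so runs are bit-stable.

## What is not claimed

No empirical claim is made about real OCT data, reading-center grading
behavior, or full-scale (hundreds of epochs, megapixel B-scans)
training. All reported numbers are computed on the synthetic phantoms
at the desk-scale settings above, by the test suite and by
`scripts/acceptance.py`.
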