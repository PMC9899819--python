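# Methods

`octaclear` implements a two-stage quality-improvement pipeline for 2-D
*en face* angiography images (OCTA and anterior-segment OCTA), where the
two dominant degradations are treated in sequence: additive stripe
artifacts from eye motion, then globally poor vessel/background contrast.

## Image model

A corrupted image is modelled as an exact additive decomposition

    I = N + C,        I, N, C : H x W,  values in [0, 1]

with `C` the clean vessel image and `N` a non-negative stripe-noise field.
Two physical priors drive the design: stripes are *bright* additive bands
aligned with the scan direction, and a field of parallel bands is
approximately *low rank* as a matrix (a full-span constant band is exactly
rank one).

## Stage 1 — stripe removal

A U-shaped encoder–decoder (`srnet`) maps `I_in` to a predicted noise map
`N_out`; the clean estimate is the residual composition
`C_out = max{I_in − N_out, 0}`.  The final layer is a ReLU, so predicted
noise is non-negative by construction.

The training objective is

    L_destripe = alpha * L_recon + beta * L_stripe + gamma * L_ATV

- `L_recon = 1/2 ||I_in − (N_out + C_out)||_F` ties the decomposition to
  the input.
- `L_stripe = ||Stripe(N_ref) − Stripe(N_out)||_F`, where
  `Stripe(N) = U·shrink(S)·V^T` soft-thresholds the singular values of
  `N` (`shrink(S) = max(S_ii − lambda, 0)`).  `Stripe(·)` is the proximal
  operator of `lambda * ||·||_*`; comparing both noise maps after this
  degradation focuses the loss on the dominant low-rank stripe component.
- `L_ATV = | ATV(C_ref) − ATV(C_out) |` matches anisotropic total
  variation (sum of L1 norms of horizontal and vertical forward
  differences, no wrap-around), preserving overall edge sharpness.

Defaults: `alpha = 0.5`, `beta = 2`, `gamma = 1`, `lambda = 0.002` on the
[0, 1] intensity scale; Adam (beta1 0.9, beta2 0.999, eps 1e-8), batch 16,
learning rate 2e-4 held constant for the first half of training and
decayed linearly to zero over the second half (default 150 + 150 epochs).

Numerical choices worth noting:

- The Frobenius norms are implemented unsquared, exactly as written; a
  `norm_variant="squared"` switch exists because the squared form has
  smoother gradients, but the literal form is the default.  The gradient
  of `sqrt(·)` is guarded at zero so a perfect batch does not produce NaNs.
- `L_ATV` literally compares two scalars.  Because that form cannot
  localize which edges changed, an elementwise variant
  (`atv_variant="map"`, comparing absolute-gradient maps) is provided; the
  scalar form is the default.
- `L_stripe` is differentiated *through* the SVD using the standard
  reduced-SVD adjoint.  Denominators coupling (near-)equal squared
  singular values, and inverse singular values, are guarded: the
  corresponding terms are zeroed, i.e. a subgradient is used at the
  non-smooth points.  The soft-threshold kink uses subgradient 0.
- The final convolution is initialized near zero (zero weights, bias
  0.02) so an untrained network predicts an almost-empty noise map and
  training refines the identity decomposition.  The small positive bias
  keeps the output ReLU active; an exactly-zero ReLU input would block all
  gradients.  Initialization from a safe identity matters at desk scale,
  where schedules are short.

### Tiny profile

All networks ship with a `tiny()` profile used by the test suite and the
acceptance script: depth 2, 8 base channels, 20 epochs (10 constant + 10
decay), learning rate 1e-3.  The hotter rate is this package's default
for short schedules; the reference recipe (2e-4 over 300 epochs) remains
the full-profile default.  Desk-scale study sizes — 200 training and 40
held-out 64x64 triplets at corruption level 2, 30 + 30 enhancement images
for 10 epochs — were chosen so a complete run takes minutes on one CPU
while the measured trends (PSNR/SSIM/Dice gains from de-striping, vessel
contrast gain from enhancement) are stable across seeds.

## Stage 2 — contrast enhancement

Low- and high-contrast images are unpaired domains X and Y.  Two residual
generators `G_XY`, `G_YX` (output = `clamp(x + f(x), 0, 1)`, zero-initialized
final layer, hence exactly the identity before training) and two
strided-convolution patch discriminators are trained with:

- baseline: least-squares adversarial losses, image-level cycle
  consistency (L1, weight 10) and identity regularization (L1, weight 5)
  — the canonical unpaired-translation recipe;
- cyclic perceptual loss (weight `xi = 0.5`): squared Frobenius distance
  between features of `x` and of the cycle reconstruction
  `G_YX(G_XY(x))`, summed over a shallow and a deep tap of a fixed
  extractor, plus the symmetric Y-direction term;
- structure loss (weights `rho1 = rho2 = 0.5`): one minus the mean
  per-window SSIM structure term, over non-overlapping 8x8 windows with
  stabilizer `c = 0.03^2 / 2`; the value is bounded in [0, 2] and is
  exactly 0 for positive affine intensity maps, so it penalizes only
  genuine structural distortion.

Setting `xi = rho1 = rho2 = 0` recovers the baseline objective exactly —
the ablation axis exercised in the tests.

The feature extractor is pluggable.  The shipped default is a fixed,
seeded-random CNN (conv + ReLU + 2x max-pool stages, taps after pooling
stages 2 and 5) — deterministic and offline; a pretrained perceptual
backbone can be substituted where available, but no pretrained weights are
bundled.  A linear (identity) extractor is included for the equivalence
check that feature-level cycle consistency with `phi(x) = x` collapses to
the squared image-space cycle error.  Grayscale inputs feed the extractor
directly (1 channel); features are compared with raw, unnormalized
Frobenius norms.

Training uses Adam (beta1 0.5), batch 1, a seeded size-50 replay buffer of
past fakes for discriminator updates, and the same constant-then-linear
rate schedule (default 100 + 100 epochs, 2e-4).

## Synthetic data

No public paired dataset exists for this problem, so the package generates
phantoms with complete ground truth:

- *Clean images*: smooth random spline curves rasterized with sampled
  thickness (1.5–3 px) and brightness (0.55–0.95) on a speckled dark
  background (level 0.15, texture sd 0.05), lightly blurred (sigma 0.7);
  the exact binary vessel mask is returned alongside.  Defaults put the
  vessel fraction near 20% of pixels, comparable to a thresholded en-face
  capillary map.
- *Stripe fields*: Poisson(3) parallel bands per field, thickness 1–4 px,
  additive amplitude 0.1–0.5, full-span with probability 0.7 (partial
  bands cover at least 30% of the row), smoothed by a 1-px Gaussian along
  the short axis only — each band stays rank one, so the field's rank is
  bounded by the stripe count.  Orientation is horizontal by default
  (constant along rows) and configurable.
- *Corruption level i*: the number of independent stripe fields summed
  onto a clean image.  The sum is clipped to [0, 1] and the stored noise
  recomputed as `corrupted − clean`, so the additive identity is exact
  even where clipping engaged — the reconstruction and stripe losses
  assume that identity.
- Files: 16-bit grayscale PNG images, 8-bit {0, 255} masks, TSV manifest
  recording ids, levels, splits and every seed; a dataset is bit-for-bit
  reproducible from its manifest.

What the phantoms do *not* emulate: instrument-specific speckle
statistics, foveal avascular zone anatomy, capillary-density variation, or
disease-specific vasculature.  Passing tests therefore demonstrate that
the machinery behaves as designed under the stated noise model, not
clinical performance.

## Evaluation

- PSNR: `10·log10(max_val² / MSE)`, `max_val = 1` for normalized images;
  identical images report an infinite sentinel which aggregation excludes.
- SSIM: standard Gaussian-weighted form (11x11 window, sigma 1.5,
  K1 = 0.01, K2 = 0.03, population moments, filter-radius border
  excluded); cross-validated against scikit-image to 1e-6.
- Segmentation route: a deliberately simple, deterministic baseline
  segmenter (Gaussian high-pass with sigma 8, then a global 75th-percentile
  or Otsu threshold) feeds Dice, sensitivity, specificity and G-mean.  A
  2-pixel border is excluded from mask comparisons (edge effects of the
  renderer).  One published formulation prints specificity as
  `FP/(FP+TN)`; that is the false-positive rate and would invert the
  G-mean's direction, so the standard `TN/(TN+FP)` is used.
- Degenerate denominators return NaN sentinels with a warning and are
  excluded from aggregates.

## Implementation notes

The networks and losses run on a small reverse-mode automatic
differentiation core (`octaclear.nn`) written on NumPy in float64:
convolution as batched GEMM over an offset-major column matrix, 2x max
pooling, nearest upsampling, instance normalization, and the SVD
soft-threshold operator with the adjoint described above.  Every gradient
is validated against central finite differences in the test suite.
Training is fully seeded (initialization, data order, replay buffers);
two runs with the same configuration are bitwise identical on the same
BLAS, and the pipeline's reproducibility test asserts agreement of all
aggregate metrics to 1e-5.

Known limitations: CPU-scale throughput (minutes per desk-scale run;
the full 300-epoch reference schedule is impractical here), 2-D en-face
processing only (no B-scan volumes), no multi-GPU or mixed precision, and
enhancement quality is bounded by the synthetic domain gap — the GAN sees
phantom contrast statistics, not clinical ones.
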