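# Methods

## Problem setting

Sparse-view, low-dose CT: a 2D attenuation image `x*` (values in [0, 1]) is
observed only through noisy line integrals `y = A x* + η`, where `A` is a
64-view parallel-beam Radon transform with 512 detector bins and `η` is
zero-mean white Gaussian noise at a prescribed sinogram signal-to-noise
ratio.  Filtered back projection (FBP) of such data is dominated by streak
artifacts and amplified noise; the package trains an image-domain denoiser
`f_θ` to clean FBP outputs **without ever seeing clean images or clean
projections**.

## Self-supervised objective

A supervised denoiser would minimise `E‖f_θ(FBP(y)) − x*‖²`.  With only the
noisy projections available, the package instead minimises the
projection-domain residual

    E‖J(A f_θ(FBP(y_Jc)) − y)‖²,

where `J` selects a subset of sinogram pixels and `y_Jc` is the sinogram with
that subset *perturbed*.  Expanding `‖A f_θ − y‖² = ‖A f_θ − A x*‖² + ‖η‖² −
2⟨A f_θ − A x*, η⟩` shows why this works: the noise-power term carries no
gradient, and the cross term has zero expectation whenever the network output
is independent of the noise in the target pixels.  The perturbation enforces
exactly that independence (the blind-spot principle): the network never sees
the value it is scored against, so it cannot satisfy the loss by copying
noise through — whereas with the perturbation disabled the trivial identity
mapping attains the loss, and training collapses onto the FBP input.  The
test suite verifies the decomposition by Monte-Carlo and the collapse by an
ablation run.

Masking lives in the *projection* domain because the noise is white there;
after back projection, noise becomes spatially correlated and the
independence argument fails (image-domain masking is reported to collapse to
the identity).

### Perturbation procedure

1. Tile the sinogram with 4x4 cells.
2. At training iteration `t`, select cell-internal position `t mod 16`
   (row-major within the cell) — the same position in every cell, so each
   16-iteration window visits every sinogram pixel exactly once.
3. Replace each selected pixel with the mean of its 4-connected neighbours,
   computed from the unperturbed sinogram.  Edge pixels use their 2-3
   in-bounds neighbours.  The loss is then evaluated *only* on the selected
   pixels, against the *unperturbed* sinogram, and averaged over them (a sum
   would only rescale the learning rate).

At inference no perturbation is applied: the reconstruction is simply
`f_θ(FBP(y))`.

## Forward operator

The projector is assembled as an explicit sparse matrix: pixel-driven,
bilinear sampling of the image on a grid rotated to each view (unit step
along both the detector axis and the ray), summed along the ray.  Angle 0
sends rays parallel to the image columns; detectors are centred on the image
centre with one-pixel spacing; angles are uniform on [0, π).  This
representation has three properties the method needs:

- the **adjoint is the exact matrix transpose** (verified to 1e-3 relative by
  inner-product tests, and in practice exact to float32 rounding), so the
  gradient of the projection-domain loss with respect to the denoised image
  is simply `Aᵀ` applied to the masked residual;
- the **same operator** serves simulation, the training loss, FBP and SART —
  no systematic operator mismatch enters the loss;
- sparse matrix-vector products are fast enough to train on one CPU core.

FBP applies the standard discrete ramp (space-domain kernel `h[0] = 1/4`,
`h[odd n] = −1/(πn)²`, zero-padded FFT) per view and scales the
backprojection by `π / (2 n_views)`.  FBP output is *not* clipped; value
range policy belongs to the evaluation layer.  Operators above ~120M
nonzeros (e.g. 720-view consistency checks) are streamed in view blocks
rather than cached.

The discretisation resolves the head phantom's interior to ~40 dB at 720
noiseless views, but sharp discontinuities (the skull rim) are blurred by
the bilinear footprint by roughly half a pixel — an accuracy limit shared
with common inverse-Radon implementations.  Consistency checks therefore
measure over the brain interior (disk of radius 0.3 x image side), away
from the rim discontinuity.

## Denoiser and training

`f_θ` is a U-Net-style encoder-decoder: two 3x3 convolutions + ReLU per
scale, 2x average pooling, nearest-neighbour upsampling with skip
concatenation, and a final 1x1 convolution.  Channels double per scale.  The
reference configuration is five scales starting at 64 channels
(64...1024, ~31.4M parameters as implemented here; published parameter
counts for this family vary widely with the unstated layer recipe, so the
package documents its own count rather than forcing a match).  Desk-scale
experiments use a compact four-scale, 8-channel preset (~122k parameters):
depth is kept because the receptive field is what streak suppression needs,
while channel counts — where the compute lives — are cut.  (In desk pilots
the four-scale net beat an equally trained three-scale one by ~1 dB and a
five-scale one by ~0.7 dB held-out.)  A four-scale/16-channel preset is
also provided.

The network is implemented directly on numpy (float32; convolutions as nine
shifted BLAS matmuls; hand-written backward passes verified against finite
differences to 1e-3).  Adam with standard moments is the optimiser; the
full-scale learning rate is 1e-4, and desk-scale runs use 3e-3 to
compensate for the shortened (2,000-iteration) schedule.  Batch size 2 at
desk scale.  Because the perturbed sinogram depends on the iteration only
through `t mod 16`, FBP inputs are cached per (sample, phase) — 16 FBPs per
training sinogram over the whole run.

Checkpoint selection uses the best *validation self-supervised loss* at a
fixed perturbation phase (offset 7): clean references do not exist by
construction, so validation must use the same masked objective.  Training
aborts with a diagnostic on non-finite loss.  Runs are bit-reproducible
given the config seed.

## Baselines

- **SART** (Andersen–Kak): per iteration the views are swept sequentially;
  for view `k`, all of its rays are corrected simultaneously,
  `x ← max(0, x + λ·A_kᵀ((y_k − A_k x)/r_k)/c_k)`, with per-ray weight sums
  `r_k` and the view's per-pixel weight sums `c_k`; 40 iterations,
  relaxation λ = 0.15.  The block-sequential sweep is what makes a
  40-iteration budget sufficient — a fully simultaneous (SIRT-style) update
  plateaus far short of convergence in that budget.  Nonnegativity is
  clamped after every view update; a residual that grows five consecutive
  iterations triggers a warning.
- **TV**: Rudin–Osher–Fatemi denoising `argmin_u ‖u − v‖²/2 + w·TV(u)` via
  the Chambolle dual projection scheme (≤200 iterations, tolerance 1e-4);
  the benchmark weight 0.9 refers to this parameterisation.  SART+TV is SART
  followed by TV post-denoising.

## Synthetic data

- **Shepp–Logan**: the standard 10-ellipse head phantom, rasterized with 4x
  supersampling (area-weighted edges), clipped to [0, 1].  Note the standard
  phantom is only *approximately* mirror-symmetric: the three small bottom
  ellipses are deliberately asymmetric in the classical parameter table.
- **Random ellipses**: emulates the artificial-ellipses benchmark
  distribution used for sparse-view CT: per image, `min(Poisson(40), 70)`
  ellipses; intensity uniform in [−0.4, 1.0] (negative values carve darker
  structure); semi-axes `0.2·Exp(1)` capped at 1; centres uniform in
  [−0.9, 0.9]²; rotations uniform in [0, 2π); the sum clipped to [0, 1].
  Rasterized with 2x supersampling.  By default the image is confined to
  the inscribed **field-of-view disk**: CT scanners measure a circular FOV,
  and circular inverse-Radon implementations reconstruct (and zero) exactly
  that region.  Benchmark comparisons mask reconstructions to the same
  disk.
- **Noise**: white Gaussian per sinogram entry with variance
  `mean(y²)·10^(−SNR/10)` — SNR is defined against whole-sinogram mean
  power.  The per-entry independence is what the blind-spot argument needs.

What the generators do *not* emulate: photon-count (Poisson) statistics,
detector cross-talk, beam hardening and scatter, anatomical texture, and the
correlated noise of real normal-dose references.  Passing tests therefore
demonstrate the mechanism (operator consistency, blind-spot training
dynamics, method orderings) on piecewise-smooth phantoms, not clinical
performance.

## Evaluation conventions

The metrics module uses the standard definitions: PSNR
`10·log10(range²/MSE)` and mean SSIM with the 11x11 Gaussian window
(σ = 1.5, K1 = 0.01, K2 = 0.03), both at data range 1.0, with
reconstructions clipped to [0, 1] first (stated in every report).

Comparisons against the published benchmark table additionally apply the
**circular field-of-view convention**: phantoms carry content only inside
the inscribed disk and reconstructions are masked to it before clipping, as
circular inverse-Radon implementations return them.  The FOV matters
quantitatively — without it, FBP's corner streaks depress SSIM severalfold
and shift PSNR by decibels; with it, the package's FBP cells at 30 dB land
inside the published values' printed standard deviations under the standard
metrics.  Our SART lands 1-2.5 dB above the published 30 dB cell (the
per-view sweep on this discretisation converges slightly better than the
reference pipeline); the 40 dB cell agrees within its printed std.

## Problem sizes and numerical choices

- Reference-table reproduction: 200 phantoms (FBP cells) and a 100-phantom
  subset (SART) at the full 512² / 64-view / 30 dB operating point.
- Desk-scale training: 128² images, 64 views, 33 dB, 12 training / 4
  validation / 6 held-out sinograms, 2,000 iterations — sized so a full
  self-supervised run finishes in a few minutes on one CPU core while still
  clearing FBP by ≥3 dB on held-out phantoms.
- Ties and degenerate inputs: ReLU subgradient at 0 is taken as 0; empty
  masks, zero-power sinograms, sub-cell sinograms and mismatched shapes are
  rejected with explicit errors; the noiseless sentinel (`snr_db=None` or
  `inf`) returns the input unchanged.
- float32 is used for the network and projector (the adjoint identity and
  gradient checks are run in float64 where precision matters).

## Known limitations

- Parallel-beam geometry only; no fan/cone beams, no physics beyond additive
  Gaussian noise.
- The projector's bilinear footprint blurs discontinuities by ~0.5 pixel;
  printed dataset-average metrics can shift slightly under a different
  (equally valid) discretisation pair.
- SART at desk resolutions (≤128²) is convergence-limited with the benchmark
  hyperparameters (40 iterations, λ = 0.15) and can score below FBP there;
  the published ordering SART > FBP emerges at the full 512² operating point
  where noise dominates FBP.
- BM3D and LPIPS comparisons require optional external packages and are not
  implemented internally; the deep-image-prior baseline is out of scope.
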