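# Methods

## Pipeline model

The simulation study is a fixed chain:

```
phantom → fan-beam projection → additive Gaussian projection noise → FBP
        → {none | classical amoeba | RBS amoeba} → quality metrics vs phantom
```

All images are 2-D float arrays indexed `(row, col)`, row 0 at the top,
intensities nominally in `[0, 1]`.  All physical lengths (source distance,
detector spacing, ray sampling) are expressed in image pixel units — the
phantom has no physical calibration, so "0.25 mm detector spacing" is read
as 0.25 px.

### Phantom

The head phantom is the classic ten-ellipse composition on `[-1, 1]²`,
sampled at pixel centers and clipped to `[0, 1]`.  Two gray-level variants
exist: the *standard* table (soft tissue at 0.01–0.04, nearly invisible
against the skull) and the *modified* high-contrast table (soft tissue at
0.1–0.4).  The experiments default to the modified variant: it is the one
whose sparse-view FBP baseline reproduces the reference study's printed
quality numbers (standard-variant SSIM comes out ~0.40 where ~0.24 is
expected), and the only one whose interior features are visible in that
study's figures.  `shepp_logan(size, modified=False)` selects the standard
table.  Note the standard ellipse table is *not* exactly mirror-symmetric:
the three small features near the bottom break left-right symmetry.

### Fan-beam geometry

Flat (equally spaced) virtual detector through the rotation center; the
source rotates at `source_to_center` from the image center; view angles
default to `0°, 2°, …, 178°` (90 views over a half rotation).

* `source_to_center` defaults to **8× the image width**.  The study this
  package models leaves the distance unstated.  At small distances a
  half-rotation fan scan is *incomplete*: a line measured at fan angle γ
  needs view angle β = θ − γ, so lines with θ < γ (and symmetrically at the
  other end) are simply never measured, and the missing wedge grows with
  the fan angle.  At 2× the width (fan half-angle ≈ 20°) the noise-free
  dense-view reconstruction error more than doubles; at 8× (≈ 5°) the scan
  is nearly parallel and a dense noise-free reconstruction reaches
  RMSE < 0.03 against the phantom.
* `detector_spacing` defaults to 0.25 px; the detector count is the
  smallest odd number whose fan covers the image diagonal.
* The projector is ray-driven: each source-to-bin ray is sampled at 0.5 px
  steps with bilinear interpolation (midpoint rule over the support
  circle's chord).  Projection is exactly linear in the image.

### Projection noise

`add_projection_noise` defaults to the *measured* convention: noise variance
`mean(signal²) / 10^(SNR/10)`, a true power ratio over the sinogram.  The
experiment pipeline instead uses the *unit-reference* convention
(`NoiseSpec(reference="unit")`): variance `10^(-SNR/10)` per sample
regardless of signal scale — the default behavior of the most widespread
engineering implementation of "add AWGN at x dB".  The distinction matters
enormously here because sinogram line integrals are O(100): under the
measured convention, 3 dB noise obliterates the reconstruction (SSIM ≈ 0.01),
which is irreconcilable with the reference study's printed baseline
(SSIM 0.24, RMSE 0.074); under the unit convention the baseline lands on
those printed values.  Both conventions are seed-reproducible.

### FBP

Cosine-weighted (`D/√(D²+s²)`) rows, band-limited ramp (Ram-Lak) filtering
via the standard discrete spatial kernel, then back-projection with the
`1/U²` magnification weight and half-scan normalization `Δβ = π/n_views`
(spans > 270° are halved for full rotations).  Output is clipped to `[0, 1]`
for metric evaluation (`clip=False` disables).

The ramp's **band limit defaults to the output grid's Nyquist** (i.e. cutoff
fraction = `detector_spacing` when bins are finer than a pixel).  With
0.25 px bins the unrestricted ramp passes frequencies up to 4× what a
512-grid can represent; that band carries no representable structure and its
(heavily amplified) noise aliases into the image — with full bandwidth the
noisy baseline degrades from RMSE 0.064 to 0.65.  `hann`, `cosine` and
`shepp-logan` apodizations are available; `cutoff=1.0` restores the full
band (useful for noise-free dense-view studies).

### Pilot images

* Wiener pilot: 9×9 reflect-padded local moments; gain
  `max(σ_L²−σ_n², 0)/σ_L²` clamped to `[0, 1]` (pixels with unit gain pass
  through exactly).  `σ_n²` defaults to the mean of the local variance map —
  the standard adaptive-Wiener estimator, slightly biased upward on
  structured images — and can be overridden with the known injected value.
* Gaussian pilot: σ = 2 px, truncated at 3σ, unit-sum kernel, reflect
  boundaries.

### RBS kernel shaping

Per window (9×9 default, truncated — never padded — at image borders):

1. **Flat test**: intensity span ≤ `uniformity_tolerance` keeps the full
   square.  Default **0.02** in `[0, 1]` units, on the order of the
   reconstruction noise floor in flat regions, so noise-only windows count
   as "little/no variation" and get the full 81-pixel average.  (A tolerance
   far below the noise floor never declares any window flat and leaves
   visible residual noise in homogeneous tissue.)
2. **Class count**: N walks 2, 3, … and stops when the relative gain in
   between-class variance drops below 5%, capped at `max_classes`
   (default 4) and at the number of occupied histogram bins.
3. **Multilevel Otsu**: the window is quantized to 64 uniform bins over its
   own `[min, max]`; the exact optimum of the between-class variance over
   all cut placements is found by dynamic programming in `O(N·64²)` (the
   test suite asserts equality with exhaustive search).  Ties break toward
   the lowest thresholds.  Thresholds are the upper bin-edge intensities.
4. **Bin of interest**: the half-open interval `(T_{k-1}, T_k]` containing
   the center intensity (a center exactly on a threshold joins the lower
   bin).
5. **Central connected component**: flood fill from the center, 8-connected
   by default (4-connected available).

A center pixel isolated in its bin keeps a singleton kernel (identity at
that pixel) rather than widening the bin.

### Classical amoeba baseline

Geodesic distances within the window by iterated relaxation; step cost
`1 + λ·|pilot difference|` with λ = 10 (on `[0, 1]` intensities) and budget
r = 4 (half the window), both unstated in the original description and
exposed in the configuration.  With λ = 0 the kernel is the hop-count ball.

### Quality metrics

* `psnr = 20·log10(i_max/rmse)` with `i_max = 1`; identical images report
  the 99 dB sentinel.  The identity with RMSE is asserted to 0.05 dB on
  every computed pair.
* SSIM with unit exponents and `C3 = C2/2` (so contrast and structure merge),
  stabilizers `(0.01·i_max)²`, `(0.03·i_max)²`; computed per 8×8 uniform
  sliding window and averaged over the interior (a global single-window mode
  exists).  Against an independent implementation with a 7×7 uniform window
  and population moments the two agree to 1e-7.
* EPI: Pearson correlation of the mean-removed responses to the 3×3
  Laplacian (all ones, center −8), over the whole image; constant inputs
  return the sentinel 0.
* SI: `−log10 Φ((μ − TV(B))/σ)` with Φ the upper Gaussian tail and μ, σ the
  Monte-Carlo mean/std of the anisotropic total variation over 100
  phase-randomized copies of B (power spectrum preserved, phases drawn from
  a seeded white-noise field).  SI is a *phase-coherence* statistic: noise
  lowers it, but blurring a clean synthetic step actually raises it, so only
  orderings on matched content are meaningful.  Constant images raise an
  undefined-metric error; `quality_report` records undefined metrics as NaN
  with a flag instead of a silent number.
* SC and NAE as plain energy-ratio and L1-ratio sums.

## Seeds and replication

Everything stochastic (projection noise, SI phase draws) is driven by
explicit integer seeds.  Sweeps use one fresh seed per (point, replicate),
shared across schemes within the point, so scheme comparisons are paired.
Reproduction checks use medians over 5 noise replicates.

## Problem sizes used by the test suite

Unit and property tests run on windows and small images (≤ 256²).  The
study-reproduction checks run at the full reference conditions (512², 90
views, 5 seeds); the ordering sweeps run at 512² over SNR ∈ {0, 3, 6, 10,
20} dB and increments ∈ {0.5, 1, 2, 4, 8}° with 5 paired seeds per point.
The clean-limit and dense-view-accuracy checks run at 256² with bounds the
package computed at that size (FBP/RBS RMSE < 0.04, classical < 0.08, all
SSIM > 0.75).

## What the synthetic study does and does not show

The generator emulates monochromatic, scatter-free, noise-stationary
acquisition of a piecewise-constant 2-D phantom.  Real CT data adds
polychromatic beam hardening, Poisson photon statistics, detector cross-talk,
patient motion and genuinely textured tissue; none of these are modeled, so
passing the reproduction checks demonstrates the *mechanism* (region-shaped
averaging preserves contours while smoothing homogeneous regions) rather
than clinical performance.  Two honest discrepancies with the reference
results are worth stating plainly:

* **EPI level of the denoised image.**  Because the RBS kernel never crosses
  a contour, the output's Laplacian response correlates with the phantom's
  at ≈ 0.95 here, where the reference study prints 0.376 for its best
  scheme.  A value that low implies substantial residual high-frequency
  decorrelation (or sub-pixel edge displacement) that is inconsistent with
  the same study's printed RMSE/SSIM for the same image; this implementation
  reports what it computes.
* **Very coarse sampling.**  At 4–8° increments the dominant degradation is
  structured streaks, not noise.  Region-based shaping treats streaks as
  anatomy and preserves them, so the classical amoeba (whose Gaussian pilot
  blurs streaks away) scores higher SSIM there; the proposed scheme wins at
  0.5–2° and at every noise level tested.  This is a real boundary of the
  method, not an implementation artifact.

## Other limitations

Mean aggregation only (no median/morphological variants); 2-D axial
geometry only; the per-window class-count rule (step 2 above) is this
package's concrete interpretation of an "adaptive" multilevel threshold
count, since no selection rule is printed in the reference description.
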