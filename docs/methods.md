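# Methods

## Scope and data model

`innervaquant` quantifies marker-positive (nerve fiber) pixel density in
fluorescence images of skin wound sections. All computation happens on a
single 2-D intensity plane (`MarkerImage`) normalized to [0, 1] by the
source dtype maximum, so an 8-bit and a 16-bit export of the same section
yield the same statistics. Spatial context comes from two integer label
masks on the same pixel grid (`RegionLabelSet`): lateral *regions* (wound
bed, outer edge 1, wound center, outer edge 2, uninjured) and vertical
*layers* (epidermis, dermis, 0 = neither). Coordinates are 0-based
(row, column), row-major, everywhere.

## Threshold model

Per image, in order:

1. **Background.** The low spectrum is every intensity ≤ Q1 of the image's
   distribution. Within that subset, values below its own lower Tukey fence
   (Q1_low − 1.5·IQR_low) are discarded as outliers; the background is the
   median of what remains. The background is subtracted from every pixel,
   floored at 0. This removes the per-slide offset so images from different
   staining batches are comparable.
2. **Robust statistics.** On the subtracted values: min, max, mean, median,
   Q1, Q3, IQR, and Tukey fences at 1.5·IQR. Quantiles interpolate linearly
   between order statistics (quantile *p* at rank *p*·(n−1)), the numpy
   default; the convention matters at small n and is pinned by unit tests.
   The *robust maximum* M is the largest value at or below the upper fence
   — isolated ultra-bright outliers (debris, dead pixels) are excluded from
   consideration.
3. **Classification.** A pixel of value v is positive iff it is strictly
   closer to M than to Q3, which is algebraically v > (M + Q3)/2. Exact
   midpoints are negative ("above the threshold" is read strictly). If
   M == Q3 (e.g. ≥ 75% of pixels share one value) the image is degenerate:
   all pixels are negative and a warning is logged rather than raising —
   nearly-empty early-timepoint sections must not abort a batch.
4. **Density.** For each (region, layer): positive pixels / cell area.
   "whole" means any named tissue layer (epidermis ∪ dermis), so epidermis
   and dermis counts add up to the whole exactly whenever they partition
   the region. Density is a dimensionless pixel fraction; when a physical
   pixel size is supplied it cancels in the ratio, so no unit conversion is
   applied.

**Statistics scope.** The threshold statistics are computed once per image
over all pixels inside any labeled region. Region masks are expected to
span the full section column (the way an annotator draws lateral wound
boundaries), so in practice the statistics population is the whole frame,
including the empty mounting medium above and below the tissue. This is
deliberate and load-bearing: the decision rule forces threshold ≥ Q3, so at
most a quarter of the statistics population can ever be classified
positive. Densely innervated tissue (uninjured skin approaches a density
of 0.9 in the literature) is only measurable because the frame's dark
non-tissue majority keeps Q3 at the tissue-background level. Conversely,
the distribution between background and fiber intensity (autofluorescent
debris in real sections, simulated speckle here) props up the robust
maximum, lifting the threshold above the background noise tail; this is
what keeps the false-positive rate of fiber-free sections below ~0.5%.
With threshold statistics restricted to pure, uniform tissue the rule would
place the cut inside the background distribution — a known property of the
method, not of this implementation.

An optional negative-control floor (99th percentile of a no-primary-antibody
section's subtracted intensities) can raise the threshold but never lower
it.

## Residual denoiser

The denoiser is the canonical residual-learning stack: Conv+ReLU, then
(depth−2) blocks of Conv+BatchNorm+ReLU, then a final Conv producing one
plane interpreted as the noise residual; output = clip(input − residual).
Zero final-layer weights therefore give an exact identity — the property
that makes shallow residual denoisers trainable and is asserted in tests.
Convolutions are 3×3, zero-padded 'same', implemented via im2col and BLAS
matmul in float32; batch normalization keeps running statistics (momentum
0.9, eps 1e-5) and switches to them at inference; training minimizes the
MSE between predicted residual and true noise with Adam. Everything is
numpy on one CPU; gradients are verified against finite differences in the
test suite. Inference on large images runs in horizontal bands with a
receptive-field halo clamped to the image border, which is exactly
equivalent to a whole-image pass.

Defaults: depth 17, 64 filters (the canonical architecture). The test and
demo profile is depth 7, 32 filters, 40×40 patches, batch 8, learning rate
2·10⁻³, 5 epochs on 512 synthetic pairs — chosen so a full training run
takes ~2–3 minutes on one CPU while still gaining ≥ 2 dB held-out PSNR at
σ = 0.1 (measured ≈ 3.5–3.7 dB). Training noise is Gaussian with σ drawn
per patch from `train_sigma_range` (blind denoising); the deterministic
3×3 median filter is available as `--denoiser median` and is the default
for the quantification tests, because it needs no training and preserves
the 2–3 px fibers the generator draws (a 5×5 median would erase them).

## Synthetic sections

The generator emulates a transverse wound section on glass:

- **Geometry.** A horizontal tissue band occupying the central 28% of the
  frame, split laterally into outer edge 1 (15% of width), wound bed (20%),
  wound center (30%), wound bed (20%), outer edge 2 (15%); the epidermis is
  the top 15% of the band. Sections from days 3 and 7 carry no epidermis
  over the bed/center (not yet re-epithelialized) — that surface is
  rendered as scab-like background fluorescence with layer label 0, so it
  contributes to the intensity distribution but never to a density
  denominator. Keeping tissue a minority of the frame mirrors real section
  scans and keeps fiber pixels a minority of the statistics population
  (see scope note above).
- **Fibers.** Persistent-direction random-walk polylines (turn angle
  ~ Normal(0, 20°), length 30–120 steps, width 1–3 px weighted 0.2/0.4/0.4
  toward 2–3 px), drawn per (region, layer) cell and trimmed so the
  ground-truth mask hits the programmed fraction to the pixel (tolerance
  0.005, or one pixel in tiny cells). Intensities uniform in (0.55, 0.95).
- **Background and noise.** Tissue autofluorescence 0.16, low-frequency
  illumination gradient ±0.01, autofluorescent debris as 2×2 blobs covering
  0.5% of tissue with intensity uniform between background and fiber
  minimum (blobs survive a 3×3 median filter, as real debris does), and
  additive Gaussian noise σ = 0.05, clipped to [0, 1].
- **Time course.** Whole-wound fraction defaults follow the published
  healing trend: 0.02 (day 3), 0.045 (day 7), 0.18 (day 10), 0.6 (day 15).
  The uninjured condition uses 0.75 — uninjured skin is reported near 0.9,
  but a mat of discrete curvilinear strokes saturates above ~0.9 coverage,
  so the generator refuses fractions > 0.9 and the demo stays safely below;
  the uninjured condition only serves as the qualitative ceiling. Replicate
  fractions jitter ±8% relative; per-replicate seeds derive from
  (master seed, day, replicate), so adding a day never reshuffles existing
  replicates. The demo couples re-epithelialization linearly to the
  programmed fraction (percent = 10 + 130·f, 5% relative noise, 8 mm total
  wound length) to exercise the correlation stage with a known answer.

What the generator does **not** emulate: tissue texture and nuclei,
out-of-focus light, Poisson shot noise, folds/tears, and annotation error
in the masks. Passing tests therefore demonstrate correctness of the
measurement chain against known truth under a plausible noise model — not
performance on any particular microscope's output.

## Statistics

Replicate summaries are mean ± sample SD (n−1; SD reported as missing for
n = 1). Group comparisons use the classical pooled-variance unpaired
two-tailed Student t-test (dof = n_a + n_b − 2, α = 0.05) — pooled rather
than Welch, matching standard practice for n = 3 wounds per group. When
both groups have zero variance the statistic is 0 (p = 1) for equal means
and ±∞ (p = 0) otherwise. The density/re-epithelialization association is
an ordinary least-squares fit of per-day mean whole-wound density against
per-day mean percent closure (day-level points, n = 4 in the demo), with
R² = 1 − SS_resid/SS_tot. No multiple-testing correction is applied; the
report prints raw p-values and a note saying so. Time-course reports list
absent-epithelium groups as 0.0 ± 0.0 so the day × region × layer grid
stays complete.

## Numerical conventions and edge cases

- Quantiles: linear interpolation (numpy default), pinned by tests.
- Ties at the threshold are negative; the classification is scale
  equivariant (scaling the image scales background, Q3, M and threshold by
  the same factor and leaves the mask unchanged).
- Background subtraction clips at zero; an all-constant image becomes all
  zeros and is handled by the degenerate path.
- `estimate_background` and `compute_threshold_stats` require ≥ 4 finite
  values; zero-area (region, layer) selections raise an explicit error and
  are skipped by the record emitter.
- All generators and training are deterministic under a fixed seed; child
  seeds come from `numpy.random.SeedSequence` spawn keys and stay below
  2³¹.

## Problem sizes

Tests and the acceptance script use 256×384 sections (3 replicates per
condition), 100×100 arrays for classifier/oracle sweeps, and the depth-7
denoiser profile on 512 40×40 patches. These sizes were chosen so the full
chain demonstrates every property at comfortable statistical margins while
a complete run stays in the minutes range on a single CPU; all quantities
scale transparently to full-resolution scans via the same code paths.

## Known limitations

- The threshold rule is distribution-coupled (see scope note): it assumes
  the statistics population contains a dark majority and intermediate-
  intensity content. Cropped images of pure tissue will be thresholded too
  aggressively; quantify full frames with full-height region masks.
- Density is a pixel fraction, not a fiber count or length; no tracing,
  branching, or 3-D morphology is attempted.
- Re-epithelialization lengths are consumed as measured values; the
  package does not segment H&E images.
- The denoiser is Gaussian-noise oriented; structured artifacts (stripes,
  vignetting) are out of scope.
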