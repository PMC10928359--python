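# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of camoquant. Nothing here asserts an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Observer model

The modelled viewer is the triplefin *Tripterygion delaisi*, a common prey
of the scorpionfish whose patterns the pipeline quantifies.

* **Spectral channels.** Single cone at λmax = 468 nm; double-cone members
  at 517 and 530 nm. Sensitivities are Govardovskii A1 alpha-band
  templates evaluated on a 400–700 nm grid at 1 nm. The beta band is
  omitted: all peaks lie above 460 nm, where its contribution is minor.
  This is a deliberate default, not a claim that the beta band is zero.
* **Illuminant.** CIE D65 (standard published 5-nm table, interpolated to
  the working grid). Catches are von Kries normalized to a perfect
  reflector under the same illuminant, so for flat-spectrum (grey) pixels
  the catch in every channel equals the pixel reflectance. Synthetic
  scenes are achromatic by construction; the full spectral machinery is
  retained so that calibrated spectral inputs use the same code path.
* **Receptor noise.** Weber fraction ω = 0.05 for the most abundant cone
  classes; channel noise scales as the inverse square root of relative
  abundance (1:4:4), giving ω = (0.1, 0.05, 0.05) from short to long
  wavelengths. Luminance is the mean catch of the 517 and 530 channels and
  carries ω_L = 0.05.
* **Distances.** Achromatic: ΔS_L = |ln(L₁/L₂)|/ω_L. Chromatic: the
  standard trichromatic receptor-noise formula on log-catch contrasts.
  Where a single discriminability number is needed (ranked filter,
  clustering), the combined distance is max(ΔS_L, ΔS_C); taking the max
  treats a pair as discriminable if either pathway can tell it apart.

## Spatial filtering

* **Acuity blur.** 7 cycles/degree at a 20 cm viewing distance. Pixels per
  degree = px/cm × 2 × distance × tan 0.5°, i.e. ≈ 29.0 at the
  experimental 83 px/cm. The Gaussian σ is set so the modulation transfer
  at the acuity frequency is 10% — a conventional detectability cutoff;
  the cutoff is an exposed constant (`ACUITY_MTF_CUTOFF`). Filtering uses
  half-sample-symmetric (reflective) boundaries, which makes the symmetric
  kernel mass-conserving, so channel means are preserved to float
  precision. Images sampled below 2 px per acuity cycle are rejected: at
  20 cm this requires > ≈ 40 px/cm.
* **RNL ranked filter.** Each pass replaces a pixel by the mean of itself
  and the neighbours within a Chebyshev radius of 2 px whose combined RNL
  distance to it is below 1 JND; pixels with no sub-threshold neighbour
  are left unchanged. Passes repeat until the mean per-pixel luminance
  change falls below 1e-4 JND, capped at 5 iterations. The filter is
  deterministic and seed-free. This realizes the contract downstream
  metrics rely on — sub-threshold variation is smoothed, supra-threshold
  edges stay in place — and does not attempt numerical identity with any
  particular interactive toolbox implementation.

## Granularity analysis

* **Band filter.** The band-pass at size *b* px is a difference of two
  Gaussian low-passes with σ = √2·b/π and σ = √2·(b+step)/π. With these
  constants a narrow bracket peaks at spatial frequency 1/(2b) — the
  fundamental of a square wave of half-period *b* — so stripe patterns of
  feature size *s* put their energy maximum at band *s* (verified exactly
  in the tests for s = 4…24 px).
* **Gain normalization.** Each band's transfer function is scaled to unit
  peak gain. Without this the narrow one-step brackets give small bands an
  order of magnitude more gain than large bands and every argmax collapses
  to the smallest band. Energies themselves remain raw standard deviations
  of the filtered luminance within the ROI — there is no cross-band energy
  normalization after filtering.
* **Discrete transfer functions.** Filtering runs in the frequency domain
  over a reflectively padded image, but the transfer function used is the
  DTFT of the *sampled, truncated* Gaussian kernel (truncation 8σ), not of
  the continuous Gaussian. At sub-pixel σ (band 2) the two differ by ~0.3%
  through aliasing; using the sampled-kernel response makes the FFT path
  exactly equivalent to direct spatial convolution, which the tests verify
  to 1e-6.
* **ROI handling.** The whole scene is filtered first and the ROI mask is
  applied afterwards, so pixels just outside the ROI legitimately
  influence near-edge values and mask edges introduce no ringing. Bands at
  least as large as the smaller ROI bounding-box dimension are recorded as
  missing (NaN), never as silent zeros. Dominant marking size is the
  argmax band, ties broken toward the smaller band; an all-zero spectrum
  yields an explicit "undefined" result.

## Clustering and edge contrast

* **RNL clustering.** Initial clusters are connected runs of identical
  catch values; the adjacent pair with the smallest combined RNL distance
  between cluster means is merged while that distance is below the
  threshold (default 1 JND). Ties break toward the lower label pair, so
  the result is deterministic. At convergence all adjacent cluster pairs
  are ≥ 1 JND apart. Merging is strictly between *adjacent* clusters, so
  equal-valued but disconnected regions remain distinct clusters.
* **Average patch size** is the simple arithmetic mean over spatially
  connected patches (4-connectivity by default; 8-connectivity and an
  area-weighted mean are toggles). The simple mean equals ROI area divided
  by patch count. Whether "cluster size" should mean connected patches or
  label classes is genuinely ambiguous; connected patches is the default
  because a disconnected label class has no single spatial extent.
* **Edge contrast (local edge intensity).** The mean ΔS_L over every
  horizontal and vertical pixel pair fully inside the ROI, zero pairs
  included. Including zeros makes the statistic sensitive to both edge
  strength and edge density; it is invariant under global luminance
  scaling and under 90° rotation. Chromatic edges are not analysed: in
  achromatic scenes the chromatic distance between any two greys is ~0
  (asserted < 0.05 JND in the tests), which is also why the luminance-only
  analysis is licensed.
* Before catch computation, reflectance is floored at 1e-3: log-ratio
  distances are undefined at zero, and a 0.1% floor is below any
  measurable reflectance in practice.

## Synthetic stimuli

The generator reproduces the *statistics* of the experimental stimuli, not
their photographic appearance.

* **Granularity backgrounds.** Gaussian-smoothed white noise thresholded
  at its median — the dark fraction is exactly 50% up to ties — with the
  smoothing length calibrated per seed by bisection until the measured
  mean 8-connected component area (dark and light pooled, border
  components included) is within 1% of the target: 0.1, 0.4 or 1.0 cm²
  for fine, medium and coarse at the experimental 83 px/cm. The real
  backgrounds were binarized photographs of sand and gravel; thresholded
  smoothed noise reproduces the two statistics the analysis consumes (tone
  balance and grain area) but not the shape statistics of real sediment.
  Tones default to 0.05/0.95 reflectance rather than 0/1 so log-based RNL
  quantities stay finite; the print reflectances of the original
  laminated backgrounds are not known and both tones are configurable.
* **Acclimation background.** A constant image at the candidate grey whose
  observer-luminance is closest to the mean observer-luminance of the
  experimental backgrounds, selected from a 0.01-step reflectance grid by
  default (emulating a choice among printed grey levels).
* **Fish textures.** Band-limited noise: white noise filtered with a
  narrow difference-of-Gaussians centred on the marking scale,
  standardized inside the body mask, scaled by the pattern amplitude
  (reflectance units) and added to the mean reflectance. The default body
  is an ellipse of ≈ 6.4 cm² (the observed mean top-view body area) with
  aspect ratio 2.5. Real fish have one dominant pattern whose internal
  contrast they modulate; the amplitude parameter emulates exactly that
  axis. Real skin patterns are not isotropic band-limited noise, so
  passing recovery tests demonstrate the pipeline's measurement fidelity,
  not realism of fish skin.
* **Scenes** place the fish at the canvas centre and two standard patches
  (12% and 72%) near the top edge, and record body / background / std12 /
  std72 ROIs. Overlap of fish and standards is an error.
* **Trial designs** assign the 6 possible orders of the three experimental
  backgrounds balanced (exactly n/6 each when 6 | n, remainder drawn
  without replacement), with acclimation always first.

All generators are bit-reproducible given (spec, seed).

## Statistics

Pairwise condition contrasts are paired response ratios: point estimate
exp(mean(ln aᵢ − ln bᵢ)) over individuals present in both conditions, with
a 95% percentile interval over bootstrap resamples of individuals
(default 10 000, seed-controlled; BCa is not implemented). This replaces a
Gamma GLMM with individual-level random effects: the mixed model is
generic machinery, while the ratio of geometric means is the quantity the
contrast tables report. The bootstrap's coverage is itself checked by
simulation in the test suite (paired log-normal data, true ratio 0.8,
n = 21). The contrast table builds all three pairwise background contrasts
per metric and species, plus acclimation-vs-first-background contrasts
pooled and split by first background type. Species aggregation is
per-species by default; pooling across species is a caller-side filter on
the input table.

## Problem sizes used by the tests

The package's own test and demonstration runs use reduced problem sizes
chosen as the smallest that leave the measured effects unambiguous:
background-statistics checks run at the full experimental scale
(83 px/cm, 800 × 600); marking-scale recovery runs at 83 px/cm on
320 × 480 scenes with 10 seeds per scale; the fine/medium/coarse ordering
and the acclimation-contrast emulation run at 45 px/cm — the coarsest
sampling that still satisfies the acuity-blur requirement — on ≈ 300 × 300
canvases with 10 seeds (ordering) and 12 individuals (contrast emulation,
per-individual amplitude lognormal around 0.10 with the acclimation
amplitude at 0.8 of each individual's experimental value, mirroring the
direction and magnitude of the observed acclimation contrast).

## Known limitations

* No camera simulation (RAW, vignetting, Bayer mosaics) and no
  camera-to-cone regression: the pipeline starts from linear reflectance.
* No ocular media transmission; no beta band; no chromatic adaptation
  beyond von Kries.
* The ranked filter and clustering follow documented contracts rather
  than replicating any specific toolbox's pixel-level output; absolute
  metric values are therefore comparable within this package, not across
  implementations.
* Synthetic backgrounds match tone balance and grain area of the
  originals but not higher-order shape statistics; synthetic fish are
  noise textures, not fish.
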