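# camoquant

Quantification of animal body patterns and camouflage **through the eyes of
a prey fish**. The package implements the full image-analysis chain used to
ask whether a benthic ambush predator (scorpionfish, *Scorpaena* spp.)
adjusts its skin pattern to the granularity of its visual background, as
that pattern would be perceived by a typical prey species, the triplefin
*Tripterygion delaisi*.

## Who this is for

Visual ecologists and behavioural biologists who want a scriptable,
reproducible alternative to interactive image-analysis toolchains for
pattern-granularity and edge-contrast analysis: calibrated reflectance in,
perceptually filtered pattern metrics and paired contrasts out. Because the
package ships a synthetic-scene generator that emulates the experimental
stimuli (binary granularity backgrounds, luminance-matched acclimation
grey, grey standards, parametric fish textures, balanced trial designs),
the entire analysis can be exercised end to end without any photographs.

## The model in brief

1. **Calibration.** Raw images are mapped to linear reflectance by the
   affine transform through two grey standards (12% and 72% reflectance).
2. **Observer.** *T. delaisi* has a single cone peaking at 468 nm and
   double-cone members at 517 and 530 nm (Govardovskii A1 templates),
   viewed here under a D65 illuminant with von Kries normalization. Quantum
   catches are `q_i = Σ_λ R(λ) I(λ) S_i(λ)`, scaled so a perfect reflector
   catches 1. Receptor noise follows the square-root abundance rule:
   with abundances 1:4:4 and ω = 0.05 for the abundant double cones,
   ω = 0.05·√4 = 0.1 for the single cone. Luminance is the mean catch of
   the 517 and 530 nm channels.
3. **Perceptual distance.** The receptor-noise-limited (RNL) model gives
   the achromatic distance `ΔS_L = |ln(L₁/L₂)|/ω_L` and the standard
   trichromatic distance on log-catch contrasts, both in just-noticeable
   differences (JND).
4. **Spatial filtering.** A Gaussian acuity blur (7 cycles/degree at
   20 cm viewing distance; 10% residual contrast at the acuity limit)
   followed by an RNL ranked filter that averages away sub-threshold
   (< 1 JND) variation while preserving supra-threshold edges.
5. **Pattern metrics.**
   *Granularity spectrum*: pattern energy (standard deviation of band-pass
   filtered luminance within the ROI) over band sizes, e.g. 2–100 px in
   1-px steps; its argmax is the **dominant marking size**.
   *RNL clustering*: adjacent image regions are merged while their
   mean-to-mean RNL distance is below 1 JND; the mean connected-patch area
   is the **average patch size**.
   *Local edge intensity*: the mean `ΔS_L` over all 4-neighbour pixel pairs
   in the ROI is the **luminance edge contrast**.
6. **Statistics.** Condition contrasts are paired response ratios — ratios
   of geometric means across individuals — with 95% bootstrap percentile
   intervals.

## Worked example

```python
import camoquant as cq

obs = cq.triplefin_observer()
cfg = cq.SceneConfig(canvas_size_px=(360, 480), px_per_cm=45.0, seed=7)
background = cq.generate_granularity_background(
    cq.GranularityBackgroundSpec(target_grain_area_cm2=0.4), cfg)
body = cq.elliptical_body_mask(cfg, area_cm2=6.4)
fish = cq.generate_fish_texture(
    cq.FishTextureSpec(body, marking_scale_px=14, pattern_amplitude=0.12, seed=7), cfg)
scene = cq.compose_scene(background, fish, cfg)

row = cq.measure_specimen(scene, obs, bands=cq.BandSet(2, 60, 2),
                          specimen_id="demo", background_id="medium")
print(f"body area        : {row.body_area_cm2:.2f} cm^2")
print(f"dominant marking : {row.dominant_marking_size_px:.0f} px "
      f"({row.dominant_marking_size_px / cfg.px_per_cm:.2f} cm)")
print(f"average patch    : {row.average_patch_size_px2:.1f} px^2")
print(f"edge contrast    : {row.leia_luminance_jnd:.2f} JND")
```

prints

```
body area        : 6.40 cm^2
dominant marking : 12 px (0.27 cm)
average patch    : 10.8 px^2
edge contrast    : 0.75 JND
```

The fish was given a marking scale of 14 px, and the granularity spectrum
of the filtered body recovers a dominant marking size of 12 px (the
pipeline's blur and ranked filter shave a little fine structure). The
average RNL-cluster patch is small — about 11 px² — because, as with the
experimental backgrounds, supra-threshold gradients at patch borders
fragment into narrow clusters. The edge-contrast value of 0.75 JND is the
mean achromatic distance over all neighbouring pixel pairs in the body.

Collecting such rows into a long table (`specimen, condition, metric,
value`) feeds `response_ratio` / `contrast_table` for paired
between-background comparisons.

A thin CLI mirrors the two entry points:

```sh
camoquant simulate --background coarse --seed 3 --out scenes/
camoquant compare metrics.csv --metric leia --n-boot 10000 --seed 1
```

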