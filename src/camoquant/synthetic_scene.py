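"""Synthetic experimental stimuli: backgrounds, fish textures, trial designs.

The experiment this package quantifies places a fish on binary black/white
backgrounds of three granularities — fine, medium and coarse, with mean
grain areas of 0.1, 0.4 and 1 cm^2 at 83 px/cm — after acclimation on a
uniform grey background luminance-matched to the patterned ones.  Scenes
carry two diffuse grey standards (12% and 72% reflectance) for calibration.

This module generates all of those programmatically:

* binary granularity backgrounds built by thresholding Gaussian-smoothed
  white noise at its median (exactly 50/50 up to ties), with the smoothing
  length calibrated by bisection so the measured mean grain area matches the
  target;
* the uniform acclimation background, chosen from a grid of candidate greys
  as the one whose observer-luminance is closest to the experimental mean;
* parametric fish-body textures — band-limited noise at a controllable
  marking scale and amplitude inside an elliptical body mask;
* composed scenes with body/background/standard ROIs, writable to 16-bit
  TIFF plus a label-mask PNG and a JSON sidecar;
* balanced randomized trial designs over the six background orders.

Everything is bit-reproducible given (spec, seed).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
import tifffile

from .granularity import SIGMA_PER_BAND
from .visual_model import ReflectanceImage, VisualSystem, compute_cone_catches, luminance_image

logger = logging.getLogger("camoquant")

BACKGROUND_GRAIN_AREAS_CM2 = {"fine": 0.1, "medium": 0.4, "coarse": 1.0}
#: Minimum resolvable grain: a 3 x 3 px feature.
MIN_GRAIN_AREA_PX2 = 9.0

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class SceneConfig:
    """Canvas geometry, calibration tones and seed for scene synthesis.

    Binary backgrounds default to 0.05/0.95 reflectance rather than 0/1 so
    log-based RNL quantities stay finite downstream.
    """

    canvas_size_px: tuple[int, int] = (600, 800)
    px_per_cm: float = 83.0
    standard_reflectances: tuple[float, float] = (0.12, 0.72)
    dark_reflectance: float = 0.05
    light_reflectance: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        if not (0.0 <= self.dark_reflectance < self.light_reflectance <= 1.0):
            raise ValueError("need 0 <= dark_reflectance < light_reflectance <= 1")
        if min(self.canvas_size_px) < 64:
            raise ValueError("canvas dimensions must be at least 64 px")


@dataclass(frozen=True)
class GranularityBackgroundSpec:
    """Target statistics of a binary background: grain area and dark fraction."""

    target_grain_area_cm2: float
    black_fraction: float = 0.5

    def __post_init__(self):
        if self.target_grain_area_cm2 <= 0:
            raise ValueError("target_grain_area_cm2 must be positive")
        if abs(self.black_fraction - 0.5) > 1e-9:
            raise ValueError("black_fraction is fixed at 0.5 in this design")


def mean_grain_area_px2(binary: np.ndarray) -> float:
    """Mean 8-connected component area, pooling dark and light components.

    Border-touching components are included; the symmetric 50/50 design
    makes pooling the two tones the natural measurement.
    """
    binary = np.asarray(binary, dtype=bool)
    areas = []
    for mask in (binary, ~binary):
        labels, n = ndimage.label(mask, structure=_EIGHT_CONN)
        if n:
            areas.append(np.bincount(labels.ravel())[1:])
    if not areas:
        raise ValueError("image has no components")
    areas = np.concatenate(areas)
    return float(areas.mean())


def _binary_from_noise(noise: np.ndarray, sigma: float) -> np.ndarray:
    smoothed = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    return smoothed < np.median(smoothed)


def generate_granularity_background(
    spec: GranularityBackgroundSpec, cfg: SceneConfig
) -> ReflectanceImage:
    """Binary background with calibrated mean grain area.

    White noise is Gaussian-smoothed and thresholded at its median, which
    pins the dark-pixel fraction at 50% up to ties.  The smoothing sigma is
    calibrated by bisection on the measured mean 8-connected component area
    (both tones pooled) until it matches the target within 1%.  The same
    noise field is reused throughout the calibration, so output is a pure
    function of (spec, cfg).
    """
    target_px2 = spec.target_grain_area_cm2 * cfg.px_per_cm ** 2
    if target_px2 < MIN_GRAIN_AREA_PX2:
        min_cm2 = MIN_GRAIN_AREA_PX2 / cfg.px_per_cm ** 2
        raise ValueError(
            f"target grain area {spec.target_grain_area_cm2:g} cm^2 is below the "
            f"minimum resolvable {min_cm2:.3g} cm^2 ({MIN_GRAIN_AREA_PX2:.0f} px^2) "
            f"at {cfg.px_per_cm:g} px/cm"
        )
    rng = np.random.default_rng(cfg.seed)
    noise = rng.standard_normal(cfg.canvas_size_px)

    def measured(sigma: float) -> float:
        return mean_grain_area_px2(_binary_from_noise(noise, sigma))

    lo, hi = 0.3, max(1.0, 0.5 * np.sqrt(target_px2))
    for _ in range(40):
        if measured(hi) >= target_px2:
            break
        lo = hi
        hi *= 2.0
        if hi > min(cfg.canvas_size_px):
            raise ValueError("target grain area too large for the canvas")
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        m = measured(mid)
        if abs(m - target_px2) <= 0.01 * target_px2:
            lo = hi = mid
            break
        if m < target_px2:
            lo = mid
        else:
            hi = mid
    binary = _binary_from_noise(noise, 0.5 * (lo + hi))
    pixels = np.where(binary, cfg.dark_reflectance, cfg.light_reflectance)
    return ReflectanceImage(
        pixels, px_per_cm=cfg.px_per_cm,
        rois={"background": np.ones(cfg.canvas_size_px, dtype=bool)},
    )


def generate_uniform_background(
    experimental: list[ReflectanceImage],
    grey_levels,
    observer: VisualSystem,
) -> ReflectanceImage:
    """Uniform grey background luminance-matched to the experimental ones.

    Returns a constant image at the candidate grey whose observer-luminance
    is nearest to the mean observer-luminance of the experimental
    backgrounds.  Ties and candidate ordering are resolved by preferring the
    lowest grey level, so the choice is order-invariant.
    """
    if not experimental:
        raise ValueError("at least one experimental background is required")
    greys = sorted(float(g) for g in np.atleast_1d(grey_levels))
    if not greys:
        raise ValueError("empty candidate grey-level list")

    def mean_luminance(img: ReflectanceImage) -> float:
        return float(np.mean(luminance_image(compute_cone_catches(img, observer), observer)))

    target = float(np.mean([mean_luminance(img) for img in experimental]))
    candidate_lum = [
        mean_luminance(
            ReflectanceImage(np.full((1, 1), g), px_per_cm=experimental[0].px_per_cm)
        )
        for g in greys
    ]
    best = greys[int(np.argmin([abs(l - target) for l in candidate_lum]))]
    ref = experimental[0]
    return ReflectanceImage(
        np.full(ref.shape, best), px_per_cm=ref.px_per_cm,
        rois={"background": np.ones(ref.shape, dtype=bool)},
    )


def acclimation_grey_grid(step: float = 0.01) -> np.ndarray:
    """Default candidate grey levels: a reflectance grid away from 0 and 1."""
    return np.round(np.arange(step, 1.0, step), 10)


# ---------------------------------------------------------------------------
# Fish textures
# ---------------------------------------------------------------------------

def elliptical_body_mask(
    cfg: SceneConfig, area_cm2: float = 6.4, aspect: float = 2.5
) -> np.ndarray:
    """Elliptical body mask of the given area on the scene canvas.

    Default area matches a typical small scorpionfish body in top view
    (~6.4 cm^2); aspect is the major/minor axis ratio.
    """
    area_px2 = area_cm2 * cfg.px_per_cm ** 2
    b = np.sqrt(area_px2 / (np.pi * aspect))  # semi-minor
    a = aspect * b
    h, w = cfg.canvas_size_px
    yy, xx = np.mgrid[:h, :w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


@dataclass(frozen=True)
class FishTextureSpec:
    """Parametric fish body: marking scale, pattern amplitude, mean tone."""

    body_mask: np.ndarray
    marking_scale_px: float
    pattern_amplitude: float
    mean_reflectance: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.marking_scale_px <= 0:
            raise ValueError("marking_scale_px must be positive")
        if self.pattern_amplitude < 0:
            raise ValueError("pattern_amplitude must be non-negative")
        if not 0.0 < self.mean_reflectance < 1.0:
            raise ValueError("mean_reflectance must lie in (0, 1)")
        if not np.asarray(self.body_mask, dtype=bool).any():
            raise ValueError("body_mask must contain at least one pixel")


def generate_fish_texture(spec: FishTextureSpec, cfg: SceneConfig) -> ReflectanceImage:
    """Band-limited noise texture at the requested marking scale.

    White noise is band-passed with a narrow difference-of-Gaussians centred
    on the marking scale, standardized to zero mean and unit variance inside
    the body mask, scaled by the pattern amplitude and added to the mean
    reflectance.  Values are clipped to [0, 1]; if clipping touches more
    than 5% of body pixels a warning is recorded in the run log.
    """
    mask = np.asarray(spec.body_mask, dtype=bool)
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(mask.shape)
    s = spec.marking_scale_px
    sigma_small = s * SIGMA_PER_BAND
    sigma_big = 1.2 * s * SIGMA_PER_BAND
    band = (
        ndimage.gaussian_filter(noise, sigma_small, mode="reflect")
        - ndimage.gaussian_filter(noise, sigma_big, mode="reflect")
    )
    inside = band[mask]
    sd = inside.std()
    if sd > 0:
        band = (band - inside.mean()) / sd
    pixels = np.full(mask.shape, spec.mean_reflectance)
    pixels[mask] = spec.mean_reflectance + spec.pattern_amplitude * band[mask]
    n_clip = int(np.sum((pixels[mask] < 0) | (pixels[mask] > 1)))
    if n_clip > 0.05 * mask.sum():
        logger.warning(
            "generate_fish_texture: amplitude %.3g clips %d of %d body pixels",
            spec.pattern_amplitude, n_clip, int(mask.sum()),
        )
    pixels = np.clip(pixels, 0.0, 1.0)
    return ReflectanceImage(pixels, px_per_cm=cfg.px_per_cm, rois={"body": mask})


# ---------------------------------------------------------------------------
# Scene composition and I/O
# ---------------------------------------------------------------------------

def _standard_patches(cfg: SceneConfig) -> tuple[np.ndarray, np.ndarray]:
    """Masks for the two grey-standard patches, side by side near the top."""
    h, w = cfg.canvas_size_px
    side = max(8, int(round(0.5 * cfg.px_per_cm)))
    top = max(2, h // 20)
    gap = side
    cx = w // 2
    std_a = np.zeros((h, w), dtype=bool)
    std_b = np.zeros((h, w), dtype=bool)
    std_a[top:top + side, cx - gap // 2 - side:cx - gap // 2] = True
    std_b[top:top + side, cx + gap // 2:cx + gap // 2 + side] = True
    return std_a, std_b


def compose_scene(
    background: ReflectanceImage,
    fish: ReflectanceImage,
    cfg: SceneConfig,
) -> ReflectanceImage:
    """Scene = background + fish at centre + the two grey standards.

    ROIs recorded: "body" (the fish mask), "background" (everything else
    except the standards), "std12" and "std72" at the configured reference
    reflectances.  Raises if the fish overlaps a standard patch or does not
    fit the canvas.
    """
    if fish.shape != background.shape:
        raise ValueError("fish canvas must match background canvas")
    body = fish.roi("body")
    std12, std72 = _standard_patches(cfg)
    if (body & (std12 | std72)).any():
        raise ValueError("fish body overlaps a grey-standard patch")
    pixels = background.pixels.copy()
    pixels[body] = fish.pixels[body]
    r12, r72 = cfg.standard_reflectances
    pixels[std12] = r12
    pixels[std72] = r72
    rois = {
        "body": body,
        "background": ~(body | std12 | std72),
        "std12": std12,
        "std72": std72,
    }
    return ReflectanceImage(pixels, px_per_cm=cfg.px_per_cm, rois=rois)


def save_scene(scene: ReflectanceImage, directory, stem: str = "scene") -> dict[str, Path]:
    """Write a scene as 16-bit TIFF + label-mask PNG + JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tiff_path = directory / f"{stem}.tif"
    png_path = directory / f"{stem}_rois.png"
    json_path = directory / f"{stem}.json"
    tifffile.imwrite(tiff_path, np.round(scene.pixels * 65535).astype(np.uint16))
    labels = np.zeros(scene.shape, dtype=np.uint8)
    names = {}
    for i, (name, mask) in enumerate(scene.rois.items(), start=1):
        labels[np.asarray(mask, dtype=bool)] = i
        names[str(i)] = name
    Image.fromarray(labels, mode="L").save(png_path)
    json_path.write_text(json.dumps(
        {"labels": names, "px_per_cm": scene.px_per_cm}, indent=2))
    return {"tiff": tiff_path, "rois": png_path, "meta": json_path}


def load_scene(directory, stem: str = "scene") -> ReflectanceImage:
    """Read back a scene written by :func:`save_scene`."""
    directory = Path(directory)
    meta = json.loads((directory / f"{stem}.json").read_text())
    pixels = tifffile.imread(directory / f"{stem}.tif").astype(float) / 65535.0
    labels = np.asarray(Image.open(directory / f"{stem}_rois.png"))
    rois = {name: labels == int(i) for i, name in meta["labels"].items()}
    return ReflectanceImage(pixels, px_per_cm=meta["px_per_cm"], rois=rois)


# ---------------------------------------------------------------------------
# Trial design
# ---------------------------------------------------------------------------

EXPERIMENTAL_BACKGROUNDS = ("fine", "medium", "coarse")


@dataclass(frozen=True)
class TrialDesign:
    """Per-individual background orders; acclimation always comes first."""

    orders: dict[int, tuple[str, ...]] = field(default_factory=dict)

    def sequence(self, individual: int) -> tuple[str, ...]:
        return ("acclimation",) + self.orders[individual]

    @property
    def individual_ids(self) -> list[int]:
        return sorted(self.orders)

    def first_backgrounds(self) -> dict[int, str]:
        return {i: order[0] for i, order in self.orders.items()}


def all_background_orders() -> list[tuple[str, ...]]:
    """The six possible orders of the three experimental backgrounds."""
    return sorted(itertools.permutations(EXPERIMENTAL_BACKGROUNDS))


def generate_trial_design(n_individuals: int, seed: int = 0) -> TrialDesign:
    """Randomized, fully balanced assignment of background orders.

    When ``n_individuals`` is a multiple of 6, each of the six orders occurs
    exactly n/6 times; otherwise the remainder orders are drawn without
    replacement.  Assignment to individuals is shuffled, seed-controlled.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    perms = all_background_orders()
    pool = perms * (n_individuals // 6)
    remainder = n_individuals % 6
    if remainder:
        extra_idx = rng.choice(len(perms), size=remainder, replace=False)
        pool += [perms[i] for i in extra_idx]
    order_idx = rng.permutation(len(pool))
    return TrialDesign(orders={i + 1: pool[j] for i, j in enumerate(order_idx)})
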