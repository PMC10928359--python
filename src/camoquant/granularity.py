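"""Granularity (pattern-energy) analysis of the luminance channel.

A granularity spectrum decomposes the luminance image into a sequence of
spatial band-pass images — one per "band size" in pixels — and measures the
pattern energy of each as the standard deviation of the filtered values
inside a region of interest.  The band with maximal energy is the dominant
(most contrasting) marking size of the pattern.

The band-pass at size ``b`` is a difference of two Gaussian low-passes whose
sigmas bracket the band: the filter's peak frequency response falls at the
frequency of a square wave whose half-period (feature size) is ``b`` pixels.
Filtering is done in the frequency domain over a reflectively padded image;
a direct spatial convolution serves as the independent oracle in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft as spfft

# Sigma of the band's smaller Gaussian per pixel of band size.  With
# sigma = sqrt(2) * b / pi, a narrow difference-of-Gaussians bracket peaks at
# spatial frequency 1 / (2b) cycles/px — a stripe pattern of half-period b.
SIGMA_PER_BAND = float(np.sqrt(2.0) / np.pi)


class BandTooLargeError(ValueError):
    """Band size exceeds what the ROI can support."""


@dataclass(frozen=True)
class BandSet:
    """Arithmetic sequence of band sizes: min, min+step, ... up to max."""

    min_px: int = 2
    max_px: int = 100
    step_px: int = 1

    def __post_init__(self):
        if self.min_px < 2:
            raise ValueError("min_px must be >= 2")
        if self.step_px < 1:
            raise ValueError("step_px must be >= 1")
        if self.max_px < self.min_px:
            raise ValueError("max_px must be >= min_px")

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.min_px, self.max_px + 1, self.step_px)

    def __len__(self) -> int:
        return len(self.sizes)


def make_band_sizes(min_px: int = 2, max_px: int = 100, step_px: int = 1) -> BandSet:
    """Band set over [min_px, max_px] in step_px increments.

    >>> len(make_band_sizes(2, 100, 1))
    99
    >>> len(make_band_sizes(2, 150, 5))
    30
    """
    return BandSet(min_px=min_px, max_px=max_px, step_px=step_px)


@dataclass
class GranularitySpectrum:
    """Pattern energy per band size within one ROI.

    ``energy`` is NaN for bands that were too large for the ROI (recorded as
    missing, never silently zero).
    """

    band_px: np.ndarray
    energy: np.ndarray
    roi_id: str
    px_per_cm: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.band_px = np.asarray(self.band_px)
        self.energy = np.asarray(self.energy, dtype=float)
        if self.band_px.shape != self.energy.shape:
            raise ValueError("band_px and energy must have equal length")
        if np.any(self.energy[np.isfinite(self.energy)] < 0):
            raise ValueError("energies must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "band_px": self.band_px,
            "band_cm": self.band_px / self.px_per_cm,
            "energy": self.energy,
        })


@dataclass(frozen=True)
class DominantMarkingSize:
    """Band of maximal pattern energy; undefined for an all-zero spectrum."""

    band_px: int | None
    px_per_cm: float
    defined: bool = True

    @property
    def band_cm(self) -> float | None:
        return None if self.band_px is None else self.band_px / self.px_per_cm


def _band_sigmas(band_px: float, step_px: float) -> tuple[float, float]:
    return band_px * SIGMA_PER_BAND, (band_px + step_px) * SIGMA_PER_BAND


def _check_roi(roi: np.ndarray, band_px: int) -> None:
    roi = np.asarray(roi, dtype=bool)
    n = int(roi.sum())
    if n < 100:
        raise ValueError(f"ROI too small for granularity analysis ({n} px < 100)")
    ys, xs = np.nonzero(roi)
    bbox_min = min(ys.max() - ys.min() + 1, xs.max() - xs.min() + 1)
    if band_px >= bbox_min:
        raise BandTooLargeError(
            f"band of {band_px} px exceeds the ROI bounding box ({bbox_min} px)"
        )


#: Gaussian kernels are truncated at this many sigmas (sampled, renormalized).
KERNEL_TRUNCATE = 8.0


def _gauss_kernel_radius(sigma: float) -> int:
    return max(1, int(np.ceil(KERNEL_TRUNCATE * sigma)))


def _gauss_kernel(sigma: float) -> np.ndarray:
    """Sampled, truncated, unit-sum 1-D Gaussian kernel."""
    r = _gauss_kernel_radius(sigma)
    x = np.arange(-r, r + 1)
    g = np.exp(-x ** 2 / (2.0 * sigma ** 2))
    return g / g.sum()


def _kernel_response(sigma: float, f: np.ndarray) -> np.ndarray:
    """Frequency response (DTFT) of the sampled Gaussian at frequencies f.

    Using the sampled kernel's own transfer function — rather than the
    continuous Gaussian's — makes the frequency-domain path exactly
    equivalent to spatial convolution with the same kernel, including at
    sub-pixel sigmas where the two differ by aliasing.
    """
    g = _gauss_kernel(sigma)
    r = len(g) // 2
    k = np.arange(1, r + 1)
    return g[r] + 2.0 * np.cos(2.0 * np.pi * np.outer(f, k)) @ g[r + 1:]


def _dog_peak_gain(sigma_small: float, sigma_big: float) -> float:
    """Peak on-axis frequency response of the difference of Gaussians.

    Each band is normalized to unit peak gain: without this, the narrow
    brackets at large bands would have far smaller gain than at small bands
    and energies would not be comparable across the spectrum.
    """
    f = np.linspace(0.0, 0.5, 4096)
    ds = _kernel_response(sigma_small, f) - _kernel_response(sigma_big, f)
    return float(ds.max())


def _dog_transfer(shape: tuple[int, int], sigma_small: float, sigma_big: float):
    fy = spfft.fftfreq(shape[0])
    fx = spfft.rfftfreq(shape[1])
    sy, by = _kernel_response(sigma_small, fy), _kernel_response(sigma_big, fy)
    sx, bx = _kernel_response(sigma_small, fx), _kernel_response(sigma_big, fx)
    transfer = sy[:, None] * sx[None, :] - by[:, None] * bx[None, :]
    return transfer / _dog_peak_gain(sigma_small, sigma_big)


def _filter_bank(luminance: np.ndarray, sigma_pairs) -> list[np.ndarray]:
    """Band-pass the image at every sigma pair with one shared forward FFT.

    Padding by the largest kernel radius makes the circular FFT convolution
    identical to linear convolution with reflective boundaries.
    """
    h, w = luminance.shape
    pad = max(_gauss_kernel_radius(sb) for _, sb in sigma_pairs)
    padded = np.pad(luminance, pad, mode="reflect")
    F = spfft.rfft2(padded)
    out = []
    for sigma_small, sigma_big in sigma_pairs:
        transfer = _dog_transfer(padded.shape, sigma_small, sigma_big)
        filtered = spfft.irfft2(F * transfer, s=padded.shape)
        out.append(filtered[pad:pad + h, pad:pad + w])
    return out


def bandpass_energy(
    luminance: np.ndarray,
    roi: np.ndarray,
    band_px: int,
    step_px: int = 1,
) -> float:
    """Pattern energy of one band: std of the band-filtered luminance in the ROI.

    The whole image is filtered and the ROI mask applied afterwards, so
    pixels just outside the ROI legitimately influence near-edge values and
    no ring artefacts are introduced at the mask boundary.
    """
    luminance = np.asarray(luminance, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    _check_roi(roi, band_px)
    filtered = _filter_bank(luminance, [_band_sigmas(band_px, step_px)])[0]
    return float(np.std(filtered[roi]))


def granularity_spectrum(
    luminance: np.ndarray,
    roi: np.ndarray,
    bands: BandSet,
    px_per_cm: float = 83.0,
    roi_id: str = "roi",
) -> GranularitySpectrum:
    """Pattern energy for every band in the set.

    Bands too large for the ROI are recorded as NaN.  All valid bands share a
    single forward FFT of the padded luminance image.
    """
    luminance = np.asarray(luminance, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    sizes = bands.sizes
    valid = []
    energy = np.full(len(sizes), np.nan)
    for i, b in enumerate(sizes):
        try:
            _check_roi(roi, int(b))
        except BandTooLargeError:
            continue
        valid.append(i)
    if valid:
        pairs = [_band_sigmas(int(sizes[i]), bands.step_px) for i in valid]
        filtered = _filter_bank(luminance, pairs)
        for i, img in zip(valid, filtered):
            energy[i] = np.std(img[roi])
    return GranularitySpectrum(
        band_px=sizes,
        energy=energy,
        roi_id=roi_id,
        px_per_cm=px_per_cm,
        provenance={"bands": (bands.min_px, bands.max_px, bands.step_px)},
    )


def dominant_marking_size(spec: GranularitySpectrum) -> DominantMarkingSize:
    """Band with maximal energy; ties broken toward the smaller band.

    An all-zero (or all-missing) spectrum has no dominant scale and is
    returned flagged as undefined.
    """
    finite = np.isfinite(spec.energy)
    if spec.energy.size == 0 or not finite.any():
        raise ValueError("empty granularity spectrum")
    if np.all(spec.energy[finite] == 0):
        return DominantMarkingSize(band_px=None, px_per_cm=spec.px_per_cm, defined=False)
    masked = np.where(finite, spec.energy, -np.inf)
    best = int(np.argmax(masked))  # first max = smaller band on ties
    return DominantMarkingSize(band_px=int(spec.band_px[best]), px_per_cm=spec.px_per_cm)
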