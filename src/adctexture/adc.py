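"""Apparent diffusion coefficient (ADC) mapping from diffusion-weighted MRI.

An ADC map is estimated from a b=0 reference image S_0 and one or more
diffusion-sensitized images S_b acquired with positive b-values (s/mm^2),
under the mono-exponential decay model S_b = S_0 * exp(-b * ADC).  Per
pixel the estimate averages ln(S_0/S_b)/b over the positive-b images, so
a decaying signal yields a positive coefficient in mm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AdcTextureError

__all__ = [
    "DWISeries",
    "ADCMap",
    "ROIMask",
    "PixelSample",
    "compute_adc",
    "extract_roi_pixels",
]


@dataclass
class DWISeries:
    """A per-slice stack of DWI intensity grids with their b-values.

    Exactly one image must be the unweighted (b=0) reference; all other
    b-values must be positive.  All grids share one shape and must be
    finite.
    """

    images: list = field(default_factory=list)
    b_values: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.images) != len(self.b_values):
            raise AdcTextureError("images and b_values must have equal length")
        self.images = [np.asarray(im, dtype=float) for im in self.images]
        self.b_values = [float(b) for b in self.b_values]
        if sum(b == 0 for b in self.b_values) != 1:
            raise AdcTextureError("exactly one b-value must equal 0")
        if any(b < 0 for b in self.b_values):
            raise AdcTextureError("b-values must be non-negative")
        shapes = {im.shape for im in self.images}
        if len(shapes) != 1:
            raise AdcTextureError("all DWI grids must share one shape")
        for im in self.images:
            if not np.all(np.isfinite(im)):
                raise AdcTextureError("DWI intensities must be finite")

    @property
    def n(self) -> int:
        """Number of positive-b images."""
        return sum(b > 0 for b in self.b_values)

    @property
    def s0(self) -> np.ndarray:
        """The b=0 reference image."""
        return self.images[self.b_values.index(0.0)]

    @property
    def shape(self) -> tuple:
        return self.images[0].shape


@dataclass
class ADCMap:
    """A 2-D grid of apparent diffusion coefficients in mm^2/s."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise AdcTextureError("ADC map must be finite everywhere")

    @property
    def shape(self) -> tuple:
        return self.values.shape


@dataclass
class ROIMask:
    """Binary tumor mask, pixel-aligned with an ADC map (0-based, row-major)."""

    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise AdcTextureError("ROI mask must contain at least one pixel")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple:
        return self.mask.shape


@dataclass
class PixelSample:
    """ADC values inside the ROI, in deterministic row-major scan order."""

    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float).ravel()

    @property
    def N(self) -> int:
        return self.pixels.size


def compute_adc(dwi: DWISeries, floor: float | None = None) -> ADCMap:
    """Estimate the ADC map from a DWI series.

    Per pixel, ADC = (1/n) * sum over positive-b images of
    ln(max(S_0, floor) / max(S_b, floor)) / b, which is positive where the
    signal decays.  ``floor`` clamps intensities so the logarithm stays
    finite; it defaults to 1e-6 times the maximum of the reference image.
    """
    if dwi.n == 0:
        raise AdcTextureError("cannot fit decay: no positive b-value present")
    s0 = dwi.s0
    if floor is None:
        floor = 1e-6 * float(np.max(s0))
        if floor <= 0:
            floor = 1e-12
    if floor <= 0:
        raise AdcTextureError("floor must be positive")
    s0c = np.maximum(s0, floor)
    acc = np.zeros_like(s0c)
    for im, b in zip(dwi.images, dwi.b_values):
        if b == 0:
            continue
        acc += np.log(s0c / np.maximum(im, floor)) / b
    return ADCMap(acc / dwi.n)


def extract_roi_pixels(adc: ADCMap, roi: ROIMask) -> PixelSample:
    """Collect the ADC values at set mask positions, row-major."""
    if adc.shape != roi.shape:
        raise AdcTextureError(
            f"shape mismatch: ADC {adc.shape} vs mask {roi.shape}"
        )
    return PixelSample(adc.values[roi.mask])
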