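"""Intra-ROI moment statistics and gray-level co-occurrence (GLCM) texture.

The ROI pixel distribution contributes its mean and the standardized
third and fourth central moments (skewness, kurtosis; kurtosis of a
normal distribution is 3).  Texture is summarized by nine statistics of
the normalized gray-level co-occurrence matrix: marginal means and
variances on the reference (i) and neighbor (j) sides, energy, entropy
(natural log), contrast, homogeneity, correlation, cluster shade and
cluster prominence.  Features are computed at pixel distance d along the
four standard orientations (0, 45, 90, 135 degrees) and averaged.

Only pixel pairs with BOTH endpoints inside the ROI contribute to a
co-occurrence matrix; out-of-ROI neighbors are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adc import ADCMap, PixelSample, ROIMask, extract_roi_pixels
from .errors import AdcTextureError, DegenerateSampleError, FeatureExtractionError

__all__ = [
    "QuantizedROI",
    "GLCMatrix",
    "GLCMFeatureSet",
    "roi_mean",
    "standardized_moment",
    "quantize",
    "compute_glcm",
    "glcm_features",
    "orientation_offsets",
    "extract_image_features",
    "IMAGE_FEATURE_NAMES",
]

# The 14 numeric image features, in canonical column order.
IMAGE_FEATURE_NAMES = [
    "mean_adc",
    "skewness",
    "kurtosis",
    "glcm_mean_1",
    "glcm_mean_2",
    "glcm_var_1",
    "glcm_var_2",
    "glcm_energy",
    "glcm_entropy",
    "glcm_contrast",
    "glcm_homogeneity",
    "glcm_correlation",
    "glcm_prominence",
    "glcm_shade",
]


def roi_mean(sample: PixelSample) -> float:
    """Arithmetic mean of the ROI pixel values."""
    if sample.N < 1:
        raise DegenerateSampleError("empty pixel sample")
    return float(np.mean(sample.pixels))


def standardized_moment(sample: PixelSample, order: int) -> float:
    """Standardized central moment m_n / sigma^n of the ROI pixel sample.

    Central moments use the empirical relative frequency 1/N per pixel
    (biased estimator); order 3 is skewness, order 4 kurtosis.  Raises
    :class:`DegenerateSampleError` for a zero-variance sample, where the
    statistic is undefined.
    """
    if order not in (3, 4):
        raise AdcTextureError("order must be 3 (skewness) or 4 (kurtosis)")
    if sample.N < 2:
        raise DegenerateSampleError("need at least 2 pixels")
    x = sample.pixels
    centered = x - x.mean()
    m2 = float(np.mean(centered**2))
    if m2 == 0.0:
        raise DegenerateSampleError("degenerate sample: zero variance")
    mn = float(np.mean(centered**order))
    return mn / m2 ** (order / 2.0)


@dataclass
class QuantizedROI:
    """ROI gray levels binned to integers in [0, levels-1].

    ``grid`` holds -1 at out-of-mask positions (explicit absent marker).
    """

    levels: int
    grid: np.ndarray
    mask: ROIMask

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.int64)
        inside = self.grid[self.mask.mask]
        if inside.size and (inside.min() < 0 or inside.max() >= self.levels):
            raise AdcTextureError("in-mask levels must lie in [0, levels-1]")


def quantize(adc: ADCMap, roi: ROIMask, levels: int) -> QuantizedROI:
    """Linearly bin in-mask ADC values into ``levels`` equal-width bins.

    Bins span the in-mask min..max; the maximum maps to level levels-1
    (half-open bins, the top edge closed).  A constant ROI maps to level
    0 everywhere.  Quantization depends only on the ordering within the
    min-max range, so any monotone affine rescaling of the ADC values
    leaves the result unchanged.
    """
    if levels < 2:
        raise AdcTextureError("need at least 2 gray levels")
    if adc.shape != roi.shape:
        raise AdcTextureError("ADC map and mask shapes differ")
    vals = adc.values[roi.mask]
    lo, hi = float(vals.min()), float(vals.max())
    grid = np.full(adc.shape, -1, dtype=np.int64)
    if hi == lo:
        grid[roi.mask] = 0
    else:
        lev = np.floor((vals - lo) / (hi - lo) * levels).astype(np.int64)
        grid[roi.mask] = np.clip(lev, 0, levels - 1)
    return QuantizedROI(levels=levels, grid=grid, mask=roi)


@dataclass
class GLCMatrix:
    """Normalized gray-level co-occurrence matrix for one pixel offset."""

    P: np.ndarray
    counts: np.ndarray
    offset: tuple
    levels: int
    symmetric: bool

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        total = self.P.sum()
        if not np.isclose(total, 1.0):
            raise AdcTextureError("GLCM probabilities must sum to 1")
        if np.any(self.P < 0):
            raise AdcTextureError("GLCM probabilities must be non-negative")


def compute_glcm(
    q: QuantizedROI, offset: tuple, symmetric: bool = True
) -> GLCMatrix:
    """Count level pairs at displacement ``offset`` = (d_row, d_col).

    A pair contributes only when both its pixels lie inside the ROI and
    the displaced pixel is in bounds.  With ``symmetric`` the transposed
    count is added, making the matrix symmetric.  Raw counts stay
    retrievable on the returned object.
    """
    dr, dc = int(offset[0]), int(offset[1])
    if dr == 0 and dc == 0:
        raise AdcTextureError("offset must be nonzero")
    g, m, n = q.grid, q.mask.mask, q.levels
    rows, cols = g.shape
    if abs(dr) >= rows or abs(dc) >= cols:
        raise AdcTextureError("ROI too small for offset: displacement exceeds grid")
    src = (slice(max(0, -dr), rows - max(0, dr)), slice(max(0, -dc), cols - max(0, dc)))
    dst = (slice(max(0, dr), rows - max(0, -dr)), slice(max(0, dc), cols - max(0, -dc)))
    valid = m[src] & m[dst]
    i = g[src][valid]
    j = g[dst][valid]
    counts = np.bincount(i * n + j, minlength=n * n).reshape(n, n).astype(float)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise AdcTextureError("ROI too small for offset: zero co-occurring pairs")
    return GLCMatrix(
        P=counts / total, counts=counts, offset=(dr, dc), levels=n, symmetric=symmetric
    )


@dataclass
class GLCMFeatureSet:
    """The nine scalar GLCM statistics for one (or an average of) matrices.

    ``correlation`` is NaN when either marginal variance is zero (the
    statistic is undefined for a constant texture); it is never silently
    reported as 0.
    """

    mean_i: float
    mean_j: float
    var_i: float
    var_j: float
    energy: float
    entropy: float
    contrast: float
    homogeneity: float
    correlation: float
    shade: float
    prominence: float


def glcm_features(M: GLCMatrix) -> GLCMFeatureSet:
    """Evaluate the nine co-occurrence statistics of a normalized GLCM.

    Entropy uses the natural logarithm with the 0*ln(0) := 0 convention.
    """
    P = M.P
    n = M.levels
    i = np.arange(n, dtype=float)[:, None]
    j = np.arange(n, dtype=float)[None, :]
    mu_i = float((i * P).sum())
    mu_j = float((j * P).sum())
    var_i = float((P * (i - mu_i) ** 2).sum())
    var_j = float((P * (j - mu_j) ** 2).sum())
    energy = float((P**2).sum())
    pos = P[P > 0]
    entropy = float(-(pos * np.log(pos)).sum())
    contrast = float((P * (i - j) ** 2).sum())
    homogeneity = float((P / (1.0 + (i - j) ** 2)).sum())
    if var_i > 0 and var_j > 0:
        correlation = float(
            (P * (i - mu_i) * (j - mu_j)).sum() / np.sqrt(var_i * var_j)
        )
    else:
        correlation = float("nan")
    dev = i + j - mu_i - mu_j
    shade = float((P * dev**3).sum())
    prominence = float((P * dev**4).sum())
    return GLCMFeatureSet(
        mean_i=mu_i,
        mean_j=mu_j,
        var_i=var_i,
        var_j=var_j,
        energy=energy,
        entropy=entropy,
        contrast=contrast,
        homogeneity=homogeneity,
        correlation=correlation,
        shade=shade,
        prominence=prominence,
    )


def orientation_offsets(distance: int = 1) -> list:
    """Pixel displacements for the 0/45/90/135 degree orientations."""
    d = int(distance)
    if d < 1:
        raise AdcTextureError("distance must be >= 1")
    return [(0, d), (-d, d), (-d, 0), (-d, -d)]


def extract_image_features(
    adc: ADCMap, roi: ROIMask, levels: int = 16, distance: int = 1
) -> dict:
    """Compute the 14 numeric image features for one slice.

    Returns a dict keyed by :data:`IMAGE_FEATURE_NAMES`.  Moments come
    from the raw ROI pixel sample; each GLCM statistic is the average of
    its values over the four symmetric co-occurrence matrices at the
    standard orientations.  With symmetric accumulation the i- and
    j-sided means (and variances) coincide, but both columns are kept.

    Raises :class:`FeatureExtractionError` when any constituent is
    undefined (zero-variance ROI, ROI too small for an offset, or
    undefined correlation), marking the slice invalid.
    """
    sample = extract_roi_pixels(adc, roi)
    try:
        features = {
            "mean_adc": roi_mean(sample),
            "skewness": standardized_moment(sample, 3),
            "kurtosis": standardized_moment(sample, 4),
        }
        q = quantize(adc, roi, levels)
        per_offset = [
            glcm_features(compute_glcm(q, off, symmetric=True))
            for off in orientation_offsets(distance)
        ]
    except AdcTextureError as exc:
        raise FeatureExtractionError(f"slice invalid: {exc}") from exc
    agg = {
        "glcm_mean_1": np.mean([f.mean_i for f in per_offset]),
        "glcm_mean_2": np.mean([f.mean_j for f in per_offset]),
        "glcm_var_1": np.mean([f.var_i for f in per_offset]),
        "glcm_var_2": np.mean([f.var_j for f in per_offset]),
        "glcm_energy": np.mean([f.energy for f in per_offset]),
        "glcm_entropy": np.mean([f.entropy for f in per_offset]),
        "glcm_contrast": np.mean([f.contrast for f in per_offset]),
        "glcm_homogeneity": np.mean([f.homogeneity for f in per_offset]),
        "glcm_correlation": np.mean([f.correlation for f in per_offset]),
        "glcm_prominence": np.mean([f.prominence for f in per_offset]),
        "glcm_shade": np.mean([f.shade for f in per_offset]),
    }
    features.update({k: float(v) for k, v in agg.items()})
    if any(not np.isfinite(v) for v in features.values()):
        raise FeatureExtractionError("slice invalid: non-finite feature value")
    return features
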