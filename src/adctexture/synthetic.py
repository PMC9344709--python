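"""Synthetic DWI slice cohorts with planted class structure.

Each synthetic case is a single 2-D axial slice: a b=0 reference image
and one diffusion-weighted image per positive b-value, plus an elliptical
tumor ROI mask, a malignant/benign label and patient demographics.  The
tumor's diffusion field is a Gaussian random field (white noise smoothed
with a Gaussian kernel of class-specific correlation length, scaled by a
class-specific heterogeneity), exponentiated through the mono-exponential
signal model S_b = S_0 * exp(-b * ADC) with multiplicative log-normal
acquisition noise.  Class-dependent ADC level, texture smoothness and a
gender covariate are the planted signals a downstream classifier can
recover; the generator is fully deterministic given its seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .adc import DWISeries, ROIMask
from .errors import AdcTextureError, DegenerateCohortError

__all__ = [
    "ClassParams",
    "SimConfig",
    "SyntheticCase",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "well_separated_class_params",
    "null_class_params",
    "reference_cohort_composition",
    "SCREENED_SLICES",
    "EXCLUDED_SLICES",
    "INCLUDED_SLICES",
]

# Study-scale bookkeeping the default cohort emulates: slices screened,
# excluded (missing information / corrupt images / extracranial ROI),
# and retained.
SCREENED_SLICES = 1896
EXCLUDED_SLICES = 297
INCLUDED_SLICES = SCREENED_SLICES - EXCLUDED_SLICES

# Reference cohort composition by WHO grade and histological type
# (slice counts per tumor type in the emulated study population).
_COMPOSITION_ROWS = [
    ("benign", "I", "meningioma", 262),
    ("benign", "I", "schwannoma", 135),
    ("benign", "I", "pilocytic astrocytoma", 13),
    ("benign", "I", "hemangioblastoma", 16),
    ("benign", "I", "craniopharyngioma", 11),
    ("benign", "I", "dermoid cyst", 13),
    ("benign", "II", "low grade glioma", 112),
    ("benign", "II", "meningioma", 21),
    ("benign", "II", "astrocytoma", 10),
    ("benign", "II", "ependymoma", 7),
    ("benign", "II", "frontal cavernoma", 4),
    ("malignant", "III", "high grade glioma", 147),
    ("malignant", "III", "anaplastic astrocytoma", 22),
    ("malignant", "III", "anaplastic meningioma", 11),
    ("malignant", "III", "anaplastic oligodendroglioma", 29),
    ("malignant", "III", "central astrocytoma", 65),
    ("malignant", "IV", "glioblastoma", 442),
    ("malignant", "IV", "medulloblastoma", 109),
    ("malignant", "IV", "metastasis", 170),
]


def reference_cohort_composition() -> pd.DataFrame:
    """Slice counts per tumor type in the emulated study population."""
    return pd.DataFrame(
        _COMPOSITION_ROWS, columns=["category", "who_grade", "tumor_type", "n_slices"]
    )


@dataclass
class ClassParams:
    """Texture and diffusion parameters of one tumor class.

    mean_adc is in mm^2/s; texture_correlation_length is the Gaussian
    kernel sigma in pixels; heterogeneity_sd is the ADC field's standard
    deviation as a fraction of mean_adc; roi_radius_range bounds the
    ellipse semi-axes in pixels.
    """

    mean_adc: float
    texture_correlation_length: float
    heterogeneity_sd: float
    roi_radius_range: tuple = (6.0, 18.0)


def _default_class_params() -> dict:
    # Malignant tumors: restricted diffusion (lower ADC), rougher and
    # more heterogeneous texture; benign: higher ADC, smoother texture.
    return {
        "malignant": ClassParams(
            mean_adc=800e-6, texture_correlation_length=1.2, heterogeneity_sd=0.20
        ),
        "benign": ClassParams(
            mean_adc=1400e-6, texture_correlation_length=3.0, heterogeneity_sd=0.10
        ),
    }


def well_separated_class_params() -> dict:
    """Strongly separated classes (2x ADC ratio, distinct correlation
    lengths) for parameter-recovery experiments."""
    return {
        "malignant": ClassParams(
            mean_adc=800e-6, texture_correlation_length=1.0, heterogeneity_sd=0.25
        ),
        "benign": ClassParams(
            mean_adc=1600e-6, texture_correlation_length=3.5, heterogeneity_sd=0.10
        ),
    }


def null_class_params() -> dict:
    """Identical parameters for both classes: no planted signal."""
    shared = ClassParams(
        mean_adc=1100e-6, texture_correlation_length=2.0, heterogeneity_sd=0.15
    )
    return {"malignant": replace(shared), "benign": replace(shared)}


@dataclass
class SimConfig:
    """Configuration of a synthetic cohort.

    Defaults mirror the emulated acquisition: 124x124 matrix, b = 0 and
    1000 s/mm^2, 62.22% malignant slices, ages uniform on 12-80 years,
    and gender probabilities that couple gender to class while keeping
    the overall male fraction near 53%.
    """

    n_slices: int = INCLUDED_SLICES
    malignant_fraction: float = 0.6222
    image_shape: tuple = (124, 124)
    b_values: tuple = (0.0, 1000.0)
    class_params: dict = field(default_factory=_default_class_params)
    gender_prob_by_class: dict = field(
        default_factory=lambda: {"malignant": 0.62, "benign": 0.39}
    )
    age_range: tuple = (12.0, 80.0)
    noise_sd: float = 0.02
    seed: int = 0
    s0_intensity: float = 1000.0

    def validate(self) -> None:
        if not (0.0 < self.malignant_fraction < 1.0):
            raise AdcTextureError("malignant_fraction must be strictly in (0,1)")
        bvals = [float(b) for b in self.b_values]
        if 0.0 not in bvals or not any(b > 0 for b in bvals):
            raise AdcTextureError("b_values must contain 0 and a positive value")
        if self.noise_sd < 0:
            raise AdcTextureError("noise_sd must be non-negative")
        rows, cols = self.image_shape
        for name in ("malignant", "benign"):
            if name not in self.class_params:
                raise AdcTextureError(f"class_params missing class '{name}'")
            lo, hi = self.class_params[name].roi_radius_range
            if lo < 2.5:
                raise AdcTextureError("roi_radius_range lower bound must be >= 2.5 px")
            if 2 * hi + 2 >= min(rows, cols):
                raise AdcTextureError("roi_radius_range does not fit inside image_shape")


@dataclass
class SyntheticCase:
    """One simulated slice: DWI stack, ROI mask, label and demographics."""

    dwi: DWISeries
    mask: ROIMask
    label: str
    age: float
    gender: int
    case_id: str


# Background (non-tumor) tissue field parameters, shared by all cases.
_BACKGROUND_ADC = 900e-6
_BACKGROUND_CL = 2.0
_BACKGROUND_SD = 0.05


def _correlated_field(rng, shape, sigma):
    """Zero-mean, unit-variance Gaussian random field."""
    white = rng.standard_normal(shape)
    if sigma > 0:
        f = gaussian_filter(white, sigma=sigma, mode="reflect")
    else:
        f = white
    sd = f.std()
    return f / sd if sd > 0 else f


def _make_case(rng, config: SimConfig, label: str, case_id: str) -> SyntheticCase:
    rows, cols = config.image_shape
    cp = config.class_params[label]
    lo, hi = cp.roi_radius_range
    a, b = rng.uniform(lo, hi, size=2)
    cr = rng.uniform(a + 1, rows - a - 2)
    cc = rng.uniform(b + 1, cols - b - 2)
    rr = np.arange(rows)[:, None]
    cgrid = np.arange(cols)[None, :]
    mask = ((rr - cr) / a) ** 2 + ((cgrid - cc) / b) ** 2 <= 1.0

    adc = _BACKGROUND_ADC * (
        1.0 + _BACKGROUND_SD * _correlated_field(rng, (rows, cols), _BACKGROUND_CL)
    )
    tumor = cp.mean_adc * (
        1.0
        + cp.heterogeneity_sd
        * _correlated_field(rng, (rows, cols), cp.texture_correlation_length)
    )
    adc[mask] = tumor[mask]
    np.clip(adc, 0.02 * cp.mean_adc, None, out=adc)

    images = []
    for bv in config.b_values:
        s = config.s0_intensity * np.exp(-float(bv) * adc)
        if config.noise_sd > 0:
            s = s * rng.lognormal(mean=0.0, sigma=config.noise_sd, size=s.shape)
        images.append(np.maximum(s, 1e-12))
    dwi = DWISeries(images=images, b_values=list(config.b_values))
    age = float(rng.uniform(*config.age_range))
    gender = int(rng.random() < config.gender_prob_by_class[label])
    return SyntheticCase(
        dwi=dwi, mask=ROIMask(mask), label=label, age=age, gender=gender, case_id=case_id
    )


def generate_cohort(config: SimConfig) -> list:
    """Simulate a labeled cohort of ``config.n_slices`` cases.

    Class counts are round(n_slices * malignant_fraction) malignant and
    the remainder benign; the case sequence is shuffled deterministically
    from the seed.
    """
    config.validate()
    n = int(config.n_slices)
    n_mal = round(n * config.malignant_fraction)
    n_ben = n - n_mal
    if n_mal < 2 or n_ben < 2:
        raise DegenerateCohortError(
            f"degenerate cohort: {n_mal} malignant / {n_ben} benign slices"
        )
    rng = np.random.default_rng(config.seed)
    labels = np.array(["malignant"] * n_mal + ["benign"] * n_ben)
    rng.shuffle(labels)
    return [
        _make_case(rng, config, label, f"case_{idx:05d}")
        for idx, label in enumerate(labels)
    ]


def _nifti_save(array: np.ndarray, path: str) -> None:
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), affine=np.eye(4))
    nib.save(img, path)


def _nifti_load(path: str) -> np.ndarray:
    import nibabel as nib

    return np.asarray(nib.load(path).get_fdata(), dtype=np.float64)


def write_cohort(cases: list, out_dir: str, overwrite: bool = False) -> pd.DataFrame:
    """Store a cohort as per-case NIfTI volumes plus a CSV manifest.

    One image file per b-value and one mask per case; the manifest lists
    case_id, per-b-value paths (columns ``b0_path``, ``b1000_path``, ...),
    mask_path, label, age, gender.  Intensities round-trip exactly
    (float64 storage).
    """
    if not cases:
        raise AdcTextureError("refusing to write an empty cohort")
    os.makedirs(out_dir, exist_ok=True)
    manifest_path = os.path.join(out_dir, "manifest.csv")
    if os.path.exists(manifest_path) and not overwrite:
        raise AdcTextureError(f"manifest already exists: {manifest_path}")
    b_values = cases[0].dwi.b_values
    rows = []
    for case in cases:
        row = {"case_id": case.case_id}
        for im, bv in zip(case.dwi.images, case.dwi.b_values):
            fname = f"{case.case_id}_b{int(bv)}.nii.gz"
            _nifti_save(im, os.path.join(out_dir, fname))
            row[f"b{int(bv)}_path"] = fname
        mask_name = f"{case.case_id}_mask.nii.gz"
        _nifti_save(case.mask.mask.astype(np.float64), os.path.join(out_dir, mask_name))
        row.update(
            mask_path=mask_name, label=case.label, age=case.age, gender=case.gender
        )
        rows.append(row)
    cols = (
        ["case_id"]
        + [f"b{int(bv)}_path" for bv in b_values]
        + ["mask_path", "label", "age", "gender"]
    )
    manifest = pd.DataFrame(rows, columns=cols)
    manifest.to_csv(manifest_path, index=False)
    return manifest


def read_cohort(manifest_path: str) -> list:
    """Load a cohort written by :func:`write_cohort`."""
    manifest = pd.read_csv(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    b_cols = [c for c in manifest.columns if c.startswith("b") and c.endswith("_path")]
    b_values = [float(c[1:-5]) for c in b_cols]
    cases = []
    for _, row in manifest.iterrows():
        images = [_nifti_load(os.path.join(base, row[c])) for c in b_cols]
        mask = _nifti_load(os.path.join(base, row["mask_path"])) > 0.5
        cases.append(
            SyntheticCase(
                dwi=DWISeries(images=images, b_values=list(b_values)),
                mask=ROIMask(mask),
                label=str(row["label"]),
                age=float(row["age"]),
                gender=int(row["gender"]),
                case_id=str(row["case_id"]),
            )
        )
    return cases
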