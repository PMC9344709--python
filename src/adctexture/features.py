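"""Per-slice feature table assembly, normalization and CSV interchange.

Each row holds 16 attributes — the 14 numeric image features plus
patient age and gender — together with the case id and the binary
malignant/benign label.  Min-max normalization X_n = (X - X_min) /
(X_max - X_min) learns its parameters from a designated fitting subset
(the training rows, to avoid leakage) and is applied unclipped
elsewhere; a z-score variant is available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AdcTextureError, FeatureExtractionError
from .texture import IMAGE_FEATURE_NAMES, extract_image_features
from .adc import ADCMap, compute_adc

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_COLUMNS",
    "TABLE_COLUMNS",
    "LABELS",
    "NormalizationParams",
    "extract_feature_table",
    "validate_table",
    "read_table",
    "write_table",
    "minmax_fit",
    "minmax_apply",
]

LABELS = ("malignant", "benign")

#: The 16 feature attributes, in canonical order.
FEATURE_COLUMNS = IMAGE_FEATURE_NAMES + ["age", "gender"]

#: Full CSV column contract.
TABLE_COLUMNS = ["case_id"] + FEATURE_COLUMNS + ["label"]


def extract_feature_table(cases, levels: int = 16, distance: int = 1) -> pd.DataFrame:
    """Extract the per-slice feature vector for every case in a cohort.

    Slices whose features are undefined (degenerate ROI, offset larger
    than the ROI) are dropped with a logged count, mirroring an
    exclusion step on real data.
    """
    rows, dropped = [], 0
    for case in cases:
        adc = compute_adc(case.dwi)
        try:
            feats = extract_image_features(adc, case.mask, levels=levels, distance=distance)
        except FeatureExtractionError as exc:
            logger.warning("dropping %s: %s", case.case_id, exc)
            dropped += 1
            continue
        row = {"case_id": case.case_id, **feats,
               "age": case.age, "gender": case.gender, "label": case.label}
        rows.append(row)
    if dropped:
        logger.info("excluded %d of %d slices during feature extraction",
                    dropped, len(cases))
    if not rows:
        raise AdcTextureError("no valid slices after feature extraction")
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Realign columns by name to the contract and check the invariants."""
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise AdcTextureError(f"feature table missing columns: {sorted(missing)}")
    df = df[TABLE_COLUMNS].copy()
    bad_label = ~df["label"].isin(LABELS)
    if bad_label.any():
        raise AdcTextureError("labels must be binary malignant/benign")
    if not df["gender"].isin((0, 1)).all():
        raise AdcTextureError("gender must be encoded {0,1}")
    return df


def read_table(path) -> pd.DataFrame:
    """Read a feature CSV, realigning columns by name.

    Rows with any missing or non-numeric feature value, an unknown
    label, or a non-binary gender are dropped with a logged count.
    """
    df = pd.read_csv(path)
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise AdcTextureError(f"feature CSV missing columns: {sorted(missing)}")
    df = df[TABLE_COLUMNS]
    n_raw = len(df)
    numeric = df[FEATURE_COLUMNS].apply(pd.to_numeric, errors="coerce")
    ok = numeric.notna().all(axis=1)
    ok &= df["label"].isin(LABELS)
    ok &= numeric["gender"].isin((0, 1))
    kept = df[ok].copy()
    kept[FEATURE_COLUMNS] = numeric[ok]
    n_dropped = n_raw - len(kept)
    if n_dropped:
        logger.info("read_table: excluded %d of %d malformed rows", n_dropped, n_raw)
    if kept.empty:
        raise AdcTextureError("feature table is empty after exclusions")
    return kept.reset_index(drop=True)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a feature table CSV at full floating precision."""
    validate_table(df).to_csv(path, index=False)


@dataclass
class NormalizationParams:
    """Per-feature scaling parameters learned from a fitting subset."""

    method: str  # "minmax" or "zscore"
    params: dict  # feature -> (min, max) or (mean, sd)


def minmax_fit(
    df: pd.DataFrame, fit_rows=None, method: str = "minmax"
) -> NormalizationParams:
    """Learn per-feature scaling parameters on ``fit_rows`` only.

    ``fit_rows`` is a boolean/positional index into ``df`` (default: all
    rows).  A feature constant on the fitting subset is an error naming
    the feature — its scale is undefined.
    """
    if method not in ("minmax", "zscore"):
        raise AdcTextureError(f"unknown normalization method '{method}'")
    sub = df if fit_rows is None else df.loc[fit_rows]
    if len(sub) == 0:
        raise AdcTextureError("fitting subset is empty")
    params = {}
    for col in FEATURE_COLUMNS:
        x = sub[col].to_numpy(dtype=float)
        if method == "minmax":
            lo, hi = float(x.min()), float(x.max())
            if hi <= lo:
                raise AdcTextureError(f"feature '{col}' is constant on the fitting subset")
            params[col] = (lo, hi)
        else:
            mu, sd = float(x.mean()), float(x.std())
            if sd == 0:
                raise AdcTextureError(f"feature '{col}' is constant on the fitting subset")
            params[col] = (mu, sd)
    return NormalizationParams(method=method, params=params)


def minmax_apply(df: pd.DataFrame, params: NormalizationParams) -> pd.DataFrame:
    """Apply learned scaling to every row; values outside the fitting
    subset's range are NOT clipped."""
    out = df.copy()
    for col in FEATURE_COLUMNS:
        if col not in params.params:
            raise AdcTextureError(f"no normalization parameters for feature '{col}'")
        a, b = params.params[col]
        x = out[col].to_numpy(dtype=float)
        if params.method == "minmax":
            out[col] = (x - a) / (b - a)
        else:
            out[col] = (x - a) / b
    return out
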