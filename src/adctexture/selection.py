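"""Univariate feature ranking by repeated one-way ANOVA F-test.

Each feature is scored by the one-way F statistic of its between-class
versus within-class variance against the binary label.  Because a single
F-test is deterministic, run-to-run variation is induced by scoring each
repeat on a stratified random subsample of the rows; the mean score over
repeats is the reported rank statistic, and the lowest-scoring features
are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AdcTextureError
from .features import FEATURE_COLUMNS, LABELS

__all__ = ["ANOVAScores", "anova_f", "repeated_anova", "select_features"]


def anova_f(feature_values, labels) -> float:
    """One-way ANOVA F statistic (between-group MS / within-group MS)
    of a feature against a binary label, df (1, N-2)."""
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(labels)
    groups = [x[y == g] for g in np.unique(y)]
    if len(groups) != 2:
        raise AdcTextureError("anova_f requires exactly two classes present")
    if any(len(g) < 2 for g in groups):
        raise AdcTextureError("each class needs at least 2 members")
    if all(np.ptp(g) == 0 for g in groups):
        raise AdcTextureError("zero within-group variance: F undefined")
    stat, _ = stats.f_oneway(*groups)
    return float(stat)


@dataclass
class ANOVAScores:
    """Per-feature F scores over repeated stratified subsamples."""

    per_repeat: pd.DataFrame  # repeats x features
    repeats: int
    resample_fraction: float

    @property
    def mean_scores(self) -> pd.Series:
        return self.per_repeat.mean(axis=0)

    @property
    def rank(self) -> pd.Series:
        """1 = highest mean score."""
        return self.mean_scores.rank(ascending=False, method="first").astype(int)


def _stratified_subsample(df: pd.DataFrame, fraction: float, rng) -> pd.DataFrame:
    parts = []
    for label in LABELS:
        idx = df.index[df["label"] == label].to_numpy()
        k = int(round(fraction * len(idx)))
        k = max(k, min(2, len(idx)))
        take = rng.choice(idx, size=k, replace=False)
        parts.append(df.loc[take])
    return pd.concat(parts)


def repeated_anova(
    table: pd.DataFrame,
    repeats: int = 5,
    resample_fraction: float = 0.8,
    seed: int = 0,
    feature_columns=None,
) -> ANOVAScores:
    """Score every feature by the mean one-way F over ``repeats``
    stratified subsamples of ``resample_fraction`` of the rows.

    Deterministic given ``seed``.  A subsample that loses a class (or
    leaves a class with fewer than 2 rows) is redrawn with bounded
    retries before erroring.
    """
    if repeats < 1:
        raise AdcTextureError("repeats must be >= 1")
    if not (0.0 < resample_fraction <= 1.0):
        raise AdcTextureError("resample_fraction must be in (0,1]")
    cols = list(feature_columns) if feature_columns is not None else FEATURE_COLUMNS
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(repeats):
        for _attempt in range(10):
            sub = (
                table
                if resample_fraction == 1.0
                else _stratified_subsample(table, resample_fraction, rng)
            )
            counts = sub["label"].value_counts()
            if all(counts.get(label, 0) >= 2 for label in LABELS):
                break
        else:
            raise AdcTextureError("could not draw a subsample with both classes")
        labels = sub["label"].to_numpy()
        rows.append({c: anova_f(sub[c].to_numpy(), labels) for c in cols})
    per_repeat = pd.DataFrame(rows, columns=cols)
    return ANOVAScores(
        per_repeat=per_repeat, repeats=repeats, resample_fraction=resample_fraction
    )


def select_features(scores: ANOVAScores, drop_k: int = 2) -> list:
    """Retain all but the ``drop_k`` lowest-mean-score features.

    Ties are broken by column order (earlier columns dropped first),
    which a stable argsort guarantees.
    """
    if drop_k < 0:
        raise AdcTextureError("drop_k must be non-negative")
    cols = list(scores.per_repeat.columns)
    if drop_k >= len(cols):
        raise AdcTextureError(
            f"drop_k={drop_k} must be smaller than the number of features ({len(cols)})"
        )
    mean = scores.mean_scores.to_numpy()
    order = np.argsort(mean, kind="stable")  # ascending; ties by column order
    dropped = {cols[i] for i in order[:drop_k]}
    return [c for c in cols if c not in dropped]
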