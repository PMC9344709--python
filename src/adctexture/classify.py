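"""Model comparison, Random Forest tuning, threshold adjustment, metrics.

The malignant class is the positive class throughout.  The workflow is:
stratified 70/30 split; ten-fold cross-validated comparison of seven
standard classifiers at their library defaults; uniform random search
over a Random Forest hyperparameter grid scored by precision or recall;
decision-threshold adjustment from the precision-recall curve (default:
a fixed 0.45 cutoff); and per-class precision/recall/F1/support
reporting with the confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import AdcTextureError
from .features import FEATURE_COLUMNS

__all__ = [
    "POSITIVE_LABEL",
    "SplitSpec",
    "CVResult",
    "RFGrid",
    "ConfusionMatrix",
    "stratified_split",
    "crossvalidate_algorithms",
    "random_search_rf",
    "fit_rf",
    "pr_threshold",
    "predict_scores",
    "evaluate",
    "report_from_counts",
    "ALGORITHM_ROSTER",
]

POSITIVE_LABEL = "malignant"


def _encode(labels) -> np.ndarray:
    return (np.asarray(labels) == POSITIVE_LABEL).astype(int)


@dataclass
class SplitSpec:
    """Stratified train/test split specification."""

    test_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.test_fraction < 1.0):
            raise AdcTextureError("test_fraction must be in (0,1)")


def stratified_split(table: pd.DataFrame, spec: SplitSpec):
    """Split rows into (train, test) preserving class proportions.

    The global test size is round(N * test_fraction); per-class test
    counts are the floors of class_count * test_fraction topped up by
    largest fractional remainder until the global total is met, so each
    class's proportion is preserved within one row.  Deterministic given
    the seed.
    """
    labels = table["label"].to_numpy()
    classes, class_counts = np.unique(labels, return_counts=True)
    if len(classes) < 2 or class_counts.min() < 2:
        raise AdcTextureError("both classes need at least 2 rows to stratify")
    n_total = len(table)
    n_test = int(round(n_total * spec.test_fraction))
    exact = class_counts * spec.test_fraction
    take = np.floor(exact).astype(int)
    remainder_order = np.argsort(-(exact - take), kind="stable")
    i = 0
    while take.sum() < n_test:
        take[remainder_order[i % len(classes)]] += 1
        i += 1
    rng = np.random.default_rng(spec.seed)
    test_idx = []
    for cls, k in zip(classes, take):
        idx = table.index[labels == cls].to_numpy()
        test_idx.extend(rng.choice(idx, size=k, replace=False))
    test_mask = table.index.isin(test_idx)
    return table.loc[~test_mask].copy(), table.loc[test_mask].copy()


def _make_roster(seed: int):
    # Paper-fixed roster at library defaults, ordered simple -> complex
    # (tie-break order).  LogisticRegression gets max_iter=1000 for
    # reliable convergence; everything else is stock.
    return [
        ("logistic_regression", LogisticRegression(max_iter=1000)),
        ("linear_discriminant_analysis", LinearDiscriminantAnalysis()),
        ("k_nearest_neighbors", KNeighborsClassifier()),
        ("decision_tree", DecisionTreeClassifier(random_state=seed)),
        ("gaussian_nb", GaussianNB()),
        ("svc", SVC()),
        ("random_forest", RandomForestClassifier(random_state=seed)),
    ]


ALGORITHM_ROSTER = [name for name, _ in _make_roster(0)]


@dataclass
class CVResult:
    """Per-algorithm fold accuracies from stratified k-fold CV."""

    fold_scores: dict  # name -> ndarray of fold accuracies
    folds: int

    @property
    def table(self) -> pd.DataFrame:
        rows = [
            {
                "algorithm": name,
                "mean_accuracy": float(np.mean(s)),
                "accuracy_sd": float(np.std(s)),
            }
            for name, s in self.fold_scores.items()
        ]
        return pd.DataFrame(rows)

    @property
    def winner(self) -> str:
        """Highest mean accuracy; ties go to the earlier (simpler) entry."""
        best, best_score = None, -1.0
        for name, s in self.fold_scores.items():
            m = float(np.mean(s))
            if m > best_score:
                best, best_score = name, m
        return best


def crossvalidate_algorithms(
    train: pd.DataFrame, feature_columns=None, folds: int = 10, seed: int = 0
) -> CVResult:
    """Stratified k-fold accuracy of the seven-algorithm roster."""
    cols = list(feature_columns) if feature_columns is not None else FEATURE_COLUMNS
    X = train[cols].to_numpy(dtype=float)
    y = _encode(train["label"])
    if min(np.bincount(y)) < folds:
        raise AdcTextureError("a class has fewer rows than folds: degenerate fold")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, model in _make_roster(seed):
            scores[name] = cross_val_score(model, X, y, cv=cv, scoring="accuracy")
    return CVResult(fold_scores=scores, folds=folds)


@dataclass
class RFGrid:
    """Random Forest hyperparameter grid for uniform random search."""

    min_samples_split: tuple = (2, 5, 10)
    n_estimators: tuple = tuple(range(200, 1001, 10))
    max_depth: tuple = tuple(range(10, 101, 10))
    max_features: tuple = (3, 5, 10, 20)
    n_sampled_candidates: int = 100
    scoring: str = "precision"  # or "recall"
    cv_folds: int = 5

    def __post_init__(self):
        if self.scoring not in ("precision", "recall"):
            raise AdcTextureError("scoring must be 'precision' or 'recall'")
        if self.n_sampled_candidates < 1:
            raise AdcTextureError("n_sampled_candidates must be >= 1")
        for name in ("min_samples_split", "n_estimators", "max_depth", "max_features"):
            if len(getattr(self, name)) == 0:
                raise AdcTextureError(f"empty grid dimension '{name}'")


@dataclass
class SearchResult:
    best_params: dict
    best_score: float
    results: pd.DataFrame = field(repr=False, default=None)


def _rf_from_params(params: dict, n_features: int, seed: int) -> RandomForestClassifier:
    # max_features cannot exceed the actual feature count.
    p = dict(params)
    p["max_features"] = min(p["max_features"], n_features)
    return RandomForestClassifier(random_state=seed, **p)


def random_search_rf(
    train: pd.DataFrame,
    grid: RFGrid | None = None,
    feature_columns=None,
    seed: int = 0,
) -> SearchResult:
    """Uniformly sample hyperparameter candidates from the grid and score
    each by stratified CV on the training rows with the grid's scoring
    (precision or recall, malignant positive).  Returns the best."""
    grid = grid or RFGrid()
    cols = list(feature_columns) if feature_columns is not None else FEATURE_COLUMNS
    X = train[cols].to_numpy(dtype=float)
    y = _encode(train["label"])
    rng = np.random.default_rng(seed)
    cv = StratifiedKFold(n_splits=grid.cv_folds, shuffle=True, random_state=seed)
    records = []
    best_params, best_score = None, -1.0
    for _ in range(grid.n_sampled_candidates):
        params = {
            "min_samples_split": int(rng.choice(grid.min_samples_split)),
            "n_estimators": int(rng.choice(grid.n_estimators)),
            "max_depth": int(rng.choice(grid.max_depth)),
            "max_features": int(rng.choice(grid.max_features)),
        }
        model = _rf_from_params(params, len(cols), seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            score = float(
                np.mean(cross_val_score(model, X, y, cv=cv, scoring=grid.scoring))
            )
        records.append({**params, "score": score})
        if score > best_score:
            best_params, best_score = params, score
    return SearchResult(
        best_params=best_params, best_score=best_score, results=pd.DataFrame(records)
    )


def fit_rf(
    train: pd.DataFrame, params: dict | None = None, feature_columns=None, seed: int = 0
) -> RandomForestClassifier:
    """Fit a Random Forest (default or tuned parameters) on training rows."""
    cols = list(feature_columns) if feature_columns is not None else FEATURE_COLUMNS
    X = train[cols].to_numpy(dtype=float)
    y = _encode(train["label"])
    if params:
        model = _rf_from_params(params, len(cols), seed)
    else:
        model = RandomForestClassifier(random_state=seed)
    model.fit(X, y)
    return model


def predict_scores(model, table: pd.DataFrame, feature_columns=None) -> np.ndarray:
    """Malignant-class probability scores for each row."""
    cols = list(feature_columns) if feature_columns is not None else FEATURE_COLUMNS
    X = table[cols].to_numpy(dtype=float)
    pos = list(model.classes_).index(1)
    return model.predict_proba(X)[:, pos]


def pr_threshold(
    scores, y_true, mode: str = "fixed", fixed_value: float = 0.45
) -> float:
    """Choose the decision threshold (malignant iff score >= threshold).

    ``fixed`` returns ``fixed_value``; ``max_f1`` scans the candidate
    thresholds of the precision-recall curve and returns the
    F1-maximizing one, ties resolved to the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    if np.ptp(scores) == 0:
        raise AdcTextureError("uninformative scorer: all scores identical")
    if mode == "fixed":
        return float(fixed_value)
    if mode != "max_f1":
        raise AdcTextureError(f"unknown threshold mode '{mode}'")
    y = np.asarray(y_true, dtype=int)
    # Candidate cutoffs: the lowest score (predict everything positive)
    # plus the midpoints between consecutive distinct scores; together
    # these realize every prediction set the curve can produce.
    uniq = np.unique(scores)
    candidates = np.concatenate([[uniq[0]], (uniq[:-1] + uniq[1:]) / 2.0])
    n_pos = int((y == 1).sum())
    best_thr, best_f1 = None, -1.0
    for t in candidates:  # ascending; strict > keeps the lowest tie
        pred = scores >= t
        tp = int(np.sum(pred & (y == 1)))
        p = tp / pred.sum() if pred.sum() else 0.0
        r = tp / n_pos if n_pos else 0.0
        f1 = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
        if f1 > best_f1:
            best_thr, best_f1 = float(t), f1
    return best_thr


@dataclass
class ConfusionMatrix:
    """Counts with malignant as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, reporting 0", RuntimeWarning)
        return 0.0
    return num / den


def report_from_counts(tp: int, tn: int, fp: int, fn: int, threshold=None) -> dict:
    """Accuracy, per-class precision/recall/F1/support and macro/weighted
    averages computed directly from confusion counts."""
    cm = ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn)
    accuracy = _safe_div(tp + tn, cm.total, "accuracy")

    def prf(tp_, fp_, fn_):
        p = _safe_div(tp_, tp_ + fp_, "precision")
        r = _safe_div(tp_, tp_ + fn_, "recall")
        f1 = _safe_div(2 * p * r, p + r, "f1") if (p + r) > 0 else 0.0
        return p, r, f1

    p_m, r_m, f_m = prf(tp, fp, fn)
    p_b, r_b, f_b = prf(tn, fn, fp)  # benign as positive
    sup_m, sup_b = tp + fn, tn + fp
    total = sup_m + sup_b
    report = {
        "per_class": {
            "malignant": {"precision": p_m, "recall": r_m, "f1": f_m, "support": sup_m},
            "benign": {"precision": p_b, "recall": r_b, "f1": f_b, "support": sup_b},
        },
        "accuracy": accuracy,
        "macro_avg": {
            "precision": (p_m + p_b) / 2,
            "recall": (r_m + r_b) / 2,
            "f1": (f_m + f_b) / 2,
            "support": total,
        },
        "weighted_avg": {
            "precision": _safe_div(p_m * sup_m + p_b * sup_b, total, "weighted precision"),
            "recall": _safe_div(r_m * sup_m + r_b * sup_b, total, "weighted recall"),
            "f1": _safe_div(f_m * sup_m + f_b * sup_b, total, "weighted f1"),
            "support": total,
        },
        "confusion_matrix": {"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    }
    if threshold is not None:
        report["decision_threshold"] = float(threshold)
    return report


def evaluate(
    model, threshold: float, test: pd.DataFrame, feature_columns=None
) -> dict:
    """Score the test rows, threshold, and report all metrics."""
    if len(test) == 0:
        raise AdcTextureError("empty test set")
    y = _encode(test["label"])
    if len(np.unique(y)) < 2:
        raise AdcTextureError("test set must contain both classes")
    scores = predict_scores(model, test, feature_columns)
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    return report_from_counts(tp, tn, fp, fn, threshold=threshold)


def curve_points(scores, y_true):
    """PR and ROC curve points as DataFrames (for CSV export)."""
    y = np.asarray(y_true, dtype=int)
    precision, recall, pr_thr = precision_recall_curve(y, scores)
    fpr, tpr, roc_thr = roc_curve(y, scores)
    pr = pd.DataFrame(
        {
            "threshold": np.concatenate([pr_thr, [np.nan]]),
            "precision": precision,
            "recall": recall,
        }
    )
    roc = pd.DataFrame({"threshold": roc_thr, "fpr": fpr, "tpr": tpr})
    return pr, roc
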