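"""Obesity classification protocol: candidate models, 10-fold CV, metrics.

Four candidate model families (logistic regression, random forest, XGBoost,
gradient boosting) are compared under stratified 10-fold cross-validation.
Random oversampling of the minority class is applied *inside each training
fold only* — test folds are never resampled — so reported metrics are free
of resampling leakage.  The random forest defaults to 5,000 trees; an
override exists because desk-scale runs do not need that many.

Metrics follow the standard confusion-table definitions; a metric with a
zero denominator is reported as an explicit ``None`` marker rather than
silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .preprocess import oversample_indices

DEFAULT_RF_TREES = 5000
DEFAULT_FOLDS = 10


@dataclass
class ConfusionCounts:
    """Binary confusion table (positive class = obese)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(bool)
        y_pred = np.asarray(y_pred).astype(bool)
        return cls(
            tp=int(np.sum(y_true & y_pred)),
            fp=int(np.sum(~y_true & y_pred)),
            tn=int(np.sum(~y_true & ~y_pred)),
            fn=int(np.sum(y_true & ~y_pred)),
        )


@dataclass
class MetricSet:
    """Accuracy / precision / recall / F1; ``None`` marks an undefined metric."""

    accuracy: float | None
    precision: float | None
    recall: float | None
    f1: float | None

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, precision, recall and F1 from a confusion table.

    accuracy  = (TP+TN) / (TP+FP+TN+FN)
    precision = TP / (TP+FP)
    recall    = TP / (TP+FN)
    f1        = harmonic mean of precision and recall

    Any ratio with a zero denominator is reported as ``None``.
    """
    if c.total <= 0:
        raise ValueError("confusion table is empty")
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return MetricSet(accuracy, precision, recall, f1)


@dataclass
class ModelSpec:
    """A named, seedable model family."""

    name: str
    factory: Callable[[int], object]  # seed -> unfitted estimator

    def build(self, seed: int):
        return self.factory(seed)


def default_model_specs(trees: int = DEFAULT_RF_TREES, max_depth: int | None = None
                        ) -> list[ModelSpec]:
    """The four candidate families, in the order they are compared."""
    import xgboost as xgb

    return [
        ModelSpec("logistic_regression",
                  lambda seed: LogisticRegression(max_iter=2000, random_state=seed)),
        ModelSpec("random_forest",
                  lambda seed: RandomForestClassifier(
                      n_estimators=trees, max_depth=max_depth, random_state=seed, n_jobs=1)),
        ModelSpec("xgboost",
                  lambda seed: xgb.XGBClassifier(
                      n_estimators=min(trees, 300), max_depth=max_depth or 6,
                      random_state=seed, n_jobs=1, verbosity=0)),
        ModelSpec("gradient_boosting",
                  lambda seed: GradientBoostingClassifier(
                      n_estimators=min(trees, 300), random_state=seed)),
    ]


def random_forest_spec(trees: int = DEFAULT_RF_TREES, max_depth: int | None = None) -> ModelSpec:
    return ModelSpec(
        "random_forest",
        lambda seed: RandomForestClassifier(
            n_estimators=trees, max_depth=max_depth, random_state=seed, n_jobs=1),
    )


@dataclass
class CvResult:
    """Per-fold and pooled cross-validation outcome for one model."""

    model_name: str
    per_fold: list[MetricSet]
    per_fold_counts: list[ConfusionCounts]
    pooled_counts: ConfusionCounts
    pooled: MetricSet
    fold_assignment: np.ndarray  # test-fold index of every record
    mean_of_folds: MetricSet = field(init=False)

    def __post_init__(self) -> None:
        # fold-averaged metrics alongside pooled ones; undefined folds are skipped
        def mean_of(attr: str) -> float | None:
            vals = [getattr(m, attr) for m in self.per_fold if getattr(m, attr) is not None]
            return float(np.mean(vals)) if vals else None

        self.mean_of_folds = MetricSet(*(mean_of(a) for a in
                                         ("accuracy", "precision", "recall", "f1")))


def kfold_cv(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    model_spec: ModelSpec,
    k: int = DEFAULT_FOLDS,
    seed: int = 0,
    oversample: bool = True,
) -> CvResult:
    """Stratified k-fold CV with training-fold-only oversampling.

    Fold assignment is stratified on the label and deterministic under
    ``seed``.  Each training split is balanced to 1:1 by random oversampling
    (seeded per fold); the test split is left untouched.  Per-fold confusion
    counts are also summed into pooled counts.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    y = np.asarray(y).astype(int)
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)

    per_fold, per_counts = [], []
    pooled = ConfusionCounts(0, 0, 0, 0)
    assignment = np.full(len(y), -1, dtype=int)
    for fold, (train_idx, test_idx) in enumerate(skf.split(Xa, y)):
        assignment[test_idx] = fold
        y_train = y[train_idx]
        if y_train.min() == y_train.max():
            raise ValueError(f"fold {fold}: training split contains a single class")
        if oversample and y_train.mean() not in (0.0, 1.0):
            rng = np.random.default_rng(seed * 100_003 + fold)
            rel = oversample_indices(y_train.astype(bool), rng)
            train_idx = train_idx[rel]
            y_train = y[train_idx]
        model = model_spec.build(seed)
        model.fit(Xa[train_idx], y_train)
        pred = np.asarray(model.predict(Xa[test_idx])).astype(int)
        counts = ConfusionCounts.from_labels(y[test_idx], pred)
        per_counts.append(counts)
        per_fold.append(compute_metrics(counts))
        pooled = pooled + counts
    return CvResult(model_spec.name, per_fold, per_counts, pooled,
                    compute_metrics(pooled), assignment)


def compare_models(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    model_specs: Sequence[ModelSpec],
    k: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> list[CvResult]:
    """Evaluate each spec on identical folds; rank by pooled accuracy.

    Ties are broken by pooled F1, then by spec order.  Returns the CvResults
    in rank order (best first).
    """
    if len(model_specs) < 2 and len(model_specs) != 1:
        raise ValueError("need at least one model spec")
    results = [kfold_cv(X, y, spec, k=k, seed=seed) for spec in model_specs]

    def key(item):
        i, r = item
        f1 = r.pooled.f1 if r.pooled.f1 is not None else -1.0
        return (-r.pooled.accuracy, -f1, i)

    return [r for _, r in sorted(enumerate(results), key=key)]


def per_district_cv(
    records: pd.DataFrame,
    feature_cols: Sequence[str],
    model_spec: ModelSpec,
    label_col: str = "obese",
    district_col: str = "district_id",
    k: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> pd.DataFrame:
    """One cross-validated model per district: a per-district metric table.

    Output has one row per district with pooled accuracy/precision/recall/f1
    plus a final 'Total' row holding the across-district mean and SD of each
    metric — the shape used to report per-district classification quality.
    """
    rows = []
    for district, grp in records.groupby(district_col, sort=True):
        res = kfold_cv(grp[list(feature_cols)], grp[label_col].to_numpy(), model_spec,
                       k=k, seed=seed)
        rows.append({district_col: district, **res.pooled.as_dict()})
    table = pd.DataFrame(rows)
    summary = {district_col: "Total"}
    for m in ("accuracy", "precision", "recall", "f1"):
        vals = table[m].astype(float)
        summary[m] = vals.mean()
        summary[f"{m}_sd"] = vals.std(ddof=1)
    return pd.concat([table, pd.DataFrame([summary])], ignore_index=True)
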