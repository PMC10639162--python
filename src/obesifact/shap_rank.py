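"""Shapley-value factor ranking over a trained tree ensemble.

Per district, the fitted classifier's predictions are decomposed into
per-record, per-feature Shapley attributions on the obese-class probability
margin (positive values push toward obesity).  Feature importance is the
mean absolute attribution over records — the ordering a summary plot uses —
with alphabetical tie-breaking for reproducible tables.  The top-k prefix
gives the "top influential factors" table, and the dependence export pairs
each record's raw response value with its attribution for one feature,
ready for scatter rendering.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .treeshap import model_margin, shap_values


@dataclass
class ShapMatrix:
    """Signed attributions (n_records x n_features) plus the expected output."""

    values: np.ndarray
    base_value: float
    feature_names: list[str]

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValueError("values shape does not match feature_names")


@dataclass
class ShapRanking:
    """Features sorted non-increasing by mean absolute attribution."""

    ordered: list[tuple[str, float]]
    district_id: str | None = None

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.ordered, columns=["feature", "mean_abs_shap"])
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        if self.district_id is not None:
            df.insert(0, "district_id", self.district_id)
        return df


def compute_shap(model, X: pd.DataFrame) -> ShapMatrix:
    """Exact tree-path Shapley attributions for every row of ``X``.

    ``model`` must be a tree ensemble fitted on exactly the columns of ``X``
    (in order).  The local-accuracy identity — base value plus the row's
    attributions equals the model margin — is guaranteed by construction.
    """
    names = list(X.columns)
    phi, base = shap_values(model, X.to_numpy(dtype=float))
    return ShapMatrix(values=phi, base_value=base, feature_names=names)


def check_local_accuracy(model, X: pd.DataFrame, shap: ShapMatrix, tol: float = 1e-6
                         ) -> float:
    """Max |base + sum(phi) - prediction| over records; raises above ``tol``."""
    pred = model_margin(model, X.to_numpy(dtype=float))
    err = float(np.abs(shap.base_value + shap.values.sum(axis=1) - pred).max())
    if err > tol:
        raise AssertionError(f"local accuracy violated: max error {err:.3g} > {tol}")
    return err


def rank_features(shap: ShapMatrix, district_id: str | None = None) -> ShapRanking:
    """Importance = mean over records of |attribution|, sorted descending.

    Ties are broken by feature name so repeated runs produce identical
    tables.
    """
    if shap.values.shape[0] == 0:
        raise ValueError("cannot rank features from an empty attribution matrix")
    importance = np.abs(shap.values).mean(axis=0)
    order = sorted(zip(shap.feature_names, importance), key=lambda t: (-t[1], t[0]))
    return ShapRanking([(name, float(v)) for name, v in order], district_id)


def top_k(ranking: ShapRanking, k: int = 5) -> list[str]:
    """The first min(k, p) feature names of the ranking."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return [name for name, _ in ranking.ordered[:k]]


def dependence_export(shap: ShapMatrix, X: pd.DataFrame, feature: str) -> pd.DataFrame:
    """(raw feature value, attribution) pairs for one feature, one row per record."""
    if feature not in shap.feature_names:
        raise ValueError(f"unknown feature {feature!r}")
    j = shap.feature_names.index(feature)
    return pd.DataFrame({feature: X[feature].to_numpy(), "shap_value": shap.values[:, j]})


def per_district_rankings(
    records: pd.DataFrame,
    feature_cols: Sequence[str],
    model_builder,
    label_col: str = "obese",
    district_col: str = "district_id",
    top: int = 5,
    shap_sample: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit one model per district and rank its features by Shapley importance.

    ``model_builder(seed)`` must return an unfitted tree ensemble.  Rankings
    are computed on all of the district's records by default, or on a seeded
    subsample of ``shap_sample`` records for large districts.  Returns the
    concatenated top-``top`` table (district_id, rank, feature,
    mean_abs_shap).
    """
    frames = []
    for district, grp in records.groupby(district_col, sort=True):
        X = grp[list(feature_cols)]
        y = grp[label_col].to_numpy().astype(int)
        model = model_builder(seed)
        model.fit(X.to_numpy(dtype=float), y)
        if shap_sample is not None and len(X) > shap_sample:
            rng = np.random.default_rng(seed)
            X = X.iloc[np.sort(rng.choice(len(X), size=shap_sample, replace=False))]
        ranking = rank_features(compute_shap(model, X), district_id=str(district))
        frames.append(ranking.as_frame().head(top))
    return pd.concat(frames, ignore_index=True)
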