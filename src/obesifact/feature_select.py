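"""Multicollinearity and significance screening of candidate features.

Two-stage screen applied before classification:

1. iterative variance-inflation-factor (VIF) pruning — VIF_j = 1/(1 - R²_j)
   with R²_j from regressing feature j on all remaining features (with
   intercept); the feature with the largest VIF above the threshold is removed
   and VIFs are recomputed until all survivors are at or below the threshold.
   The default threshold of 30 is deliberately permissive: a conventional
   threshold of 10 discards ordinal survey items that carry real signal, while
   VIF in (10, 30] indicates only weak multicollinearity.
2. a single multivariable ordinary-least-squares fit of the response on all
   surviving features (a linear-probability screen when the response is the
   0/1 obesity label); features whose two-sided coefficient p-value exceeds
   ``alpha`` (default 0.05) are dropped.

Categorical survey answers enter as numeric ordinal codes, the usual
survey-coding practice; no dummy expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: VIF at or above this is reported as effectively infinite (exact collinearity).
VIF_INFINITE = 1e12

DEFAULT_VIF_THRESHOLD = 30.0
DEFAULT_ALPHA = 0.05


@dataclass
class VifReport:
    """Outcome of iterative VIF pruning."""

    vif: dict[str, float]                 # VIFs of the surviving features
    removal_order: list[str] = field(default_factory=list)
    removed_vif: dict[str, float] = field(default_factory=dict)  # VIF at removal time
    threshold: float = DEFAULT_VIF_THRESHOLD


def _validate_design(X: pd.DataFrame) -> None:
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features to compute VIF")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than features to compute VIF")
    stds = X.std(axis=0, ddof=0)
    constant = stds.index[stds.to_numpy() == 0].tolist()
    if constant:
        raise ValueError(f"constant column(s) not allowed in VIF computation: {constant}")


def compute_vif(X: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor for each column of ``X``.

    VIF_j = 1/(1 - R²_j), R²_j from an intercept-included OLS of column j on
    the other columns.  Exact collinearity yields ``float('inf')``.
    """
    _validate_design(X)
    vifs: dict[str, float] = {}
    cols = list(X.columns)
    arr = X.to_numpy(dtype=float)
    for j, name in enumerate(cols):
        others = np.delete(arr, j, axis=1)
        fit = sm.OLS(arr[:, j], sm.add_constant(others)).fit()
        r2 = fit.rsquared
        if r2 >= 1.0 - 1.0 / VIF_INFINITE:
            vifs[name] = float("inf")
        else:
            v = 1.0 / (1.0 - r2)
            vifs[name] = float("inf") if v >= VIF_INFINITE else float(v)
    return vifs


def iterative_vif_prune(
    X: pd.DataFrame, threshold: float = DEFAULT_VIF_THRESHOLD
) -> tuple[pd.DataFrame, VifReport]:
    """Repeatedly drop the single worst-VIF feature until all VIFs <= threshold.

    Ties on the maximal VIF are broken toward the earliest column in the
    original order, so the run is deterministic.  Terminates in at most p
    steps.  Returns the surviving table and a :class:`VifReport`.
    """
    work = X.copy()
    report = VifReport(vif={}, threshold=threshold)
    while True:
        vifs = compute_vif(work)
        worst_name, worst_val = None, threshold
        for name in work.columns:  # original order => deterministic tie-break
            v = vifs[name]
            if v > worst_val:
                worst_name, worst_val = name, v
        if worst_name is None:
            report.vif = vifs
            return work, report
        report.removal_order.append(worst_name)
        report.removed_vif[worst_name] = worst_val
        work = work.drop(columns=[worst_name])
        if work.shape[1] < 2:
            # a single survivor has no multicollinearity by definition
            report.vif = {work.columns[0]: 1.0}
            return work, report


def ols_screen(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[list[str], pd.Series]:
    """Drop features insignificant in one joint OLS fit of y on all features.

    Fits a single multivariable linear regression with intercept and removes
    every feature whose two-sided coefficient t-test p-value exceeds
    ``alpha``.  Returns (surviving feature names, p-values for all features).
    """
    y = np.asarray(y, dtype=float)
    if X.shape[0] <= X.shape[1] + 1:
        raise ValueError("need more rows than features + 1 for the OLS screen")
    design = sm.add_constant(X.to_numpy(dtype=float))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient; run VIF pruning first")
    fit = sm.OLS(y, design).fit()
    pvals = pd.Series(fit.pvalues[1:], index=X.columns, name="p_value")
    survivors = [c for c in X.columns if pvals[c] <= alpha]
    return survivors, pvals


def screen_features(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    vif_threshold: float = DEFAULT_VIF_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, VifReport, pd.Series]:
    """Full screen: VIF pruning first, then the OLS significance screen."""
    pruned, report = iterative_vif_prune(X, vif_threshold)
    survivors, pvals = ols_screen(pruned, y, alpha)
    return pruned[survivors], report, pvals
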