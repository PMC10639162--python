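"""Geographically weighted LASSO (GWLASSO) for district-level obesity rates.

The model lets regression coefficients vary smoothly over space: for focal
district i with planar centroid (u_i, v_i),

    y_i = beta_0(u_i, v_i) + sum_k x_ik * beta_k(u_i, v_i) + eps_i,

and the local coefficients solve one weighted-lasso subproblem per district,

    argmin_{beta_0, beta}  sum_j w_ij (y_j - beta_0 - x_j . beta)^2
                           + lambda_i * sum_k |beta_k|,

with kernel weights w_ij decaying in the Euclidean inter-centroid distance
and the intercept unpenalized.  Each subproblem is solved by cyclic
coordinate descent with soft-thresholding on weighted-standardized
covariates; correctness is certified by the weighted-lasso KKT conditions.
The per-district penalty lambda_i is selected on a grid inside [0.001, 0.03]
by leave-one-out weighted prediction error.

Coefficients are reported on the standardized scale (weighted mean 0 /
variance 1 covariates), so magnitudes are comparable across factors; the
raw-scale back-transform is emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_LAMBDA_RANGE = (0.001, 0.03)
DEFAULT_GRID_SIZE = 30

#: coordinate-descent stopping rule: max coefficient change below this, or
#: the sweep cap is hit
CD_TOL = 1e-10
CD_MAX_SWEEPS = 10_000


def default_lambda_grid(
    lo: float = DEFAULT_LAMBDA_RANGE[0],
    hi: float = DEFAULT_LAMBDA_RANGE[1],
    num: int = DEFAULT_GRID_SIZE,
) -> np.ndarray:
    """Log-spaced penalty grid inside the configured range."""
    return np.geomspace(lo, hi, num)


@dataclass
class KernelSpec:
    """Spatial weighting scheme: kernel family and bandwidth.

    bandwidth shares the length unit of the centroid coordinates.  The
    string ``"median"`` resolves to the median nonzero pairwise distance at
    fit time — a scale-free default that suits ~25 districts.
    """

    family: str = "gaussian"
    bandwidth: float | str = "median"

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "bisquare", "uniform"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "median":
                raise ValueError("bandwidth must be a positive number or 'median'")
        elif self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


def pairwise_distances(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Euclidean inter-district distance matrix d_ij (symmetric, zero diagonal)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    du = u[:, None] - u[None, :]
    dv = v[:, None] - v[None, :]
    return np.sqrt(du * du + dv * dv)


def resolve_bandwidth(d: np.ndarray, spec: KernelSpec) -> float:
    if spec.bandwidth == "median":
        off = d[np.triu_indices_from(d, k=1)]
        off = off[off > 0]
        if off.size == 0:
            raise ValueError("all districts share one location; cannot infer a bandwidth")
        return float(np.median(off))
    return float(spec.bandwidth)


def kernel_weights(d: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Weight matrix in [0, 1] from the distance matrix.

    gaussian: exp(-d^2 / (2 h^2)); bisquare: (1 - (d/h)^2)^2 for d < h else 0;
    uniform: 1 everywhere (reduces GWLASSO to one global lasso).
    """
    if spec.family == "uniform":
        return np.ones_like(d)
    h = resolve_bandwidth(d, spec)
    if spec.family == "gaussian":
        return np.exp(-(d * d) / (2.0 * h * h))
    w = 1.0 - (d / h) ** 2
    w[w < 0] = 0.0
    return w * w


def _standardize(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted-centre y and weighted-standardize X; returns transform info."""
    W = w.sum()
    if W <= 0:
        raise ValueError("weights must include at least one positive entry")
    omega = w / W
    mx = omega @ X
    Xc = X - mx
    sx = np.sqrt(omega @ (Xc * Xc))
    if np.any(sx == 0):
        bad = list(np.flatnonzero(sx == 0))
        raise ValueError(f"covariate column(s) {bad} constant under these weights")
    my = float(omega @ y)
    return Xc / sx, y - my, mx, sx, my, W


def _cd_solve(Xs: np.ndarray, ys: np.ndarray, w: np.ndarray, lam: float,
              beta0: np.ndarray | None = None,
              objective_trace: list | None = None) -> tuple[np.ndarray, int]:
    """Cyclic coordinate descent for min sum w (ys - Xs b)^2 + lam sum|b|."""
    n, p = Xs.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    wX = w[:, None] * Xs
    a = 2.0 * np.einsum("ij,ij->j", wX, Xs)  # 2 * sum_i w_i x_ik^2
    r = ys - Xs @ beta
    for sweep in range(CD_MAX_SWEEPS):
        delta = 0.0
        if objective_trace is not None:
            objective_trace.append(float(w @ (r * r) + lam * np.abs(beta).sum()))
        for k in range(p):
            bk = beta[k]
            c = 2.0 * (wX[:, k] @ r) + a[k] * bk
            if c > lam:
                bnew = (c - lam) / a[k]
            elif c < -lam:
                bnew = (c + lam) / a[k]
            else:
                bnew = 0.0
            if bnew != bk:
                r += Xs[:, k] * (bk - bnew)
                beta[k] = bnew
                delta = max(delta, abs(bnew - bk))
        if delta < CD_TOL:
            break
    return beta, sweep + 1


@dataclass
class WeightedLassoResult:
    """Solution of one focal-location weighted-lasso subproblem."""

    intercept: float
    coef: np.ndarray        # raw (original covariate) scale
    coef_std: np.ndarray    # standardized scale (unit weighted variance)
    lam: float
    n_sweeps: int

    def __iter__(self):
        yield self.intercept
        yield self.coef

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coef


def fit_weighted_lasso(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, lam: float,
    objective_trace: list | None = None,
) -> WeightedLassoResult:
    """Solve  min_{b0,b}  sum_i w_i (y_i - b0 - x_i.b)^2 + lam sum_k |b_k|.

    The intercept is unpenalized (handled by weighted centring); covariates
    are weighted-standardized internally and the solution is returned on
    both scales.  At ``lam = 0`` this is weighted least squares; at
    ``lam >= lambda_max`` all slope coefficients are exactly zero and the
    intercept is the weighted mean of y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    Xs, ys, mx, sx, my, W = _standardize(X, y, w)
    beta_std, sweeps = _cd_solve(Xs, ys, w, lam, objective_trace=objective_trace)
    coef = beta_std / sx
    intercept = my - float(mx @ coef)
    return WeightedLassoResult(intercept, coef, beta_std, lam, sweeps)


def lambda_max(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Smallest penalty shrinking every slope to zero: 2·max_k |sum w x̃_k ỹ|."""
    Xs, ys, *_ = _standardize(np.asarray(X, float), np.asarray(y, float),
                              np.asarray(w, float))
    return float(2.0 * np.max(np.abs((w * ys) @ Xs)))


def kkt_residual(X: np.ndarray, y: np.ndarray, w: np.ndarray,
                 res: WeightedLassoResult) -> float:
    """Max violation of the weighted-lasso KKT conditions (standardized scale).

    With g_k = 2 sum_i w_i x̃_ik r_i on the standardized data: |g_k| <= lam
    for zero coefficients, and g_k = lam * sign(beta_k) for nonzero ones.
    """
    Xs, ys, *_ = _standardize(np.asarray(X, float), np.asarray(y, float),
                              np.asarray(w, float))
    r = ys - Xs @ res.coef_std
    g = 2.0 * (w * r) @ Xs
    viol = np.where(
        res.coef_std == 0.0,
        np.maximum(np.abs(g) - res.lam, 0.0),
        np.abs(g - res.lam * np.sign(res.coef_std)),
    )
    return float(viol.max())


def select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    grid: Sequence[float] | np.ndarray | None = None,
    lambda_range: tuple[float, float] = DEFAULT_LAMBDA_RANGE,
) -> float:
    """Penalty minimizing leave-one-out weighted squared prediction error.

    For each held-out district j (with positive weight), the model is refit
    on the remaining districts and y_j is predicted; errors are combined as
    sum_j w_j (y_j - yhat_(-j))^2.  Ties are broken toward the larger
    (more parsimonious) penalty.
    """
    if grid is None:
        grid = default_lambda_grid(*lambda_range)
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("lambda grid must be nonempty")
    lo, hi = lambda_range
    if np.any(grid < lo - 1e-12) or np.any(grid > hi + 1e-12):
        raise ValueError(f"grid values must lie within {lambda_range}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    order = np.argsort(grid)[::-1]  # descending: warm starts + tie -> larger lam
    held = np.flatnonzero(w > 0)
    cv = np.zeros(grid.size)
    for j in held:
        mask = np.ones(len(y), dtype=bool)
        mask[j] = False
        Xj, yj, wj = X[mask], y[mask], w[mask]
        if not np.any(wj > 0):
            continue
        Xs, ys, mx, sx, my, _ = _standardize(Xj, yj, wj)
        warm = None
        for pos in order:
            beta_std, _ = _cd_solve(Xs, ys, wj, grid[pos], beta0=warm)
            warm = beta_std
            coef = beta_std / sx
            pred = my - mx @ coef + X[j] @ coef
            cv[pos] += w[j] * (y[j] - pred) ** 2
    best = order[0]
    for pos in order[1:]:  # strict improvement required => ties keep larger lam
        if cv[pos] < cv[best]:
            best = pos
    return float(grid[best])


@dataclass
class GwlassoFit:
    """Per-district local lasso solutions and everything needed to audit them."""

    district_ids: list[str]
    factor_names: list[str]
    intercepts: np.ndarray          # raw scale, per district
    coef_std: pd.DataFrame          # districts x factors, standardized scale
    coef_raw: pd.DataFrame          # districts x factors, raw scale
    lambdas: np.ndarray
    weights: np.ndarray             # n x n kernel weights actually used
    residuals: np.ndarray           # y_i - fitted value at district i
    kernel: KernelSpec = field(default_factory=KernelSpec)
    bandwidth: float | None = None

    def coefficients_table(self) -> pd.DataFrame:
        """Long-format (district_id, factor, beta_std, beta_raw, lambda)."""
        rows = []
        for i, d in enumerate(self.district_ids):
            for f in self.factor_names:
                rows.append({
                    "district_id": d, "factor": f,
                    "beta_std": self.coef_std.loc[d, f],
                    "beta_raw": self.coef_raw.loc[d, f],
                    "lambda": self.lambdas[i],
                })
        return pd.DataFrame(rows)


def fit_gwlasso(
    panel: pd.DataFrame,
    factor_names: Sequence[str],
    kernel: KernelSpec | None = None,
    grid: Sequence[float] | np.ndarray | None = None,
    lambda_range: tuple[float, float] = DEFAULT_LAMBDA_RANGE,
    y_col: str = "obesity_rate",
) -> GwlassoFit:
    """Fit one weighted-lasso subproblem per district.

    ``panel`` needs columns district_id, u, v, ``y_col`` and the factors.
    For each district i: kernel weights from row i of the weight matrix, a
    per-district penalty from :func:`select_lambda`, then
    :func:`fit_weighted_lasso`; the residual is y_i minus the local fitted
    value at i.
    """
    if len(panel) < 3:
        raise ValueError("need at least 3 districts")
    factor_names = list(factor_names)
    if not factor_names:
        raise ValueError("need at least one factor")
    kernel = kernel or KernelSpec()
    X = panel[factor_names].to_numpy(dtype=float)
    y = panel[y_col].to_numpy(dtype=float)
    d = pairwise_distances(panel["u"].to_numpy(), panel["v"].to_numpy())
    Wmat = kernel_weights(d, kernel)
    bw = None if kernel.family == "uniform" else resolve_bandwidth(d, kernel)

    ids = panel["district_id"].astype(str).tolist()
    n, p = X.shape
    intercepts = np.zeros(n)
    coef_std = np.zeros((n, p))
    coef_raw = np.zeros((n, p))
    lambdas = np.zeros(n)
    residuals = np.zeros(n)
    for i in range(n):
        w = Wmat[i]
        lam = select_lambda(X, y, w, grid=grid, lambda_range=lambda_range)
        res = fit_weighted_lasso(X, y, w, lam)
        intercepts[i] = res.intercept
        coef_std[i] = res.coef_std
        coef_raw[i] = res.coef
        lambdas[i] = lam
        residuals[i] = y[i] - res.predict(X[i : i + 1])[0]
    return GwlassoFit(
        district_ids=ids,
        factor_names=factor_names,
        intercepts=intercepts,
        coef_std=pd.DataFrame(coef_std, index=ids, columns=factor_names),
        coef_raw=pd.DataFrame(coef_raw, index=ids, columns=factor_names),
        lambdas=lambdas,
        weights=Wmat,
        residuals=residuals,
        kernel=kernel,
        bandwidth=bw,
    )


def summarize_coefficients(fit: GwlassoFit, scale: str = "std") -> pd.DataFrame:
    """Min/mean/max over districts per factor, plus POS and NEG counts.

    POS counts districts with a strictly positive coefficient, NEG strictly
    negative; exact zeros (the lasso produces them) belong to neither, so
    POS + NEG + zeros = number of districts.
    """
    table = fit.coef_std if scale == "std" else fit.coef_raw
    rows = []
    for f in fit.factor_names:
        b = table[f].to_numpy()
        rows.append({
            "factor": f,
            "min": float(b.min()),
            "mean": float(b.mean()),
            "max": float(b.max()),
            "pos": int((b > 0).sum()),
            "neg": int((b < 0).sum()),
        })
    return pd.DataFrame(rows)


def export_coefficients_geojson(fit: GwlassoFit, panel: pd.DataFrame, path) -> None:
    """Choropleth-ready GeoJSON: one Point per district with its coefficients."""
    import json
    from pathlib import Path

    lookup = panel.set_index(panel["district_id"].astype(str))
    features = []
    for i, d in enumerate(fit.district_ids):
        props = {
            "district_id": d,
            "lambda": float(fit.lambdas[i]),
            "intercept": float(fit.intercepts[i]),
            "residual": float(fit.residuals[i]),
        }
        for f in fit.factor_names:
            props[f"beta_{f}"] = float(fit.coef_std.loc[d, f])
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [float(lookup.loc[d, "u"]), float(lookup.loc[d, "v"])]},
            "properties": props,
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features},
                                     indent=2))
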