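"""Exact path-dependent TreeSHAP for scikit-learn decision trees and forests.

Computes, for every record and feature, the Shapley value of that feature
for the tree-ensemble prediction, using the polynomial-time tree algorithm:
a single depth-first pass per tree maintains the set of features split on
along the current path together with the proportion of all feature-subset
permutations that flow down the path ("path weights"), extending the path at
each split and unwinding it at leaves to read off each feature's weighted
contribution.  Conditional expectations for features outside a subset follow
the tree's own cover (training-sample) proportions — the path-dependent
formulation, which needs no background dataset.

The attribution unit is the model's output margin: class-1 probability for
classifiers, the raw prediction for regressors.  For every record

    base_value + sum_k phi[k] == model prediction        (local accuracy)

holds to floating-point accuracy; tests enforce 1e-6 and cross-check the
values against a brute-force Shapley enumeration on small trees.

The inner recursion is numba-jitted; a pure-Python fallback keeps the module
importable (and correct, just slower) if JIT compilation is unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor


def _recurse(cl, cr, feat, thr, val, cover, x, phi,
             node, unique_depth, parent_offset, pzf, pof, pfi,
             fi, zf, of, pw):
    """One DFS step; path arrays (fi, zf, of, pw) are flat buffers of segments."""
    # copy the parent's path segment into this call's own segment
    offset = parent_offset + unique_depth + 1
    for i in range(unique_depth + 1):
        fi[offset + i] = fi[parent_offset + i]
        zf[offset + i] = zf[parent_offset + i]
        of[offset + i] = of[parent_offset + i]
        pw[offset + i] = pw[parent_offset + i]

    # extend the path with the incoming split
    fi[offset + unique_depth] = pfi
    zf[offset + unique_depth] = pzf
    of[offset + unique_depth] = pof
    pw[offset + unique_depth] = 1.0 if unique_depth == 0 else 0.0
    for i in range(unique_depth - 1, -1, -1):
        pw[offset + i + 1] += pof * pw[offset + i] * (i + 1.0) / (unique_depth + 1.0)
        pw[offset + i] = pzf * pw[offset + i] * (unique_depth - i) / (unique_depth + 1.0)

    if cl[node] < 0:  # leaf
        for path_index in range(1, unique_depth + 1):
            # sum of permutation weights with element path_index unwound
            one_frac = of[offset + path_index]
            zero_frac = zf[offset + path_index]
            next_one = pw[offset + unique_depth]
            total = 0.0
            for i in range(unique_depth - 1, -1, -1):
                if one_frac != 0.0:
                    tmp = next_one * (unique_depth + 1.0) / ((i + 1.0) * one_frac)
                    total += tmp
                    next_one = pw[offset + i] - tmp * zero_frac * (unique_depth - i) / (
                        unique_depth + 1.0)
                else:
                    total += pw[offset + i] / (zero_frac * (unique_depth - i) / (
                        unique_depth + 1.0))
            phi[fi[offset + path_index]] += total * (one_frac - zero_frac) * val[node]
        return

    split = feat[node]
    if x[split] <= thr[node]:
        hot, cold = cl[node], cr[node]
    else:
        hot, cold = cr[node], cl[node]
    hot_zero = cover[hot] / cover[node]
    cold_zero = cover[cold] / cover[node]

    # if this feature was already split on along the path, unwind its element
    inc_zero = 1.0
    inc_one = 1.0
    depth_here = unique_depth
    found = -1
    for i in range(1, unique_depth + 1):
        if fi[offset + i] == split:
            found = i
            break
    if found >= 0:
        inc_zero = zf[offset + found]
        inc_one = of[offset + found]
        # unwind pweights
        one_frac = inc_one
        zero_frac = inc_zero
        next_one = pw[offset + unique_depth]
        for i in range(unique_depth - 1, -1, -1):
            if one_frac != 0.0:
                tmp = pw[offset + i]
                pw[offset + i] = next_one * (unique_depth + 1.0) / ((i + 1.0) * one_frac)
                next_one = tmp - pw[offset + i] * zero_frac * (unique_depth - i) / (
                    unique_depth + 1.0)
            else:
                pw[offset + i] = pw[offset + i] * (unique_depth + 1.0) / (
                    zero_frac * (unique_depth - i))
        for i in range(found, unique_depth):
            fi[offset + i] = fi[offset + i + 1]
            zf[offset + i] = zf[offset + i + 1]
            of[offset + i] = of[offset + i + 1]
        depth_here = unique_depth - 1

    _recurse(cl, cr, feat, thr, val, cover, x, phi,
             hot, depth_here + 1, offset, hot_zero * inc_zero, inc_one, split,
             fi, zf, of, pw)
    _recurse(cl, cr, feat, thr, val, cover, x, phi,
             cold, depth_here + 1, offset, cold_zero * inc_zero, 0.0, split,
             fi, zf, of, pw)


_recurse_py = _recurse
try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _recurse = njit(cache=True)(_recurse)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    HAVE_NUMBA = False


@dataclass
class TreeArrays:
    """Flat arrays describing one fitted decision tree."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray       # per-node output margin (class-1 prob for classifiers)
    cover: np.ndarray       # weighted training-sample count per node
    max_depth: int

    @property
    def base_value(self) -> float:
        """Cover-weighted mean leaf value = expected model output."""
        leaves = self.children_left < 0
        return float(np.sum(self.value[leaves] * self.cover[leaves]) / self.cover[0])


def _node_values(tree, is_classifier: bool) -> np.ndarray:
    raw = tree.tree_.value  # (n_nodes, 1, n_outputs)
    if is_classifier:
        counts = raw[:, 0, :]
        return counts[:, 1] / counts.sum(axis=1)
    return raw[:, 0, 0].copy()


def tree_arrays(tree, is_classifier: bool | None = None) -> TreeArrays:
    """Extract :class:`TreeArrays` from a fitted sklearn decision tree."""
    if is_classifier is None:
        is_classifier = isinstance(tree, DecisionTreeClassifier)
    t = tree.tree_
    return TreeArrays(
        children_left=t.children_left.astype(np.int64),
        children_right=t.children_right.astype(np.int64),
        feature=t.feature.astype(np.int64),
        threshold=t.threshold.astype(np.float64),
        value=np.ascontiguousarray(_node_values(tree, is_classifier), dtype=np.float64),
        cover=t.weighted_n_node_samples.astype(np.float64),
        max_depth=int(t.max_depth),
    )


def single_tree_shap(arrays: TreeArrays, X: np.ndarray) -> np.ndarray:
    """Shapley attributions (n_records, n_features) for one tree."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    n, p = X.shape
    phi = np.zeros((n, p))
    d = arrays.max_depth + 2
    size = (d + 1) * (d + 2) // 2 + d + 2
    fi = np.empty(size, dtype=np.int64)
    zf = np.empty(size, dtype=np.float64)
    of = np.empty(size, dtype=np.float64)
    pw = np.empty(size, dtype=np.float64)
    global _recurse
    for i in range(n):
        fi[0] = -1
        zf[0] = 1.0
        of[0] = 1.0
        pw[0] = 1.0
        try:
            _recurse(arrays.children_left, arrays.children_right, arrays.feature,
                     arrays.threshold, arrays.value, arrays.cover, X[i], phi[i],
                     0, 0, 0, 1.0, 1.0, -1, fi, zf, of, pw)
        except Exception:
            # JIT compilation failed at first use: drop to the Python path
            _recurse = _recurse_py
            phi[i] = 0.0
            _recurse(arrays.children_left, arrays.children_right, arrays.feature,
                     arrays.threshold, arrays.value, arrays.cover, X[i], phi[i],
                     0, 0, 0, 1.0, 1.0, -1, fi, zf, of, pw)
    return phi


def _ensemble_trees(model) -> tuple[list[TreeArrays], bool]:
    if isinstance(model, (RandomForestClassifier, RandomForestRegressor)):
        is_cls = isinstance(model, RandomForestClassifier)
        return [tree_arrays(est, is_cls) for est in model.estimators_], is_cls
    if isinstance(model, (DecisionTreeClassifier, DecisionTreeRegressor)):
        return [tree_arrays(model)], isinstance(model, DecisionTreeClassifier)
    raise TypeError(
        f"unsupported model type {type(model).__name__}: expected a sklearn "
        "decision tree or random forest")


def shap_values(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-record, per-feature Shapley attributions for a tree model.

    Returns ``(phi, base_value)`` on the model's probability margin (class 1)
    for classifiers, raw output for regressors.  Forest attributions are the
    mean of per-tree attributions, matching the forest's averaged prediction.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    n_expected = getattr(model, "n_features_in_", X.shape[1])
    if X.shape[1] != n_expected:
        raise ValueError(
            f"feature mismatch: model was fitted on {n_expected} features, "
            f"X has {X.shape[1]}")
    trees, _ = _ensemble_trees(model)
    phi = np.zeros(X.shape)
    base = 0.0
    for arr in trees:
        phi += single_tree_shap(arr, X)
        base += arr.base_value
    k = len(trees)
    return phi / k, base / k


def model_margin(model, X: np.ndarray) -> np.ndarray:
    """The output margin the attributions explain."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.predict(X)
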