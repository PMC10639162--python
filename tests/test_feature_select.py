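import numpy as np
import pandas as pd
import pytest

from obesifact.feature_select import (compute_vif, iterative_vif_prune, ols_screen,
                                      screen_features)


def lstsq_vif_oracle(X: pd.DataFrame) -> dict:
    """Independent VIF: explicit normal-equation least squares per column."""
    out = {}
    arr = X.to_numpy(dtype=float)
    for j, name in enumerate(X.columns):
        yj = arr[:, j]
        A = np.column_stack([np.ones(len(arr)), np.delete(arr, j, axis=1)])
        beta, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ beta
        ss_res = resid @ resid
        ss_tot = ((yj - yj.mean()) ** 2).sum()
        out[name] = 1.0 / (1.0 - (1.0 - ss_res / ss_tot))
    return out


def orthogonal_design(n=64):
    # Exactly orthogonal, zero-mean columns from a +-1 pattern
    a = np.tile([1.0, -1.0], n // 2)
    b = np.repeat([1.0, -1.0], n // 2)
    c = a * b
    return pd.DataFrame({"a": a, "b": b, "c": c})


class TestComputeVif:
    def test_orthogonal_columns_have_unit_vif(self):
        vifs = compute_vif(orthogonal_design())
        assert all(v == pytest.approx(1.0, abs=1e-8) for v in vifs.values())

    def test_exact_duplicate_is_infinite(self, rng):
        x = rng.normal(size=100)
        X = pd.DataFrame({"x": x, "x_dup": x.copy(), "z": rng.normal(size=100)})
        vifs = compute_vif(X)
        assert np.isinf(vifs["x"]) and np.isinf(vifs["x_dup"])
        assert np.isfinite(vifs["z"])

    def test_matches_explicit_least_squares_oracle(self, rng):
        # correlated 6-feature design, compared to the regress-each-on-rest oracle
        n, p = 200, 6
        base = rng.normal(size=(n, p))
        base[:, 1] += 0.7 * base[:, 0]
        base[:, 2] += 0.5 * base[:, 0] - 0.3 * base[:, 1]
        X = pd.DataFrame(base, columns=[f"f{i}" for i in range(p)])
        vifs = compute_vif(X)
        oracle = lstsq_vif_oracle(X)
        for name in X.columns:
            assert vifs[name] == pytest.approx(oracle[name], abs=1e-8)

    def test_constant_column_named_in_error(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=50), "flat": np.ones(50)})
        with pytest.raises(ValueError, match="flat"):
            compute_vif(X)

    def test_requires_more_rows_than_features(self, rng):
        X = pd.DataFrame(rng.normal(size=(3, 4)))
        with pytest.raises(ValueError):
            compute_vif(X)


class TestIterativeVifPrune:
    def test_duplicate_pair_loses_exactly_one(self, rng):
        x = rng.normal(size=120)
        X = pd.DataFrame({"x": x, "x_dup": x.copy(), "z": rng.normal(size=120)})
        survivors, report = iterative_vif_prune(X, threshold=30)
        assert len(report.removal_order) == 1
        assert set(report.removal_order) <= {"x", "x_dup"}
        assert all(np.isfinite(v) and v <= 30 for v in compute_vif(survivors).values())

    def test_orthogonal_design_untouched(self):
        X = orthogonal_design()
        survivors, report = iterative_vif_prune(X, threshold=30)
        assert list(survivors.columns) == list(X.columns)
        assert report.removal_order == []

    def test_collinear_triplet_pruned_until_threshold_met(self, rng):
        n = 300
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        X = pd.DataFrame({
            "a": a, "b": b,
            "combo": a + b + rng.normal(scale=0.01, size=n),  # near-collinear triplet
            "indep": rng.normal(size=n),
        })
        survivors, report = iterative_vif_prune(X, threshold=30)
        assert len(report.removal_order) <= X.shape[1]
        assert max(compute_vif(survivors).values()) <= 30

    def test_removed_feature_had_maximal_vif(self, rng):
        x = rng.normal(size=200)
        X = pd.DataFrame({
            "a": x + rng.normal(scale=0.05, size=200),
            "b": x,
            "c": rng.normal(size=200),
        })
        _, report = iterative_vif_prune(X, threshold=30)
        if report.removal_order:
            first = report.removal_order[0]
            vifs = compute_vif(X)
            finite_max = max(vifs.values())
            assert vifs[first] == finite_max or np.isinf(vifs[first])


class TestOlsScreen:
    def test_perfect_signal_always_survives(self, rng):
        n = 500
        X = pd.DataFrame(rng.normal(size=(n, 5)), columns=list("abcde"))
        y = X["a"].to_numpy()
        survivors, pvals = ols_screen(X, y)
        assert "a" in survivors
        assert pvals["a"] < 1e-10

    def test_alpha_one_keeps_everything(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("abcd"))
        y = rng.normal(size=100)
        survivors, _ = ols_screen(X, y, alpha=1.0)
        assert survivors == list("abcd")

    def test_null_features_survive_at_roughly_alpha(self):
        # light version of the type-I simulation; the full 1,000-rep check is
        # in the acceptance suite
        hits = 0
        reps = 200
        rng = np.random.default_rng(7)
        for _ in range(reps):
            X = pd.DataFrame(rng.normal(size=(120, 3)), columns=list("abc"))
            y = rng.normal(size=120)
            survivors, _ = ols_screen(X, y, alpha=0.05)
            hits += len(survivors)
        rate = hits / (reps * 3)
        assert 0.02 < rate < 0.09

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.normal(size=60)
        X = pd.DataFrame({"x": x, "x_dup": x.copy()})
        with pytest.raises(ValueError, match="rank deficient"):
            ols_screen(X, rng.normal(size=60))


def test_full_screen_drops_duplicate_and_keeps_signal(individual_frame, truth):
    X = individual_frame[truth.individual_feature_names]
    y = individual_frame["obese"].astype(int).to_numpy()
    selected, report, pvals = screen_features(X, y)
    dup, src = next(iter(truth.duplicate_features.items()))
    # exactly one of the duplicated pair was removed by VIF
    assert len({dup, src} & set(report.removal_order)) == 1
    dominant = max(truth.individual_effects, key=truth.individual_effects.get)
    assert dominant in selected.columns or dominant in report.removal_order
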