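import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.linear_model import Lasso

from obesifact.gwlasso import (KernelSpec, _standardize, default_lambda_grid,
                               fit_gwlasso, fit_weighted_lasso, kernel_weights,
                               kkt_residual, lambda_max, pairwise_distances,
                               select_lambda, summarize_coefficients)
from obesifact.synthetic import (CoefficientSurface, default_truth,
                                 generate_district_panel, generate_districts)


class TestDistancesAndKernels:
    def test_three_four_five(self):
        d = pairwise_distances(np.array([0.0, 3.0]), np.array([0.0, 4.0]))
        assert d[0, 1] == pytest.approx(5.0)
        assert d[0, 0] == d[1, 1] == 0.0

    def test_identical_coordinates(self):
        d = pairwise_distances(np.array([1.0, 1.0]), np.array([2.0, 2.0]))
        assert np.all(d == 0.0)

    def test_symmetry(self, rng):
        u, v = rng.normal(size=10), rng.normal(size=10)
        d = pairwise_distances(u, v)
        np.testing.assert_array_equal(d, d.T)

    @pytest.mark.parametrize("family, d, h, expected", [
        ("gaussian", 0.0, 2.0, 1.0),
        ("bisquare", 2.0, 2.0, 0.0),        # boundary: weight vanishes at d = h
        ("bisquare", 1.0, 2.0, (1 - 0.25) ** 2),
        ("gaussian", 2.0, 2.0, np.exp(-0.5)),
    ])
    def test_kernel_values(self, family, d, h, expected):
        w = kernel_weights(np.array([[d]]), KernelSpec(family, h))
        assert w[0, 0] == pytest.approx(expected)

    def test_uniform_kernel_is_all_ones(self, rng):
        d = pairwise_distances(rng.normal(size=6), rng.normal(size=6))
        assert np.all(kernel_weights(d, KernelSpec("uniform")) == 1.0)

    def test_self_weight_is_maximal_for_decreasing_kernels(self, rng):
        d = pairwise_distances(rng.uniform(0, 10, 8), rng.uniform(0, 10, 8))
        for family in ("gaussian", "bisquare"):
            w = kernel_weights(d, KernelSpec(family, "median"))
            assert np.all(np.diag(w) >= w.max(axis=1) - 1e-15)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec("triangular", 1.0)


def random_instance(rng, n=30, p=5):
    X = rng.normal(size=(n, p))
    y = rng.normal(size=n)
    w = rng.uniform(0.1, 1.0, size=n)
    return X, y, w


class TestWeightedLasso:
    def test_zero_penalty_matches_weighted_least_squares(self, rng):
        X, y, w = random_instance(rng)
        res = fit_weighted_lasso(X, y, w, 0.0)
        A = np.column_stack([np.ones(len(y)), X])
        closed = np.linalg.solve(A.T @ (w[:, None] * A), A.T @ (w * y))
        np.testing.assert_allclose([res.intercept, *res.coef], closed, atol=1e-6)

    def test_full_shrinkage_at_lambda_max(self, rng):
        X, y, w = random_instance(rng)
        lam = lambda_max(X, y, w)
        res = fit_weighted_lasso(X, y, w, lam * (1 + 1e-9))
        assert np.all(res.coef == 0.0)
        assert res.intercept == pytest.approx((w @ y) / w.sum())
        # just below lambda_max, at least one coefficient activates
        res2 = fit_weighted_lasso(X, y, w, lam * 0.99)
        assert np.any(res2.coef != 0.0)

    def test_univariate_soft_threshold_against_grid_oracle(self, rng):
        n = 40
        x = rng.normal(size=n)
        y = 0.7 * x + rng.normal(size=n) * 0.5
        w = rng.uniform(0.2, 1.0, size=n)
        lam = 0.8
        res = fit_weighted_lasso(x[:, None], y, w, lam)
        # dense grid search over the standardized 1-D objective
        Xs, ys, *_ = _standardize(x[:, None], y, w)
        grid = np.linspace(-3, 3, 200_001)
        obj = (w[:, None] * (ys[:, None] - Xs @ grid[None, :]) ** 2).sum(axis=0) \
            + lam * np.abs(grid)
        assert res.coef_std[0] == pytest.approx(grid[np.argmin(obj)], abs=1e-4)
        # closed form: soft-threshold of the weighted correlation
        W = w.sum()
        rho = (w * Xs[:, 0] * ys).sum() / W
        closed = np.sign(rho) * max(abs(rho) - lam / (2 * W), 0.0)
        assert res.coef_std[0] == pytest.approx(closed, abs=1e-8)

    def test_kkt_certificate_on_random_instances(self, rng):
        for _ in range(20):
            X, y, w = random_instance(rng)
            lam = rng.uniform(0.0, 0.05)
            res = fit_weighted_lasso(X, y, w, lam)
            assert kkt_residual(X, y, w, res) <= 1e-6

    def test_objective_monotone_over_sweeps(self, rng):
        X, y, w = random_instance(rng, n=50, p=8)
        trace: list = []
        fit_weighted_lasso(X, y, w, 0.5, objective_trace=trace)
        assert len(trace) >= 2
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_matches_sklearn_lasso_on_prestandardized_data(self, rng):
        # independent solver cross-check: on covariates that are already
        # weighted-standardized the two objectives coincide with
        # alpha = lam / (2 sum w)
        n, p = 60, 4
        X0 = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        w = rng.uniform(0.3, 1.0, size=n)
        Xs, ys, *_ = _standardize(X0, y, w)
        lam = 0.9
        ours = fit_weighted_lasso(Xs, y, w, lam)
        ref = Lasso(alpha=lam / (2 * w.sum()), fit_intercept=True, tol=1e-12,
                    max_iter=100_000)
        ref.fit(Xs, y, sample_weight=w)
        np.testing.assert_allclose(ours.coef_std, ref.coef_, atol=1e-6)

    def test_invalid_inputs(self, rng):
        X, y, w = random_instance(rng)
        with pytest.raises(ValueError):
            fit_weighted_lasso(X, y, w, -0.1)
        with pytest.raises(ValueError):
            fit_weighted_lasso(X, y, np.zeros_like(w), 0.01)

    def test_penalty_path_sparsity_nondecreasing_in_lambda(self, rng):
        X, y, w = random_instance(rng, n=25, p=6)
        # rescale y so the paper's grid actually bites on this subproblem
        y = y * 0.01
        nnz = []
        for lam in default_lambda_grid():
            res = fit_weighted_lasso(X, y, w, lam)
            nnz.append(int(np.sum(res.coef_std != 0)))
        assert all(b <= a for a, b in zip(nnz, nnz[1:]))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), lam=st.floats(0.0, 2.0))
def test_kkt_holds_for_arbitrary_instances(seed, lam):
    rng = np.random.default_rng(seed)
    X, y, w = random_instance(rng, n=20, p=4)
    res = fit_weighted_lasso(X, y, w, lam)
    assert kkt_residual(X, y, w, res) <= 1e-6


class TestSelectLambda:
    def test_single_element_grid(self, rng):
        X, y, w = random_instance(rng)
        assert select_lambda(X, y, w, grid=[0.01]) == 0.01

    def test_noiseless_data_prefers_smallest_penalty(self, rng):
        n, p = 25, 3
        X = rng.normal(size=(n, p))
        beta = np.array([0.5, -0.3, 0.2])
        y = 0.3 + X @ beta  # exactly linear, no noise
        w = np.ones(n)
        assert select_lambda(X, y, w, grid=[0.001, 0.03]) == 0.001

    def test_selection_is_a_grid_member(self, rng):
        X, y, w = random_instance(rng)
        grid = default_lambda_grid(num=7)
        assert select_lambda(X, y, w, grid=grid) in grid

    def test_out_of_range_grid_rejected(self, rng):
        X, y, w = random_instance(rng)
        with pytest.raises(ValueError):
            select_lambda(X, y, w, grid=[0.1])


@pytest.fixture(scope="module")
def small_panel():
    truth = default_truth(seed=17)
    geoms = generate_districts(25, seed=17)
    panel, coefs = generate_district_panel(geoms, truth)
    return truth, panel, coefs


class TestFitGwlasso:
    def test_uniform_kernel_reduces_to_global_lasso(self, small_panel):
        truth, panel, _ = small_panel
        factors = truth.district_factor_names
        fit = fit_gwlasso(panel, factors, KernelSpec("uniform"))
        w = np.ones(len(panel))
        X = panel[factors].to_numpy()
        y = panel["obesity_rate"].to_numpy()
        lam = select_lambda(X, y, w)
        glob = fit_weighted_lasso(X, y, w, lam)
        assert np.abs(fit.coef_std.to_numpy() - glob.coef_std[None, :]).max() <= 1e-8
        assert np.abs(fit.intercepts - glob.intercept).max() <= 1e-8

    def test_constant_surfaces_recovered_without_noise(self):
        truth = default_truth(seed=23, noise_sd=0.0)
        truth.intercept_surface = CoefficientSurface("intercept", lambda u, v: 0.31)
        const = {"f1": 0.4, "f2": -0.3}
        truth.district_surfaces = [
            CoefficientSurface(k, (lambda val: lambda u, v: val)(v0))
            for k, v0 in const.items()
        ]
        geoms = generate_districts(25, seed=23)
        panel, coefs = generate_district_panel(geoms, truth)
        fit = fit_gwlasso(panel, list(const), KernelSpec("gaussian", "median"),
                          grid=[0.001])
        for k, v0 in const.items():
            assert np.abs(fit.coef_raw[k].to_numpy() - v0).max() <= 0.02

    def test_district_order_equivariance(self, small_panel):
        truth, panel, _ = small_panel
        factors = truth.district_factor_names
        fit = fit_gwlasso(panel, factors, KernelSpec("gaussian", 3.0))
        perm = np.random.default_rng(0).permutation(len(panel))
        fit_p = fit_gwlasso(panel.iloc[perm].reset_index(drop=True), factors,
                            KernelSpec("gaussian", 3.0))
        reordered = fit_p.coef_std.loc[fit.coef_std.index]
        np.testing.assert_allclose(fit.coef_std.to_numpy(), reordered.to_numpy(),
                                   atol=1e-10)

    def test_selected_lambdas_stay_in_range(self, small_panel):
        truth, panel, _ = small_panel
        fit = fit_gwlasso(panel, truth.district_factor_names,
                          KernelSpec("gaussian", "median"))
        assert np.all(fit.lambdas >= 0.001 - 1e-12)
        assert np.all(fit.lambdas <= 0.03 + 1e-12)

    def test_too_few_districts_rejected(self, small_panel):
        truth, panel, _ = small_panel
        with pytest.raises(ValueError):
            fit_gwlasso(panel.head(2), truth.district_factor_names)


class TestSummary:
    def _fit(self, coef_std, ids=None):
        import obesifact.gwlasso as g

        n, p = coef_std.shape
        ids = ids or [f"D{i}" for i in range(n)]
        names = [f"f{j}" for j in range(p)]
        return g.GwlassoFit(
            district_ids=ids, factor_names=names,
            intercepts=np.zeros(n),
            coef_std=pd.DataFrame(coef_std, index=ids, columns=names),
            coef_raw=pd.DataFrame(coef_std, index=ids, columns=names),
            lambdas=np.full(n, 0.001), weights=np.ones((n, n)),
            residuals=np.zeros(n))

    def test_constant_negative_factor(self):
        fit = self._fit(np.full((5, 1), -0.5))
        row = summarize_coefficients(fit).iloc[0]
        assert row["min"] == row["mean"] == row["max"] == -0.5
        assert row["pos"] == 0 and row["neg"] == 5

    def test_fully_shrunk_factor_counts_nowhere(self):
        fit = self._fit(np.zeros((4, 1)))
        row = summarize_coefficients(fit).iloc[0]
        assert row["pos"] == row["neg"] == 0

    def test_pos_neg_zero_partition(self, rng):
        vals = rng.choice([-0.2, 0.0, 0.3], size=(10, 3))
        fit = self._fit(vals)
        table = summarize_coefficients(fit)
        for j, row in table.iterrows():
            zeros = int((vals[:, j] == 0).sum())
            assert row["pos"] + row["neg"] + zeros == 10
            assert row["min"] <= row["mean"] <= row["max"]
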