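import itertools

import numpy as np
import pytest

from anthemet.lasso import (DesignMatrix, LassoError, alpha_sweep,
                            default_alpha_grid, fit_lasso, kfold_cv,
                            kkt_residual, mse, null_alpha, predict, r2_score,
                            refit_panel, select_elbow, select_min_cv_mse,
                            soft_threshold, SweepRecord)
from oracles import fista_lasso, lasso_objective


def random_design(rng, n=20, m=5, standardize=True):
    X = rng.standard_normal((n, m))
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0)
    w = rng.standard_normal(m) * (rng.random(m) < 0.7)
    y = X @ w + 0.3 * rng.standard_normal(n) + rng.normal(0, 2)
    return DesignMatrix(X, y, [f"f{j}" for j in range(m)])


@pytest.mark.parametrize("z, gamma, expected", [
    (0.5, 1.0, 0.0),
    (2.0, 0.5, 1.5),
    (-2.0, 0.5, -1.5),
    (0.0, 0.0, 0.0),
])
def test_soft_threshold(z, gamma, expected):
    assert soft_threshold(z, gamma) == pytest.approx(expected)


def test_soft_threshold_rejects_negative_gamma():
    with pytest.raises(LassoError):
        soft_threshold(1.0, -0.1)


class TestFitLasso:
    def test_null_solution_above_threshold(self, rng):
        d = random_design(rng)
        a0 = null_alpha(d)
        sol = fit_lasso(d, a0 * 1.000001)
        assert sol.support.size == 0
        assert sol.w0 == pytest.approx(d.y.mean())

    def test_ols_limit_single_column(self, rng):
        x = rng.standard_normal(30)
        x = (x - x.mean()) / x.std()
        y = 2.0 * x + 1.0
        d = DesignMatrix(x[:, None], y, ["f0"])
        sol = fit_lasso(d, 0.0)
        assert sol.w[0] == pytest.approx(2.0, abs=1e-8)
        assert sol.w0 == pytest.approx(y.mean(), abs=1e-8)

    def test_matches_proximal_gradient_oracle(self, rng):
        for _ in range(5):
            d = random_design(rng)
            for alpha in (0.01, 0.1, 0.3):
                sol = fit_lasso(d, alpha)
                w_ref, w0_ref = fista_lasso(d.X, d.y, alpha, n_iter=5000)
                obj_cd = lasso_objective(d.X, d.y, sol.w, sol.w0, alpha)
                obj_ref = lasso_objective(d.X, d.y, w_ref, w0_ref, alpha)
                assert obj_cd <= obj_ref + 1e-8
                assert kkt_residual(d, sol) <= 1e-6

    def test_objective_trace_nonincreasing(self, rng):
        d = random_design(rng, n=40, m=8)
        sol = fit_lasso(d, 0.05, track_objective=True)
        trace = sol.objective_trace
        assert np.all(np.diff(trace) <= 1e-12)
        assert trace[-1] == pytest.approx(sol.objective_value, rel=1e-9)

    def test_kkt_conditions_at_convergence(self, rng):
        d = random_design(rng, n=60, m=12)
        sol = fit_lasso(d, 0.07)
        r = d.y - predict(sol, d.X)
        g = d.X.T @ r / d.n
        active = sol.w != 0
        assert np.all(np.abs(g[~active]) <= 0.07 + 1e-7)
        assert np.allclose(g[active], 0.07 * np.sign(sol.w[active]), atol=1e-7)

    def test_sign_restricted_enumeration_oracle(self, rng):
        # brute force over active sets and sign patterns for m <= 6
        d = random_design(rng, n=25, m=4)
        alpha = 0.1
        sol = fit_lasso(d, alpha)
        n = d.n
        Xc = d.X - d.X.mean(axis=0)
        yc = d.y - d.y.mean()
        best = lasso_objective(d.X, d.y, np.zeros(d.m), d.y.mean(), alpha)
        for r in range(1, d.m + 1):
            for active in itertools.combinations(range(d.m), r):
                for signs in itertools.product((-1.0, 1.0), repeat=r):
                    A = Xc[:, active]
                    s = np.array(signs)
                    try:
                        w_a = np.linalg.solve(A.T @ A, A.T @ yc - n * alpha * s)
                    except np.linalg.LinAlgError:
                        continue
                    if not np.all(np.sign(w_a) == s):
                        continue
                    w = np.zeros(d.m)
                    w[list(active)] = w_a
                    w0 = d.y.mean() - d.X.mean(axis=0) @ w
                    best = min(best, lasso_objective(d.X, d.y, w, w0, alpha))
        assert sol.objective_value <= best + 1e-8

    def test_alpha_zero_matches_normal_equations(self, rng):
        d = random_design(rng, n=40, m=6)
        sol = fit_lasso(d, 0.0)
        Xc = d.X - d.X.mean(axis=0)
        yc = d.y - d.y.mean()
        w_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
        assert np.allclose(sol.w, w_ols, atol=1e-6)

    def test_matches_sklearn_reference(self, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        for _ in range(3):
            d = random_design(rng, n=30, m=8)
            ref = sklearn.Lasso(alpha=0.05, tol=1e-12, max_iter=200000).fit(d.X, d.y)
            sol = fit_lasso(d, 0.05)
            assert np.allclose(sol.w, ref.coef_, atol=1e-6)
            assert sol.w0 == pytest.approx(ref.intercept_, abs=1e-6)

    def test_nonfinite_entries_rejected(self):
        X = np.ones((3, 2))
        X[0, 0] = np.inf
        with pytest.raises(LassoError, match="finite"):
            DesignMatrix(X, np.ones(3), ["a", "b"])


class TestPredictAndMetrics:
    def test_zero_coefficients_predict_intercept(self, rng):
        d = random_design(rng)
        sol = fit_lasso(d, null_alpha(d) * 1.01)
        assert np.allclose(predict(sol, d.X), d.y.mean())

    def test_exact_interpolation_at_alpha_zero(self, rng):
        x = rng.standard_normal(15)
        x = (x - x.mean()) / x.std()
        y = -1.7 * x + 0.4
        d = DesignMatrix(x[:, None], y, ["f0"])
        sol = fit_lasso(d, 0.0)
        assert np.allclose(predict(sol, d.X), y, atol=1e-8)

    def test_prediction_linear_in_features(self, rng):
        d = random_design(rng)
        sol = fit_lasso(d, 0.05)
        base = predict(sol, d.X) - sol.w0
        doubled = predict(sol, 2 * d.X) - sol.w0
        assert np.allclose(doubled, 2 * base, atol=1e-10)

    def test_dimension_mismatch(self, rng):
        d = random_design(rng)
        sol = fit_lasso(d, 0.1)
        with pytest.raises(LassoError):
            predict(sol, np.ones((4, 3)))

    def test_r2_and_mse_closed_forms(self):
        y = np.array([0.0, 0.0, 1.0, 1.0])
        y_hat = np.array([0.0, 1.0, 0.0, 1.0])
        assert mse(y, y_hat) == pytest.approx(0.5)
        assert r2_score(y, y_hat) == pytest.approx(-1.0)
        assert r2_score(y, y) == pytest.approx(1.0)
        assert r2_score(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_r2_rejects_constant_y(self):
        with pytest.raises(LassoError):
            r2_score(np.ones(4), np.zeros(4))


class TestCrossValidation:
    def test_noiseless_model_reaches_unity(self, rng):
        X = rng.standard_normal((60, 4))
        X = (X - X.mean(0)) / X.std(0)
        y = X @ np.array([1.0, -2.0, 0.5, 0.0]) + 3
        d = DesignMatrix(X, y, list("abcd"))
        out = kfold_cv(d, 1e-6, k=10, seed=0)
        assert out["cv_r2"] == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_has_no_skill(self):
        scores = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((40, 6))
            y = rng.standard_normal(40)
            d = DesignMatrix(X, y, [f"f{j}" for j in range(6)])
            scores.append(kfold_cv(d, 0.05, k=5, seed=seed)["cv_r2"])
        assert np.mean(scores) < 0.05

    def test_same_seed_reproduces_folds_and_metrics(self, rng):
        d = random_design(rng, n=50, m=6)
        a = kfold_cv(d, 0.1, k=10, seed=42)
        b = kfold_cv(d, 0.1, k=10, seed=42)
        assert a["cv_r2"] == b["cv_r2"]
        assert np.allclose(a["oof_predictions"], b["oof_predictions"])

    def test_k_larger_than_n_rejected(self, rng):
        d = random_design(rng, n=5, m=2)
        with pytest.raises(LassoError):
            kfold_cv(d, 0.1, k=6)

    def test_fold_safe_standardization_runs(self, rng):
        d = random_design(rng, n=40, m=5, standardize=False)
        out = kfold_cv(d, 0.1, k=5, seed=1, fold_safe=True)
        assert np.isfinite(out["cv_r2"])


class TestAlphaSweep:
    def test_default_grid_endpoints(self):
        grid = default_alpha_grid()
        assert grid[0] == pytest.approx(5e-5)
        assert grid[-1] == pytest.approx(0.5)
        assert len(grid) == 50

    def test_largest_alpha_above_null_threshold_empty_support(self, rng):
        d = random_design(rng, n=40, m=6)
        grid = np.array([0.01, null_alpha(d) * 1.1])
        records = alpha_sweep(d, grid, k=5, seed=0)
        assert records[-1].support_size == 0

    def test_small_alpha_approaches_ols_r2(self, rng):
        d = random_design(rng, n=80, m=6)
        Xc = d.X - d.X.mean(0)
        yc = d.y - d.y.mean()
        w_ols = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
        r2_ols = r2_score(d.y, d.y.mean() + Xc @ w_ols)
        records = alpha_sweep(d, default_alpha_grid(), k=5, seed=0,
                              max_sweeps=100_000)
        assert records[0].train_r2 == pytest.approx(r2_ols, abs=1e-3)

    def test_train_r2_nonincreasing_in_alpha(self, rng):
        d = random_design(rng, n=60, m=8)
        records = alpha_sweep(d, default_alpha_grid(n_alphas=20), k=5, seed=0,
                              max_sweeps=100_000)
        train = np.array([r.train_r2 for r in records])
        assert np.all(np.diff(train) <= 1e-6)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(LassoError):
            alpha_sweep(random_design(rng), np.array([]))


def rec(alpha, cv_r2, support_size, cv_mse=1.0):
    return SweepRecord(alpha=alpha, train_r2=0.9, cv_r2=cv_r2, cv_mse=cv_mse,
                       support_size=support_size,
                       support_ids=[f"f{j}" for j in range(support_size)])


class TestSelection:
    def test_dominating_record_chosen(self):
        records = [rec(0.1, 0.80, 10), rec(0.05, 0.70, 30)]
        assert select_elbow(records).alpha == 0.1

    def test_smallest_support_within_tolerance(self):
        records = [rec(0.01, 0.750, 60), rec(0.1, 0.748, 29)]
        assert select_elbow(records, tol=0.02).support_size == 29

    def test_ties_break_to_larger_alpha(self):
        records = [rec(0.01, 0.75, 29), rec(0.1, 0.74, 29)]
        assert select_elbow(records, tol=0.02).alpha == 0.1

    def test_all_nan_metrics_rejected(self):
        with pytest.raises(LassoError):
            select_elbow([rec(0.1, np.nan, 3)])

    def test_min_cv_mse_selection(self):
        records = [rec(0.1, 0.7, 10, cv_mse=0.5), rec(0.05, 0.72, 20, cv_mse=0.4)]
        assert select_min_cv_mse(records).cv_mse == 0.4


class TestRefitPanel:
    def test_single_dataset_equals_direct_fit_on_panel(self, rng):
        d = random_design(rng, n=60, m=8)
        panel = ["f1", "f3", "f5"]
        grid = default_alpha_grid(n_alphas=10)
        sol, record, records = refit_panel(panel, [d], grid, k=5, seed=3,
                                           per_dataset_standardize=False)
        direct = alpha_sweep(d.select_features(panel), grid, k=5, seed=3)
        chosen = select_min_cv_mse(direct)
        assert record.alpha == chosen.alpha
        assert np.allclose(sol.w, chosen.solution.w, atol=1e-10)

    def test_panel_of_one_feature(self, rng):
        d = random_design(rng, n=40, m=5)
        sol, record, _ = refit_panel(["f0"], [d], default_alpha_grid(n_alphas=8),
                                     k=5, seed=0)
        assert record.support_size <= 1

    def test_missing_panel_feature_named(self, rng):
        d = random_design(rng)
        with pytest.raises(LassoError, match="nope"):
            refit_panel(["nope"], [d])

    def test_multi_batch_recovers_most_of_true_support(self):
        # three batches sharing a sparse truth; min-CV-MSE re-fit keeps most
        from anthemet.simulate import SyntheticSpec, generate_dataset
        from anthemet.preprocess import preprocess_peak_table, standardize

        hits, totals = [], []
        for seed in (3, 4):
            spec = SyntheticSpec.full_study(seed=seed, rate_linkage="sample")
            table, _, truth, _ = generate_dataset(spec)
            matrix = preprocess_peak_table(table)
            designs = []
            for exp in ("TK01", "IA04", "IA06"):
                mask = (matrix.sample_meta["experiment"] == exp).to_numpy()
                sub = matrix.select_samples(mask)
                y = np.array([truth["sample_rates"][s] for s in sub.values.index])
                designs.append(DesignMatrix(sub.values.to_numpy(), y,
                                            list(sub.values.columns)))
            panel = truth["support_ids"]
            sol, record, _ = refit_panel(panel, designs,
                                         default_alpha_grid(n_alphas=25),
                                         k=10, seed=seed)
            assert set(record.support_ids) <= set(panel)
            hits.append(len(set(record.support_ids) & set(panel)))
            totals.append(len(panel))
        assert sum(hits) / sum(totals) >= 0.8
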