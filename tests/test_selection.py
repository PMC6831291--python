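import numpy as np
import pytest

from cfpanel.selection import (bootstrap_select, choose_lambda_min,
                               fit_elastic_net, make_lambda_grid)


def orthonormal_design(n, p, seed=0):
    """Columns centered, population-sd 1, mutually orthogonal:
    the standardized Gram is the identity."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    X -= X.mean(axis=0)
    Q, _ = np.linalg.qr(X)
    return Q[:, :p] * np.sqrt(n)


class TestFitElasticNet:
    def test_full_shrinkage_limit(self):
        rng = np.random.default_rng(1)
        X = rng.random((20, 6))
        y = rng.integers(0, 2, 20).astype(float)
        fit = fit_elastic_net(X, y, lam=1e6, mixing=1.0)
        assert (fit.coefficients == 0.0).all()
        assert fit.intercept == pytest.approx(y.mean(), abs=1e-10)

    @pytest.mark.parametrize("lam", [0.02, 0.1, 0.3])
    def test_soft_threshold_on_orthonormal_design(self, lam):
        n, p = 50, 8
        X = orthonormal_design(n, p, seed=3)
        rng = np.random.default_rng(4)
        y = rng.normal(size=n)
        fit = fit_elastic_net(X, y, lam=lam, mixing=1.0)
        w_ols = X.T @ (y - y.mean()) / n  # per-coordinate OLS on this design
        expected = np.sign(w_ols) * np.maximum(np.abs(w_ols) - lam, 0.0)
        np.testing.assert_allclose(fit.coefficients.to_numpy(), expected,
                                   atol=1e-8)

    def test_lambda_zero_matches_ols(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + rng.normal(size=40)
        fit = fit_elastic_net(X, y, lam=0.0, mixing=1.0)
        X1 = np.c_[np.ones(40), X]
        beta = np.linalg.lstsq(X1, y, rcond=None)[0]
        np.testing.assert_allclose(fit.coefficients.to_numpy(), beta[1:],
                                   atol=1e-6)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-6)

    def test_scaling_equivariance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        fit = fit_elastic_net(X, y, lam=0.05, mixing=1.0)
        X2 = X.copy()
        X2[:, 1] *= 10.0
        fit2 = fit_elastic_net(X2, y, lam=0.05, mixing=1.0)
        np.testing.assert_allclose(fit2.coefficients.iloc[1],
                                   fit.coefficients.iloc[1] / 10.0,
                                   atol=1e-8)
        np.testing.assert_allclose(fit2.coefficients.drop(fit2.coefficients.index[1]),
                                   fit.coefficients.drop(fit.coefficients.index[1]),
                                   atol=1e-8)

    def test_sparsity_non_increasing_in_lambda(self):
        # near-orthogonal designs (n >> p); on strongly correlated designs
        # the lasso active set can transiently shrink along the path
        rng = np.random.default_rng(13)
        for _ in range(5):
            X = rng.normal(size=(100, 10))
            y = rng.normal(size=100)
            grid = make_lambda_grid(X, y, mixing=1.0, n_lambda=30)
            nnz = [int((np.abs(fit_elastic_net(X, y, lam, 1.0)
                               .coefficients) > 1e-10).sum())
                   for lam in grid]
            # grid descends, so the active set can only grow
            assert all(b >= a for a, b in zip(nnz[:-1], nnz[1:]))

    def test_zero_variance_column_dropped_with_warning(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 3))
        X[:, 2] = 0.7
        y = rng.normal(size=20)
        with pytest.warns(UserWarning, match="zero-variance"):
            fit = fit_elastic_net(X, y, 0.1, 1.0)
        assert fit.coefficients.iloc[2] == 0.0


class TestChooseLambda:
    def test_single_value_grid(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        assert choose_lambda_min(X, y, lambda_grid=[0.3]) == 0.3

    def test_fewer_samples_than_folds(self):
        X = np.eye(3)
        y = np.array([0.0, 1.0, 0.0])
        with pytest.raises(ValueError):
            choose_lambda_min(X, y, k_folds=5)

    def test_pure_noise_prefers_heavy_penalty(self):
        # with no signal, CV error is minimized near the top of the grid
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 10))
            y = np.r_[np.zeros(15), np.ones(15)]
            grid = make_lambda_grid(X, y, mixing=1.0, n_lambda=30)
            lam = choose_lambda_min(X, y, mixing=1.0, lambda_grid=grid,
                                    seed=seed)
            if lam >= grid[len(grid) // 3]:  # top third of the grid
                hits += 1
        assert hits / n_seeds >= 0.8

    def test_planted_signal_beats_null_cv_error(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(40, 10))
        y = (X[:, 0] > 0).astype(float)  # strong signal in one column
        grid = make_lambda_grid(X, y, mixing=1.0)
        lam = choose_lambda_min(X, y, mixing=1.0, lambda_grid=grid, seed=1)
        assert lam < grid[0]  # not the all-zero solution


class TestBootstrapSelect:
    def test_perfect_separation_is_selected(self):
        y = np.r_[np.zeros(10), np.ones(10)]
        X = (np.r_[np.full(10, 0.2), np.full(10, 0.8)]
             + np.random.default_rng(0).normal(0, 0.01, 20)).reshape(-1, 1)
        res = bootstrap_select(X, y, "hyper", B=50, seed=1)
        assert res.table["selected"].iloc[0]
        assert res.table["ci_lower"].iloc[0] > 0

    def test_ci_bounds_ordered(self):
        rng = np.random.default_rng(3)
        X = rng.random((30, 8))
        y = np.r_[np.zeros(15), np.ones(15)]
        res = bootstrap_select(X, y, "hyper", B=40, seed=2)
        assert (res.table["ci_lower"] <= res.table["ci_upper"]).all()

    def test_selection_rule_matches_ci_signs(self):
        rng = np.random.default_rng(4)
        X = rng.random((30, 6))
        y = np.r_[np.zeros(15), np.ones(15)]
        for d, col, cmp in (("hyper", "ci_lower", np.greater),
                            ("hypo", "ci_upper", np.less)):
            res = bootstrap_select(X, y, d, B=30, seed=5)
            expected = cmp(res.table[col].to_numpy(), 0.0)
            np.testing.assert_array_equal(res.table["selected"].to_numpy(),
                                          expected)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        X = rng.random((24, 5))
        y = np.r_[np.zeros(12), np.ones(12)]
        a = bootstrap_select(X, y, "hyper", B=30, seed=9)
        b = bootstrap_select(X, y, "hyper", B=30, seed=9)
        assert a.table.equals(b.table)

    def test_defaults_match_published_operating_point(self):
        import inspect
        sig = inspect.signature(bootstrap_select)
        assert sig.parameters["B"].default == 100
        assert sig.parameters["ci_level"].default == 0.95
        assert sig.parameters["mixing"].default == 0.05


class TestMarkerRecoveryTissueScale:
    def test_planted_markers_dominate_selection(self):
        """With tissue-level signal (delta 0.3 against kappa=100 noise),
        CI-sign bootstrap selection recovers planted markers among a
        larger candidate pool with high precision."""
        from cfpanel.simulate import SyntheticConfig, generate_study

        true_sel, all_sel = 0, 0
        for seed in range(2):
            cfg = SyntheticConfig(n_probes=400, n_hyper_markers=15,
                                  n_hypo_markers=0, seed=seed,
                                  frac_markers_leukocyte_confounded=0.0)
            bundles, truth = generate_study(cfg)
            beta = bundles["tissue_set_1"].beta
            markers = list(truth.markers.index)
            nulls = [p for p in beta.probe_ids if p not in markers][:85]
            res = bootstrap_select(beta.values.loc[:, markers + nulls],
                                   beta.labels01(), "hyper", B=100,
                                   seed=seed)
            chosen = set(res.selected_probes)
            true_sel += len(chosen & set(markers))
            all_sel += len(chosen)
        assert all_sel >= 10
        assert true_sel / all_sel >= 0.60


class TestSklearnCrossCheck:
    def test_matches_sklearn_elastic_net(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(31)
        n, p = 60, 12
        # pre-standardize so both solvers see the same problem
        X = rng.normal(size=(n, p))
        X = (X - X.mean(0)) / X.std(0)
        y = X @ rng.normal(size=p) * 0.3 + rng.normal(size=n)
        for lam, mix in [(0.05, 1.0), (0.2, 0.5), (0.1, 0.05)]:
            ours = fit_elastic_net(X, y, lam, mix)
            ref = sklearn.ElasticNet(alpha=lam, l1_ratio=mix, tol=1e-12,
                                     max_iter=100000).fit(X, y)
            np.testing.assert_allclose(ours.coefficients.to_numpy(),
                                       ref.coef_, atol=1e-5)
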