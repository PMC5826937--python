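"""Penalized Poisson solver: primitives, KKT optimality, oracles, CV."""

import shutil
import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import stabnet.elasticnet as en


def make_instance(seed, N=25, p=8, sparse=True):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(N, p))
    X -= X.mean(axis=0)
    beta = np.zeros(p)
    nz = rng.choice(p, size=max(1, p // 3), replace=False)
    beta[nz] = rng.uniform(-0.5, 0.5, len(nz))
    y = rng.poisson(np.exp(1.3 + X @ beta)).astype(float)
    if np.all(y == y[0]):
        y[0] += 1
    return X, y


class TestPrimitives:
    @pytest.mark.parametrize("z,g,expected", [
        (3.0, 1.0, 2.0), (0.5, 1.0, 0.0), (-3.0, 1.0, -2.0), (0.0, 0.0, 0.0),
    ])
    def test_soft_threshold(self, z, g, expected):
        assert en.soft_threshold(z, g) == expected

    def test_soft_threshold_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            en.soft_threshold(1.0, -0.1)

    def test_deviance_zero_iff_equal(self):
        y = np.array([0.0, 2.0, 5.0])
        assert en.poisson_deviance(y, np.maximum(y, 1e-12)) < 1e-6
        assert en.poisson_deviance(y, y + 0.5) > 0

    @pytest.mark.parametrize("y,mu,expected", [
        ([0.0], [3.0], 6.0),
        ([2.0], [1.0], 2 * (2 * np.log(2) - 1)),
    ])
    def test_deviance_closed_forms(self, y, mu, expected):
        assert en.poisson_deviance(y, mu) == pytest.approx(expected, abs=1e-12)

    def test_deviance_rejects_nonpositive_mu(self):
        with pytest.raises(ValueError):
            en.poisson_deviance([1.0], [0.0])

    def test_objective_at_zero_is_one(self):
        X, y = make_instance(0)
        # -(1/N) sum(y*0 - e^0) = 1 regardless of data
        assert en.penalized_objective(X, y, 0.5, 0.0, 0.0, np.zeros(X.shape[1])) \
            == pytest.approx(1.0)

    def test_objective_linear_in_lambda(self):
        X, y = make_instance(1)
        beta = np.linspace(-0.3, 0.4, X.shape[1])
        pen = 0.5 * 0.5 * beta @ beta + 0.5 * np.abs(beta).sum()
        o1 = en.penalized_objective(X, y, 0.5, 0.2, 0.1, beta)
        o2 = en.penalized_objective(X, y, 0.5, 0.4, 0.1, beta)
        assert o2 - o1 == pytest.approx(0.2 * pen, rel=1e-10)

    def test_objective_alpha_endpoints_differ_by_penalty_gap(self):
        X, y = make_instance(2)
        beta = np.linspace(-0.3, 0.4, X.shape[1])
        lam = 0.3
        o_l1 = en.penalized_objective(X, y, 1.0, lam, 0.0, beta)
        o_l2 = en.penalized_objective(X, y, 0.0, lam, 0.0, beta)
        gap = lam * (np.abs(beta).sum() - 0.5 * beta @ beta)
        assert o_l1 - o_l2 == pytest.approx(gap, rel=1e-10)


class TestLambdaGrid:
    def test_fit_at_lambda_max_is_null_model(self):
        X, y = make_instance(3)
        grid = en.compute_lambda_grid(X, y, 0.5)
        m = en.fit_elastic_net_poisson(X, y, 0.5, grid[0])
        assert np.all(m.coef == 0)
        assert m.intercept == pytest.approx(np.log(y.mean()), abs=1e-12)

    def test_above_lambda_max_also_null(self):
        X, y = make_instance(4)
        lam_max = en.compute_lambda_grid(X, y, 1.0)[0]
        m = en.fit_elastic_net_poisson(X, y, 1.0, 1.01 * lam_max)
        assert np.all(m.coef == 0)

    def test_halving_alpha_doubles_lambda_max(self):
        X, y = make_instance(5)
        g1 = en.compute_lambda_grid(X, y, 1.0)
        g2 = en.compute_lambda_grid(X, y, 0.5)
        assert g2[0] == pytest.approx(2 * g1[0], rel=1e-12)

    def test_constant_outcome_rejected(self):
        X, _ = make_instance(6)
        with pytest.raises(ValueError):
            en.compute_lambda_grid(X, np.full(X.shape[0], 4.0), 0.5)

    def test_grid_descending(self):
        X, y = make_instance(7)
        g = en.compute_lambda_grid(X, y, 0.5, n_lambda=20)
        assert (np.diff(g) < 0).all()


class TestFit:
    def test_uncentered_input_rejected(self):
        X, y = make_instance(8)
        with pytest.raises(ValueError, match="centered"):
            en.fit_elastic_net_poisson(X + 1.0, y, 0.5, 0.1)

    def test_objective_not_above_perturbed_numeric_minimizer(self):
        X, y = make_instance(9, N=20, p=5)
        m = en.fit_elastic_net_poisson(X, y, 0.5, 0.1)
        obj = en.penalized_objective(X, y, 0.5, 0.1, m.intercept, m.coef)
        f = lambda th: en.penalized_objective(X, y, 0.5, 0.1, th[0], th[1:])
        rng = np.random.default_rng(0)
        best = np.inf
        for trial in range(3):
            x0 = np.concatenate([[m.intercept], m.coef])
            if trial:
                x0 = x0 + rng.normal(0, 0.05, len(x0))
            r = optimize.minimize(f, x0, method="Powell",
                                  options={"xtol": 1e-12, "ftol": 1e-14,
                                           "maxiter": 50000})
            best = min(best, r.fun)
        assert obj <= best + 1e-6

    def test_ridge_limit_matches_irls_glm(self):
        import statsmodels.api as sm

        X, y = make_instance(10, N=40, p=5)
        m = en.fit_elastic_net_poisson(X, y, 0.0, 1e-8, tol=1e-10)
        glm = sm.GLM(y, sm.add_constant(X), family=sm.families.Poisson()).fit()
        ours = np.concatenate([[m.intercept], m.coef])
        np.testing.assert_allclose(ours, glm.params, atol=1e-4)

    def test_kkt_certificate_random_instances(self):
        for seed in range(20):
            X, y = make_instance(seed, N=25, p=8)
            alpha = [0.0, 0.5, 1.0][seed % 3]
            grid = en.compute_lambda_grid(X, y, alpha, n_lambda=4,
                                          lambda_min_ratio=1e-2)
            for lam in grid:
                m = en.fit_elastic_net_poisson(X, y, alpha, lam)
                assert en.kkt_residuals(X, y, alpha, lam, m).max() <= 1e-5

    def test_training_deviance_nonincreasing_down_path(self):
        X, y = make_instance(11, N=30, p=10)
        grid = en.compute_lambda_grid(X, y, 0.5, n_lambda=25,
                                      lambda_min_ratio=1e-3)
        models = en.fit_lambda_path(X, y, 0.5, grid)
        devs = [en.poisson_deviance(y, en.predict_storage_days(m, X))
                for m in models]
        assert (np.diff(devs) <= 1e-8).all()

    def test_lasso_cardinality_bounded_by_n(self):
        rng = np.random.default_rng(12)
        N, p = 15, 60
        X = rng.normal(size=(N, p))
        X -= X.mean(axis=0)
        y = rng.poisson(np.exp(1.0 + X[:, 0] * 0.5)).astype(float)
        grid = en.compute_lambda_grid(X, y, 1.0, n_lambda=30,
                                      lambda_min_ratio=1e-3)
        for m in en.fit_lambda_path(X, y, 1.0, grid):
            assert len(m.nonzero) <= N

    def test_python_fallback_kernel_equivalent(self, monkeypatch):
        X, y = make_instance(13, N=20, p=6)
        m_fast = en.fit_elastic_net_poisson(X, y, 0.5, 0.05)
        monkeypatch.setattr(en, "_cd_solve", en._py_cd_solve)
        m_py = en.fit_elastic_net_poisson(X, y, 0.5, 0.05)
        assert m_py.intercept == pytest.approx(m_fast.intercept, abs=1e-8)
        np.testing.assert_allclose(m_py.coef, m_fast.coef, atol=1e-8)

    def test_matches_r_glmnet_when_available(self):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        X, y = make_instance(14, N=40, p=6)
        alpha, lam = 0.5, 0.05
        m = en.fit_elastic_net_poisson(X, y, alpha, lam, tol=1e-9)
        with tempfile.TemporaryDirectory() as d:
            np.savetxt(f"{d}/X.csv", X, delimiter=",")
            np.savetxt(f"{d}/y.csv", y, delimiter=",")
            script = (
                f'X <- as.matrix(read.csv("{d}/X.csv", header=FALSE));'
                f'y <- scan("{d}/y.csv");'
                'suppressMessages(library(glmnet));'
                f'fit <- glmnet(X, y, family="poisson", alpha={alpha},'
                f'lambda={lam}, standardize=FALSE, thresh=1e-14);'
                'cat(as.numeric(coef(fit)), sep=",")'
            )
            out = subprocess.run(["Rscript", "-e", script],
                                 capture_output=True, text=True, timeout=120)
            if out.returncode != 0:
                pytest.skip(f"glmnet unavailable: {out.stderr[-200:]}")
            ref = np.array([float(v) for v in out.stdout.strip().split(",")])
        ours = np.concatenate([[m.intercept], m.coef])
        np.testing.assert_allclose(ours, ref, atol=2e-4)


class TestCrossValidation:
    def test_loo_produces_n_folds(self):
        X, y = make_instance(15, N=12, p=4)
        cv = en.cross_validate_lambda(X, y, 0.5, folds="loo")
        assert cv.n_folds == 12
        assert cv.fold_scheme == "loo"

    def test_high_lambda_cv_equals_null_deviance(self):
        X, y = make_instance(16, N=15, p=4)
        big = en.compute_lambda_grid(X, y, 0.5)[0] * 5
        lambdas = np.array([big * 2, big])
        cv = en.cross_validate_lambda(X, y, 0.5, folds="loo", lambdas=lambdas)
        # directly computed held-out null deviance per LOO fold
        devs = []
        for i in range(len(y)):
            mu = np.delete(y, i).mean()
            devs.append(en.poisson_deviance(y[i:i + 1], np.array([mu])))
        np.testing.assert_allclose(cv.mean_deviance, np.mean(devs), atol=1e-8)

    def test_lambda_1se_at_least_lambda_min(self):
        for seed in (17, 18, 19):
            X, y = make_instance(seed, N=24, p=6)
            cv = en.cross_validate_lambda(X, y, 0.5, folds=6, seed=seed,
                                          n_lambda=30)
            assert cv.lambda_1se >= cv.lambda_min

    def test_seed_changes_folds_not_grid(self):
        X, y = make_instance(20, N=20, p=5)
        cv1 = en.cross_validate_lambda(X, y, 0.5, folds=5, seed=1, n_lambda=15)
        cv2 = en.cross_validate_lambda(X, y, 0.5, folds=5, seed=2, n_lambda=15)
        np.testing.assert_array_equal(cv1.lambdas, cv2.lambdas)
        cv1b = en.cross_validate_lambda(X, y, 0.5, folds=5, seed=1, n_lambda=15)
        np.testing.assert_array_equal(cv1.mean_deviance, cv1b.mean_deviance)


class TestAlphaAndSplit:
    def test_singleton_grid(self):
        X, y = make_instance(21, N=15, p=4)
        best, results = en.select_alpha(X, y, alpha_grid=(0.5,), folds=5, seed=0,
                                        n_lambda=10)
        assert best == 0.5 and set(results) == {0.5}

    def test_degenerate_data_ties_break_to_half(self):
        # all-zero design: every alpha fits the null model at every lambda,
        # so the CV curves are identical and the tie breaks toward 0.5
        rng = np.random.default_rng(22)
        X = np.zeros((15, 3))
        y = rng.poisson(5.0, 15).astype(float)
        best, results = en.select_alpha(
            X, y, alpha_grid=(0.25, 0.5, 0.75), folds=5, seed=0,
            lambdas=np.array([0.5, 0.25, 0.1]))
        assert best == 0.5
        curves = [r.mean_deviance.tolist() for r in results.values()]
        assert curves[0] == curves[1] == curves[2]

    def test_invalid_alpha_rejected(self):
        X, y = make_instance(23, N=12, p=3)
        with pytest.raises(ValueError):
            en.select_alpha(X, y, alpha_grid=(0.5, 1.5), folds=4, seed=0)

    def test_split_per_day_ceiling(self):
        samples = pd.DataFrame({
            "role": "study",
            "storage_day": np.repeat(np.arange(0, 33, 3), 10),
            "replicate": list(range(10)) * 11,
        }, index=[f"s{i}" for i in range(110)])
        train, test = en.split_train_test(samples, 0.75, seed=0)
        assert len(train) == 88 and len(test) == 22
        days = samples.loc[train, "storage_day"].value_counts()
        assert (days == 8).all()

    def test_split_union_disjoint_reproducible(self):
        samples = pd.DataFrame({
            "role": "study",
            "storage_day": np.repeat([0, 3, 6], 4),
            "replicate": list(range(4)) * 3,
        }, index=[f"s{i}" for i in range(12)])
        for seed in range(5):
            tr, te = en.split_train_test(samples, 0.75, seed=seed)
            assert set(tr) | set(te) == set(samples.index)
            assert not set(tr) & set(te)
        tr1, _ = en.split_train_test(samples, 0.75, seed=3)
        tr2, _ = en.split_train_test(samples, 0.75, seed=3)
        assert tr1 == tr2

    def test_single_sample_day_goes_to_train_with_warning(self):
        samples = pd.DataFrame({
            "role": "study", "storage_day": [0, 0, 3],
            "replicate": ["a", "b", "a"],
        }, index=["s0", "s1", "s2"])
        with pytest.warns(UserWarning, match="single sample"):
            tr, te = en.split_train_test(samples, 0.75, seed=0)
        assert "s2" in tr


class TestPredictEvaluate:
    def test_intercept_only_prediction(self):
        m = en.ElasticNetModel(alpha=0.5, lam=1.0, intercept=np.log(15.0),
                               coef=np.zeros(3))
        np.testing.assert_allclose(
            en.predict_storage_days(m, np.zeros((4, 3))), 15.0)

    def test_prediction_monotone_in_positive_coefficient(self):
        m = en.ElasticNetModel(alpha=0.5, lam=1.0, intercept=0.5,
                               coef=np.array([0.1, 0.0]))
        grid = np.linspace(-3, 3, 25)
        X = np.column_stack([grid, np.zeros_like(grid)])
        yhat = en.predict_storage_days(m, X)
        assert (np.diff(yhat) > 0).all()

    def test_feature_mismatch_rejected(self):
        m = en.ElasticNetModel(alpha=0.5, lam=1.0, intercept=0.0,
                               coef=np.zeros(3))
        with pytest.raises(ValueError):
            en.predict_storage_days(m, np.zeros((2, 4)))

    def test_perfect_and_offset_predictions(self):
        y = np.array([0.0, 3.0, 6.0])
        ev = en.evaluate_predictions(y, y)
        assert ev.rmse == 0 and ev.r2 == pytest.approx(1.0)
        ev2 = en.evaluate_predictions(y, y + 1)
        assert ev2.rmse == pytest.approx(1.0)
        assert ev2.r2 == pytest.approx(1.0)

    def test_permuted_predictions_have_null_r2(self):
        rng = np.random.default_rng(24)
        y = np.repeat(np.arange(0, 33, 3.0), 3)
        r2s = [en.evaluate_predictions(y, rng.permutation(y)).r2
               for _ in range(200)]
        assert np.median(r2s) < 0.05

    def test_constant_vector_r2_missing(self):
        ev = en.evaluate_predictions([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert ev.r2 is None and ev.p_value is None

    def test_rank_selected_features(self):
        m = en.ElasticNetModel(
            alpha=0.5, lam=1.0, intercept=0.0,
            coef=np.array([0.5, -0.8, 0.0]),
            feature_names=["f1", "f2", "f3"])
        ranked = en.rank_selected_features(m)
        assert ranked["feature_id"].tolist() == ["f2", "f1"]
        m_neg = en.ElasticNetModel(alpha=0.5, lam=1.0, intercept=0.0,
                                   coef=-m.coef, feature_names=m.feature_names)
        assert en.rank_selected_features(m_neg)["feature_id"].tolist() == ["f2", "f1"]

    def test_empty_model_empty_ranking(self):
        m = en.ElasticNetModel(alpha=0.5, lam=1.0, intercept=0.0,
                               coef=np.zeros(2), feature_names=["a", "b"])
        assert len(en.rank_selected_features(m)) == 0
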