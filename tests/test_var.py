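import numpy as np
import pytest

from conftest import latent_matrix
from oracles import soft_threshold_lasso
from tvgranger.simulate import VARSpec, make_sparse_spec, simulate_var
from tvgranger.var import (
    VARConfig,
    build_design,
    cross_validate,
    description_length,
    es_metric,
    escv_select,
    fit_target,
    lasso_path,
    select_lambda_escv,
    select_order,
)


class TestBuildDesign:
    def test_univariate_lag_one(self):
        mat = latent_matrix(np.array([[1.0, 2.0, 3.0, 4.0]]))
        sysd = build_design(mat, d=1)
        np.testing.assert_array_equal(sysd.y(0), [2, 3, 4])
        np.testing.assert_array_equal(sysd.phi[:, 1], [1, 2, 3])
        np.testing.assert_array_equal(sysd.phi[:, 0], 1.0)

    def test_shapes(self, rng):
        mat = latent_matrix(rng.normal(size=(2, 10)))
        sysd = build_design(mat, d=2)
        assert sysd.phi.shape == (8, 5)
        assert sysd.targets.shape == (8, 2)

    def test_window_too_short_names_minimum(self):
        mat = latent_matrix(np.ones((2, 4)))
        with pytest.raises(ValueError, match="at least"):
            build_design(mat, d=3)

    def test_noiseless_var1_ols_round_trip(self, rng):
        A = np.array([[0.5, -0.3], [0.2, 0.4]])
        spec = VARSpec(k=2, d=1, A=[A], noise_sd=1.0)
        data, _ = simulate_var(spec, T=200, seed=0)
        # refit noiselessly: y(t) = A y(t-1) + e; OLS on the design recovers A
        sysd = build_design(latent_matrix(data), d=1)
        for i in range(2):
            coef, *_ = np.linalg.lstsq(sysd.phi, sysd.y(i), rcond=None)
            np.testing.assert_allclose(coef[1:3], A[i], atol=0.15)

    def test_column_labels(self, rng):
        mat = latent_matrix(rng.normal(size=(3, 12)), genes=["a", "b", "c"])
        sysd = build_design(mat, d=2)
        assert sysd.column_label(0) == "intercept"
        assert sysd.column_label(1) == ("a", 1)
        assert sysd.column_label(4) == ("a", 2)
        assert sysd.column_label(6) == ("c", 2)


class TestLassoPath:
    def _system(self, rng, n=40, p=6):
        phi = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
        beta = np.zeros(p + 1)
        beta[0], beta[1], beta[3] = 0.5, 2.0, -1.5
        y = phi @ beta + 0.1 * rng.normal(size=n)
        return phi, y

    def test_all_zero_at_lambda_max(self, rng):
        phi, y = self._system(rng)
        path = lasso_path(phi, y)
        assert path.nnz[0] == 0

    def test_matches_least_squares_at_tiny_lambda(self, rng):
        phi, y = self._system(rng)
        path = lasso_path(phi, y, np.array([1e-8]))
        ols, *_ = np.linalg.lstsq(phi, y, rcond=None)
        np.testing.assert_allclose(path.coefficients[0], ols, atol=1e-5)

    def test_matches_soft_threshold_oracle_along_path(self, rng):
        """Coordinate-wise soft-threshold fixed point agrees to 1e-8."""
        for seed in range(3):
            r = np.random.default_rng(seed)
            phi, y = self._system(r)
            cfg = VARConfig(n_lambdas=25)
            path = lasso_path(phi, y, config=cfg)
            for idx in [0, 6, 12, 18, 24]:
                lam = path.lambdas[idx]
                oracle = soft_threshold_lasso(phi, y, lam)
                np.testing.assert_allclose(
                    path.coefficients[idx], oracle, atol=1e-8
                )

    def test_increasing_grid_rejected(self, rng):
        phi, y = self._system(rng)
        with pytest.raises(ValueError, match="decreasing"):
            lasso_path(phi, y, np.array([0.1, 1.0]))

    def test_joint_scale_equivariance_of_fitted_values(self, rng):
        # scaling all predictors by c and the grid by c leaves the selected
        # support and fitted values unchanged
        phi, y = self._system(rng)
        path = lasso_path(phi, y)
        fit1 = phi @ path.coefficients[40]
        phi2 = phi.copy()
        phi2[:, 1:] *= 10.0
        path2 = lasso_path(phi2, y, path.lambdas * 10.0)
        fit2 = phi2 @ path2.coefficients[40]
        np.testing.assert_allclose(fit1, fit2, atol=1e-6)


class TestCrossValidationAndES:
    def test_pure_noise_prefers_null_model(self, rng):
        phi = np.column_stack([np.ones(60), rng.normal(size=(60, 8))])
        y = rng.normal(size=60)
        sel, path = escv_select(phi, y, VARConfig(seed=0))
        # lambda_cv within the top (sparsest) decade of the grid
        assert sel.idx_cv <= 25
        assert (np.abs(path.coefficients[sel.idx_escv, 1:]) > 0).sum() <= 2

    def test_strong_predictor_selected(self, rng):
        phi = np.column_stack([np.ones(60), rng.normal(size=(60, 8))])
        y = 3.0 * phi[:, 1] + 0.1 * rng.normal(size=60)
        sel, path = escv_select(phi, y, VARConfig(seed=0))
        assert abs(path.coefficients[sel.idx_escv, 1]) > 0.5

    def test_same_seed_same_folds_and_choice(self, rng):
        phi = np.column_stack([np.ones(50), rng.normal(size=(50, 5))])
        y = phi[:, 2] + 0.5 * rng.normal(size=50)
        lam1, folds1 = cross_validate(phi, y, VARConfig(seed=11))
        lam2, folds2 = cross_validate(phi, y, VARConfig(seed=11))
        assert lam1 == lam2
        for a, b in zip(folds1, folds2):
            np.testing.assert_array_equal(a, b)

    def test_es_metric_identical_fits_zero(self):
        yhat = np.tile(np.arange(1.0, 5.0), (4, 1))[:, :, None]
        assert es_metric(yhat)[0] == 0.0

    def test_es_metric_direct_evaluation(self):
        # two folds fitting (1,1) and (3,3): variance 2, mean-norm 8, ES 0.25
        yhat = np.array([[[1.0], [1.0]], [[3.0], [3.0]]])
        assert es_metric(yhat)[0] == pytest.approx(0.25)

    def test_es_metric_scale_invariant(self, rng):
        yhat = rng.normal(size=(5, 20, 7))
        np.testing.assert_allclose(es_metric(yhat), es_metric(3.7 * yhat))

    def test_es_zero_mean_fit_is_infinite(self):
        yhat = np.array([[[1.0], [-1.0]], [[-1.0], [1.0]]])
        assert np.isinf(es_metric(yhat)[0])


class TestSelectLambdaESCV:
    def test_single_local_minimum_above_cv(self):
        lambdas = np.array([8.0, 4.0, 2.0, 1.0, 0.5])
        es = np.array([0.5, 0.2, 0.4, 0.45, 0.3])
        assert select_lambda_escv(es, lambdas, lambda_cv=1.0) == 4.0

    def test_smallest_of_several_minima_above_cv(self):
        lambdas = np.array([8.0, 4.0, 2.0, 1.0, 0.5])
        es = np.array([0.5, 0.2, 0.4, 0.1, 0.3])
        assert select_lambda_escv(es, lambdas, lambda_cv=1.0) == 1.0

    def test_fallback_to_cv_choice(self):
        lambdas = np.array([8.0, 4.0, 2.0, 1.0, 0.5])
        es = np.array([0.5, 0.4, 0.3, 0.2, 0.1])  # monotone: no interior min
        assert select_lambda_escv(es, lambdas, lambda_cv=2.0) == 2.0

    def test_never_below_cv(self):
        lambdas = np.geomspace(10, 0.01, 30)
        rng = np.random.default_rng(0)
        for _ in range(20):
            es = rng.uniform(size=30)
            cv = float(rng.choice(lambdas))
            assert select_lambda_escv(es, lambdas, cv) >= cv


class TestDescriptionLength:
    def test_unit_rss(self):
        assert description_length(1.0, T=50, d=3) == pytest.approx(
            1.5 * np.log(50)
        )

    def test_direct_arithmetic(self):
        # T=100, RSS=e^2, d=2: 100 + ln 100
        assert description_length(np.e**2, 100, 2) == pytest.approx(
            100 + np.log(100)
        )

    def test_monotone_in_order(self):
        dls = [description_length(3.7, 80, d) for d in range(1, 10)]
        assert np.all(np.diff(dls) > 0)

    def test_zero_rss_sentinel(self):
        assert description_length(0.0, 50, 1) == -np.inf


class TestOrderSelection:
    def test_white_noise_prefers_order_one(self, rng):
        mat = latent_matrix(rng.normal(size=(2, 60)))
        sel = select_order(mat, "g00", VARConfig(d_max=5, seed=0))
        assert sel.d_opt == 1

    def test_var2_order_recovery_rate(self):
        # damped-oscillator lag-2 dynamics at T=60: MDL finds order 2 in
        # >= 80% of runs
        spec = VARSpec(
            k=3,
            d=2,
            A=[np.diag([0.2, 0.15, 0.25]), np.diag([-0.75, -0.7, -0.8])],
            noise_sd=1.0,
        )
        hits = 0
        runs = 40
        for seed in range(runs):
            data, _ = simulate_var(spec, T=60, seed=seed, snr=5)
            mat = latent_matrix(data)
            sel = select_order(mat, "g00", VARConfig(d_max=5, seed=seed))
            hits += sel.d_opt == 2
        assert hits / runs >= 0.8


class TestFitTarget:
    def test_single_driver_noiseless(self):
        # gene A at lag 2 drives gene B; B's fit keeps exactly that term
        k, T = 3, 80
        rng = np.random.default_rng(5)
        data = np.zeros((k, T))
        data[0] = rng.normal(size=T)
        data[2] = rng.normal(size=T)
        data[1, 2:] = 0.9 * data[0, :-2]
        mat = latent_matrix(data, genes=["A", "B", "C"])
        fit = fit_target(mat, "B", VARConfig(order=3, seed=0))
        keys = set(fit.coefficients)
        assert ("A", 2) in keys
        off_target = keys - {("A", 2), ("B", 1), ("B", 2), ("B", 3)}
        assert not off_target

    def test_deterministic_under_seed(self, rng):
        spec = make_sparse_spec(5, 2, 0.08, seed=2)
        data, _ = simulate_var(spec, T=60, seed=3)
        mat = latent_matrix(data)
        f1 = fit_target(mat, 1, VARConfig(order=2, seed=9))
        f2 = fit_target(mat, 1, VARConfig(order=2, seed=9))
        assert f1.coefficients == f2.coefficients
        assert f1.lambda_escv == f2.lambda_escv

    def test_escv_contract_sparser_than_cv(self):
        # lambda_escv >= lambda_cv and nnz(ES-CV) <= nnz(CV) on every fit
        for seed in range(6):
            spec = make_sparse_spec(8, 2, 0.06, seed=seed)
            data, _ = simulate_var(spec, T=80, seed=seed + 50, snr=5)
            mat = latent_matrix(data)
            for i in range(0, 8, 3):
                fit = fit_target(mat, i, VARConfig(order=2, seed=seed))
                assert fit.lambda_escv >= fit.lambda_cv
                assert fit.nnz_escv <= fit.nnz_cv
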