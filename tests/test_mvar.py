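"""Autoregressive estimators: design construction, OLS, penalized fits,
coordinate-descent optimality and LOOCV tuning."""

import numpy as np
import pytest
from sklearn.linear_model import ElasticNet

from grnstab import (
    CoefficientMatrix,
    ConnectivityMatrix,
    ExpressionMatrix,
    NoiseSpec,
    build_design,
    fit_ols,
    fit_penalized,
    loocv_tune,
    simulate_timeseries,
)
from grnstab.mvar import RegressionDesign, lambda_path
from grnstab._solvers import _objective, cd_path_gram


def random_design(n, p, seed, sparse_truth=True, noise=0.5):
    rng = np.random.default_rng(seed)
    Z = rng.normal(size=(n, p))
    beta = rng.normal(size=(p, p))
    if sparse_truth:
        beta *= rng.random((p, p)) < 0.4
    Y = Z @ beta + noise * rng.normal(size=(n, p))
    return RegressionDesign(Y=Y, Z=Z, gene_labels=[f"g{i}" for i in range(p)]), beta


class TestBuildDesign:
    def test_two_timepoint_alignment(self):
        data = ExpressionMatrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        design = build_design(data)
        assert design.Y.shape == design.Z.shape == (1, 3)
        np.testing.assert_array_equal(design.Z[0], [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(design.Y[0], [4.0, 5.0, 6.0])

    def test_row_count_is_t_minus_one(self, ten_gene_series):
        assert build_design(ten_gene_series).n_samples == 49

    def test_noiseless_series_satisfies_lag_equation(self, ten_gene_truth):
        _, coeffs = ten_gene_truth
        data = simulate_timeseries(
            coeffs, 20, noise=NoiseSpec(innovation_cov=0.0), seed=0
        )
        design = build_design(data)
        np.testing.assert_allclose(design.Y, design.Z @ coeffs.beta, atol=1e-10)

    def test_single_timepoint_rejected(self):
        with pytest.raises(ValueError):
            build_design(ExpressionMatrix(np.ones((3, 1))))


class TestFitOls:
    def test_recovers_truth_on_noiseless_full_rank_design(self):
        design, beta = random_design(20, 5, seed=1, noise=0.0)
        model = fit_ols(design)
        np.testing.assert_allclose(model.beta_hat, beta, atol=1e-8)

    def test_scalar_autoregression(self):
        z = np.arange(1.0, 9.0)
        design = RegressionDesign(
            Y=(0.5 * z)[:, None], Z=z[:, None], gene_labels=["g"]
        )
        assert fit_ols(design).beta_hat[0, 0] == pytest.approx(0.5)

    def test_matches_generic_least_squares_solver(self):
        design, _ = random_design(20, 5, seed=2)
        expected = np.linalg.lstsq(design.Z, design.Y, rcond=None)[0]
        np.testing.assert_allclose(fit_ols(design).beta_hat, expected, atol=1e-10)

    def test_rank_deficient_design_warns_and_flags(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(10, 4))
        Z[:, 3] = Z[:, 0] + Z[:, 1]  # exact collinearity
        design = RegressionDesign(Y=rng.normal(size=(10, 4)), Z=Z,
                                  gene_labels=list("abcd"))
        with pytest.warns(UserWarning):
            model = fit_ols(design)
        assert model.rank_deficient


class TestFitPenalized:
    def test_zero_penalty_equals_ols(self):
        design, _ = random_design(30, 6, seed=4)
        ols = fit_ols(design)
        for penalty in ("ridge", "lasso"):
            model = fit_penalized(design, penalty, 0.0, tol=1e-24)
            np.testing.assert_allclose(model.beta_hat, ols.beta_hat, atol=1e-8)

    @pytest.mark.parametrize("penalty,alpha", [("ridge", None), ("lasso", None),
                                               ("enet", 0.5)])
    def test_huge_penalty_shrinks_to_zero(self, penalty, alpha):
        design, _ = random_design(30, 6, seed=5)
        model = fit_penalized(design, penalty, 1e8, alpha)
        assert np.abs(model.beta_hat).max() < 1e-6

    def test_ridge_on_orthonormal_design_is_scaled_ols(self):
        rng = np.random.default_rng(6)
        Q, _ = np.linalg.qr(rng.normal(size=(30, 5)))
        design = RegressionDesign(Y=rng.normal(size=(30, 5)), Z=Q,
                                  gene_labels=list("abcde"))
        lam = 2.5
        ols = fit_ols(design)
        ridge = fit_penalized(design, "ridge", lam)
        np.testing.assert_allclose(
            ridge.beta_hat, ols.beta_hat / (1.0 + lam), atol=1e-10
        )

    def test_lasso_solution_is_objective_minimizer(self):
        """The fitted coefficients beat 200 random perturbations and satisfy
        the subgradient stationarity conditions of the lasso objective."""
        design, _ = random_design(30, 8, seed=7)
        lam = 0.1
        model = fit_penalized(design, "lasso", lam, tol=1e-14)
        Z, n = design.Z, design.n_samples
        rng = np.random.default_rng(8)
        for j in range(design.n_genes):
            y, b = design.Y[:, j], model.beta_hat[:, j]

            def objective(beta):
                return (
                    ((y - Z @ beta) ** 2).sum() / (2 * n)
                    + lam * np.abs(beta).sum()
                )

            obj = objective(b)
            for _ in range(200):
                assert obj <= objective(b + rng.normal(scale=0.05, size=b.shape)) + 1e-12
            # subgradient oracle: |Z'(y - Zb)/n| = lam on the support, <= lam off it
            grad = Z.T @ (y - Z @ b) / n
            on = b != 0
            np.testing.assert_allclose(grad[on], lam * np.sign(b[on]), atol=1e-6)
            assert (np.abs(grad[~on]) <= lam + 1e-6).all()

    @pytest.mark.parametrize("l1_ratio,lam", [(1.0, 0.05), (0.5, 0.1), (0.2, 0.3)])
    def test_matches_independent_coordinate_descent_oracle(self, l1_ratio, lam):
        design, _ = random_design(30, 8, seed=9)
        penalty = "lasso" if l1_ratio == 1.0 else "enet"
        alpha = None if l1_ratio == 1.0 else l1_ratio
        model = fit_penalized(design, penalty, lam, alpha, tol=1e-12)
        for j in range(design.n_genes):
            oracle = ElasticNet(
                alpha=lam, l1_ratio=l1_ratio, fit_intercept=False,
                tol=1e-12, max_iter=100_000,
            ).fit(design.Z, design.Y[:, j])
            np.testing.assert_allclose(
                model.beta_hat[:, j], oracle.coef_, atol=1e-5
            )

    def test_enet_alpha_one_equals_lasso(self):
        design, _ = random_design(25, 6, seed=10)
        lasso = fit_penalized(design, "lasso", 0.2)
        # alpha is validated to (0,1) for enet; 1 - 1e-12 is numerically lasso
        enet = fit_penalized(design, "enet", 0.2, 1.0 - 1e-12)
        np.testing.assert_allclose(enet.beta_hat, lasso.beta_hat, atol=1e-8)

    def test_enet_alpha_to_zero_approaches_ridge(self):
        design, _ = random_design(25, 6, seed=11)
        lam, alpha = 0.5, 1e-4
        enet = fit_penalized(design, "enet", lam, alpha, tol=1e-14)
        # closed-form ridge on the same 1/(2n) loss scale
        n, p = design.Z.shape
        G = design.Z.T @ design.Z
        expected = np.linalg.solve(
            G + n * lam * (1 - alpha) * np.eye(p), design.Z.T @ design.Y
        )
        assert np.abs(enet.beta_hat - expected).max() < 1e-4

    def test_invalid_arguments_rejected(self):
        design, _ = random_design(10, 3, seed=12)
        with pytest.raises(ValueError):
            fit_penalized(design, "lasso", -0.1)
        with pytest.raises(ValueError):
            fit_penalized(design, "enet", 0.1, 1.5)
        with pytest.raises(ValueError):
            fit_penalized(design, "elastic", 0.1)


class TestCoordinateDescentPath:
    def test_objective_non_increasing_across_sweeps(self):
        design, _ = random_design(30, 8, seed=13)
        Z, y = design.Z, design.Y[:, 0]
        G, Xy, yty, n = Z.T @ Z, Z.T @ y, float(y @ y), len(y)
        lam, l1 = 0.05, 1.0
        objs = []
        for sweeps in range(1, 12):
            coefs, _ = cd_path_gram(G, Xy, yty, n, np.array([lam]), l1, 0.0, sweeps)
            objs.append(_objective(G, Xy, yty, n, coefs[0], lam, l1))
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_warm_path_matches_cold_refits(self):
        design, _ = random_design(40, 8, seed=14)
        Z, y = design.Z, design.Y[:, 0]
        G, Xy, yty, n = Z.T @ Z, Z.T @ y, float(y @ y), len(y)
        grid = lambda_path(Z, y, 1.0, n_lambdas=30, standardize=False,
                           intercept=False)
        warm, _ = cd_path_gram(G, Xy, yty, n, grid, 1.0, 1e-13, 100_000)
        for k in (0, 10, 20, 29):
            cold, _ = cd_path_gram(G, Xy, yty, n, grid[k:k + 1], 1.0, 1e-13, 100_000)
            assert np.abs(warm[k] - cold[0]).max() < 1e-5

    def test_tuned_lasso_support_never_exceeds_sample_count(self, ten_gene_truth):
        # undersampled series (9 design rows, 10 genes): the tuned lasso
        # keeps at most n active coefficients per target
        _, coeffs = ten_gene_truth
        for seed in range(3):
            data = simulate_timeseries(coeffs, 10, seed=200 + seed)
            model = loocv_tune(data, "lasso")
            support_sizes = (model.beta_hat != 0).sum(axis=0)
            assert (support_sizes <= 9).all()


class TestLoocvTune:
    def test_single_candidate_grid_is_returned(self, ten_gene_series):
        model = loocv_tune(ten_gene_series, "lasso", lambda_grid=np.array([0.07]))
        assert (model.lambda_ == 0.07).all()

    def test_noiseless_lasso_finds_every_true_edge(self, ring_truth):
        """On noise-free data from a persistent truth, LOOCV lasso keeps all
        true edges (the regulators perfectly predict their targets).  Exact
        support is not guaranteed: a single trajectory spans an
        ill-conditioned Krylov subspace, and the cross-validation curves are
        degenerate near zero error."""
        support, coeffs = ring_truth
        for seed in (15, 16):
            data = simulate_timeseries(
                coeffs, 50, noise=NoiseSpec(innovation_cov=0.0), seed=seed
            )
            model = loocv_tune(data, "lasso")
            detected = np.abs(model.beta_hat) > 1e-4
            assert detected[support.adjacency == 1].all()

    def test_noiseless_lasso_support_is_exact_on_full_rank_designs(self):
        """With a well-conditioned design and an exactly sparse response,
        the lasso support equals the true support across a penalty range."""
        rng = np.random.default_rng(21)
        Z = rng.normal(size=(49, 10))
        beta = np.zeros((10, 10))
        mask = rng.random((10, 10)) < 0.15
        beta[mask] = rng.uniform(0.8, 1.0, mask.sum()) * rng.choice(
            [-1, 1], mask.sum()
        )
        design = RegressionDesign(
            Y=Z @ beta, Z=Z, gene_labels=[f"g{i}" for i in range(10)]
        )
        for lam in (1e-3, 1e-2):
            model = fit_penalized(design, "lasso", lam, tol=1e-12)
            np.testing.assert_array_equal(
                np.abs(model.beta_hat) > 1e-4, beta != 0
            )

    def test_ridge_prefers_smallest_penalty_when_noise_is_tiny(self, ring_truth):
        # strong persistent signal with negligible noise: bias dominates the
        # CV error, so every target picks the smallest ridge penalty
        _, coeffs = ring_truth
        data = simulate_timeseries(
            coeffs, 50, noise=NoiseSpec(innovation_cov=1e-10), seed=16
        )
        model = loocv_tune(data, "ridge")
        assert (model.lambda_ == 0.001).all()

    def test_enet_alpha_restricted_to_grid(self, ten_gene_series):
        model = loocv_tune(ten_gene_series, "enet")
        assert set(np.round(model.alpha, 1)) <= set(np.round(np.arange(0.1, 1.0, 0.1), 1))

    def test_deterministic(self, ten_gene_series):
        a = loocv_tune(ten_gene_series, "lasso")
        b = loocv_tune(ten_gene_series, "lasso")
        np.testing.assert_array_equal(a.beta_hat, b.beta_hat)

    def test_invalid_inputs_rejected(self, ten_gene_series):
        with pytest.raises(ValueError):
            loocv_tune(ten_gene_series, "ols")
        with pytest.raises(ValueError):
            loocv_tune(ten_gene_series, "lasso", lambda_grid=np.array([]))
        with pytest.raises(ValueError):
            loocv_tune(ExpressionMatrix(np.ones((3, 2))), "lasso")
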