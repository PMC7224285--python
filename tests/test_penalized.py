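import numpy as np
import pytest

from selstab.estimators import (
    ConvergenceError,
    PenaltySpec,
    fit_adaptive_enet,
    fit_penalized,
    fit_sparsestep,
    lambda_max,
    ols_fit,
    penalized_objective,
    selected_support,
)
from conftest import make_dataset


def _objective_of(fit, X, y, kind):
    return penalized_objective(
        X, y, fit.intercept, fit.coefficients, kind, fit.hyperparameters
    )


class TestAnalyticReductions:
    @pytest.mark.parametrize("kind", ["lasso", "ridge", "enet", "scad", "mcp"])
    def test_zero_penalty_recovers_ols(self, small_xy, kind):
        X, y = small_xy
        spec = PenaltySpec(lam=0.0, alpha=0.5, gamma=3.7 if kind == "scad" else 3.0)
        fit = fit_penalized((X, y), kind, spec, tol=1e-11)
        _, beta_ols = ols_fit(X, y)
        assert np.max(np.abs(fit.coefficients - beta_ols)) < 1e-8

    def test_sparsestep_zero_penalty_recovers_ols(self, small_xy):
        X, y = small_xy
        fit = fit_sparsestep((X, y), PenaltySpec(lam=0.0, gamma=1.0))
        _, beta_ols = ols_fit(X, y)
        assert np.max(np.abs(fit.coefficients - beta_ols)) < 1e-8

    def test_lambda_max_kills_every_coefficient(self, small_xy):
        X, y = small_xy
        lam = lambda_max(X, y)
        fit = fit_penalized((X, y), "lasso", PenaltySpec(lam=lam * 1.0001))
        assert np.all(fit.coefficients == 0.0)
        fit_below = fit_penalized((X, y), "lasso", PenaltySpec(lam=lam * 0.95))
        assert np.any(fit_below.coefficients != 0.0)

    def test_ridge_matches_closed_form_on_fixed_instance(self):
        X = np.array(
            [[1.0, 0.5, -1.0], [2.0, -0.3, 0.4], [0.1, 1.2, 0.2],
             [-1.0, 0.8, 1.5], [0.3, -1.1, -0.2], [1.4, 0.2, 0.6]]
        )
        y = np.array([1.0, 2.5, -0.3, 0.8, -1.2, 2.0])
        lam = 0.7
        fit = fit_penalized((X, y), "ridge", PenaltySpec(lam=lam), tol=1e-12)
        n = len(y)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        beta = np.linalg.solve(Xc.T @ Xc / n + lam * np.eye(3), Xc.T @ yc / n)
        assert np.max(np.abs(fit.coefficients - beta)) < 1e-8

    def test_enet_alpha_one_is_lasso_and_zero_is_ridge(self, small_xy):
        X, y = small_xy
        lam = 0.2
        lasso = fit_penalized((X, y), "lasso", PenaltySpec(lam=lam), tol=1e-11)
        enet1 = fit_penalized((X, y), "enet", PenaltySpec(lam=lam, alpha=1.0), tol=1e-11)
        assert np.max(np.abs(lasso.coefficients - enet1.coefficients)) < 1e-8
        ridge = fit_penalized((X, y), "ridge", PenaltySpec(lam=lam), tol=1e-11)
        enet0 = fit_penalized((X, y), "enet", PenaltySpec(lam=lam, alpha=0.0), tol=1e-11)
        assert np.max(np.abs(ridge.coefficients - enet0.coefficients)) < 1e-8

    def test_mcp_limit_is_lasso_at_huge_gamma(self, small_xy):
        X, y = small_xy
        # unit-second-moment columns so the internal MCP scale matches the
        # lasso penalty scale exactly
        Xc = X - X.mean(axis=0)
        Xu = Xc / np.sqrt(np.mean(Xc**2, axis=0))
        lam = 0.15
        lasso = fit_penalized((Xu, y), "lasso", PenaltySpec(lam=lam), tol=1e-11)
        mcp = fit_penalized(
            (Xu, y), "mcp", PenaltySpec(lam=lam, gamma=1e6), tol=1e-11
        )
        assert np.max(np.abs(lasso.coefficients - mcp.coefficients)) < 1e-4


class TestPenalizedContracts:
    def test_objective_value_matches_recomputation(self, small_xy):
        X, y = small_xy
        for kind, spec in [
            ("lasso", PenaltySpec(lam=0.1)),
            ("enet", PenaltySpec(lam=0.1, alpha=0.4)),
            ("scad", PenaltySpec(lam=0.1, gamma=3.7)),
        ]:
            fit = fit_penalized((X, y), kind, spec)
            assert fit.objective_value == pytest.approx(
                _objective_of(fit, X, y, kind), rel=1e-12
            )
            assert np.isfinite(fit.objective_value)

    def test_support_is_exactly_the_nonzeros(self, small_xy):
        X, y = small_xy
        fit = fit_penalized((X, y), "lasso", PenaltySpec(lam=0.3))
        nz = {fit.covariate_ids[j] for j in np.flatnonzero(fit.coefficients)}
        assert set(fit.support) == nz == selected_support(fit)

    @pytest.mark.parametrize(
        "kind, gamma",
        [("lasso", float("nan")), ("scad", 3.7), ("mcp", 3.0),
         ("sparsestep", 0.01)],
    )
    def test_support_size_nonincreasing_in_lambda(self, small_xy, kind, gamma):
        X, y = small_xy
        if kind == "sparsestep":
            # lambda prices covariates on the single-coordinate RSS-gain scale
            Xc = X - X.mean(axis=0)
            c = Xc.T @ (y - y.mean()) / len(y)
            lam_hi = float(np.max(c**2 / np.mean(Xc**2, axis=0))) * 2
        else:
            lam_hi = lambda_max(X, y) * (2.0 if kind != "lasso" else 1.0)
        sizes = []
        for lam in np.geomspace(lam_hi, lam_hi * 1e-3, 30):
            spec = PenaltySpec(lam=lam, gamma=gamma)
            if kind == "sparsestep":
                fit = fit_sparsestep((X, y), spec)
            else:
                fit = fit_penalized((X, y), kind, spec)
            sizes.append(len(fit.support))
        assert all(a <= b for a, b in zip(sizes, sizes[1:]))

    def test_coordinate_descent_objective_monotone_per_sweep(self, small_xy):
        """Each coordinate-descent sweep is non-increasing in the loss."""
        from selstab import _cd

        X, y = small_xy
        p = X.shape[1]
        spec = PenaltySpec(lam=0.15, alpha=0.7)
        G, c, y_mean, x_means = _cd.gram_arrays(X, y)
        beta = np.zeros(p)
        l1 = np.full(p, spec.lam * spec.alpha)
        l2 = np.full(p, spec.lam * (1 - spec.alpha))
        prev = np.inf
        for _ in range(25):
            _cd.cd_gram(G, c, beta, l1, l2, _cd.KIND_ENET, 0.0, 0.0, 1)
            intercept = y_mean - float(x_means @ beta)
            obj = penalized_objective(X, y, intercept, beta, "enet", spec)
            assert obj <= prev + 1e-12
            prev = obj

    def test_nonconvergence_raises_with_last_iterate(self, small_xy):
        X, y = small_xy
        with pytest.raises(ConvergenceError) as exc:
            fit_penalized((X, y), "lasso", PenaltySpec(lam=1e-4), max_iter=1)
        assert exc.value.coefficients.shape == (X.shape[1],)
        assert exc.value.iterations == 1


class TestAdaptiveEnet:
    def test_gamma_zero_equals_plain_enet(self, small_xy):
        X, y = small_xy
        spec = PenaltySpec(lam=0.1, alpha=0.5, gamma=0.0)
        aenet = fit_adaptive_enet((X, y), spec, tol=1e-11)
        enet = fit_penalized(
            (X, y), "enet", PenaltySpec(lam=0.1, alpha=0.5), tol=1e-11
        )
        # gamma = 0 gives unit weights, but stage 2 only refits the stage-1
        # support; on it the fits agree
        active = np.flatnonzero(enet.coefficients)
        assert np.max(np.abs(aenet.coefficients[active] - enet.coefficients[active])) < 1e-6

    def test_stage1_zero_excluded_from_final_support(self, small_xy):
        X, y = small_xy
        spec = PenaltySpec(lam=0.3, alpha=1.0, gamma=1.0)
        stage1 = fit_penalized((X, y), "lasso", PenaltySpec(lam=0.3))
        aenet = fit_adaptive_enet(
            (X, y), spec, stage1=stage1
        )
        assert set(aenet.support) <= set(stage1.support)

    def test_all_zero_stage1_gives_intercept_only(self, small_xy):
        X, y = small_xy
        lam = lambda_max(X, y) * 2
        fit = fit_adaptive_enet((X, y), PenaltySpec(lam=lam, alpha=1.0, gamma=1.0))
        assert fit.support == ()
        assert fit.intercept == pytest.approx(float(np.mean(y)))

    def test_stage2_objective_dominates_stage1_point(self, rng):
        n, p = 80, 5
        X = rng.standard_normal((n, p))
        y = 2 * X[:, 0] - 1.5 * X[:, 1] + rng.normal(0, 0.5, n)
        spec = PenaltySpec(lam=0.08, alpha=0.6, gamma=1.0)
        stage1 = fit_penalized((X, y), "enet", PenaltySpec(lam=0.08, alpha=0.6))
        aenet = fit_adaptive_enet((X, y), spec, stage1=stage1)
        full_spec = aenet.hyperparameters
        obj_stage2 = penalized_objective(
            X, y, aenet.intercept, aenet.coefficients, "aenet", full_spec
        )
        obj_stage1_point = penalized_objective(
            X, y, stage1.intercept, stage1.coefficients, "aenet", full_spec
        )
        assert obj_stage2 <= obj_stage1_point + 1e-10


class TestSparseStep:
    def test_penalty_limits(self):
        from selstab.estimators import sparsestep_penalty

        assert sparsestep_penalty(np.array([0.0]), 2.0, 1.0)[0] == 0.0
        assert sparsestep_penalty(np.array([1e8]), 2.0, 1.0)[0] == pytest.approx(2.0)

    def test_univariate_matches_grid_search(self):
        rng = np.random.default_rng(8)
        n = 50
        x = rng.standard_normal(n)
        y = 1.2 * x + rng.normal(0, 0.4, n)
        spec = PenaltySpec(lam=0.3, gamma=0.5)
        fit = fit_sparsestep((x[:, None], y), spec)
        xc = x - x.mean()
        yc = y - y.mean()
        grid = np.linspace(-3, 3, 60001)
        vals = [
            np.sum((yc - b * xc) ** 2) / (2 * n)
            + spec.lam * b**2 / (b**2 + spec.gamma**2)
            for b in grid
        ]
        b_star = grid[int(np.argmin(vals))]
        assert fit.coefficients[0] == pytest.approx(b_star, abs=1e-4)
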