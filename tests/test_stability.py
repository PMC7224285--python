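import numpy as np
import pytest

from selstab.datasets import ConfigurationError
from selstab.estimators import LinearFit
from selstab.model_selection import repeated_kfold_cv
from selstab.stability import (
    StabilityResult,
    aggregate_stability,
    bootstrap_stability,
    refit_subset_cv,
    stability_spearman,
    stable_subsets,
)


def _stub_selector(ids, chooser):
    """A fake fitting routine selecting covariates via `chooser(rng)`."""

    def fit(X, y, rng):
        chosen = chooser(rng)
        coefs = np.zeros(len(ids))
        for cid in chosen:
            coefs[ids.index(cid)] = 1.0
        return LinearFit(
            method="lasso",
            intercept=0.0,
            coefficients=coefs,
            covariate_ids=ids,
            support=tuple(chosen),
        )

    return fit


def _stab(method, ids, pct):
    return StabilityResult(
        method=method,
        n_bootstraps=500,
        covariate_ids=list(ids),
        selection_pct=np.asarray(pct, dtype=float),
        coef_distributions={},
        bootstrap_seed=0,
    )


class TestBootstrapStability:
    def test_constant_selector_gives_zero_one_hundred(self, small_ds):
        ids = small_ds.covariate_ids
        fit_fn = _stub_selector(ids, lambda rng: [ids[0], ids[1]])
        res = bootstrap_stability(small_ds, fit_fn, B=25, seed=0)
        assert res.selection_pct[0] == 100.0
        assert res.selection_pct[1] == 100.0
        assert np.all(res.selection_pct[2:] == 0.0)
        assert set(res.coef_distributions) == {ids[0], ids[1]}

    def test_bernoulli_selector_matches_binomial_band(self, small_ds):
        """A stub selecting covariate 1 with probability 0.5 lands inside the
        3-sigma binomial band at B=500."""
        ids = small_ds.covariate_ids
        fit_fn = _stub_selector(
            ids, lambda rng: [ids[0]] if rng.random() < 0.5 else []
        )
        res = bootstrap_stability(small_ds, fit_fn, B=500, seed=3)
        band = 3 * np.sqrt(0.25 / 500) * 100
        assert abs(res.selection_pct[0] - 50.0) < band

    def test_single_bootstrap_gives_zero_or_hundred(self, small_ds):
        ids = small_ds.covariate_ids
        fit_fn = _stub_selector(ids, lambda rng: [ids[2]])
        res = bootstrap_stability(small_ds, fit_fn, B=1, seed=0)
        assert set(np.unique(res.selection_pct)) <= {0.0, 100.0}

    def test_excess_failures_abort(self, small_ds):
        def failing(X, y, rng):
            raise RuntimeError("unstable")

        with pytest.raises(ConfigurationError, match="unstable"):
            bootstrap_stability(small_ds, failing, B=20, seed=0)

    def test_rare_failures_excluded_from_denominator(self, small_ds):
        ids = small_ds.covariate_ids
        state = {"n": 0}

        def mostly_ok(X, y, rng):
            state["n"] += 1
            if state["n"] == 1:
                raise RuntimeError("one bad resample")
            return _stub_selector(ids, lambda r: [ids[0]])(X, y, rng)

        res = bootstrap_stability(small_ds, mostly_ok, B=30, seed=0)
        assert res.n_failures == 1
        assert res.n_bootstraps == 29
        assert res.selection_pct[0] == 100.0


class TestAggregation:
    def test_identical_vectors_collapse(self):
        ids = ["V1", "V2"]
        rs = [_stab(m, ids, [70, 10]) for m in ("lasso", "mcp", "scad")]
        summary = aggregate_stability(rs, include=("lasso", "mcp", "scad"))
        assert np.allclose(summary.max_stability, [70, 10])
        assert np.allclose(summary.median_stability, [70, 10])

    def test_eight_method_median_and_max(self):
        """Stability profile of a dominant covariate across eight methods:
        (100,100,65,100,100,100,99,100) has median 100 and max 100."""
        ids = ["V40"]
        vals = [100, 100, 65, 100, 100, 100, 99, 100]
        methods = ["scad", "lasso", "mars", "mcp", "aenet", "enet", "rbvs",
                   "sparsestep"]
        rs = [_stab(m, ids, [v]) for m, v in zip(methods, vals)]
        summary = aggregate_stability(rs, include=methods)
        assert summary.max_stability[0] == 100.0
        assert summary.median_stability[0] == 100.0

    def test_single_high_method_does_not_move_the_median(self):
        ids = ["V1"]
        methods = ["mars", "lasso", "enet", "aenet", "scad", "mcp",
                   "sparsestep", "rbvs"]
        vals = [95, 0, 0, 0, 0, 0, 0, 0]
        rs = [_stab(m, ids, [v]) for m, v in zip(methods, vals)]
        summary = aggregate_stability(rs, include=methods)
        assert summary.max_stability[0] == 95.0
        assert summary.median_stability[0] == 0.0

    def test_mismatched_covariates_rejected(self):
        rs = [_stab("lasso", ["V1"], [10]), _stab("mcp", ["V2"], [10])]
        with pytest.raises(ConfigurationError):
            aggregate_stability(rs, include=("lasso", "mcp"))


class TestStableSubsets:
    def test_strict_threshold_boundary(self):
        rs = [_stab(m, ["V1", "V2"], [90.0, 90.5]) for m in ("lasso", "mcp")]
        summary = aggregate_stability(rs, include=("lasso", "mcp"))
        summary = stable_subsets(summary)
        assert summary.any90_set == {"V2"}  # 90.0 exactly is excluded

    def test_all_zero_stability_gives_empty_sets(self):
        rs = [_stab(m, ["V1"], [0.0]) for m in ("lasso", "mcp")]
        summary = stable_subsets(aggregate_stability(rs, include=("lasso", "mcp")))
        assert summary.any90_set == set() and summary.median50_set == set()


class TestRefitSubsetCv:
    def test_full_subset_equals_full_ols_cv(self, small_ds):
        from selstab.methods import _OlsModel

        cv_sub = refit_subset_cv(small_ds, small_ds.covariate_ids, k=5,
                                 repeats=1, seed=0)
        cols = list(range(small_ds.p))
        cv_full = repeated_kfold_cv(
            small_ds, lambda X, y: _OlsModel(X, y, cols), k=5, repeats=1, seed=0
        )
        assert cv_sub.cv_mae == pytest.approx(cv_full.cv_mae)

    def test_true_support_attains_generating_r2(self, small_ds, small_spec):
        ids = [f"V{j + 1}" for j in small_spec.true_support]
        cv = refit_subset_cv(small_ds, ids, k=5, repeats=2, seed=0)
        # attainable R^2 from the generating spec: signal / (signal + noise)
        signal = 0.25 * sum(b**2 for b in small_spec.true_coefficients)
        attainable = signal / (signal + small_spec.noise_sd**2)
        assert abs(cv.cv_r2 - attainable) < 0.05

    def test_adding_noise_covariate_never_hurts_internal_fit(self, small_ds):
        base = refit_subset_cv(small_ds, ["V1", "V7"], k=5, repeats=1, seed=0)
        bigger = refit_subset_cv(small_ds, ["V1", "V7", "V12"], k=5,
                                 repeats=1, seed=0)
        assert bigger.internal_r2 >= base.internal_r2 - 1e-12

    def test_empty_subset_rejected(self, small_ds):
        with pytest.raises(ConfigurationError, match="null"):
            refit_subset_cv(small_ds, [])


class TestSpearman:
    def test_identical_and_reversed_rankings(self):
        p = 20
        up = list(range(p))
        rs = [
            _stab("lasso", [f"V{i}" for i in range(p)], up),
            _stab("enet", [f"V{i}" for i in range(p)], up),
            _stab("mcp", [f"V{i}" for i in range(p)], up[::-1]),
        ]
        mat, methods = stability_spearman(rs)
        assert mat[0, 1] == pytest.approx(1.0)
        assert mat[0, 2] == pytest.approx(-1.0)
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)

    def test_constant_vector_flagged_as_undefined(self):
        rs = [
            _stab("lasso", ["V1", "V2", "V3"], [10, 50, 90]),
            _stab("ridge", ["V1", "V2", "V3"], [100, 100, 100]),
        ]
        mat, _ = stability_spearman(rs)
        assert np.isnan(mat[0, 1])

    def test_independent_vectors_weakly_correlated(self, rng):
        p = 337
        ids = [f"V{i}" for i in range(p)]
        rs = [
            _stab("lasso", ids, rng.uniform(0, 100, p)),
            _stab("mcp", ids, rng.uniform(0, 100, p)),
        ]
        mat, _ = stability_spearman(rs)
        assert abs(mat[0, 1]) < 0.15
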