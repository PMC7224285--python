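import numpy as np
import pytest

from selstab.datasets import ConfigurationError
from selstab.model_selection import (
    fold_indices,
    mae,
    r_squared,
    repeated_kfold_cv,
    tune_hyperparameters,
)


class _Mean:
    def __init__(self, X, y):
        self.m = float(np.mean(y))

    def predict(self, X):
        return np.full(X.shape[0], self.m)


class TestMetrics:
    def test_mae_values(self):
        assert mae([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert mae([0.0, 2.0], [1.0, 1.0]) == 1.0
        # the outcome's median/IQR values used as a toy vector against their mean
        y = np.array([197.0, 120.0, 297.0])
        assert mae(y, np.full(3, y.mean())) == pytest.approx(61.556, abs=0.01)

    def test_mae_rejects_mismatched_lengths(self):
        with pytest.raises(ConfigurationError):
            mae([1.0], [1.0, 2.0])

    def test_r_squared_values(self, rng):
        y = rng.normal(0, 1, 50)
        assert r_squared(y, y) == 1.0
        assert r_squared(y, np.full(50, y.mean())) == pytest.approx(0.0)
        assert r_squared(y, -3 * y) < 0.0
        with pytest.raises(ConfigurationError):
            r_squared(np.ones(5), np.zeros(5))


class TestRepeatedKFold:
    def test_every_row_held_out_once_per_repeat(self):
        folds = fold_indices(53, k=5, repeats=3, seed=0)
        assert len(folds) == 15
        for r in range(3):
            held = np.concatenate([te for _, te in folds[r * 5 : (r + 1) * 5]])
            assert np.array_equal(np.sort(held), np.arange(53))

    def test_k_times_repeats_fits_performed(self, rng):
        X = rng.standard_normal((40, 2))
        y = rng.normal(0, 1, 40)
        calls = []

        def fit_fn(Xt, yt):
            calls.append(len(yt))
            return _Mean(Xt, yt)

        cv = repeated_kfold_cv((X, y), fit_fn, k=10, repeats=10, seed=0)
        assert len(calls) == 101  # 100 fold fits + 1 internal fit
        assert cv.per_fold_mae.shape == (100,)
        assert cv.cv_mae == pytest.approx(float(np.mean(cv.per_fold_mae)))

    def test_bitwise_reproducibility_under_a_seed(self, rng):
        X = rng.standard_normal((60, 3))
        y = rng.normal(0, 1, 60)
        a = repeated_kfold_cv((X, y), _Mean, k=5, repeats=2, seed=9)
        b = repeated_kfold_cv((X, y), _Mean, k=5, repeats=2, seed=9)
        assert a.cv_mae == b.cv_mae
        assert np.array_equal(a.per_fold_mae, b.per_fold_mae)

    def test_intercept_only_cv_mae_matches_gaussian_mad(self, rng):
        # for y ~ N(mu, sigma), the mean-model MAE converges to sigma*sqrt(2/pi)
        sigma = 3.0
        y = rng.normal(10.0, sigma, 2000)
        X = np.zeros((2000, 1))
        cv = repeated_kfold_cv((X, y), _Mean, k=10, repeats=2, seed=0)
        expected = sigma * np.sqrt(2 / np.pi)
        assert abs(cv.cv_mae - expected) / expected < 0.05

    def test_fold_failures_marked_incomplete(self, rng):
        X = rng.standard_normal((30, 2))
        y = rng.normal(0, 1, 30)
        state = {"n": 0}

        def flaky(Xt, yt):
            state["n"] += 1
            if state["n"] == 2:
                raise RuntimeError("boom")
            return _Mean(Xt, yt)

        cv = repeated_kfold_cv((X, y), flaky, k=5, repeats=1, seed=0)
        assert cv.incomplete
        assert len(cv.per_fold_mae) == 4


class TestTuning:
    def test_single_candidate_grid_returns_it(self, rng):
        X = rng.standard_normal((40, 2))
        y = rng.normal(0, 1, 40)
        result = tune_hyperparameters(
            (X, y), lambda cand: _Mean, ["only"], k=5, repeats=1, seed=0
        )
        assert result.best == "only"

    def test_fold_assignments_shared_across_candidates(self, rng):
        X = rng.standard_normal((45, 2))
        y = rng.normal(0, 1, 45)
        seen = {}

        def factory(cand):
            def fit_fn(Xt, yt):
                seen.setdefault(cand, []).append(hash(yt.tobytes()))
                return _Mean(Xt, yt)

            return fit_fn

        tune_hyperparameters(
            (X, y), factory, ["a", "b"], k=5, repeats=2, seed=3,
            compute_best_cv=False,
        )
        assert seen["a"] == seen["b"]

    def test_strong_regularisation_wins_on_pure_noise(self, rng):
        from selstab.estimators import PenaltySpec, fit_penalized

        n, p = 80, 60
        X = rng.standard_normal((n, p))
        y = rng.normal(0, 1, n)

        def factory(lam):
            return lambda Xt, yt: fit_penalized(
                (Xt, yt), "lasso", PenaltySpec(lam=lam), tol=1e-5
            )

        result = tune_hyperparameters(
            (X, y), factory, [1e6, 1e-4], k=5, repeats=1, seed=0,
            compute_best_cv=False,
        )
        assert result.best == 1e6

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            tune_hyperparameters(
                (rng.standard_normal((20, 2)), rng.normal(0, 1, 20)),
                lambda c: _Mean,
                [],
            )
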