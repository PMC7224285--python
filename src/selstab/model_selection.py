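"""Repeated k-fold cross-validation, fit metrics and hyperparameter tuning.

The evaluation protocol is: tune hyperparameters once on the full data by
repeated k-fold cross-validation (default 10 folds, 10 repeats) minimising
the mean absolute error; then report, for the final model, both the
"internal" fit (metrics on the full training data) and the cross-validation
fit (metrics on held-out folds with hyperparameters held fixed).  The gap
between the two quantifies overfitting.

Fold partitions are simple seeded random splits (the outcome is continuous,
so no stratification); all candidates in a tuning grid share the same
partitions.  The CV MAE is the mean of the per-fold MAEs; the CV R-squared
is computed on the pooled held-out residuals, which is the more stable
choice at k = 10.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.model_selection import RepeatedKFold

from .datasets import ConfigurationError, Dataset

logger = logging.getLogger(__name__)


def mae(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute error."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ConfigurationError("y_true and y_pred must be equal-length, nonempty")
    return float(np.mean(np.abs(y_true - y_pred)))


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (may be negative)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ConfigurationError("y_true and y_pred must be equal-length, nonempty")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ConfigurationError("y_true has zero variance; R^2 undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


@dataclass
class CVResult:
    """Internal and cross-validated fit metrics for one model."""

    internal_mae: float
    internal_r2: float
    cv_mae: float
    cv_r2: float
    per_fold_mae: np.ndarray
    folds_seed: int
    k: int
    repeats: int
    incomplete: bool = False
    failures: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "internal_mae": self.internal_mae,
            "internal_r2": self.internal_r2,
            "cv_mae": self.cv_mae,
            "cv_r2": self.cv_r2,
            "k": self.k,
            "repeats": self.repeats,
            "folds_seed": self.folds_seed,
            "incomplete": self.incomplete,
        }


def fold_indices(
    n: int, k: int, repeats: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """The k * repeats (train, test) index pairs for a seeded partition."""
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if n < k:
        raise ConfigurationError("need at least k observations")
    splitter = RepeatedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.empty((n, 1)))]


def repeated_kfold_cv(
    data: Dataset | tuple[np.ndarray, np.ndarray],
    fit_fn: Callable[[np.ndarray, np.ndarray], object],
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated k-fold cross-validation of ``fit_fn``.

    ``fit_fn(X_train, y_train)`` must return an object with a
    ``predict(X)`` method; hyperparameters are the caller's business and stay
    fixed across folds.  Fold-level failures are logged, recorded on the
    result and the result marked incomplete.
    """
    if isinstance(data, Dataset):
        X, y = data.X, data.y
    else:
        X, y = np.asarray(data[0], float), np.asarray(data[1], float)
    folds = fold_indices(len(y), k, repeats, seed)
    per_fold = []
    failures: list[str] = []
    pooled_pred = np.empty(0)
    pooled_true = np.empty(0)
    for i, (tr, te) in enumerate(folds):
        try:
            model = fit_fn(X[tr], y[tr])
            pred = model.predict(X[te])
        except Exception as exc:  # noqa: BLE001 - surfaced on the result
            logger.warning("fold %d failed: %s", i, exc)
            failures.append(f"fold {i}: {exc}")
            continue
        per_fold.append(mae(y[te], pred))
        pooled_pred = np.concatenate([pooled_pred, pred])
        pooled_true = np.concatenate([pooled_true, y[te]])
    if not per_fold:
        raise ConfigurationError("every cross-validation fold failed")
    model_full = fit_fn(X, y)
    pred_full = model_full.predict(X)
    return CVResult(
        internal_mae=mae(y, pred_full),
        internal_r2=r_squared(y, pred_full),
        cv_mae=float(np.mean(per_fold)),
        cv_r2=r_squared(pooled_true, pooled_pred),
        per_fold_mae=np.asarray(per_fold),
        folds_seed=seed,
        k=k,
        repeats=repeats,
        incomplete=bool(failures),
        failures=failures,
    )


@dataclass
class TuningResult:
    """Grid, per-candidate CV error and the selected candidate."""

    grid: list
    cv_mae_per_candidate: np.ndarray
    best: object
    best_index: int
    best_cv: Optional[CVResult] = None

    def to_records(self) -> list[dict]:
        return [
            {"candidate": repr(c), "cv_mae": float(m)}
            for c, m in zip(self.grid, self.cv_mae_per_candidate)
        ]


def tune_hyperparameters(
    data: Dataset | tuple[np.ndarray, np.ndarray],
    fit_factory: Callable[[object], Callable[[np.ndarray, np.ndarray], object]],
    grid: Sequence[object],
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    compute_best_cv: bool = True,
) -> TuningResult:
    """Grid search by repeated k-fold CV with shared fold partitions.

    ``fit_factory(candidate)`` returns the ``fit_fn`` for that candidate.
    The winner attains the minimum CV MAE; among exact ties the
    first-listed candidate wins, so order grids with the sparser-inducing
    values (larger lambda, smaller nprune) first.
    """
    grid = list(grid)
    if not grid:
        raise ConfigurationError("tuning grid must be nonempty")
    if isinstance(data, Dataset):
        X, y = data.X, data.y
    else:
        X, y = np.asarray(data[0], float), np.asarray(data[1], float)
    folds = fold_indices(len(y), k, repeats, seed)
    scores = np.full(len(grid), np.inf)
    ok = np.zeros(len(grid), dtype=bool)
    for ci, cand in enumerate(grid):
        fit_fn = fit_factory(cand)
        per_fold = []
        try:
            for tr, te in folds:
                model = fit_fn(X[tr], y[tr])
                per_fold.append(mae(y[te], model.predict(X[te])))
            scores[ci] = float(np.mean(per_fold))
            ok[ci] = True
        except Exception as exc:  # noqa: BLE001
            logger.warning("candidate %r failed during tuning: %s", cand, exc)
    if not ok.any():
        raise ConfigurationError("all tuning candidates failed")
    best_index = int(np.argmin(scores))
    best = grid[best_index]
    best_cv = None
    if compute_best_cv:
        best_cv = repeated_kfold_cv(data, fit_factory(best), k, repeats, seed)
    return TuningResult(
        grid=grid,
        cv_mae_per_candidate=scores,
        best=best,
        best_index=best_index,
        best_cv=best_cv,
    )
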