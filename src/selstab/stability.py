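"""Bootstrap selection stability and cross-method triangulation.

For one method, selection stability of a covariate is the percentage of
bootstrap resamples (rows drawn with replacement, hyperparameters frozen at
their full-data tuned values) in which the refitted model selects that
covariate.  Triangulation aggregates the stability vectors of several
methods: the maximum and median stability per covariate, the covariates
exceeding 90% stability in at least one method, those with median stability
above 50%, and OLS refits of those stable subsets evaluated by repeated
k-fold cross-validation.  Agreement between methods is summarised by the
Spearman rank correlation of their stability vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats

from .datasets import ConfigurationError, Dataset
from .estimators import selected_support
from .methods import _OlsModel, bootstrap_fit_fn
from .model_selection import CVResult, repeated_kfold_cv

logger = logging.getLogger(__name__)

DEFAULT_TRIANGULATED = (
    "mars",
    "lasso",
    "enet",
    "aenet",
    "scad",
    "mcp",
    "sparsestep",
    "rbvs",
)


@dataclass
class StabilityResult:
    """Per-covariate selection percentages for one method over B bootstraps."""

    method: str
    n_bootstraps: int
    covariate_ids: list[str]
    selection_pct: np.ndarray
    coef_distributions: dict[str, dict[str, float]]
    bootstrap_seed: int
    n_failures: int = 0

    def __post_init__(self) -> None:
        self.selection_pct = np.asarray(self.selection_pct, dtype=float)
        if np.any(self.selection_pct < 0) or np.any(self.selection_pct > 100):
            raise ConfigurationError("selection percentages must lie in [0, 100]")

    def pct(self, cov_id: str) -> float:
        return float(self.selection_pct[self.covariate_ids.index(cov_id)])


@dataclass
class TriangulationSummary:
    """Cross-method stability aggregates and stable-subset refits."""

    methods_included: list[str]
    covariate_ids: list[str]
    max_stability: np.ndarray
    median_stability: np.ndarray
    any90_set: set[str] = field(default_factory=set)
    median50_set: set[str] = field(default_factory=set)
    consensus_set: set[str] = field(default_factory=set)
    refit_cv: dict[str, CVResult] = field(default_factory=dict)
    spearman: Optional[np.ndarray] = None
    spearman_methods: list[str] = field(default_factory=list)


def bootstrap_stability(
    data: Dataset,
    method_spec,
    B: int = 500,
    seed: int = 0,
    support_tol: float = 1e-3,
) -> StabilityResult:
    """Estimate selection stability for one method over B bootstrap resamples.

    ``method_spec`` is either a ``(method_tag, hyperparameters)`` pair (the
    tuned values are frozen across resamples) or a callable
    ``f(X, y, rng) -> fit`` for custom or stub selectors.  Each fitted model's
    support is read via :func:`selected_support`; the coefficient of a
    covariate is recorded whenever it is selected, and summarised by the
    2.5/50/97.5 percentiles.  Resamples where the fit raises are logged and
    excluded from the denominator; more than 10% failures aborts.
    """
    if B < 1:
        raise ConfigurationError("B must be >= 1")
    if callable(method_spec):
        method, fit_fn = "custom", method_spec
    else:
        method, hyper = method_spec
        fit_fn = bootstrap_fit_fn(data, method, hyper, seed)
    n = data.n
    ids = list(data.covariate_ids)
    index = {cid: j for j, cid in enumerate(ids)}
    counts = np.zeros(len(ids))
    coef_draws: dict[str, list[float]] = {cid: [] for cid in ids}
    failures = 0
    master = np.random.default_rng(seed)
    streams = master.spawn(B)
    for b in range(B):
        rng = streams[b]
        rows = rng.integers(0, n, size=n)
        try:
            fit = fit_fn(data.X[rows], data.y[rows], rng)
            support = selected_support(fit, tol=support_tol)
        except Exception as exc:  # noqa: BLE001 - logged and counted
            logger.warning("bootstrap resample %d failed: %s", b, exc)
            failures += 1
            if failures > 0.1 * B:
                raise ConfigurationError(
                    f"method unstable on this data: {failures} of {b + 1} "
                    "resamples failed"
                ) from exc
            continue
        coef_map = fit.coefficient_map() if hasattr(fit, "coefficient_map") else {}
        for cid in support:
            if cid in index:
                counts[index[cid]] += 1
                if cid in coef_map:
                    coef_draws[cid].append(coef_map[cid])
    denom = B - failures
    if denom == 0:
        raise ConfigurationError("all bootstrap resamples failed")
    pct = 100.0 * counts / denom
    distributions = {
        cid: {
            "q2.5": float(np.percentile(v, 2.5)),
            "median": float(np.percentile(v, 50)),
            "q97.5": float(np.percentile(v, 97.5)),
            "n_selected": len(v),
        }
        for cid, v in coef_draws.items()
        if v
    }
    return StabilityResult(
        method=method,
        n_bootstraps=denom,
        covariate_ids=ids,
        selection_pct=pct,
        coef_distributions=distributions,
        bootstrap_seed=seed,
        n_failures=failures,
    )


def aggregate_stability(
    results: Sequence[StabilityResult],
    include: Sequence[str] = DEFAULT_TRIANGULATED,
) -> TriangulationSummary:
    """Max and median stability per covariate over the included methods.

    The default exclusion of BSLR and ridge reflects their near-total
    covariate retention, which makes their stability vectors uninformative
    for triangulation.  The median over an even method count is the midpoint
    of the two middle order statistics.
    """
    by_method = {r.method: r for r in results}
    missing = [m for m in include if m not in by_method]
    chosen = [by_method[m] for m in include if m in by_method]
    if missing:
        logger.warning("stability results missing for: %s", ", ".join(missing))
    if not chosen:
        raise ConfigurationError("no stability results to aggregate")
    ids = chosen[0].covariate_ids
    for r in chosen:
        if r.covariate_ids != ids:
            raise ConfigurationError("stability results disagree on covariates")
    mat = np.vstack([r.selection_pct for r in chosen])
    return TriangulationSummary(
        methods_included=[r.method for r in chosen],
        covariate_ids=list(ids),
        max_stability=mat.max(axis=0),
        median_stability=np.median(mat, axis=0),
    )


def stable_subsets(
    summary: TriangulationSummary,
    any_threshold: float = 90.0,
    median_threshold: float = 50.0,
) -> TriangulationSummary:
    """Populate the strict-threshold stable covariate sets on ``summary``.

    ``any90_set``: stability strictly above ``any_threshold`` in at least one
    included method; ``median50_set``: median stability strictly above
    ``median_threshold``.
    """
    for thr in (any_threshold, median_threshold):
        if not 0.0 <= thr <= 100.0:
            raise ConfigurationError("thresholds must lie in [0, 100]")
    ids = np.array(summary.covariate_ids)
    summary.any90_set = set(ids[summary.max_stability > any_threshold])
    summary.median50_set = set(ids[summary.median_stability > median_threshold])
    return summary


def refit_subset_cv(
    data: Dataset,
    subset: Sequence[str],
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> CVResult:
    """OLS on a covariate subset, evaluated by repeated k-fold CV."""
    subset = sorted(set(subset))
    if not subset:
        raise ConfigurationError(
            "empty subset: report a null (intercept-only) model instead"
        )
    if len(subset) >= data.n:
        raise ConfigurationError("subset size must be below n")
    ids = list(data.covariate_ids)
    try:
        cols = [ids.index(cid) for cid in subset]
    except ValueError as exc:
        raise ConfigurationError(f"unknown covariate in subset: {exc}") from exc
    return repeated_kfold_cv(
        data, lambda X, y: _OlsModel(X, y, cols), k=k, repeats=repeats, seed=seed
    )


def stability_spearman(
    results: Sequence[StabilityResult],
) -> tuple[np.ndarray, list[str]]:
    """Pairwise Spearman correlation of the methods' stability vectors.

    Ties receive average ranks.  A method whose stability vector is constant
    has no ranking; its correlations are reported as NaN (undefined) rather
    than zero, with a logged warning.
    """
    if len(results) < 2:
        raise ConfigurationError("need at least two methods")
    ids = results[0].covariate_ids
    for r in results:
        if r.covariate_ids != ids:
            raise ConfigurationError("stability results disagree on covariates")
    m = len(results)
    out = np.eye(m)
    constant = [bool(np.ptp(r.selection_pct) == 0) for r in results]
    for r, flag in zip(results, constant):
        if flag:
            logger.warning(
                "method %s has a constant stability vector; its Spearman "
                "correlations are undefined",
                r.method,
            )
    for i in range(m):
        for j in range(i + 1, m):
            if constant[i] or constant[j]:
                rho = float("nan")
            else:
                rho = float(
                    stats.spearmanr(
                        results[i].selection_pct, results[j].selection_pct
                    ).statistic
                )
            out[i, j] = out[j, i] = rho
    return out, [r.method for r in results]
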