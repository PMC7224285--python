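"""Method registry: tuning, final fits and cross-validation per method tag.

The ten supported tags are ``bslr``, ``mars``, ``lasso``, ``ridge``,
``enet``, ``aenet``, ``scad``, ``mcp``, ``sparsestep`` and ``rbvs``.  This
module wires each tag to its estimator, its default hyperparameter grid and
an efficient tuner.  The penalized-family tuners fit descending-lambda paths
with warm starts inside each cross-validation fold (one path per fold per
(alpha, gamma) combination), so a 50-point lambda grid costs little more
than a single fit; the MARS tuner runs one forward pass per fold per degree
and evaluates every pruned size from the backward-deletion sequence.

Final-model conventions: RBVS reports OLS coefficients on its selected
support, and its cross-validation refits that OLS per fold (the selection
itself is re-run per resample only in the bootstrap-stability analysis);
BSLR re-runs its full stepwise search on every training split.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from . import _cd
from .datasets import ConfigurationError, Dataset
from .estimators import (
    LinearFit,
    sparsestep_solve,
    PenaltySpec,
    RbvsConfig,
    fit_adaptive_enet,
    fit_bslr,
    fit_penalized,
    fit_rbvs,
    fit_sparsestep,
    lambda_max,
    ols_fit,
)
from .mars import MarsModel, fit_mars, mars_sequence
from .model_selection import (
    CVResult,
    TuningResult,
    fold_indices,
    mae,
    r_squared,
    repeated_kfold_cv,
)

logger = logging.getLogger(__name__)

METHODS = (
    "bslr",
    "mars",
    "lasso",
    "ridge",
    "enet",
    "aenet",
    "scad",
    "mcp",
    "sparsestep",
    "rbvs",
)

TUNABLE = ("mars", "lasso", "ridge", "enet", "aenet", "scad", "mcp", "sparsestep")


class _OlsModel:
    """OLS on a fixed column subset, with predict()."""

    def __init__(self, X: np.ndarray, y: np.ndarray, cols: Sequence[int]):
        self.cols = list(cols)
        if self.cols:
            self.intercept, self.beta = ols_fit(X[:, self.cols], y)
        else:
            self.intercept, self.beta = float(np.mean(y)), np.empty(0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.cols:
            return np.full(X.shape[0], self.intercept)
        return self.intercept + X[:, self.cols] @ self.beta


# ---------------------------------------------------------------------------
# default grids
# ---------------------------------------------------------------------------

N_LAMBDA = 50
LAMBDA_MIN_RATIO = 1e-3
ALPHA_GRID = tuple(round(0.1 * i, 1) for i in range(1, 11))
SCAD_GAMMAS = (2.5, 3.7, 5.0)
MCP_GAMMAS = (1.5, 3.0, 5.0)
AENET_GAMMAS = (0.5, 1.0, 2.0)
SPARSESTEP_GAMMAS = (1e-4, 1e-3, 1e-2)
NPRUNE_GRID = tuple(range(2, 31))
DEGREE_GRID = (1, 2)


def lambda_grid(lam_hi: float, n_lambdas: int = N_LAMBDA,
                min_ratio: float = LAMBDA_MIN_RATIO) -> np.ndarray:
    return np.geomspace(lam_hi, lam_hi * min_ratio, n_lambdas)


# ---------------------------------------------------------------------------
# path-based tuners for the penalized family
# ---------------------------------------------------------------------------

def _path_predictions(X_tr, y_tr, X_te, kind, lambdas, alpha, gamma,
                      tol=1e-4, max_iter=5000):
    """Predictions on X_te for a warm-started descending-lambda path."""
    n, p = X_tr.shape
    G, c, y_mean, x_means = _cd.gram_arrays(X_tr, y_tr)
    preds = np.empty((len(lambdas), X_te.shape[0]))
    zeros = np.zeros(p)
    if kind == "ridge":
        d, V = scipy.linalg.eigh(G)
        d = np.maximum(d, 0.0)
        ctil = V.T @ c
        for i, lam in enumerate(lambdas):
            beta = V @ (ctil / (d + lam))
            preds[i] = (y_mean - x_means @ beta) + X_te @ beta
        return preds
    if kind in ("scad", "mcp"):
        s = np.sqrt(np.diag(G))
        s = np.where(s > 0, s, 1.0)
        Gw = G / np.outer(s, s)
        cw = c / s
        kind_code = _cd.KIND_SCAD if kind == "scad" else _cd.KIND_MCP
        beta_s = np.zeros(p)
        for i, lam in enumerate(lambdas):
            _cd.cd_gram(Gw, cw, beta_s, np.full(p, lam), zeros, kind_code,
                        gamma, tol, max_iter)
            beta = beta_s / s
            preds[i] = (y_mean - x_means @ beta) + X_te @ beta
        return preds
    # lasso / enet
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        l1 = np.full(p, lam * alpha)
        l2 = np.full(p, lam * (1 - alpha))
        _cd.cd_gram(G, c, beta, l1, l2, _cd.KIND_ENET, 0.0, tol, max_iter)
        preds[i] = (y_mean - x_means @ beta) + X_te @ beta
    return preds


def _tune_penalized(data, kind, k, repeats, seed, combos, lambda_for_combo):
    """Shared machinery: combos is a list of (alpha, gamma) pairs."""
    X, y = (data.X, data.y) if isinstance(data, Dataset) else data
    folds = fold_indices(len(y), k, repeats, seed)
    grids = {combo: lambda_for_combo(combo) for combo in combos}
    fold_mae = {combo: np.zeros((len(grids[combo]), len(folds))) for combo in combos}
    for fi, (tr, te) in enumerate(folds):
        for combo in combos:
            alpha, gamma = combo
            preds = _path_predictions(
                X[tr], y[tr], X[te], kind, grids[combo], alpha, gamma
            )
            fold_mae[combo][:, fi] = np.mean(np.abs(preds - y[te]), axis=1)
    candidates: list[PenaltySpec] = []
    scores: list[float] = []
    per_fold: list[np.ndarray] = []
    for combo in combos:
        alpha, gamma = combo
        means = fold_mae[combo].mean(axis=1)
        for li, lam in enumerate(grids[combo]):
            candidates.append(PenaltySpec(lam=float(lam), alpha=alpha, gamma=gamma))
            scores.append(float(means[li]))
            per_fold.append(fold_mae[combo][li])
    scores_arr = np.asarray(scores)
    best_index = int(np.argmin(scores_arr))  # lambda grids descend: ties -> sparser
    return candidates, scores_arr, per_fold, best_index, folds


def _internal_cv_result(data, method, hyper, candidates_fold_mae, folds, seed,
                        k, repeats):
    X, y = (data.X, data.y) if isinstance(data, Dataset) else data
    fit = fit_method(data, method, hyper)
    pred = fit.predict(X)
    return CVResult(
        internal_mae=mae(y, pred),
        internal_r2=r_squared(y, pred),
        cv_mae=float(np.mean(candidates_fold_mae)),
        cv_r2=float("nan"),
        per_fold_mae=np.asarray(candidates_fold_mae),
        folds_seed=seed,
        k=k,
        repeats=repeats,
    )


def tune_method(
    data: Dataset,
    method: str,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
    grids: Optional[dict] = None,
) -> TuningResult:
    """Tune a method's hyperparameters by repeated k-fold CV (minimum MAE).

    Returns a :class:`TuningResult` whose ``best`` is directly usable as the
    ``hyper`` argument of :func:`fit_method`.  ``bslr`` and ``rbvs`` have no
    tuned hyperparameters and return a single-candidate result.  For
    ``aenet``, pass ``grids={"enet_hyper": PenaltySpec(...)}`` to reuse an
    already-tuned elastic net for stage 1 (otherwise one is tuned here).
    """
    grids = grids or {}
    X, y = data.X, data.y
    if method in ("lasso", "ridge", "enet", "scad", "mcp"):
        lam_l = lambda_max(X, y)
        if method == "lasso":
            combos = [(1.0, float("nan"))]
            lam_for = lambda _c: grids.get("lambdas", lambda_grid(lam_l))
        elif method == "ridge":
            combos = [(0.0, float("nan"))]
            lam_for = lambda _c: grids.get(
                "lambdas", np.geomspace(lam_l * 1e3, lam_l * 1e-3, N_LAMBDA)
            )
        elif method == "enet":
            combos = [(a, float("nan")) for a in grids.get("alphas", ALPHA_GRID)]
            lam_for = lambda c: grids.get("lambdas", lambda_grid(lam_l / max(c[0], 1e-3)))
        else:
            gammas = grids.get(
                "gammas", SCAD_GAMMAS if method == "scad" else MCP_GAMMAS
            )
            combos = [(1.0, g) for g in gammas]
            G, c, _, _ = _cd.gram_arrays(X, y)
            s = np.sqrt(np.maximum(np.diag(G), 1e-12))
            lam_hi = float(np.max(np.abs(c / s)))
            # nonconvex paths: a higher lambda floor (coordinate descent is
            # slow and unstable in the dense, effectively-unpenalized tail)
            lam_for = lambda _c: grids.get("lambdas", lambda_grid(lam_hi, 30, 1e-2))
        cands, scores, per_fold, bi, folds = _tune_penalized(
            data, method, k, repeats, seed, combos, lam_for
        )
        best_cv = _internal_cv_result(
            data, method, cands[bi], per_fold[bi], folds, seed, k, repeats
        )
        return TuningResult(cands, scores, cands[bi], bi, best_cv)

    if method == "aenet":
        enet_hyper = grids.get("enet_hyper")
        if enet_hyper is None:
            enet_hyper = tune_method(data, "enet", k, repeats, seed, grids).best
        folds = fold_indices(len(y), k, repeats, seed)
        gammas = grids.get("gammas", AENET_GAMMAS)
        fold_mae = np.zeros((len(gammas), len(folds)))
        for fi, (tr, te) in enumerate(folds):
            stage1 = fit_penalized(
                (X[tr], y[tr]), "enet",
                PenaltySpec(lam=enet_hyper.lam, alpha=enet_hyper.alpha),
                tol=1e-6, max_iter=5000,
            )
            for gi, g in enumerate(gammas):
                fit = fit_adaptive_enet(
                    (X[tr], y[tr]),
                    PenaltySpec(lam=enet_hyper.lam, alpha=enet_hyper.alpha, gamma=g),
                    stage1=stage1, tol=1e-6, max_iter=5000,
                )
                fold_mae[gi, fi] = mae(y[te], fit.predict(X[te]))
        cands = [
            PenaltySpec(lam=enet_hyper.lam, alpha=enet_hyper.alpha, gamma=g)
            for g in gammas
        ]
        scores = fold_mae.mean(axis=1)
        bi = int(np.argmin(scores))
        best_cv = _internal_cv_result(data, method, cands[bi], fold_mae[bi],
                                      folds, seed, k, repeats)
        return TuningResult(cands, scores, cands[bi], bi, best_cv)

    if method == "sparsestep":
        folds = fold_indices(len(y), k, repeats, seed)
        gammas = grids.get("gammas", SPARSESTEP_GAMMAS)
        G, c, _, _ = _cd.gram_arrays(X, y)
        diag = np.maximum(np.diag(G), 1e-12)
        # lambda acts as an approximate per-covariate L0 price at small gamma,
        # so the grid spans the single-coordinate RSS gains
        lam_hi = float(np.max(c**2 / diag))
        lambdas = grids.get("lambdas", np.geomspace(lam_hi * 2, lam_hi * 1e-4, 12))
        fold_mae = np.zeros((len(gammas), len(lambdas), len(folds)))
        for fi, (tr, te) in enumerate(folds):
            Gf, cf, ym, xm = _cd.gram_arrays(X[tr], y[tr])
            for gi, g in enumerate(gammas):
                for li, lam in enumerate(lambdas):
                    beta = sparsestep_solve(Gf, cf, float(lam), g,
                                            tol=1e-6, max_iter=100)
                    pred = (ym - xm @ beta) + X[te] @ beta
                    fold_mae[gi, li, fi] = mae(y[te], pred)
        cands, scores = [], []
        for gi, g in enumerate(gammas):
            for li, lam in enumerate(lambdas):  # lambda descends: ties -> sparser
                cands.append(PenaltySpec(lam=float(lam), gamma=g))
                scores.append(float(fold_mae[gi, li].mean()))
        scores_arr = np.asarray(scores)
        bi = int(np.argmin(scores_arr))
        gi, li = divmod(bi, len(lambdas))
        best_cv = _internal_cv_result(
            data, method, cands[bi], fold_mae[gi, li], folds, seed, k, repeats,
        )
        return TuningResult(cands, scores_arr, cands[bi], bi, best_cv)

    if method == "mars":
        folds = fold_indices(len(y), k, repeats, seed)
        nprunes = tuple(grids.get("nprunes", NPRUNE_GRID))
        degrees = tuple(grids.get("degrees", DEGREE_GRID))
        max_terms = min(2 * max(nprunes) + 1, 2 * X.shape[1] + 1)
        fold_mae = np.full((len(degrees), len(nprunes), len(folds)), np.nan)
        for fi, (tr, te) in enumerate(folds):
            for di, deg in enumerate(degrees):
                terms, subsets, _rss, B, term_ids = mars_sequence(
                    _as_dataset(X[tr], y[tr], list(data.covariate_ids)),
                    max_terms, deg,
                )
                # basis columns of the forward-pass terms on the held-out rows
                model_all = MarsModel(
                    basis_terms=list(terms),
                    term_coefficients=np.zeros(len(terms)),
                    intercept=0.0,
                    degree=deg,
                    nprune=len(terms) + 1,
                    covariate_ids=term_ids,
                )
                B_te = model_all.basis_matrix(X[te])
                for ni, npr in enumerate(nprunes):
                    want = min(npr - 1, len(terms))
                    keep = subsets[len(terms) - want]
                    if keep:
                        D = np.column_stack([np.ones(len(tr)), B[:, keep]])
                        coefs, *_ = np.linalg.lstsq(D, y[tr], rcond=None)
                        pred = coefs[0] + B_te[:, keep] @ coefs[1:]
                    else:
                        pred = np.full(len(te), float(np.mean(y[tr])))
                    fold_mae[di, ni, fi] = mae(y[te], pred)
        cands, scores = [], []
        for di, deg in enumerate(degrees):
            for ni, npr in enumerate(nprunes):
                cands.append({"nprune": npr, "degree": deg})
                scores.append(float(fold_mae[di, ni].mean()))
        scores_arr = np.asarray(scores)
        bi = int(np.argmin(scores_arr))  # nprune ascends: ties -> sparser
        di, ni = divmod(bi, len(nprunes))
        best_cv = _internal_cv_result(
            data, method, cands[bi], fold_mae[di, ni], folds, seed, k, repeats
        )
        return TuningResult(cands, scores_arr, cands[bi], bi, best_cv)

    if method in ("bslr", "rbvs"):
        hyper = None if method == "bslr" else {"config": grids.get("config", RbvsConfig())}
        return TuningResult([hyper], np.array([float("nan")]), hyper, 0, None)

    raise ConfigurationError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# final fits and CV
# ---------------------------------------------------------------------------

def fit_method(
    data: Dataset | tuple[np.ndarray, np.ndarray],
    method: str,
    hyper=None,
    seed: int = 0,
):
    """Fit one of the ten methods with fixed hyperparameters."""
    if method in ("lasso", "ridge", "enet", "scad", "mcp"):
        return fit_penalized(data, method, hyper)
    if method == "aenet":
        return fit_adaptive_enet(data, hyper)
    if method == "sparsestep":
        return fit_sparsestep(data, hyper)
    if method == "mars":
        hyper = hyper or {}
        return fit_mars(data, nprune=hyper.get("nprune", 20),
                        degree=hyper.get("degree", 1))
    if method == "bslr":
        return fit_bslr(data)
    if method == "rbvs":
        hyper = hyper or {}
        return fit_rbvs(data, hyper.get("config", RbvsConfig()), seed=seed)
    raise ConfigurationError(f"unknown method {method!r}")


def cv_method(
    data: Dataset,
    method: str,
    hyper=None,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated k-fold CV of a final model with hyperparameters held fixed."""
    ids = list(data.covariate_ids)
    if method == "rbvs":
        hyper = hyper or {}
        support = hyper.get("support")
        if support is None:
            support = fit_rbvs(data, hyper.get("config", RbvsConfig()), seed=seed).support
        cols = [ids.index(cid) for cid in support]
        fit_fn = lambda X, y: _OlsModel(X, y, cols)
    elif method == "mars":
        hp = dict(hyper or {})
        fit_fn = lambda X, y: fit_mars(
            _as_dataset(X, y, ids), nprune=hp.get("nprune", 20),
            degree=hp.get("degree", 1),
        )
    elif method == "bslr":
        fit_fn = lambda X, y: fit_bslr((X, y))
    elif method == "aenet":
        fit_fn = lambda X, y: fit_adaptive_enet((X, y), hyper, tol=1e-6, max_iter=5000)
    elif method == "sparsestep":
        fit_fn = lambda X, y: fit_sparsestep((X, y), hyper)
    else:
        fit_fn = lambda X, y: fit_penalized((X, y), method, hyper,
                                            tol=1e-6, max_iter=5000)
    return repeated_kfold_cv(data, fit_fn, k=k, repeats=repeats, seed=seed)


def _as_dataset(X: np.ndarray, y: np.ndarray, ids: list[str]) -> Dataset:
    return Dataset(
        X=X, y=y, covariate_ids=ids,
        covariate_kind=["continuous"] * len(ids),
    )


def bootstrap_fit_fn(data: Dataset, method: str, hyper, seed: int = 0):
    """The refit rule used inside the bootstrap-stability analysis.

    Hyperparameters are frozen at their full-data tuned values; selection
    procedures without tuned hyperparameters (BSLR, RBVS) re-run their full
    search on every resample.
    """
    ids = list(data.covariate_ids)
    if method == "rbvs":
        hp = dict(hyper or {})
        config = hp.get("config", RbvsConfig())
        return lambda X, y, rng: fit_rbvs(
            (X, y), config, seed=int(rng.integers(2**31 - 1))
        )
    if method == "bslr":
        return lambda X, y, rng: fit_bslr((X, y))
    if method == "mars":
        hp = dict(hyper or {})
        return lambda X, y, rng: fit_mars(
            _as_dataset(X, y, ids), nprune=hp.get("nprune", 20),
            degree=hp.get("degree", 1),
        )
    if method == "aenet":
        return lambda X, y, rng: fit_adaptive_enet((X, y), hyper,
                                                   tol=1e-6, max_iter=5000)
    if method == "sparsestep":
        return lambda X, y, rng: fit_sparsestep((X, y), hyper)
    return lambda X, y, rng: fit_penalized((X, y), method, hyper,
                                           tol=1e-6, max_iter=5000)
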