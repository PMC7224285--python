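"""The ten variable-selection estimators, defined by their loss functions.

Linear model: ``y = b0 + X @ beta + e`` with Gaussian errors.  The penalized
family (lasso, ridge, elastic net, adaptive elastic net, SCAD, MCP,
SparseStep) minimises ``1/(2n) * RSS + penalty`` by cyclic coordinate descent
or iterative majorization; the intercept is never penalized.  Backward
stepwise regression minimises the AIC; MARS lives in :mod:`selstab.mars`;
ranking-based variable selection (RBVS) aggregates lasso rankings over
subsamples.

Scaling conventions
-------------------
All losses use the 1/(2n)-scaled residual sum of squares, so one lambda scale
is coherent across methods (a lambda on the raw-SSE scale maps to
``lambda / (2n)`` here).  For the nonconvex SCAD and MCP penalties the
coordinate-wise thresholding operators are only valid on unit-scale columns,
so those two solvers standardise columns to unit second moment internally and
apply the penalty on that scale; the returned coefficients are mapped back to
the input scale and the reported objective is the loss actually minimised.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.linalg

from . import _cd
from .datasets import ConfigurationError, Dataset

logger = logging.getLogger(__name__)

PENALIZED_KINDS = ("lasso", "ridge", "enet", "scad", "mcp")
METHOD_TAGS = (
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

DEFAULT_TOL = 1e-7
DEFAULT_MAX_ITER = 10_000
SPARSESTEP_ZERO_TOL = 1e-6
RIDGE_SUPPORT_TOL = 1e-3


class ConvergenceError(RuntimeError):
    """Solver did not converge; carries the last iterate."""

    def __init__(self, message: str, coefficients: np.ndarray, iterations: int):
        super().__init__(message)
        self.coefficients = coefficients
        self.iterations = iterations


@dataclass(frozen=True)
class PenaltySpec:
    """Regularization hyperparameters shared by the penalized family.

    ``lam`` is the penalty strength on the 1/(2n)-RSS objective scale;
    ``alpha`` mixes L1 (alpha=1) and L2 (alpha=0) for the elastic net;
    ``gamma`` shapes the nonconvex penalties (SCAD needs gamma > 2, MCP
    gamma > 1, SparseStep gamma > 0) or the adaptive-weight exponent;
    ``weights`` are per-covariate L1 multipliers for the adaptive elastic net.
    """

    lam: float
    alpha: float = 1.0
    gamma: float = float("nan")
    weights: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ConfigurationError("lam must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError("alpha must be in [0, 1]")
        if self.weights is not None:
            object.__setattr__(self, "weights", tuple(float(w) for w in self.weights))
            if any(w < 0 for w in self.weights):
                raise ConfigurationError("weights must be non-negative")

    def validate_for(self, kind: str) -> None:
        if kind == "scad" and not self.gamma > 2:
            raise ConfigurationError("SCAD requires gamma > 2")
        if kind == "mcp" and not self.gamma > 1:
            raise ConfigurationError("MCP requires gamma > 1")
        if kind == "sparsestep" and not self.gamma > 0:
            raise ConfigurationError("SparseStep requires gamma > 0")

    def to_dict(self) -> dict:
        return {
            "lam": self.lam,
            "alpha": self.alpha,
            "gamma": None if math.isnan(self.gamma) else self.gamma,
            "weights": list(self.weights) if self.weights is not None else None,
        }


@dataclass
class LinearFit:
    """A fitted (possibly sparse) linear model."""

    method: str
    intercept: float
    coefficients: np.ndarray
    covariate_ids: list[str]
    support: tuple[str, ...]
    hyperparameters: object = None
    objective_value: float = float("nan")

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.isfinite(self.objective_value):
            pass  # objective may be filled in later
        unknown = set(self.support) - set(self.covariate_ids)
        if unknown:
            raise ConfigurationError(f"support ids not in covariates: {unknown}")

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coefficients

    def coefficient_map(self) -> dict[str, float]:
        return {
            cid: float(b)
            for cid, b in zip(self.covariate_ids, self.coefficients)
            if b != 0.0
        }

    def to_json(self) -> str:
        hyper = self.hyperparameters
        if isinstance(hyper, PenaltySpec):
            hyper = hyper.to_dict()
        elif hasattr(hyper, "to_dict"):
            hyper = hyper.to_dict()
        return json.dumps(
            {
                "method": self.method,
                "intercept": self.intercept,
                "coefficients": self.coefficient_map(),
                "covariate_ids": self.covariate_ids,
                "support": list(self.support),
                "hyperparameters": hyper,
                "objective_value": self.objective_value,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, payload: str) -> "LinearFit":
        d = json.loads(payload)
        coefs = np.zeros(len(d["covariate_ids"]))
        index = {cid: j for j, cid in enumerate(d["covariate_ids"])}
        for cid, b in d["coefficients"].items():
            coefs[index[cid]] = b
        return cls(
            method=d["method"],
            intercept=d["intercept"],
            coefficients=coefs,
            covariate_ids=d["covariate_ids"],
            support=tuple(d["support"]),
            hyperparameters=d.get("hyperparameters"),
            objective_value=d.get("objective_value", float("nan")),
        )


# ---------------------------------------------------------------------------
# univariate thresholding operators
# ---------------------------------------------------------------------------

def soft_threshold(z: float, lam: float) -> float:
    """Minimiser of ``(b - z)^2 / 2 + lam * |b|``: sign(z) * max(|z| - lam, 0)."""
    if lam < 0:
        raise ConfigurationError("lam must be >= 0")
    return math.copysign(max(abs(z) - lam, 0.0), z)


def scad_threshold(z: float, lam: float, gamma: float) -> float:
    """Minimiser of the SCAD-penalized univariate quadratic.

    Soft-thresholding for small |z|, reduced shrinkage in the transition
    region, and no shrinkage at all beyond ``gamma * lam``.
    """
    if not gamma > 2:
        raise ConfigurationError("SCAD requires gamma > 2")
    if lam < 0:
        raise ConfigurationError("lam must be >= 0")
    az = abs(z)
    if az <= 2 * lam:
        return soft_threshold(z, lam)
    if az <= gamma * lam:
        return ((gamma - 1) * z - math.copysign(gamma * lam, z)) / (gamma - 2)
    return z


def mcp_threshold(z: float, lam: float, gamma: float) -> float:
    """Minimiser of the MCP-penalized univariate quadratic (firm threshold)."""
    if not gamma > 1:
        raise ConfigurationError("MCP requires gamma > 1")
    if lam < 0:
        raise ConfigurationError("lam must be >= 0")
    if abs(z) <= gamma * lam:
        return soft_threshold(z, lam) / (1.0 - 1.0 / gamma)
    return z


# ---------------------------------------------------------------------------
# penalty values and objectives
# ---------------------------------------------------------------------------

def scad_penalty(b: np.ndarray, lam: float, gamma: float) -> np.ndarray:
    ab = np.abs(b)
    out = np.where(
        ab <= lam,
        lam * ab,
        np.where(
            ab <= gamma * lam,
            (2 * gamma * lam * ab - ab**2 - lam**2) / (2 * (gamma - 1)),
            lam**2 * (gamma + 1) / 2,
        ),
    )
    return out


def mcp_penalty(b: np.ndarray, lam: float, gamma: float) -> np.ndarray:
    ab = np.abs(b)
    return np.where(ab <= gamma * lam, lam * ab - ab**2 / (2 * gamma), gamma * lam**2 / 2)


def sparsestep_penalty(b: np.ndarray, lam: float, gamma: float) -> np.ndarray:
    return lam * b**2 / (b**2 + gamma**2)


def column_scales(X: np.ndarray) -> np.ndarray:
    """Root mean square of the centred columns (the internal SCAD/MCP scale)."""
    Xc = X - X.mean(axis=0)
    return np.sqrt(np.mean(Xc**2, axis=0))


def penalized_objective(
    X: np.ndarray,
    y: np.ndarray,
    intercept: float,
    beta: np.ndarray,
    kind: str,
    spec: PenaltySpec,
) -> float:
    """Value of the loss that ``fit_penalized``/``fit_sparsestep`` minimise."""
    n = X.shape[0]
    rss = float(np.sum((y - intercept - X @ beta) ** 2))
    lam, alpha, gamma = spec.lam, spec.alpha, spec.gamma
    b = np.asarray(beta, dtype=float)
    if kind == "lasso":
        pen = lam * np.sum(np.abs(b))
    elif kind == "ridge":
        pen = lam / 2 * np.sum(b**2)
    elif kind in ("enet", "aenet"):
        w = np.ones(len(b)) if spec.weights is None else np.asarray(spec.weights)
        pen = lam * np.sum((1 - alpha) / 2 * b**2 + alpha * w * np.abs(b))
    elif kind == "scad":
        pen = float(np.sum(scad_penalty(column_scales(X) * b, lam, gamma)))
    elif kind == "mcp":
        pen = float(np.sum(mcp_penalty(column_scales(X) * b, lam, gamma)))
    elif kind == "sparsestep":
        pen = float(np.sum(sparsestep_penalty(b, lam, gamma)))
    else:
        raise ConfigurationError(f"unknown penalty kind {kind!r}")
    return rss / (2 * n) + pen


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def ols_fit(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Least-squares intercept and coefficients (minimum-norm if deficient)."""
    x_means = X.mean(axis=0)
    y_mean = float(np.mean(y))
    beta, *_ = np.linalg.lstsq(X - x_means, y - y_mean, rcond=None)
    return y_mean - float(x_means @ beta), beta


def lambda_max(X: np.ndarray, y: np.ndarray, alpha: float = 1.0,
               weights: Optional[np.ndarray] = None) -> float:
    """Smallest lambda that zeroes every coordinate of an L1-type fit."""
    Xc = X - X.mean(axis=0)
    c = np.abs(Xc.T @ (y - y.mean())) / X.shape[0]
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        with np.errstate(divide="ignore"):
            c = np.where(w > 0, c / w, 0.0)
    a = max(alpha, 1e-3)
    return float(np.max(c)) / a


def _dataset_xy(data: Dataset | tuple[np.ndarray, np.ndarray]):
    if isinstance(data, Dataset):
        return data.X, data.y, list(data.covariate_ids)
    X, y = data
    X = np.asarray(X, dtype=float)
    return X, np.asarray(y, dtype=float), [f"V{j + 1}" for j in range(X.shape[1])]


def _run_cd(G, c, beta, l1, l2, kind_code, gamma, tol, max_iter):
    sweeps = _cd.cd_gram(G, c, beta, l1, l2, kind_code, gamma, tol, max_iter)
    if sweeps < 0:
        raise ConvergenceError(
            f"coordinate descent did not converge in {max_iter} sweeps",
            beta.copy(),
            max_iter,
        )
    return beta


# ---------------------------------------------------------------------------
# penalized fits
# ---------------------------------------------------------------------------

def fit_penalized(
    data: Dataset | tuple[np.ndarray, np.ndarray],
    penalty_kind: str,
    spec: PenaltySpec,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    warm_start: Optional[np.ndarray] = None,
) -> LinearFit:
    """Fit lasso / ridge / elastic net / SCAD / MCP by coordinate descent.

    SCAD and MCP are solved with warm starts along a descending lambda path
    (the standard continuation device for nonconvex penalties); the reported
    fit is the warm-started local minimum at the requested lambda.
    """
    if penalty_kind not in PENALIZED_KINDS:
        raise ConfigurationError(f"unknown penalty kind {penalty_kind!r}")
    spec.validate_for(penalty_kind)
    X, y, ids = _dataset_xy(data)
    n, p = X.shape
    G, c, y_mean, x_means = _cd.gram_arrays(X, y)
    lam, alpha = spec.lam, spec.alpha

    if penalty_kind in ("scad", "mcp"):
        s = np.sqrt(np.diag(G))
        s = np.where(s > 0, s, 1.0)
        Gs = G / np.outer(s, s)
        cs = c / s
        kind_code = _cd.KIND_SCAD if penalty_kind == "scad" else _cd.KIND_MCP
        beta_s = np.zeros(p) if warm_start is None else warm_start * s
        lam_hi = float(np.max(np.abs(cs)))
        if warm_start is None and lam < lam_hi and lam_hi > 0:
            path = np.geomspace(lam_hi, max(lam, 1e-12 * lam_hi), 25)
        else:
            path = np.array([lam])
        path[-1] = lam
        zeros = np.zeros(p)
        for lam_k in path:
            l1 = np.full(p, lam_k)
            _run_cd(Gs, cs, beta_s, l1, zeros, kind_code, spec.gamma, tol, max_iter)
        beta = beta_s / s
    else:
        if penalty_kind == "lasso":
            l1, l2 = np.full(p, lam), np.zeros(p)
        elif penalty_kind == "ridge":
            l1, l2 = np.zeros(p), np.full(p, lam)
        else:  # enet (optionally weighted, for the adaptive stage)
            w = np.ones(p) if spec.weights is None else np.asarray(spec.weights)
            l1, l2 = lam * alpha * w, np.full(p, lam * (1 - alpha))
        beta = np.zeros(p) if warm_start is None else warm_start.copy()
        _run_cd(G, c, beta, l1, l2, _cd.KIND_ENET, 0.0, tol, max_iter)

    intercept = y_mean - float(x_means @ beta)
    support = tuple(ids[j] for j in np.flatnonzero(beta))
    fit = LinearFit(
        method=penalty_kind,
        intercept=intercept,
        coefficients=beta,
        covariate_ids=ids,
        support=support,
        hyperparameters=spec,
        objective_value=penalized_objective(X, y, intercept, beta, penalty_kind, spec),
    )
    return fit


def fit_adaptive_enet(
    data: Dataset | tuple[np.ndarray, np.ndarray],
    spec: PenaltySpec,
    stage1: Optional[LinearFit] = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> LinearFit:
    """Two-stage adaptive elastic net.

    Stage 1 fits a plain elastic net at (lam, alpha); stage 2 re-solves the
    elastic-net loss with L1 weights ``w_j = |beta1_j| ** -gamma``.  Covariates
    zeroed in stage 1 have infinite weight and are excluded from stage 2.
    """
    if spec.gamma < 0 or math.isnan(spec.gamma):
        raise ConfigurationError("adaptive elastic net requires gamma >= 0")
    X, y, ids = _dataset_xy(data)
    if stage1 is None:
        stage1 = fit_penalized(
            data, "enet", PenaltySpec(lam=spec.lam, alpha=spec.alpha), tol, max_iter
        )
    b1 = stage1.coefficients
    active = np.flatnonzero(b1)
    if len(active) == 0:
        logger.warning("adaptive elastic net: stage-1 fit is empty; intercept-only")
        intercept = float(np.mean(y))
        return LinearFit(
            method="aenet",
            intercept=intercept,
            coefficients=np.zeros(X.shape[1]),
            covariate_ids=ids,
            support=(),
            hyperparameters=spec,
            objective_value=float(np.sum((y - intercept) ** 2)) / (2 * len(y)),
        )
    w_active = np.abs(b1[active]) ** (-spec.gamma)
    sub_spec = PenaltySpec(
        lam=spec.lam, alpha=spec.alpha, weights=tuple(w_active)
    )
    sub = fit_penalized((X[:, active], y), "enet", sub_spec, tol, max_iter)
    beta = np.zeros(X.shape[1])
    beta[active] = sub.coefficients
    weights_full = np.zeros(X.shape[1])
    weights_full[active] = w_active
    full_spec = PenaltySpec(
        lam=spec.lam, alpha=spec.alpha, gamma=spec.gamma, weights=tuple(weights_full)
    )
    support = tuple(ids[j] for j in np.flatnonzero(beta))
    return LinearFit(
        method="aenet",
        intercept=sub.intercept,
        coefficients=beta,
        covariate_ids=ids,
        support=support,
        hyperparameters=full_spec,
        objective_value=penalized_objective(
            X, y, sub.intercept, beta, "aenet", full_spec
        ),
    )


def sparsestep_solve(
    G: np.ndarray,
    c: np.ndarray,
    lam: float,
    gamma: float,
    tol: float = 1e-8,
    max_iter: int = 500,
    anneal: bool = True,
    anneal_factor: float = 3.0,
    anneal_steps: int = 2,
    refine: bool = False,
    n_refine_starts: int = 8,
) -> np.ndarray:
    """SparseStep coefficients on a precomputed Gram system.

    Iterative majorization: the penalty ``lam * b^2 / (b^2 + gamma^2)`` is
    majorized at the current iterate by a quadratic with per-coefficient
    weight ``lam * gamma^2 / (b^2 + gamma^2)^2``, so each step is a weighted
    ridge solve.  Following the method's reference algorithm, gamma is
    annealed from a large starting value down to the target by constant
    factors with a fixed small number of majorization steps per level (a
    continuation from the least-squares solution towards the L0-like target
    penalty); the terminal level iterates to convergence, so the returned
    point is stationary for the stated loss at the target gamma.

    The loss is nonconvex in general; with ``refine=True`` the majorization
    is additionally run from hard-thresholded least-squares starts (up to
    ``n_refine_starts`` threshold levels, which explore the on/off basin
    structure of the penalty) and the point with the lowest objective is
    returned.  Tuning paths skip the refinement for speed.
    """
    p = G.shape[0]

    def objective(b):
        return float(
            0.5 * b @ G @ b - c @ b + lam * np.sum(b**2 / (b**2 + gamma**2))
        )

    def im_steps(beta, g, steps, inner_tol):
        for _ in range(steps):
            w = lam * g**2 / (beta**2 + g**2) ** 2
            A = G + np.diag(2 * w)
            try:
                new = scipy.linalg.solve(A, c, assume_a="pos")
            except scipy.linalg.LinAlgError:
                new = np.linalg.lstsq(A, c, rcond=None)[0]
            change = float(np.max(np.abs(new - beta)))
            beta = new
            if change < inner_tol:
                return beta, True
        return beta, False

    # start from a barely-regularised solve (OLS when full rank)
    ridge_eps = 1e-10 * max(np.trace(G) / p, 1e-12)
    beta_ls = scipy.linalg.solve(G + ridge_eps * np.eye(p), c, assume_a="pos")
    if lam == 0:
        return beta_ls

    beta = beta_ls.copy()
    if anneal:
        g = max(gamma, 1e3 * max(1.0, float(np.max(np.abs(beta)))))
        while g > gamma:
            beta, _ = im_steps(beta, g, anneal_steps, 0.0)
            g = max(gamma, g / anneal_factor)
    beta, converged = im_steps(beta, gamma, max_iter, tol)
    if not converged:
        raise ConvergenceError(
            f"SparseStep majorization did not converge in {max_iter} iterations",
            beta,
            max_iter,
        )
    if not refine:
        return beta

    best, best_obj = beta, objective(beta)
    mags = np.unique(np.abs(beta_ls))[::-1]
    idx = np.unique(
        np.linspace(0, len(mags) - 1, min(n_refine_starts, len(mags)))
        .round()
        .astype(int)
    )
    taus = [0.0] + [float(mags[i]) * 0.999 for i in idx]
    for tau in taus:
        start = np.where(np.abs(beta_ls) > tau, beta_ls, 0.0)
        cand, ok = im_steps(start, gamma, max_iter, tol)
        if ok:
            obj = objective(cand)
            if obj < best_obj - 1e-14:
                best, best_obj = cand, obj
    return best


def fit_sparsestep(
    data: Dataset | tuple[np.ndarray, np.ndarray],
    spec: PenaltySpec,
    tol: float = 1e-8,
    max_iter: int = 500,
    zero_tol: float = SPARSESTEP_ZERO_TOL,
    anneal: bool = True,
) -> LinearFit:
    """Minimise the SparseStep loss by annealed iterative majorization.

    ``spec.gamma`` is the target penalty shape: small values (the default
    grid uses 1e-4 to 1e-2) make the penalty an approximate L0 count and the
    fit genuinely sparse, mirroring the method's reference implementation;
    large values degrade towards an adaptive ridge.  Coefficients below
    ``zero_tol`` after convergence are hard-zeroed to define the support.
    """
    spec.validate_for("sparsestep")
    X, y, ids = _dataset_xy(data)
    n, p = X.shape
    G, c, y_mean, x_means = _cd.gram_arrays(X, y)
    beta = sparsestep_solve(G, c, spec.lam, spec.gamma, tol, max_iter, anneal,
                            refine=True)
    beta = np.where(np.abs(beta) < zero_tol, 0.0, beta)
    intercept = y_mean - float(x_means @ beta)
    support = tuple(ids[j] for j in np.flatnonzero(beta))
    return LinearFit(
        method="sparsestep",
        intercept=intercept,
        coefficients=beta,
        covariate_ids=ids,
        support=support,
        hyperparameters=spec,
        objective_value=penalized_objective(X, y, intercept, beta, "sparsestep", spec),
    )


# ---------------------------------------------------------------------------
# backward stepwise AIC
# ---------------------------------------------------------------------------

def _gaussian_aic(n: int, rss: float, n_slopes: int) -> float:
    # profile Gaussian log-likelihood; k counts slopes + intercept + variance
    rss = max(rss, float(np.finfo(float).tiny))
    k = n_slopes + 2
    loglik = -0.5 * n * (math.log(2 * math.pi * rss / n) + 1.0)
    return 2 * k - 2 * loglik


def fit_bslr(data: Dataset | tuple[np.ndarray, np.ndarray]) -> LinearFit:
    """Backward stepwise linear regression minimising the AIC.

    Starts from the full OLS model and repeatedly removes the single covariate
    whose removal most decreases the AIC, stopping when no removal helps.
    Requires n > p + 1 so the full model is identifiable.  The per-covariate
    RSS increase is computed from the inverse Gram matrix, which is downdated
    after each removal, so the whole search is O(p^3).
    """
    X, y, ids = _dataset_xy(data)
    n, p = X.shape
    if n <= p + 1:
        raise ConfigurationError("full model unidentifiable: need n > p + 1")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    # rank-revealing pivoted QR: aliased columns (e.g. on bootstrap resamples
    # with few distinct rows) are dropped from the search, as R's lm() does
    R, piv = scipy.linalg.qr(Xc, mode="r", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag[0] == 0:
        raise ConfigurationError("design matrix is zero")
    rank = int(np.sum(diag > max(n, p) * np.finfo(float).eps * diag[0]))
    rank = min(rank, n - 2)  # keep the Gaussian AIC well defined
    cols = np.sort(piv[:rank])
    if rank < p:
        logger.warning("dropping %d aliased covariates from the stepwise search",
                       p - rank)
        Xc = Xc[:, cols]
    gram = Xc.T @ Xc
    try:
        A = scipy.linalg.inv(gram)
    except scipy.linalg.LinAlgError as exc:
        raise ConfigurationError("full model unidentifiable: singular design") from exc
    xty = Xc.T @ yc
    beta = A @ xty
    rss = float(yc @ yc - beta @ xty)
    if rss <= 0:
        rss = np.finfo(float).tiny
    active = list(range(rank))
    aic = _gaussian_aic(n, rss, len(active))

    while active:
        diag = np.diag(A)
        d_rss = beta**2 / diag
        cand_rss = rss + d_rss
        cand_aic = np.array(
            [_gaussian_aic(n, r, len(active) - 1) for r in cand_rss]
        )
        j = int(np.argmin(cand_aic))  # ties resolve to the lowest index
        if cand_aic[j] >= aic:
            break
        # downdate the inverse Gram and coefficients
        aj = A[:, j]
        beta = beta - aj * (beta[j] / diag[j])
        A = A - np.outer(aj, aj) / diag[j]
        keep = np.arange(len(active)) != j
        A = A[np.ix_(keep, keep)]
        beta = beta[keep]
        rss = float(cand_rss[j])
        aic = float(cand_aic[j])
        del active[j]

    kept = cols[active]
    coefs = np.zeros(p)
    coefs[kept] = beta
    x_means = X.mean(axis=0)
    intercept = float(np.mean(y)) - float(x_means @ coefs)
    return LinearFit(
        method="bslr",
        intercept=intercept,
        coefficients=coefs,
        covariate_ids=ids,
        support=tuple(ids[j] for j in kept),
        hyperparameters={"criterion": "aic"},
        objective_value=aic,
    )


# ---------------------------------------------------------------------------
# ranking-based variable selection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RbvsConfig:
    """Configuration of iterative ranking-based variable selection."""

    subsample_size: int = 200
    repeats_per_iteration: int = 100
    max_set_size: int = 10
    ranking_method: str = "lasso"
    max_iterations: int = 5

    def __post_init__(self) -> None:
        if min(
            self.subsample_size,
            self.repeats_per_iteration,
            self.max_set_size,
            self.max_iterations,
        ) < 1:
            raise ConfigurationError("all RBVS counts must be >= 1")

    def to_dict(self) -> dict:
        return {
            "subsample_size": self.subsample_size,
            "repeats_per_iteration": self.repeats_per_iteration,
            "max_set_size": self.max_set_size,
            "ranking_method": self.ranking_method,
            "max_iterations": self.max_iterations,
        }


def _lasso_ranking(X: np.ndarray, y: np.ndarray, n_lambdas: int = 12) -> np.ndarray:
    """Rank covariates by lasso path entry order (earliest entry first).

    Ties are broken by absolute coefficient at the smallest lambda, then by
    absolute marginal correlation.  Uses residual-update coordinate descent,
    which is the cheap formulation on the p > n subsamples RBVS draws; the
    path stops at 10% of lambda_max or once 35 covariates have entered —
    only the leading ranks matter.
    """
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    c = np.abs(Xc.T @ yc) / n
    lam_hi = float(c.max())
    if lam_hi <= 0:
        return np.arange(p)
    lambdas = np.geomspace(lam_hi * 0.999, lam_hi * 0.1, n_lambdas)
    beta, entry = _cd.cd_naive_lasso_path(Xc, yc, lambdas, 1e-3, 200, 35)
    return np.lexsort((-c, -np.abs(beta), entry))


def fit_rbvs(
    data: Dataset | tuple[np.ndarray, np.ndarray],
    config: RbvsConfig = RbvsConfig(),
    seed: int = 0,
) -> LinearFit:
    """Iterative ranking-based variable selection.

    Per iteration, covariates are ranked on ``repeats_per_iteration`` random
    subsamples (without replacement) of ``subsample_size`` rows; for each
    k <= ``max_set_size`` the most frequent top-k set and its frequency f_k
    are recorded (f_0 = 1 by convention).  The accepted set size maximises
    the ratio f_k / f_{k+1}; if that maximiser is k = 0 the iteration accepts
    nothing and the procedure stops.  Accepted covariates are removed from the
    candidate pool between iterations.  The final model refits OLS on the
    union of accepted sets.
    """
    X, y, ids = _dataset_xy(data)
    n, p = X.shape
    if config.subsample_size >= n:
        raise ConfigurationError("subsample_size must be smaller than n")
    rng = np.random.default_rng(seed)
    active = np.arange(p)
    accepted: list[int] = []
    iterations: list[dict] = []

    for _ in range(config.max_iterations):
        if len(active) == 0:
            break
        from collections import Counter

        counters = [Counter() for _ in range(config.max_set_size)]
        for _r in range(config.repeats_per_iteration):
            idx = rng.choice(n, size=config.subsample_size, replace=False)
            order = _lasso_ranking(X[np.ix_(idx, active)], y[idx])
            for k in range(1, min(config.max_set_size, len(active)) + 1):
                counters[k - 1][frozenset(order[:k])] += 1
        kmax = min(config.max_set_size, len(active))
        freqs = [1.0]
        top_sets: list[frozenset] = [frozenset()]
        for k in range(1, kmax + 1):
            best_set, count = counters[k - 1].most_common(1)[0]
            freqs.append(count / config.repeats_per_iteration)
            top_sets.append(best_set)
        floor = 1.0 / config.repeats_per_iteration
        ratios = [freqs[k] / max(freqs[k + 1], floor) for k in range(kmax)]
        k_star = int(np.argmax(ratios))  # ties resolve to the smallest k
        iterations.append(
            {"frequencies": freqs[1:], "accepted_size": k_star}
        )
        if k_star == 0:
            break
        chosen_local = sorted(top_sets[k_star])
        chosen = active[list(chosen_local)]
        accepted.extend(int(j) for j in chosen)
        active = np.array([j for j in active if j not in set(chosen)])

    coefs = np.zeros(p)
    if accepted:
        sub = sorted(accepted)
        intercept, b = ols_fit(X[:, sub], y)
        coefs[sub] = b
    else:
        intercept = float(np.mean(y))
    resid = y - intercept - X @ coefs
    fit = LinearFit(
        method="rbvs",
        intercept=intercept,
        coefficients=coefs,
        covariate_ids=ids,
        support=tuple(ids[j] for j in sorted(accepted)),
        hyperparameters=config,
        objective_value=float(resid @ resid) / (2 * n),
    )
    fit.iterations = iterations
    return fit


# ---------------------------------------------------------------------------
# support extraction
# ---------------------------------------------------------------------------

def selected_support(fit, tol: float = RIDGE_SUPPORT_TOL) -> set[str]:
    """Covariate ids a fitted model 'selects'.

    Sparsity-inducing linear fits select their nonzero coefficients.  Ridge,
    which never produces exact zeros, selects coefficients whose magnitude
    exceeds ``tol`` times the largest magnitude (tol=0 selects everything).
    MARS models select the union of parent covariates of retained hinge
    terms.  Polynomial expansion columns count as their own covariates.
    """
    if tol < 0:
        raise ConfigurationError("tol must be >= 0")
    if hasattr(fit, "basis_terms"):  # MarsModel
        out: set[str] = set()
        for term in fit.basis_terms:
            for cov_id, _knot, _direction in term:
                out.add(cov_id)
        return out
    if fit.method == "ridge":
        mags = np.abs(fit.coefficients)
        top = mags.max() if len(mags) else 0.0
        return {
            cid
            for cid, m in zip(fit.covariate_ids, mags)
            if m > tol * top
        }
    return {cid for cid, b in zip(fit.covariate_ids, fit.coefficients) if b != 0.0}
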