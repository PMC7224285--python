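"""Independent oracles used by the test-suite and the acceptance script.

These deliberately avoid the package's own solvers: a split-variable
L-BFGS-B minimiser for the penalized objectives, dense grid minimisation for
the univariate thresholding operators, and exhaustive subset enumeration for
the stepwise-AIC search.  The penalty *formulas* are shared with the package
(the oracle must minimise the identical loss); the optimisation path is not.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize

from selstab.estimators import (
    column_scales,
    mcp_penalty,
    ols_fit,
    scad_penalty,
    sparsestep_penalty,
)


def _penalty_of(beta, absbeta, kind, spec, scales):
    lam, alpha, gamma = spec.lam, spec.alpha, spec.gamma
    if kind == "lasso":
        return lam * np.sum(absbeta)
    if kind == "ridge":
        return lam / 2 * np.sum(beta**2)
    if kind in ("enet", "aenet"):
        w = np.ones(len(beta)) if spec.weights is None else np.asarray(spec.weights)
        return lam * np.sum((1 - alpha) / 2 * beta**2 + alpha * w * absbeta)
    if kind == "scad":
        return float(np.sum(scad_penalty(scales * absbeta, lam, gamma)))
    if kind == "mcp":
        return float(np.sum(mcp_penalty(scales * absbeta, lam, gamma)))
    if kind == "sparsestep":
        return float(np.sum(sparsestep_penalty(beta, lam, gamma)))
    raise ValueError(kind)


def penalized_oracle(X, y, kind, spec, extra_starts=()):
    """Best objective value found by a general-purpose numeric minimiser.

    Split parameterisation beta = bp - bn with bp, bn >= 0: every
    non-smooth penalty here is an increasing function of |beta|, evaluated at
    bp + bn, which equals |beta| at any minimiser, so the relaxation is exact
    and the objective is smooth on the feasible region.  Multi-started from
    zero, the OLS solution and shrunken variants of it.
    """
    n, p = X.shape
    scales = column_scales(X)

    def objective(z):
        b0 = z[0]
        bp, bn = z[1 : p + 1], z[p + 1 :]
        beta = bp - bn
        rss = float(np.sum((y - b0 - X @ beta) ** 2)) / (2 * n)
        return rss + _penalty_of(beta, bp + bn, kind, spec, scales)

    b0_ols, beta_ols = ols_fit(X, y)
    starts = [
        np.zeros(p),
        beta_ols,
        0.5 * beta_ols,
        np.where(np.abs(beta_ols) > 0.5, beta_ols, 0.0),
    ]
    starts.extend(np.asarray(s, dtype=float) for s in extra_starts)
    bounds = [(None, None)] + [(0.0, None)] * (2 * p)
    best = math.inf
    for beta0 in starts:
        z0 = np.zeros(2 * p + 1)
        z0[0] = b0_ols if np.any(beta0) else float(np.mean(y))
        z0[1 : p + 1] = np.maximum(beta0, 0.0)
        z0[p + 1 :] = np.maximum(-beta0, 0.0)
        res = minimize(
            objective,
            z0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12},
        )
        best = min(best, float(res.fun))
    return best


def threshold_grid_oracle(z, lam, gamma, penalty):
    """Two-stage dense grid minimisation of 0.5*(b - z)**2 + penalty(b)."""
    lo, hi = -abs(z) - 1.0, abs(z) + 1.0
    grid = np.linspace(lo, hi, 20001)
    vals = 0.5 * (grid - z) ** 2 + penalty(grid, lam, gamma)
    b = grid[np.argmin(vals)]
    fine = np.linspace(b - 2e-3, b + 2e-3, 4001)
    vals = 0.5 * (fine - z) ** 2 + penalty(fine, lam, gamma)
    return float(fine[np.argmin(vals)])


def gaussian_aic(n, rss, n_slopes):
    rss = max(rss, np.finfo(float).tiny)
    k = n_slopes + 2
    loglik = -0.5 * n * (math.log(2 * math.pi * rss / n) + 1.0)
    return 2 * k - 2 * loglik


def exhaustive_best_aic_subset(X, y):
    """The AIC-minimal covariate subset by brute-force enumeration."""
    n, p = X.shape
    best_subset, best_aic = (), math.inf
    for r in range(p + 1):
        for subset in itertools.combinations(range(p), r):
            if subset:
                _, beta = ols_fit(X[:, subset], y)
                xc = X[:, subset] - X[:, subset].mean(axis=0)
                resid = (y - y.mean()) - xc @ beta
            else:
                resid = y - y.mean()
            aic = gaussian_aic(n, float(resid @ resid), r)
            if aic < best_aic:
                best_subset, best_aic = subset, aic
    return best_subset, best_aic
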