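"""Multivariate adaptive regression splines (MARS).

MARS builds a regression surface from products of hinge functions
``(x - t)+`` and ``(t - x)+`` with knots ``t`` at observed covariate values.
A greedy forward pass adds mirrored hinge pairs (and, for ``degree >= 2``,
products of a hinge pair with a term already in the model), each step taking
the candidate that most reduces the residual sum of squares.  A backward
deletion pass then removes terms one at a time, always deleting the term
whose removal increases the RSS least, down to the best subset with at most
``nprune`` terms (including the intercept).

Implementation notes: candidate scoring orthogonalises candidate columns
against the current basis so each step costs one matrix product rather than
one least-squares fit per candidate; knot candidates are quantile-spaced
observed values (``max_knots`` per covariate); interaction candidates are
restricted to the ``fast_k`` most recently added parent terms, a standard
forward-pass acceleration.  Each covariate appears at most once per product
term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .datasets import ConfigurationError, Dataset

HINGE_POS = "x-t"  # (x - t)+
HINGE_NEG = "t-x"  # (t - x)+

_EPS = 1e-10


@dataclass(frozen=True)
class Hinge:
    """One hinge factor: (x - t)+ if direction == 'x-t' else (t - x)+."""

    cov_id: str
    knot: float
    direction: str

    def __iter__(self):
        # allows ``for cov_id, knot, direction in term`` unpacking
        yield self.cov_id
        yield self.knot
        yield self.direction

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        if self.direction == HINGE_POS:
            return np.maximum(x - self.knot, 0.0)
        return np.maximum(self.knot - x, 0.0)


@dataclass
class MarsModel:
    """A pruned MARS fit: intercept plus products of hinge functions."""

    basis_terms: list[tuple[Hinge, ...]]
    term_coefficients: np.ndarray
    intercept: float
    degree: int
    nprune: int
    covariate_ids: list[str]
    method: str = "mars"

    def __post_init__(self) -> None:
        self.term_coefficients = np.asarray(self.term_coefficients, dtype=float)
        if len(self.basis_terms) != len(self.term_coefficients):
            raise ConfigurationError("one coefficient per basis term required")
        if len(self.basis_terms) + 1 > self.nprune:
            raise ConfigurationError("retained terms (incl. intercept) exceed nprune")
        if any(len(t) > self.degree for t in self.basis_terms):
            raise ConfigurationError("term order exceeds the allowed degree")

    def basis_matrix(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        cols = []
        index = {cid: j for j, cid in enumerate(self.covariate_ids)}
        for term in self.basis_terms:
            col = np.ones(X.shape[0])
            for h in term:
                col = col * h.evaluate(X[:, index[h.cov_id]])
            cols.append(col)
        if not cols:
            return np.empty((X.shape[0], 0))
        return np.column_stack(cols)

    def predict(self, X: np.ndarray) -> np.ndarray:
        B = self.basis_matrix(X)
        return self.intercept + (B @ self.term_coefficients if B.size else 0.0)


def _knot_candidates(x: np.ndarray, max_knots: int) -> np.ndarray:
    """Quantile-spaced distinct observed values, avoiding the extremes."""
    vals = np.unique(x)
    if len(vals) <= 2:
        return vals[:-1]  # binary column: single usable knot
    vals = vals[:-1]  # a knot at the maximum makes (x - t)+ degenerate
    if len(vals) <= max_knots:
        return vals
    qs = np.linspace(0, len(vals) - 1, max_knots).round().astype(int)
    return vals[np.unique(qs)]


def _pair_scores(U1, U2, r):
    """RSS drop from adding each candidate column pair to the current basis.

    U1/U2 hold the candidate columns already orthogonalised against the
    basis; the drop is the squared norm of the projection of the residual
    onto their joint span.
    """
    a = np.einsum("ij,ij->j", U1, U1)
    d = np.einsum("ij,ij->j", U2, U2)
    b = np.einsum("ij,ij->j", U1, U2)
    r1 = r @ U1
    r2 = r @ U2
    det = a * d - b * b
    scale = np.maximum(a * d, _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        joint = (d * r1**2 - 2 * b * r1 * r2 + a * r2**2) / det
        single = np.maximum(
            np.where(a > _EPS, r1**2 / a, 0.0),
            np.where(d > _EPS, r2**2 / d, 0.0),
        )
    ok = det > 1e-8 * scale
    return np.where(ok, joint, single)


class _Forward:
    """State of the forward pass: orthonormal basis, residual, terms.

    ``U1``/``U2`` hold the precomputed intercept-parent candidate columns
    kept orthogonal to the growing basis by rank-one updates, so each step
    costs O(n * n_candidates) rather than a fresh projection of every
    candidate against every basis vector.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, covariate_ids: Sequence[str]):
        self.X = X
        self.y = y
        self.ids = list(covariate_ids)
        n = X.shape[0]
        self.Q = np.full((n, 1), 1.0 / np.sqrt(n))
        self.r = y - y.mean()
        self.terms: list[tuple[Hinge, ...]] = []
        self.cols: list[np.ndarray] = []
        self.U1: Optional[np.ndarray] = None
        self.U2: Optional[np.ndarray] = None

    def orthogonalise(self, C: np.ndarray) -> np.ndarray:
        U = C - self.Q @ (self.Q.T @ C)
        return U - self.Q @ (self.Q.T @ U)  # second pass for stability

    def add_column(self, col: np.ndarray) -> bool:
        u = self.orthogonalise(col[:, None])[:, 0]
        nrm = np.linalg.norm(u)
        if nrm < 1e-8 * max(np.linalg.norm(col), 1.0):
            return False
        q = u / nrm
        self.Q = np.column_stack([self.Q, q])
        self.r = self.r - q * (q @ self.r)
        if self.U1 is not None:
            self.U1 -= np.outer(q, q @ self.U1)
            self.U2 -= np.outer(q, q @ self.U2)
        return True


def _forward_pass(
    X: np.ndarray,
    y: np.ndarray,
    covariate_ids: Sequence[str],
    max_terms: int,
    degree: int,
    max_knots: int,
    fast_k: int,
    rel_tol: float,
) -> _Forward:
    n, p = X.shape
    state = _Forward(X, y, covariate_ids)
    tss = float(state.r @ state.r)
    if tss <= 0:
        return state

    knots = [_knot_candidates(X[:, v], max_knots) for v in range(p)]
    # precomputed intercept-parent candidates: columns (x_v - t)+ per (v, t)
    hp_cols, hp_meta = [], []
    for v in range(p):
        for t in knots[v]:
            hp_cols.append(np.maximum(X[:, v] - t, 0.0))
            hp_meta.append((v, float(t)))
    if not hp_cols:
        return state
    HP = np.column_stack(hp_cols)
    XV = X[:, [v for v, _ in hp_meta]]
    TV = np.array([t for _, t in hp_meta])
    HN = np.maximum(TV[None, :] - XV, 0.0)
    state.U1 = state.orthogonalise(HP)
    state.U2 = state.orthogonalise(HN)
    # interaction candidates use a thinned knot set
    int_mask = np.zeros(len(hp_meta), dtype=bool)
    int_mask[::2] = True
    cand_cov = np.array([covariate_ids[v] for v, _ in hp_meta])

    while len(state.terms) + 1 < max_terms:
        rss = float(state.r @ state.r)
        if rss < 1e-12 * tss:
            break
        # degree-1 candidates (parent = intercept)
        scores = _pair_scores(state.U1, state.U2, state.r)
        best_idx = int(np.argmax(scores))
        best = (scores[best_idx], None, hp_meta[best_idx])

        if degree >= 2 and state.terms:
            parents = list(range(len(state.terms)))[-fast_k:]
            for ti in parents:
                if len(state.terms[ti]) >= degree:
                    continue
                bcol = state.cols[ti]
                used = {h.cov_id for h in state.terms[ti]}
                mask = int_mask & ~np.isin(cand_cov, list(used))
                if not mask.any():
                    continue
                C1 = bcol[:, None] * HP[:, mask]
                C2 = bcol[:, None] * HN[:, mask]
                u1 = state.orthogonalise(C1)
                u2 = state.orthogonalise(C2)
                s = _pair_scores(u1, u2, state.r)
                kk = int(np.argmax(s))
                if s[kk] > best[0]:
                    meta_idx = np.flatnonzero(mask)[kk]
                    best = (s[kk], ti, hp_meta[meta_idx])

        drop, parent_ti, (v, t) = best
        if drop <= rel_tol * tss:
            break
        cid = covariate_ids[v]
        parent = state.terms[parent_ti] if parent_ti is not None else ()
        parent_col = state.cols[parent_ti] if parent_ti is not None else 1.0
        added = False
        for direction, hinge_col in (
            (HINGE_POS, np.maximum(X[:, v] - t, 0.0)),
            (HINGE_NEG, np.maximum(t - X[:, v], 0.0)),
        ):
            col = parent_col * hinge_col
            term = parent + (Hinge(cid, float(t), direction),)
            if state.add_column(col):
                state.terms.append(term)
                state.cols.append(col)
                added = True
                if len(state.terms) + 1 >= max_terms:
                    break
        if not added:
            break
    return state


def _backward_sequence(B: np.ndarray, y: np.ndarray) -> tuple[list[list[int]], list[float]]:
    """Greedy deletion order over basis columns (intercept always kept).

    Returns, for each size m = M..0 (number of non-intercept terms), the
    retained term indices and the training RSS, computed by downdating the
    inverse Gram matrix.
    """
    n, M = B.shape
    ones = np.ones((n, 1))
    D = np.column_stack([ones, B]) if M else ones
    gram = D.T @ D
    A = np.linalg.pinv(gram)
    dty = D.T @ y
    beta = A @ dty
    rss = float(y @ y - beta @ dty)
    active = list(range(M))  # term indices (0-based, excluding intercept)
    subsets = [list(active)]
    rss_seq = [rss]
    while active:
        diag = np.diag(A)[1:]
        safe = np.where(np.abs(diag) > _EPS, diag, np.inf)
        d_rss = beta[1:] ** 2 / safe
        j = int(np.argmin(d_rss))  # smallest RSS increase; ties -> lowest index
        col = j + 1
        aj = A[:, col]
        beta = beta - aj * (beta[col] / A[col, col])
        A = A - np.outer(aj, aj) / A[col, col]
        keep = np.arange(A.shape[0]) != col
        A = A[np.ix_(keep, keep)]
        beta = beta[keep]
        rss = rss + float(d_rss[j])
        del active[j]
        subsets.append(list(active))
        rss_seq.append(rss)
    return subsets, rss_seq


def mars_sequence(
    data: Dataset | tuple[np.ndarray, np.ndarray],
    max_terms: int,
    degree: int,
    max_knots: int = 15,
    fast_k: int = 4,
    rel_tol: float = 1e-3,
):
    """Forward pass plus backward deletion sequence.

    Returns ``(terms, subsets, rss_seq, B, ids)`` where ``subsets[i]`` lists
    the term indices retained with ``len(terms) - i`` non-intercept terms.
    Used by the cross-validation tuner, which evaluates every pruned size
    from a single forward pass per training split.
    """
    if isinstance(data, Dataset):
        X, y, ids = data.X, data.y, list(data.covariate_ids)
    else:
        X, y = data
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        ids = [f"V{j + 1}" for j in range(X.shape[1])]
    state = _forward_pass(X, y, ids, max_terms, degree, max_knots, fast_k, rel_tol)
    B = (
        np.column_stack(state.cols)
        if state.cols
        else np.empty((X.shape[0], 0))
    )
    subsets, rss_seq = _backward_sequence(B, y)
    return state.terms, subsets, rss_seq, B, ids


def _fit_terms(
    terms: list[tuple[Hinge, ...]],
    B: np.ndarray,
    y: np.ndarray,
    keep: list[int],
    degree: int,
    nprune: int,
    ids: list[str],
) -> MarsModel:
    if keep:
        D = np.column_stack([np.ones(len(y)), B[:, keep]])
        coefs, *_ = np.linalg.lstsq(D, y, rcond=None)
        return MarsModel(
            basis_terms=[terms[i] for i in keep],
            term_coefficients=coefs[1:],
            intercept=float(coefs[0]),
            degree=degree,
            nprune=nprune,
            covariate_ids=ids,
        )
    return MarsModel(
        basis_terms=[],
        term_coefficients=np.empty(0),
        intercept=float(np.mean(y)),
        degree=degree,
        nprune=nprune,
        covariate_ids=ids,
    )


def fit_mars(
    data: Dataset | tuple[np.ndarray, np.ndarray],
    nprune: int = 20,
    degree: int = 1,
    max_terms: Optional[int] = None,
    max_knots: int = 15,
    fast_k: int = 4,
    rel_tol: float = 1e-3,
) -> MarsModel:
    """Fit a MARS model with at most ``nprune`` terms (incl. intercept).

    ``max_terms`` caps the forward pass (default ``2 * nprune + 1``, bounded
    by ``2p + 1``); the backward pass deletes down to the best recorded
    subset of size <= nprune; coefficients come from least squares on the
    retained basis.
    """
    if nprune < 1:
        raise ConfigurationError("nprune must be >= 1")
    if degree < 1:
        raise ConfigurationError("degree must be >= 1")
    if isinstance(data, Dataset):
        p = data.p
    else:
        p = np.asarray(data[0]).shape[1]
    if max_terms is None:
        max_terms = min(2 * nprune + 1, 2 * p + 1)
    terms, subsets, rss_seq, B, ids = mars_sequence(
        data, max_terms, degree, max_knots, fast_k, rel_tol
    )
    y = data.y if isinstance(data, Dataset) else np.asarray(data[1], dtype=float)
    want = min(nprune - 1, len(terms))  # non-intercept terms to retain
    keep = subsets[len(terms) - want]
    return _fit_terms(terms, B, y, keep, degree, nprune, ids)
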