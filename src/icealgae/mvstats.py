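"""Ordination and permutation statistics, implemented from first principles.

PCA, redundancy analysis (RDA) with a Monte-Carlo permutation test,
rank-based analysis of similarities (ANOSIM), Bray-Curtis dissimilarity
and univariate OLS regression.  All permutation tests are
seed-deterministic and report (statistic, p, n_permutations, seed); the
sampled permutation p uses the add-one convention (1 + more extreme) /
(1 + N) so p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sympy.utilities.iterables import multiset_permutations

__all__ = [
    "OrdinationResult",
    "AnosimResult",
    "RegressionResult",
    "bray_curtis",
    "anosim",
    "pca",
    "rda",
    "rda_forward_select",
    "linear_regression",
]

_EXHAUSTIVE_LIMIT = 10_000


@dataclass
class OrdinationResult:
    """Scores, loadings and explained-variance fractions of an ordination.

    For constrained runs (RDA) the constrained-variance fraction,
    pseudo-F, permutation p and bookkeeping fields are populated.
    """

    scores: np.ndarray  # samples x axes
    loadings: np.ndarray  # variables x axes (orthonormal columns)
    explained: np.ndarray  # fraction of total variance per axis
    constrained_fraction: float | None = None
    pseudo_f: float | None = None
    p_value: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    predictors: tuple[str, ...] | None = None


@dataclass(frozen=True)
class AnosimResult:
    r: float
    p: float
    n_permutations: int
    seed: int | None
    metric: str
    method: str  # 'exhaustive' or 'sampled'


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    f: float
    df: tuple[int, int]
    r_squared: float
    p: float
    residuals: np.ndarray
    fitted: np.ndarray

    def diagnostic(self) -> dict[str, float]:
        """Residual-vs-fitted summary for a homoscedasticity eyeball check."""
        rho = 0.0
        if np.std(self.fitted) > 0 and np.std(np.abs(self.residuals)) > 0:
            rho = float(np.corrcoef(np.abs(self.residuals), self.fitted)[0, 1])
        return {
            "residual_mean": float(np.mean(self.residuals)),
            "residual_sd": float(np.std(self.residuals, ddof=2)) if self.residuals.size > 2 else float("nan"),
            "abs_residual_vs_fitted_corr": rho,
        }


# ---------------------------------------------------------------------------
# Dissimilarity
# ---------------------------------------------------------------------------

def bray_curtis(counts: np.ndarray) -> np.ndarray:
    """Pairwise Bray-Curtis dissimilarity of a samples x taxa count matrix.

    D(x, y) = sum |x_i - y_i| / sum (x_i + y_i); symmetric, zero diagonal,
    entries in [0, 1].  Negative entries or an all-zero sample raise.
    """
    X = np.asarray(counts, dtype=float)
    if X.ndim != 2:
        raise ValueError("counts must be a 2-D samples x taxa matrix")
    if np.any(X < 0):
        raise ValueError("counts must be nonnegative")
    rowsums = X.sum(axis=1)
    if np.any(rowsums == 0):
        bad = np.flatnonzero(rowsums == 0).tolist()
        raise ValueError(f"all-zero sample row(s): {bad}")
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        num = np.abs(X[i] - X[i + 1:]).sum(axis=1)
        den = (X[i] + X[i + 1:]).sum(axis=1)
        D[i, i + 1:] = num / den
    return D + D.T


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def _anosim_r(rank_matrix: np.ndarray, labels: np.ndarray) -> float:
    n = labels.size
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    within = rank_matrix[iu][same[iu]]
    between = rank_matrix[iu][~same[iu]]
    m = n * (n - 1) / 2
    return float((between.mean() - within.mean()) / (m / 2.0))


def _n_distinct_relabellings(labels: np.ndarray) -> int:
    _, counts = np.unique(labels, return_counts=True)
    total = 1
    remaining = int(counts.sum())
    for c in counts:
        total *= comb(remaining, int(c))
        remaining -= int(c)
    return total


def anosim(
    D: np.ndarray,
    groups: Sequence,
    n_permutations: int = 999,
    seed: int | None = 0,
    metric: str = "precomputed",
    method: str = "auto",
) -> AnosimResult:
    """Clarke's analysis of similarities on a precomputed dissimilarity matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2, computed on the ranked upper-triangle dissimilarities.
    The label-permutation null is enumerated exhaustively whenever the
    number of distinct relabellings is <= 10,000 (``method='auto'``);
    otherwise ``n_permutations`` random relabellings are sampled and
    p = (1 + #{R_perm >= R_obs}) / (n_permutations + 1).
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be a square dissimilarity matrix")
    if not np.allclose(D, D.T):
        raise ValueError("D must be symmetric")
    labels = np.asarray(groups)
    if labels.size != D.shape[0]:
        raise ValueError("group labels must match the matrix dimension")
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("ANOSIM requires at least 2 groups")
    if np.any(counts < 2):
        small = uniq[counts < 2].tolist()
        raise ValueError(f"every group needs >= 2 members; offending group(s): {small}")

    n = labels.size
    iu = np.triu_indices(n, k=1)
    ranks = np.zeros_like(D)
    ranks[iu] = sps.rankdata(D[iu])
    ranks = ranks + ranks.T
    r_obs = _anosim_r(ranks, labels)

    n_distinct = _n_distinct_relabellings(labels)
    use_exhaustive = (method == "exhaustive") or (
        method == "auto" and n_distinct <= _EXHAUSTIVE_LIMIT
    )
    if method not in ("auto", "exhaustive", "sampled"):
        raise ValueError(f"unknown method {method!r}")

    if use_exhaustive:
        count_ge = 0
        total = 0
        for perm in multiset_permutations(list(labels)):
            total += 1
            if _anosim_r(ranks, np.asarray(perm)) >= r_obs - 1e-12:
                count_ge += 1
        return AnosimResult(r=r_obs, p=count_ge / total, n_permutations=total,
                            seed=seed, metric=metric, method="exhaustive")

    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, perm) >= r_obs - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (n_permutations + 1)
    return AnosimResult(r=r_obs, p=p, n_permutations=n_permutations,
                        seed=seed, metric=metric, method="sampled")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(X: np.ndarray, centre: bool = True, scale: bool = True,
        columns: Sequence[str] | None = None) -> OrdinationResult:
    """Principal component analysis by singular value decomposition.

    Axes are ordered by decreasing explained variance; scores @ loadings.T
    reconstructs the centred(/scaled) data.  A constant column with
    ``scale=True`` raises, naming the column.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x variables)")
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA requires >= 2 samples and >= 2 variables")
    if np.any(~np.isfinite(X)):
        raise ValueError("X contains missing or non-finite values")
    Z = X - X.mean(axis=0) if centre else X.copy()
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = np.flatnonzero(sd == 0)
            names = [columns[i] for i in bad] if columns is not None else bad.tolist()
            raise ValueError(f"constant column(s) cannot be scaled: {names}")
        Z = Z / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = S**2 / (n - 1)
    total = eig.sum()
    keep = S > max(S.max(), 1.0) * max(n, p) * np.finfo(float).eps if S.size else np.array([], bool)
    k = int(keep.sum())
    return OrdinationResult(
        scores=U[:, :k] * S[:k],
        loadings=Vt[:k].T,
        explained=eig[:k] / total,
    )


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------

def _check_full_rank(Xc: np.ndarray, names: Sequence[str] | None) -> None:
    n, q = Xc.shape
    _, Rq = np.linalg.qr(Xc)
    diag = np.abs(np.diag(Rq))
    tol = max(n, q) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = np.flatnonzero(diag <= tol)
    if bad.size:
        labels = [names[i] for i in bad] if names is not None else bad.tolist()
        raise ValueError(f"predictor matrix is rank deficient; collinear column(s): {labels}")


def rda(
    Y: np.ndarray,
    X: np.ndarray,
    n_permutations: int = 999,
    seed: int | None = 0,
    predictor_names: Sequence[str] | None = None,
) -> OrdinationResult:
    """Redundancy analysis of response matrix Y constrained to predictors X.

    Both matrices are column-centred; the constrained-variance fraction is
    trace(var(Yhat)) / trace(var(Y)) for the multivariate least-squares
    fit Yhat, the axes come from the SVD of Yhat, and the permutation p
    shuffles rows against the predictors (pseudo-F null).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.ndim == 1:
        X = X[:, None]
    if Y.shape[0] != X.shape[0]:
        raise ValueError("Y and X must have the same number of rows")
    n, q = X.shape
    if n < q + 2:
        raise ValueError("too few samples for the number of predictors")
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    _check_full_rank(Xc, predictor_names)

    Q, _ = np.linalg.qr(Xc)
    Yhat = Q @ (Q.T @ Yc)
    ss_tot = float((Yc**2).sum())
    ss_fit = float((Yhat**2).sum())
    if ss_tot == 0:
        raise ValueError("response matrix has zero total variance")
    fraction = ss_fit / ss_tot
    df_resid = n - q - 1
    ss_resid = ss_tot - ss_fit
    pseudo_f = (ss_fit / q) / (ss_resid / df_resid) if ss_resid > 0 else float("inf")

    U, S, Vt = np.linalg.svd(Yhat, full_matrices=False)
    eig = S**2 / (n - 1)
    keep = S > max(S.max(), 1.0) * n * np.finfo(float).eps if S.size else np.array([], bool)
    k = int(keep.sum())
    total_var = ss_tot / (n - 1)

    rng = np.random.default_rng(seed)
    count_ge = 0
    # permuting Y rows against fixed X is the exchangeable-rows null; the
    # statistic is monotone in ss_fit at fixed dfs, so compare that
    for _ in range(n_permutations):
        Yp = Yc[rng.permutation(n)]
        ssp = float(((Q.T @ Yp) ** 2).sum())
        if ssp >= ss_fit - 1e-12:
            count_ge += 1
    p = (1 + count_ge) / (n_permutations + 1)

    return OrdinationResult(
        scores=U[:, :k] * S[:k],
        loadings=Vt[:k].T,
        explained=(eig[:k] / total_var) if total_var > 0 else eig[:k],
        constrained_fraction=fraction,
        pseudo_f=pseudo_f,
        p_value=p,
        n_permutations=n_permutations,
        seed=seed,
        predictors=tuple(predictor_names) if predictor_names is not None else None,
    )


def rda_forward_select(
    Y: np.ndarray,
    X: np.ndarray,
    predictor_names: Sequence[str],
    alpha: float = 0.05,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> OrdinationResult:
    """Forward model optimisation: greedily add predictors with permutation
    p < alpha, then refit the RDA on the retained set.

    Raises when no predictor is significant at ``alpha``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = list(predictor_names)
    if X.shape[1] != len(names):
        raise ValueError("predictor_names must match the number of X columns")
    selected: list[int] = []
    remaining = list(range(X.shape[1]))
    rng = np.random.default_rng(seed)
    while remaining:
        best = None
        for j in remaining:
            cols = selected + [j]
            res = rda(Y, X[:, cols], n_permutations=n_permutations,
                      seed=int(rng.integers(0, 2**31 - 1)))
            key = (res.p_value, -res.pseudo_f)
            if best is None or key < best[0]:
                best = (key, j, res)
        (p_best, _), j_best, _ = best
        if p_best >= alpha:
            break
        selected.append(j_best)
        remaining.remove(j_best)
    if not selected:
        raise ValueError(f"no predictor significant at alpha = {alpha}")
    return rda(Y, X[:, selected], n_permutations=n_permutations, seed=seed,
               predictor_names=[names[j] for j in selected])


# ---------------------------------------------------------------------------
# Univariate regression
# ---------------------------------------------------------------------------

def linear_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares of y on x with F = (R^2/(1-R^2)) * (n-2).

    A perfect fit reports the overflow-safe sentinel F = inf, p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError(f"regression requires n >= 3, got n = {n}")
    if np.var(x) == 0:
        raise ValueError("x is constant; slope undefined")
    xm, ym = x.mean(), y.mean()
    slope = float(np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2))
    intercept = float(ym - slope * xm)
    fitted = intercept + slope * x
    residuals = y - fitted
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    df = (1, n - 2)
    if 1.0 - r2 < 1e-14:
        f_stat, p = float("inf"), 0.0
        r2 = 1.0
    else:
        f_stat = (r2 / (1.0 - r2)) * (n - 2)
        p = float(sps.f.sf(f_stat, *df))
    return RegressionResult(slope=slope, intercept=intercept, f=f_stat, df=df,
                            r_squared=r2, p=p, residuals=residuals, fitted=fitted)
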