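"""Questionnaire reliability and exploratory factor analysis.

Implements the preprocessing stage that condenses Likert-scale item responses
into common factors: Pearson item correlations, Cronbach's alpha internal
consistency, the Kaiser-Meyer-Olkin sampling-adequacy statistic, Bartlett's
test of sphericity, and principal-component factor extraction with varimax
rotation. Likert responses are treated as numeric throughout (Pearson, not
polychoric, correlations), matching common survey practice.

All sample variances use the n-1 denominator. Missing responses are rejected
by default; pass ``dropna=True`` to apply listwise deletion instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "compute_correlation",
    "cronbach_alpha",
    "kmo_statistic",
    "bartlett_sphericity",
    "varimax_rotate",
    "varimax_criterion",
    "efa",
    "EfaResult",
    "BartlettResult",
    "ExploratoryFactorAnalysis",
]


def _as_frame(responses, dropna: bool = False) -> pd.DataFrame:
    df = pd.DataFrame(responses)
    if df.isna().any().any():
        if not dropna:
            bad = df.columns[df.isna().any()].tolist()
            raise ValueError(
                f"missing responses in items {bad}; pass dropna=True for "
                "listwise deletion"
            )
        df = df.dropna(axis=0)
    if df.shape[0] < 2:
        raise ValueError("need at least 2 respondents")
    if df.shape[1] < 2:
        raise ValueError("need at least 2 items")
    return df.astype(float)


def compute_correlation(responses, dropna: bool = False) -> pd.DataFrame:
    """Pearson correlation matrix of item responses (unit diagonal exact).

    Raises ``ValueError`` naming the first item with zero variance.
    """
    df = _as_frame(responses, dropna=dropna)
    variances = df.var(ddof=1)
    dead = variances.index[variances == 0.0].tolist()
    if dead:
        raise ValueError(f"item {dead[0]!r} has zero variance; correlation undefined")
    corr = df.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def cronbach_alpha(responses, items: Sequence | None = None, dropna: bool = False) -> float:
    """Cronbach's alpha: ``(k/(k-1)) * (1 - sum(item var) / var(total score))``.

    ``items`` restricts the computation to a subset (e.g. one Haddon
    dimension). Sample variances (ddof=1). Raises if the total-score variance
    is zero, where alpha is undefined.
    """
    df = _as_frame(responses, dropna=dropna)
    if items is not None:
        df = df.loc[:, list(items)]
    k = df.shape[1]
    if k < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    item_var = df.var(ddof=1).sum()
    total_var = df.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        raise ValueError("total-score variance is zero; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def kmo_statistic(corr, ridge: float = 0.0) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy.

    Anti-image partial correlations ``q_ij = -s_ij / sqrt(s_ii s_jj)`` come
    from the inverse correlation matrix ``S = R^-1``; the statistic is
    ``sum r_ij^2 / (sum r_ij^2 + sum q_ij^2)`` over off-diagonal pairs.

    An identity correlation matrix has no common variance at all; by
    convention the statistic is 0 there (with a warning). For a numerically
    singular ``R`` pass a small ``ridge`` (e.g. 1e-8) added to the diagonal
    before inversion.
    """
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p):
        raise ValueError("correlation matrix must be square")
    try:
        S = np.linalg.inv(R + ridge * np.eye(p) if ridge else R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "correlation matrix is singular; retry with a small ridge "
            "(e.g. kmo_statistic(corr, ridge=1e-8))"
        ) from exc
    d = np.sqrt(np.abs(np.diag(S)))
    Q = -S / np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    r2 = float((R[off] ** 2).sum())
    q2 = float((Q[off] ** 2).sum())
    if r2 + q2 == 0.0:
        warnings.warn(
            "all off-diagonal correlations are zero; KMO undefined (0/0), "
            "returning 0.0 (no sampling adequacy)",
            stacklevel=2,
        )
        return 0.0
    return r2 / (r2 + q2)


class BartlettResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def bartlett_sphericity(corr, n: int) -> BartlettResult:
    """Bartlett's test that the correlation matrix is the identity.

    ``chi2 = -(n - 1 - (2p + 5)/6) * ln|R|`` with ``p(p-1)/2`` degrees of
    freedom; ``n`` is the number of respondents behind ``R``.
    """
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    if n <= p:
        raise ValueError(f"need more respondents (n={n}) than items (p={p})")
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("correlation matrix has non-positive determinant")
    statistic = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return BartlettResult(float(statistic), int(df), float(stats.chi2.sf(statistic, df)))


def varimax_criterion(loadings) -> float:
    """Varimax objective: summed column variance of squared loadings."""
    L = np.asarray(loadings, dtype=float)
    sq = L**2
    return float(np.sum(sq**2) / L.shape[0] - np.sum((sq.mean(axis=0)) ** 2))


def varimax_rotate(loadings, max_iter: int = 100, angle_tol: float = 1e-10) -> np.ndarray:
    """Orthogonal varimax rotation of an item x factor loading matrix.

    Kaiser's pairwise algorithm: sweep over factor pairs, rotating each by
    its closed-form criterion-maximizing angle phi = arctan2(D - 2AB/p,
    C - (A^2 - B^2)/p) / 4, until no pair moves. Each planar rotation is
    orthogonal, so row communalities are preserved exactly up to floating
    point, and the criterion never decreases. A single factor is returned
    unchanged (every 1-D orthogonal rotation is a sign flip).
    """
    L = np.array(loadings, dtype=float)
    if L.ndim != 2:
        raise ValueError("loadings must be a 2-D item x factor matrix")
    p, k = L.shape
    if k < 1:
        raise ValueError("need at least one factor")
    if k == 1:
        return L
    for _ in range(max_iter):
        moved = False
        for a in range(k - 1):
            for b in range(a + 1, k):
                x, y = L[:, a], L[:, b]
                u = x**2 - y**2
                v = 2.0 * x * y
                A, B = u.sum(), v.sum()
                C, D = (u**2 - v**2).sum(), 2.0 * (u * v).sum()
                phi = 0.25 * np.arctan2(D - 2.0 * A * B / p, C - (A**2 - B**2) / p)
                if abs(phi) > angle_tol:
                    c, s = np.cos(phi), np.sin(phi)
                    L[:, a], L[:, b] = c * x + s * y, -s * x + c * y
                    moved = True
        if not moved:
            break
    return L


def _tidy_loadings(L: np.ndarray) -> np.ndarray:
    """Deterministic presentation: columns by explained SS descending, then
    sign-flipped so each column's largest-|loading| entry is positive."""
    order = np.argsort(-np.sum(L**2, axis=0), kind="stable")
    L = L[:, order]
    for j in range(L.shape[1]):
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return L


@dataclass
class EfaResult:
    """Principal-component extraction summary.

    ``variance_contribution[j] = 100 * eigenvalue_j / n_items`` for each
    retained factor; ``cumulative_contribution`` is its prefix sum. Loadings
    are post-rotation when ``rotate`` was requested.
    """

    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    variance_contribution: np.ndarray
    cumulative_contribution: np.ndarray
    retained_k: int

    def variance_table(self) -> pd.DataFrame:
        """Table with columns Code / Eigenvalue / Variance contribution
        rate/% / Cumulative contribution rate/% for the retained factors."""
        return pd.DataFrame(
            {
                "Code": [f"Factor{j + 1}" for j in range(self.retained_k)],
                "Eigenvalue": self.eigenvalues[: self.retained_k],
                "Variance contribution rate/%": self.variance_contribution,
                "Cumulative contribution rate/%": self.cumulative_contribution,
            }
        )


def efa(
    corr,
    retention: Literal["kaiser", "cumulative", "fixed"] = "kaiser",
    cumulative_threshold: float = 85.0,
    n_factors: int | None = None,
    rotate: bool = True,
) -> EfaResult:
    """Exploratory factor analysis by principal components.

    Eigendecomposition of the correlation matrix; loadings are eigenvectors
    scaled by the square root of their eigenvalues; retained factors are
    varimax-rotated. Retention rules:

    * ``"kaiser"`` — eigenvalue strictly greater than 1;
    * ``"cumulative"`` — smallest k whose cumulative variance contribution
      reaches ``cumulative_threshold`` percent;
    * ``"fixed"`` — exactly ``n_factors``.

    Run on a correlation matrix of an item subset (e.g. a single Haddon
    dimension) to reproduce per-dimension extraction layouts.
    """
    R = pd.DataFrame(corr)
    vals = R.to_numpy(dtype=float)
    if not np.allclose(vals, vals.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    p = vals.shape[0]
    eigval, eigvec = np.linalg.eigh(vals)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    if retention == "kaiser":
        k = int(np.sum(eigval > 1.0))
    elif retention == "cumulative":
        cum = 100.0 * np.cumsum(eigval) / p
        reached = np.nonzero(cum >= cumulative_threshold)[0]
        k = int(reached[0]) + 1 if reached.size else p
    elif retention == "fixed":
        if n_factors is None:
            raise ValueError("retention='fixed' requires n_factors")
        k = int(n_factors)
    else:
        raise ValueError(f"unknown retention rule {retention!r}")
    if k < 1:
        raise ValueError(f"retention rule {retention!r} retained zero factors")
    if k > p or eigval[k - 1] <= 0:
        raise ValueError("retained factors must have positive eigenvalues")

    L = eigvec[:, :k] * np.sqrt(eigval[:k])
    if rotate and k >= 2:
        L = varimax_rotate(L)
    L = _tidy_loadings(L)
    contrib = 100.0 * eigval[:k] / p
    return EfaResult(
        eigenvalues=eigval,
        loadings=pd.DataFrame(L, index=R.index, columns=[f"Factor{j + 1}" for j in range(k)]),
        variance_contribution=contrib,
        cumulative_contribution=np.cumsum(contrib),
        retained_k=k,
    )


class ExploratoryFactorAnalysis(BaseEstimator):
    """Estimator wrapper over :func:`efa` for raw response matrices.

    Parameters
    ----------
    retention : {"kaiser", "cumulative", "fixed"}
        Factor retention rule (strict eigenvalue > 1 for "kaiser").
    cumulative_threshold : float
        Percent cumulative variance for ``retention="cumulative"``.
    n_factors : int or None
        Factor count for ``retention="fixed"``.
    rotate : bool
        Apply varimax rotation to the retained loadings.
    dropna : bool
        Listwise-delete incomplete respondents instead of raising.

    Fitted attributes: ``correlation_``, ``eigenvalues_``, ``loadings_``,
    ``variance_contribution_``, ``cumulative_contribution_``, ``n_factors_``.
    """

    def __init__(
        self,
        retention: Literal["kaiser", "cumulative", "fixed"] = "kaiser",
        cumulative_threshold: float = 85.0,
        n_factors: int | None = None,
        rotate: bool = True,
        dropna: bool = False,
    ):
        self.retention = retention
        self.cumulative_threshold = cumulative_threshold
        self.n_factors = n_factors
        self.rotate = rotate
        self.dropna = dropna

    def fit(self, X, y=None):
        df = _as_frame(X, dropna=self.dropna)
        self.n_features_in_ = df.shape[1]
        self.feature_names_in_ = np.asarray(df.columns)
        self.correlation_ = compute_correlation(df)
        result = efa(
            self.correlation_,
            retention=self.retention,
            cumulative_threshold=self.cumulative_threshold,
            n_factors=self.n_factors,
            rotate=self.rotate,
        )
        self.result_ = result
        self.eigenvalues_ = result.eigenvalues
        self.loadings_ = result.loadings
        self.variance_contribution_ = result.variance_contribution
        self.cumulative_contribution_ = result.cumulative_contribution
        self.n_factors_ = result.retained_k
        return self
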