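"""Latent-variable modeling: NIPALS PCA with Q2 cross-validation, a
two-sample Hotelling T-squared test on scores, and single-component PLS1
regression of tumor mass on the predictor panel.

PCA is extracted component-wise by NIPALS on mean-centered, unit-variance
scaled data (the chemometrics default).  R2X per component is the fraction
of total (scaled) sum of squares captured; Q2 is estimated by contiguous
row-wise K-fold cross-validation with per-component PRESS:

    Q2_a   = 1 - PRESS_a / SS_{a-1},
    Q2cum  = 1 - prod_a PRESS_a / SS_{a-1},

where SS_{a-1} is the residual sum of squares of the full-data model after
a-1 components.  Commercial element-wise CV schemes differ in detail;
published R2X/Q2 values from such tools are data- and scheme-dependent and
are not reproduction targets of this implementation.

Sign convention: each loading's largest-magnitude element is made
positive, so loadings and scores are reproducible across runs and match
oracle decompositions up to that convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InsufficientDataError

_NIPALS_TOL = 1e-9
_NIPALS_MAX_ITER = 500


@dataclass(frozen=True)
class MultivariateModel:
    """NIPALS PCA model on centered/UV-scaled data."""

    n_components: int
    loadings: np.ndarray  # variables x components, orthonormal columns
    scores: np.ndarray  # observations x components
    r2x: np.ndarray  # per component
    r2x_cum: np.ndarray
    variables: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray


@dataclass(frozen=True)
class Q2Result:
    q2: np.ndarray  # per component
    q2_cum: np.ndarray
    n_folds: int


@dataclass(frozen=True)
class HotellingResult:
    t2: float
    f_statistic: float
    df1: int
    df2: int
    p_value: float


@dataclass(frozen=True)
class PLSModel:
    """One-component PLS1: coefficients on the UV-scaled predictor scale."""

    n_components: int
    coefficients: pd.Series  # indexed by variable name
    weights: pd.Series
    explained_y_variance: float


def _as_matrix(X) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(map(str, X.columns))
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be a 2-D matrix of observations x variables")
    return arr, tuple(f"x{j}" for j in range(arr.shape[1]))


def _preprocess(X, names=None):
    arr, cols = _as_matrix(X)
    if names is not None:
        cols = names
    center = arr.mean(axis=0)
    scale = arr.std(axis=0, ddof=1)
    zero = np.flatnonzero(scale == 0)
    if zero.size:
        raise DegenerateDataError(
            f"zero-variance column(s) under unit-variance scaling: "
            f"{[cols[j] for j in zero]}"
        )
    return (arr - center) / scale, cols, center, scale


def _nipals_component(E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One NIPALS component of the residual matrix E -> (scores, loading)."""
    start = int(np.argmax((E**2).sum(axis=0)))
    t = E[:, start].copy()
    if not np.any(t):
        t = E[:, 0] + 1e-12
    for _ in range(_NIPALS_MAX_ITER):
        p = E.T @ t / (t @ t)
        p /= np.linalg.norm(p)
        t_new = E @ p
        if np.linalg.norm(t_new - t) <= _NIPALS_TOL * max(np.linalg.norm(t_new), 1e-300):
            t = t_new
            break
        t = t_new
    # sign convention: largest-|element| of the loading is positive
    j = int(np.argmax(np.abs(p)))
    if p[j] < 0:
        p = -p
        t = -t
    return t, p


def pca_fit(X, n_components: int) -> MultivariateModel:
    """NIPALS principal-component model of centered, UV-scaled X."""
    Z, cols, center, scale = _preprocess(X)
    n, m = Z.shape
    if n < 3 or m < 2:
        raise InsufficientDataError("need >= 3 observations and >= 2 variables")
    if not 1 <= n_components <= min(n, m):
        raise ValueError(
            f"n_components must lie in [1, min(n_obs, n_vars)] = [1, {min(n, m)}]"
        )
    total_ss = float((Z**2).sum())
    E = Z.copy()
    scores = np.empty((n, n_components))
    loadings = np.empty((m, n_components))
    r2x = np.empty(n_components)
    for a in range(n_components):
        t, p = _nipals_component(E)
        E -= np.outer(t, p)
        scores[:, a] = t
        loadings[:, a] = p
        r2x[a] = (t @ t) / total_ss
    return MultivariateModel(
        n_components=n_components,
        loadings=loadings,
        scores=scores,
        r2x=r2x,
        r2x_cum=np.cumsum(r2x),
        variables=cols,
        center=center,
        scale=scale,
    )


def q2_crossval(X, n_components: int, n_folds: int = 7) -> Q2Result:
    """Cross-validated Q2 per component via contiguous row-wise folds.

    Preprocessing (center/scale) is estimated once on the full data; each
    fold refits the NIPALS model on the remaining rows and predicts the
    held-out rows by projection onto the training loadings.
    """
    Z, _, _, _ = _preprocess(X)
    n, m = Z.shape
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n < n_folds:
        raise InsufficientDataError(
            f"need at least n_folds={n_folds} observations, got {n}"
        )
    if not 1 <= n_components <= min(n - int(np.ceil(n / n_folds)), m):
        raise ValueError("n_components too large for the fold sizes")

    # residual SS of the full-data model after each number of components
    full = pca_fit(X, n_components)
    ss = np.empty(n_components + 1)
    ss[0] = float((Z**2).sum())
    E = Z.copy()
    for a in range(n_components):
        E -= np.outer(full.scores[:, a], full.loadings[:, a])
        ss[a + 1] = float((E**2).sum())

    press = np.zeros(n_components)
    fold_ids = np.array_split(np.arange(n), n_folds)
    for held in fold_ids:
        train = np.setdiff1d(np.arange(n), held)
        Etr = Z[train].copy()
        Eho = Z[held].copy()
        for a in range(n_components):
            t, p = _nipals_component(Etr)
            Etr -= np.outer(t, p)
            t_ho = Eho @ p
            Eho -= np.outer(t_ho, p)
            press[a] += float((Eho**2).sum())
    ratio = press / ss[:-1]
    return Q2Result(q2=1.0 - ratio, q2_cum=1.0 - np.cumprod(ratio), n_folds=n_folds)


def hotelling_two_group(scores, labels) -> HotellingResult:
    """Two-sample Hotelling T-squared test with pooled covariance.

    The statistic is referred to its exact F distribution,
    F = (n1+n2-p-1)/(p (n1+n2-2)) * T2 ~ F(p, n1+n2-p-1).
    In one dimension T2 equals the squared pooled two-sample t statistic.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    lab = np.asarray(labels)
    names = np.unique(lab)
    if names.size != 2:
        raise ValueError(f"need exactly 2 groups, got {names.size}")
    A = S[lab == names[0]]
    B = S[lab == names[1]]
    n1, n2, p = len(A), len(B), S.shape[1]
    if n1 < p + 1 or n2 < p + 1:
        raise InsufficientDataError(
            f"each group needs >= dimensions+1 = {p + 1} observations "
            f"(got {n1} and {n2})"
        )
    diff = A.mean(axis=0) - B.mean(axis=0)
    Sp = ((n1 - 1) * np.cov(A, rowvar=False, ddof=1)
          + (n2 - 1) * np.cov(B, rowvar=False, ddof=1)) / (n1 + n2 - 2)
    Sp = np.atleast_2d(Sp)
    try:
        sol = np.linalg.solve(Sp, diff)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError("pooled covariance matrix is singular") from exc
    t2 = float((n1 * n2) / (n1 + n2) * (diff @ sol))
    df1 = p
    df2 = n1 + n2 - p - 1
    f_stat = t2 * df2 / (df1 * (n1 + n2 - 2))
    p_value = float(stats.f.sf(f_stat, df1, df2))
    return HotellingResult(t2=t2, f_statistic=float(f_stat), df1=df1, df2=df2,
                           p_value=p_value)


def pls1_fit(X, y) -> PLSModel:
    """Single-component PLS1 of a scalar response on the UV-scaled panel.

    NIPALS for one PLS component reduces to the closed form
    w = X'y / ||X'y||, t = Xw, q = y't / t't; the regression coefficient
    vector on the scaled scale is b = w q.  Coefficient magnitudes rank the
    predictive strength of each X variable; signs give the direction of
    association with the response.
    """
    Z, cols, _, _ = _preprocess(X)
    yv = np.asarray(y, dtype=float).ravel()
    if len(yv) != Z.shape[0]:
        raise ValueError("y length must match the number of observations")
    if np.std(yv) == 0:
        raise DegenerateDataError("response y is constant")
    yc = (yv - yv.mean()) / yv.std(ddof=1)
    w = Z.T @ yc
    norm = np.linalg.norm(w)
    if norm == 0:
        raise DegenerateDataError("X carries no covariance with y")
    w /= norm
    t = Z @ w
    q = float(yc @ t / (t @ t))
    coef = w * q
    resid = yc - t * q
    explained = 1.0 - float(resid @ resid) / float(yc @ yc)
    return PLSModel(
        n_components=1,
        coefficients=pd.Series(coef, index=list(cols), name="pls1_coefficient"),
        weights=pd.Series(w, index=list(cols), name="pls1_weight"),
        explained_y_variance=explained,
    )
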