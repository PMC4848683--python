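"""Per-field mitotic/apoptotic count modeling.

Census counts of mitotic figures and apoptotic bodies per high-power field
(700-1000 cells) are overdispersed relative to Poisson, consistent with a
gamma-mixed Poisson: field-to-field heterogeneity in the latent event rate
yields a negative binomial marginal with variance mean + mean^2/k (k > 0
the gamma shape; k -> infinity recovers Poisson).  This module provides

* per-tumor and group-level indices on both the events-per-field and
  per-cell-fraction scales,
* maximum-likelihood Poisson and negative-binomial fits (profile
  likelihood over the dispersion) with comparable AICs,
* a one-sided index-of-dispersion score test for variance > mean,
* a two-group comparison via a negative-binomial GLM with a group
  indicator (log link, Wald test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .errors import DegenerateDataError, InsufficientDataError


@dataclass(frozen=True)
class CountModelFit:
    family: str  # "poisson" | "negative_binomial"
    mean: float
    dispersion: float | None  # gamma shape k; None for Poisson
    log_likelihood: float
    aic: float
    poisson_limit: bool = False  # NB fit collapsed to the Poisson boundary


@dataclass(frozen=True)
class IndexSummary:
    event: str
    per_tumor: pd.DataFrame  # tumor_id, events_per_field, per_cell_fraction, n_fields
    group_summary: pd.DataFrame | None  # group, mean/sem on both scales


@dataclass(frozen=True)
class OverdispersionResult:
    statistic: float  # index-of-dispersion chi-square
    dof: int
    p_value: float  # one-sided, variance > mean


@dataclass(frozen=True)
class GroupComparison:
    p_value: float
    rate_ratio: float  # group B mean / group A mean under the GLM
    mean_a: float
    mean_b: float
    per_cell_probability_a: float | None
    per_cell_probability_b: float | None
    dispersion: float | None
    method: str


def _validate_counts(counts, minimum: int) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1 or len(arr) < minimum:
        raise InsufficientDataError(f"need >= {minimum} counts, got {arr.size}")
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("counts must be non-negative integers")
    return arr.astype(int)


def compute_indices(
    fields: pd.DataFrame,
    event: str = "mitotic",
    labels: pd.Series | dict | None = None,
) -> IndexSummary:
    """Per-tumor index means over fields, optionally summarized by group.

    The per-tumor value is the mean over that tumor's fields of the event
    count (events per field) and of the per-field fraction events/cells
    (per-cell scale); group mean +/- SEM is then taken over tumors.
    """
    if event not in ("mitotic", "apoptotic"):
        raise ValueError("event must be 'mitotic' or 'apoptotic'")
    col = f"{event}_count"
    if fields.empty:
        raise InsufficientDataError("no fields provided")
    work = fields.copy()
    work["_fraction"] = work[col] / work["total_cells"]
    per_tumor = (
        work.groupby("tumor_id")
        .agg(
            events_per_field=(col, "mean"),
            per_cell_fraction=("_fraction", "mean"),
            n_fields=(col, "size"),
        )
        .reset_index()
    )
    group_summary = None
    if labels is not None:
        lab = pd.Series(labels) if isinstance(labels, dict) else labels
        per_tumor["group"] = per_tumor["tumor_id"].map(lab)
        rows = []
        for name, grp in per_tumor.groupby("group", sort=True):
            rows.append(
                {
                    "group": name,
                    "n_tumors": len(grp),
                    "events_per_field_mean": grp["events_per_field"].mean(),
                    "events_per_field_sem": grp["events_per_field"].sem(),
                    "per_cell_fraction_mean": grp["per_cell_fraction"].mean(),
                    "per_cell_fraction_sem": grp["per_cell_fraction"].sem(),
                }
            )
        group_summary = pd.DataFrame(rows)
    return IndexSummary(event=event, per_tumor=per_tumor, group_summary=group_summary)


def fit_poisson(counts) -> CountModelFit:
    """ML Poisson fit: mean = sample mean; AIC with one parameter."""
    arr = _validate_counts(counts, minimum=5)
    mean = float(arr.mean())
    if mean == 0:
        raise DegenerateDataError("all counts are zero; Poisson mean not positive")
    ll = float(stats.poisson.logpmf(arr, mean).sum())
    return CountModelFit(
        family="poisson", mean=mean, dispersion=None, log_likelihood=ll,
        aic=2.0 - 2.0 * ll,
    )


def _nb_loglik(arr: np.ndarray, mean: float, k: float) -> float:
    # scipy parameterization: n = k, p = k / (k + mean)
    return float(stats.nbinom.logpmf(arr, k, k / (k + mean)).sum())


_K_MAX = 1e8  # dispersion above this is operationally Poisson


def fit_negbin(counts) -> CountModelFit:
    """ML negative-binomial fit via profile likelihood on the dispersion k.

    For fixed k the mean MLE is the sample mean, so only k is profiled
    (maximized over log k).  When the sample variance does not exceed the
    mean the profile maximizes at the k -> infinity boundary; the fit is
    then returned with ``poisson_limit=True`` and the Poisson likelihood,
    rather than failing.
    """
    arr = _validate_counts(counts, minimum=5)
    mean = float(arr.mean())
    if mean == 0:
        raise DegenerateDataError("all counts are zero; cannot fit a count model")
    var = float(arr.var(ddof=1))
    if var <= mean:
        base = fit_poisson(arr)
        return CountModelFit(
            family="negative_binomial", mean=mean, dispersion=math.inf,
            log_likelihood=base.log_likelihood, aic=4.0 - 2.0 * base.log_likelihood,
            poisson_limit=True,
        )
    res = optimize.minimize_scalar(
        lambda logk: -_nb_loglik(arr, mean, math.exp(logk)),
        bounds=(-12.0, math.log(_K_MAX)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    k = float(math.exp(res.x))
    ll = _nb_loglik(arr, mean, k)
    poisson_limit = k >= _K_MAX * 0.99
    return CountModelFit(
        family="negative_binomial", mean=mean, dispersion=k,
        log_likelihood=ll, aic=4.0 - 2.0 * ll, poisson_limit=poisson_limit,
    )


def overdispersion_test(counts) -> OverdispersionResult:
    """Index-of-dispersion score test of Poisson against variance > mean.

    D = sum (y - ybar)^2 / ybar is approximately chi-square(n-1) under the
    Poisson null; the p-value is the upper tail (one-sided for
    overdispersion).
    """
    arr = _validate_counts(counts, minimum=10)
    mean = float(arr.mean())
    if np.all(arr == arr[0]):
        raise DegenerateDataError("constant counts carry no dispersion information")
    if mean == 0:
        raise DegenerateDataError("zero-mean counts")
    d = float(((arr - mean) ** 2).sum() / mean)
    dof = arr.size - 1
    p = float(stats.chi2.sf(d, dof))
    return OverdispersionResult(statistic=d, dof=dof, p_value=p)


def compare_groups_nb(
    counts_a,
    counts_b,
    cells_a=None,
    cells_b=None,
) -> GroupComparison:
    """Two-group comparison via a negative-binomial GLM group contrast.

    Fits log E[y] = b0 + b1*group with NB variance (alpha = 1/k estimated
    from a pooled profile-ML fit) and reports the Wald p-value for b1.  If
    the pooled fit collapses to the Poisson boundary the GLM is Poisson.
    Per-cell event probabilities (mean events per field / mean cells per
    field) are reported when field censuses are supplied.
    """
    a = _validate_counts(counts_a, minimum=5)
    b = _validate_counts(counts_b, minimum=5)
    if a.mean() == 0 or b.mean() == 0:
        raise DegenerateDataError("a group has all-zero counts")
    pooled = fit_negbin(np.concatenate([a, b]))
    y = np.concatenate([a, b]).astype(float)
    X = sm.add_constant(np.concatenate([np.zeros(len(a)), np.ones(len(b))]))
    if pooled.poisson_limit:
        family = sm.families.Poisson()
        method = "poisson-glm-wald"
        dispersion = None
    else:
        family = sm.families.NegativeBinomial(alpha=1.0 / pooled.dispersion)
        method = "nb-glm-wald"
        dispersion = pooled.dispersion
    fit = sm.GLM(y, X, family=family).fit()
    coef = float(fit.params[1])
    p = float(fit.pvalues[1])
    prob_a = prob_b = None
    if cells_a is not None and cells_b is not None:
        prob_a = float(np.mean(a) / np.mean(np.asarray(cells_a, dtype=float)))
        prob_b = float(np.mean(b) / np.mean(np.asarray(cells_b, dtype=float)))
    return GroupComparison(
        p_value=p,
        rate_ratio=float(math.exp(coef)),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        per_cell_probability_a=prob_a,
        per_cell_probability_b=prob_b,
        dispersion=dispersion,
        method=method,
    )
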