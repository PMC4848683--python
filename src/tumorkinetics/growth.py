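"""Strain-specific tumor growth rates from detection-week/necropsy-mass data.

A tumor first palpated *w* weeks before termination has had *w* weeks to
grow beyond the ~100 mg detection threshold, so regressing necropsy mass on
``week_prior_to_end`` estimates the mass-accumulation rate (g/week) under
the tissue-size balance model dS = n(kP - kD): a positive slope quantifies
the net imbalance between proliferation and death.  Note the x-axis
orientation — larger ``week_prior_to_end`` means a longer growth window, so
the expected slope is positive.

Tumors are treated as independent observations (multiple tumors per rat are
statistically clustered; that caveat is inherited from the study design and
documented rather than modeled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InsufficientDataError, SingularDesignError
from .synthgen import TumorRecord, tumors_to_frame


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of necropsy mass (g) on detection week prior to end."""

    slope: float
    slope_se: float
    intercept: float
    n: int
    r_squared: float


@dataclass(frozen=True)
class SlopeComparison:
    """DS-vs-DR growth-rate contrast: fold ratio and slope-difference test."""

    ratio: float
    difference: float
    difference_se: float
    p_value: float
    method: str


def _as_frame(tumors) -> pd.DataFrame:
    if isinstance(tumors, pd.DataFrame):
        return tumors
    if tumors and isinstance(tumors[0], TumorRecord):
        return tumors_to_frame(list(tumors))
    raise TypeError("expected a DataFrame or a list of TumorRecord")


def fit_mass_on_week(tumors) -> RegressionFit:
    """Ordinary least squares of necropsy mass on week prior to end.

    Requires >= 3 tumors spanning >= 2 distinct weeks; the slope standard
    error is the classical OLS formula.
    """
    frame = _as_frame(tumors)
    if len(frame) < 3:
        raise InsufficientDataError(
            f"need >= 3 tumors for a regression fit, got {len(frame)}"
        )
    x = frame["week_prior_to_end"].to_numpy(dtype=float)
    y = frame["necropsy_mass_g"].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise SingularDesignError(
            "all tumors were detected in the same week; slope is not identifiable"
        )
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        n=len(frame),
        r_squared=float(res.rvalue**2),
    )


def fit_by_strain(tumors) -> dict[str, RegressionFit]:
    frame = _as_frame(tumors)
    return {
        strain: fit_mass_on_week(group)
        for strain, group in frame.groupby("strain", sort=True)
    }


def compare_slopes(dr, ds) -> SlopeComparison:
    """Compare DS vs. DR growth rates.

    With raw data (DataFrames or TumorRecord lists) the primary method is
    the pooled-model strain x week interaction t-test.  With summary
    ``RegressionFit`` objects a Welch-style z-test on the slope difference
    is used instead.  The ratio is always slope_DS / slope_DR.
    """
    if isinstance(dr, RegressionFit) and isinstance(ds, RegressionFit):
        return _compare_summary(dr, ds)
    return _compare_pooled(_as_frame(dr), _as_frame(ds))


def _compare_summary(dr: RegressionFit, ds: RegressionFit) -> SlopeComparison:
    if dr.slope == 0:
        raise ZeroDivisionError("DR slope is zero; fold ratio undefined")
    diff = ds.slope - dr.slope
    se = float(np.hypot(dr.slope_se, ds.slope_se))
    if se == 0:
        p = 1.0 if diff == 0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(diff) / se))
    return SlopeComparison(
        ratio=ds.slope / dr.slope,
        difference=diff,
        difference_se=se,
        p_value=p,
        method="summary-z",
    )


def _compare_pooled(dr: pd.DataFrame, ds: pd.DataFrame) -> SlopeComparison:
    fit_dr = fit_mass_on_week(dr)
    fit_ds = fit_mass_on_week(ds)
    if fit_dr.slope == 0:
        raise ZeroDivisionError("DR slope is zero; fold ratio undefined")
    week = np.concatenate(
        [
            dr["week_prior_to_end"].to_numpy(dtype=float),
            ds["week_prior_to_end"].to_numpy(dtype=float),
        ]
    )
    group = np.concatenate([np.zeros(len(dr)), np.ones(len(ds))])
    y = np.concatenate(
        [
            dr["necropsy_mass_g"].to_numpy(dtype=float),
            ds["necropsy_mass_g"].to_numpy(dtype=float),
        ]
    )
    X = sm.add_constant(np.column_stack([week, group, week * group]))
    ols = sm.OLS(y, X).fit()
    # interaction term = slope difference (DS - DR)
    diff = float(ols.params[3])
    se = float(ols.bse[3])
    p = float(ols.pvalues[3])
    if not np.isfinite(p):  # identical duplicated designs can yield se == 0
        p = 1.0 if diff == 0 else 0.0
    return SlopeComparison(
        ratio=fit_ds.slope / fit_dr.slope,
        difference=diff,
        difference_se=se,
        p_value=p,
        method="interaction-t",
    )
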