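"""Deconvolution of tumor growth into cell-cycle and apoptotic durations.

The tissue-size balance dS = n(kP - kD) splits each rate into a compartment
size and a process duration: proliferation contributes Pn/Pd cells per cell
per unit time (Pn = Ki67 immunoreactive percent, Pd = cell-cycle duration
in hours) and death removes Dn/Dd (Dn = apoptotic index, Dd = how long
apoptotic morphology persists, in hours).  Two estimators follow:

* cell-cycle duration:  Pd = Pn / mitotic index;
* apoptotic duration:   Dd = Dn / (Pn/Pd - dS/n),

where dS is the per-tumor growth rate (necropsy mass over the hours between
palpation and termination, in cells/h at 1e-9 g per cell) and n is the
strain-level growth slope converted to cells gained per hour.

Unit caveats, inherited from the estimators' derivation and documented
rather than silently "fixed":

* The published durations arise from dividing Ki67 *percent* by mitotic
  *figures per field* (mode ``as-published``).  A dimensionally strict
  per-cell percentage denominator (mode ``per-cell``) yields durations
  ~8x longer (on the order of a week); both modes are available.
* In the Dd estimator n enters as a *rate* (cells gained/h) although the
  balance equation defines it as a cell number; the estimator is
  implemented as specified, and a non-positive denominator (growth
  exceeding proliferative supply under the model) yields NaN flagged as
  undefined, never a negative duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UndefinedDurationError

#: mass of a single tumor cell, grams
CELL_MASS_G = 1e-9
HOURS_PER_WEEK = 168.0

MODES = ("as-published", "per-cell")


@dataclass(frozen=True)
class KineticEstimate:
    """Per-tumor kinetic deconvolution outputs."""

    tumor_id: str
    strain: str
    pn_pct: float  # Ki67 immunoreactive percent
    mitotic_index: float  # figures per field (as-published) or percent (per-cell)
    dn_index: float  # apoptotic bodies per field (same unit family)
    pd_hours: float  # cell-cycle duration
    delta_s_rate: float  # cells/h, NaN if elapsed time is zero
    n_rate: float  # cells gained/h from the strain slope
    dd_hours: float  # apoptotic duration; NaN when undefined
    dd_defined: bool


def cell_cycle_duration(
    pn_pct: float,
    mitotic_index: float,
    mode: str = "as-published",
    total_cells: float | None = None,
) -> float:
    """Cell-cycle duration (h) = proliferative fraction / mitotic index.

    In ``as-published`` mode ``mitotic_index`` is mitotic figures per field
    and is used as-is.  In ``per-cell`` mode it is converted to a per-cell
    percentage, 100 x figures / ``total_cells``, before dividing.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if pn_pct <= 0:
        raise UndefinedDurationError("proliferative fraction must be > 0")
    if mitotic_index <= 0:
        raise UndefinedDurationError(
            "mitotic index must be > 0 for a finite cell-cycle duration"
        )
    if mode == "per-cell":
        if total_cells is None or total_cells <= 0:
            raise UndefinedDurationError("per-cell mode requires total_cells > 0")
        mitotic_index = 100.0 * mitotic_index / total_cells
    return pn_pct / mitotic_index


def grams_per_week_to_cells_per_hour(rate_g_per_week: float) -> float:
    """Convert a mass-accumulation slope (g/week) to cells gained per hour."""
    if rate_g_per_week < 0:
        raise ValueError("growth rate must be >= 0")
    return rate_g_per_week / (HOURS_PER_WEEK * CELL_MASS_G)


def cells_per_hour_to_grams_per_week(rate_cells_per_hour: float) -> float:
    """Inverse conversion, for unit round-trips."""
    if rate_cells_per_hour < 0:
        raise ValueError("growth rate must be >= 0")
    return rate_cells_per_hour * HOURS_PER_WEEK * CELL_MASS_G


def delta_s_rate(necropsy_mass_g: float, elapsed_hours: float) -> float:
    """Per-tumor growth rate dS (cells/h): final mass over elapsed time."""
    if elapsed_hours <= 0:
        raise ValueError("elapsed hours between palpation and termination must be > 0")
    if necropsy_mass_g < 0:
        raise ValueError("necropsy mass must be >= 0")
    return (necropsy_mass_g / CELL_MASS_G) / elapsed_hours


def apoptotic_duration(
    dn_index: float,
    pn_pct: float,
    pd_hours: float,
    delta_s: float,
    n_rate: float,
) -> float:
    """Apoptotic duration Dd (h) = Dn / ((Pn/Pd) - (dS/n)).

    Returns NaN when the denominator is <= 0, i.e. when observed growth
    meets or exceeds the proliferative supply implied by Pn/Pd — under the
    balance model no finite positive death duration is consistent with
    such a tumor.  A NaN is deliberate: callers must exclude (and count)
    undefined tumors rather than average a negative duration.
    """
    if pd_hours <= 0:
        raise UndefinedDurationError("cell-cycle duration must be > 0")
    if n_rate <= 0:
        raise UndefinedDurationError("cell-gain rate n must be > 0")
    denom = pn_pct / pd_hours - delta_s / n_rate
    if denom <= 0:
        return math.nan
    return dn_index / denom


def percent_difference(reference: float, other: float) -> float:
    """Signed percent difference of ``other`` relative to ``reference``."""
    if reference == 0:
        raise ValueError("reference value must be non-zero")
    return 100.0 * (other - reference) / reference


def compute_kinetics(
    tumors: pd.DataFrame,
    fields: pd.DataFrame,
    ki67: pd.DataFrame,
    strain_slopes: dict[str, float],
    mode: str = "as-published",
) -> pd.DataFrame:
    """Per-tumor kinetic estimates for a whole cohort.

    ``strain_slopes`` maps strain -> growth slope in g/week (from the growth
    stage); it supplies the cell-gain rate n for the Dd estimator.  Tumors
    detected at termination (zero elapsed hours) get NaN dS and undefined Dd.
    """
    per_field = fields.groupby("tumor_id").agg(
        mitotic_per_field=("mitotic_count", "mean"),
        apoptotic_per_field=("apoptotic_count", "mean"),
        cells_per_field=("total_cells", "mean"),
    )
    merged = tumors.merge(ki67[["tumor_id", "ki67_pct"]], on="tumor_id")
    merged = merged.merge(per_field, on="tumor_id")
    rows = []
    for r in merged.itertuples():
        n_rate = grams_per_week_to_cells_per_hour(strain_slopes[r.strain])
        if mode == "per-cell":
            mit_idx = 100.0 * r.mitotic_per_field / r.cells_per_field
            dn_idx = 100.0 * r.apoptotic_per_field / r.cells_per_field
        else:
            mit_idx = r.mitotic_per_field
            dn_idx = r.apoptotic_per_field
        try:
            pd_hours = cell_cycle_duration(r.ki67_pct, mit_idx)
        except UndefinedDurationError:
            pd_hours = math.nan
        hours = r.week_prior_to_end * HOURS_PER_WEEK
        ds = delta_s_rate(r.necropsy_mass_g, hours) if hours > 0 else math.nan
        if math.isnan(pd_hours) or math.isnan(ds):
            dd = math.nan
        else:
            dd = apoptotic_duration(dn_idx, r.ki67_pct, pd_hours, ds, n_rate)
        rows.append(
            KineticEstimate(
                tumor_id=r.tumor_id,
                strain=r.strain,
                pn_pct=float(r.ki67_pct),
                mitotic_index=float(mit_idx),
                dn_index=float(dn_idx),
                pd_hours=float(pd_hours),
                delta_s_rate=float(ds),
                n_rate=float(n_rate),
                dd_hours=float(dd),
                dd_defined=not math.isnan(dd),
            )
        )
    return pd.DataFrame([e.__dict__ for e in rows])


def summarize_kinetics(
    estimates: pd.DataFrame,
    group_col: str = "strain",
    reference_group: str = "DR",
) -> dict:
    """Group mean +/- SEM of each kinetic quantity, plus percent differences.

    Durations are averaged per tumor then across tumors (mean of ratios);
    undefined Dd values are excluded and their count reported.  Percent
    differences are of each non-reference group relative to
    ``reference_group`` on the group means.
    """
    numeric = ["pn_pct", "mitotic_index", "dn_index", "pd_hours", "dd_hours"]
    groups = {}
    for name, grp in estimates.groupby(group_col, sort=True):
        if len(grp) < 2:
            raise InsufficientDataError(
                f"group {name!r} has {len(grp)} tumor(s); need >= 2 for a SEM"
            )
        summary = {}
        for col in numeric:
            vals = grp[col].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                summary[col] = {"mean": math.nan, "sem": math.nan, "n": 0}
                continue
            sem = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) > 1 else 0.0
            summary[col] = {"mean": float(np.mean(vals)), "sem": sem, "n": int(len(vals))}
        summary["n_tumors"] = int(len(grp))
        summary["n_dd_undefined"] = int((~grp["dd_defined"]).sum())
        groups[str(name)] = summary
    result = {"groups": groups, "percent_difference_vs_" + reference_group: {}}
    if reference_group in groups:
        ref = groups[reference_group]
        for name, summary in groups.items():
            if name == reference_group:
                continue
            diffs = {}
            for col in numeric:
                ref_mean = ref[col]["mean"]
                if ref_mean and not math.isnan(ref_mean):
                    diffs[col] = percent_difference(ref_mean, summary[col]["mean"])
            result["percent_difference_vs_" + reference_group][name] = diffs
    return result
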