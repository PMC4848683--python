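"""Protein-expression normalization and derived ratios.

Densitometry/capillary-electrophoresis signals are normalized to the GAPDH
loading control of the same lane (AUOD, arbitrary units of optical density
per GAPDH); derived quantities include the phospho/total ratio (e.g.
phosphorylated to total Rb) and group fold-change / percent-difference
summaries such as the adiposity-depot report.  Image processing is out of
scope: inputs are already-extracted signal numbers.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .kinetics import percent_difference

PANEL_LONG_COLUMNS = ["tumor_id", "analyte", "raw_signal", "gapdh_signal"]


def normalize_to_loading_control(raw_signal, gapdh_signal):
    """Normalized AUOD = raw signal / GAPDH signal (scalar or array)."""
    raw = np.asarray(raw_signal, dtype=float)
    gapdh = np.asarray(gapdh_signal, dtype=float)
    if np.any(gapdh <= 0):
        raise ValueError("GAPDH loading-control signal must be > 0")
    if np.any(raw < 0):
        raise ValueError("raw signal must be >= 0")
    out = raw / gapdh
    return float(out) if out.ndim == 0 else out


def phospho_total_ratio(phospho_norm, total_norm):
    """Ratio of phosphorylated to total protein (normalized signals)."""
    phospho = np.asarray(phospho_norm, dtype=float)
    total = np.asarray(total_norm, dtype=float)
    if np.any(total <= 0):
        raise ValueError("total-protein signal must be > 0")
    out = phospho / total
    return float(out) if out.ndim == 0 else out


def normalize_panel(panel_long: pd.DataFrame) -> pd.DataFrame:
    """Long (tumor_id, analyte, raw_signal, gapdh_signal) -> wide AUOD.

    One row per tumor, one column per analyte, each cell raw/GAPDH; this is
    the input layout for the multivariate stage.
    """
    missing = set(PANEL_LONG_COLUMNS) - set(panel_long.columns)
    if missing:
        raise ValueError(f"panel table is missing column(s): {sorted(missing)}")
    work = panel_long.copy()
    work["auod"] = normalize_to_loading_control(
        work["raw_signal"].to_numpy(), work["gapdh_signal"].to_numpy()
    )
    wide = work.pivot(index="tumor_id", columns="analyte", values="auod")
    wide.columns.name = None
    return wide.reset_index()


def group_summary(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Mean +/- SEM per group for one analyte."""
    frame = pd.DataFrame({"value": values, "group": groups})
    rows = []
    for name, grp in frame.groupby("group", sort=True):
        rows.append(
            {
                "group": name,
                "n": len(grp),
                "mean": grp["value"].mean(),
                "sem": grp["value"].sem(),
            }
        )
    return pd.DataFrame(rows)


def table1_ratio_report(
    depot_means: Mapping[str, tuple[float, float]],
    reference: str = "DR",
    comparison: str = "DS",
) -> pd.DataFrame:
    """Fold changes and percent differences per adiposity depot.

    ``depot_means`` maps depot name -> (reference mean, comparison mean),
    e.g. mammary-gland adipocyte area (um^2/field) of 1128 (DR) vs 1561
    (DS) gives fold 1.38 and +38% to the nearest integer.
    """
    if not depot_means:
        raise ValueError("no depots provided")
    rows = []
    for depot, means in depot_means.items():
        if len(means) != 2:
            raise ValueError(f"depot {depot!r} needs exactly (reference, comparison) means")
        ref, comp = float(means[0]), float(means[1])
        if ref <= 0:
            raise ValueError(f"depot {depot!r}: reference mean must be > 0")
        rows.append(
            {
                "depot": depot,
                f"{reference}_mean": ref,
                f"{comparison}_mean": comp,
                "fold": comp / ref,
                "percent_difference": percent_difference(ref, comp),
            }
        )
    return pd.DataFrame(rows)
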