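"""End-to-end orchestration: simulate -> growth -> kinetics -> counts ->
multivariate, with a consolidated JSON report and a run manifest.

A single config seed fans out deterministically to per-stage child streams
(see ``synthgen``), so the whole run — and any stage re-run in isolation —
is bit-reproducible for the same config.  The report (including its
manifest block) is free of wall-clock information; the wall-clock timestamp
is written to a separate ``run_manifest.json`` outside the determinism
contract.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import CohortConfig
from .errors import InsufficientDataError
from .growth import compare_slopes, fit_by_strain
from .histocounts import compare_groups_nb, compute_indices, fit_negbin, fit_poisson, overdispersion_test
from .kinetics import compute_kinetics, summarize_kinetics
from .multivariate import hotelling_two_group, pca_fit, pls1_fit, q2_crossval
from .synthgen import write_cohort

REPORT_KEYS = ("growth", "kinetics", "counts", "multivariate", "manifest")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise PipelineError(f"stage {stage!r}: required input file not found: {path}")
    return path


def growth_stage(tumors: pd.DataFrame) -> dict:
    fits = fit_by_strain(tumors)
    out = {"per_strain": {s: dataclasses.asdict(f) for s, f in fits.items()}}
    if {"DR", "DS"} <= set(fits):
        comparison = compare_slopes(
            tumors[tumors["strain"] == "DR"], tumors[tumors["strain"] == "DS"]
        )
        out["comparison_ds_vs_dr"] = dataclasses.asdict(comparison)
    return out


def kinetics_stage(tumors, fields, ki67, growth_report, mode="as-published") -> tuple[pd.DataFrame, dict]:
    slopes = {s: f["slope"] for s, f in growth_report["per_strain"].items()}
    estimates = compute_kinetics(tumors, fields, ki67, slopes, mode=mode)
    summary = summarize_kinetics(estimates)
    summary["mode"] = mode
    return estimates, summary


def counts_stage(tumors: pd.DataFrame, fields: pd.DataFrame) -> dict:
    labels = tumors.set_index("tumor_id")["strain"]
    out: dict = {}
    for event in ("mitotic", "apoptotic"):
        col = f"{event}_count"
        idx = compute_indices(fields, event=event, labels=labels)
        entry: dict = {
            "group_indices": idx.group_summary.to_dict(orient="records")
            if idx.group_summary is not None
            else None,
        }
        counts = fields[col].to_numpy()
        entry["poisson_fit"] = dataclasses.asdict(fit_poisson(counts))
        entry["negbin_fit"] = dataclasses.asdict(fit_negbin(counts))
        entry["overdispersion"] = dataclasses.asdict(overdispersion_test(counts))
        by_strain = fields.merge(tumors[["tumor_id", "strain"]], on="tumor_id")
        strains = sorted(by_strain["strain"].unique())
        if len(strains) == 2:
            a = by_strain[by_strain["strain"] == strains[0]]
            b = by_strain[by_strain["strain"] == strains[1]]
            entry["group_comparison"] = dataclasses.asdict(
                compare_groups_nb(
                    a[col].to_numpy(), b[col].to_numpy(),
                    cells_a=a["total_cells"].to_numpy(),
                    cells_b=b["total_cells"].to_numpy(),
                )
            )
            entry["group_comparison"]["groups"] = strains
        out[event] = entry
    return out


def multivariate_stage(panel: pd.DataFrame, tumors: pd.DataFrame, n_components: int = 4) -> dict:
    X = panel.drop(columns=["tumor_id", "strain"])
    n_components = min(n_components, len(X) - int(np.ceil(len(X) / 7)), X.shape[1])
    model = pca_fit(X, n_components)
    q2 = q2_crossval(X, n_components)
    out = {
        "n_components": model.n_components,
        "r2x": model.r2x.tolist(),
        "r2x_cum": model.r2x_cum.tolist(),
        "q2": q2.q2.tolist(),
        "q2_cum": q2.q2_cum.tolist(),
        "variables": list(model.variables),
    }
    labels = panel["strain"].to_numpy()
    if np.unique(labels).size == 2:
        min_group = min(np.sum(labels == g) for g in np.unique(labels))
        n_hot = min(model.n_components, int(min_group) - 1)
        if n_hot >= 1:
            hot = hotelling_two_group(model.scores[:, :n_hot], labels)
            out["hotelling"] = dataclasses.asdict(hot)
            out["hotelling"]["n_score_dimensions"] = n_hot
    mass = panel.merge(tumors[["tumor_id", "necropsy_mass_g"]], on="tumor_id")[
        "necropsy_mass_g"
    ]
    pls = pls1_fit(X, mass.to_numpy())
    coef = pls.coefficients.sort_values(ascending=False)
    out["pls1"] = {
        "coefficients": coef.to_dict(),
        "explained_y_variance": pls.explained_y_variance,
        "top_positive": list(coef.index[:3]),
        "top_negative": list(coef.index[-3:][::-1]),
    }
    return out


def _analysis_report(tumors, fields, ki67, panel, mode: str, out: Path) -> dict:
    report: dict = {}
    stage = "growth"
    try:
        report["growth"] = growth_stage(tumors)
        stage = "kinetics"
        estimates, kin_summary = kinetics_stage(tumors, fields, ki67, report["growth"], mode)
        estimates.to_csv(out / "kinetics.csv", index=False)
        report["kinetics"] = kin_summary
        stage = "counts"
        report["counts"] = counts_stage(tumors, fields)
        stage = "multivariate"
        report["multivariate"] = multivariate_stage(panel, tumors)
    except (InsufficientDataError, ValueError) as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return report


def _finalize(report: dict, manifest: dict, out: Path) -> dict:
    report["manifest"] = manifest
    report = _jsonable(report)
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    wall = dict(report["manifest"])
    wall["timestamp"] = datetime.now(timezone.utc).isoformat()
    wall["report_digest"] = _sha256(report_path)
    (out / "run_manifest.json").write_text(json.dumps(wall, indent=2, sort_keys=True))
    return report


def run_pipeline(config_path, out_dir, mode: str = "as-published") -> dict:
    """Simulate a cohort from a YAML config, then run every analysis stage.

    Writes tumors/fields/ki67/panel CSVs, kinetics.csv, report.json and
    run_manifest.json into ``out_dir``.
    """
    config_path = Path(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = CohortConfig.from_yaml(_require(config_path, "config"))

    paths = write_cohort(config, out)
    tumors = pd.read_csv(_require(paths["tumors"], "simulate"))
    fields = pd.read_csv(_require(paths["fields"], "simulate"))
    ki67 = pd.read_csv(_require(paths["ki67"], "simulate"))
    panel = pd.read_csv(_require(paths["panel"], "simulate"))

    report = _analysis_report(tumors, fields, ki67, panel, mode, out)
    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "version": __version__,
        "input_digests": {name: _sha256(path) for name, path in paths.items()},
    }
    return _finalize(report, manifest, out)


def run_analysis(data_dir, out_dir, mode: str = "as-published") -> dict:
    """Run the analysis stages on existing tumors/fields/ki67/panel CSVs.

    This is the entry point for user-supplied (non-simulated) tables laid
    out like the generator's outputs.
    """
    data = Path(data_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: _require(data / f"{name}.csv", "load") for name in
             ("tumors", "fields", "ki67", "panel")}
    tumors = pd.read_csv(paths["tumors"])
    fields = pd.read_csv(paths["fields"])
    ki67 = pd.read_csv(paths["ki67"])
    panel = pd.read_csv(paths["panel"])
    report = _analysis_report(tumors, fields, ki67, panel, mode, out)
    manifest = {
        "config": None,
        "seed": None,
        "version": __version__,
        "input_digests": {name: _sha256(path) for name, path in paths.items()},
    }
    return _finalize(report, manifest, out)
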