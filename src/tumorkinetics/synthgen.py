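"""Synthetic cohort generator for the two-strain mammary carcinoma study.

Emulates the data-generating process the downstream analysis assumes:

* rats per strain develop carcinomas with strain-specific incidence and
  multiplicity (truncated Poisson, >=1 per tumor-bearing rat);
* each tumor is first palpated an integer number of weeks before study
  termination (uniform over 0..max_detection_week by default) and its
  necropsy mass is linear in that growth window — detection threshold plus
  slope x weeks — with Gaussian noise truncated below at the threshold;
* per-field mitotic/apoptotic figures are gamma-mixed Poisson (negative
  binomial, variance = mean + mean^2/k) over a census of ~700-1000 cells;
* per-tumor Ki67 immunoreactive percent is truncated normal in (0, 100);
* a 29-variable protein/count panel is drawn independently per strain.

All draws descend from ``config.seed`` through fixed ``SeedSequence`` spawn
keys, so each generator is individually reproducible and the full cohort is
byte-identical across runs with the same config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .config import CohortConfig
from .errors import ConfigurationError

_STAGE_COHORT, _STAGE_FIELDS, _STAGE_KI67, _STAGE_PANEL = 0, 1, 2, 3


@dataclass(frozen=True)
class TumorRecord:
    """One carcinoma: identity, detection week and necropsy mass."""

    tumor_id: str
    rat_id: str
    strain: str
    week_prior_to_end: int  # 0 = detected at the termination week
    necropsy_mass_g: float


@dataclass(frozen=True)
class FieldObservation:
    """One 400x high-power field of an H&E-stained tumor section."""

    tumor_id: str
    field_index: int
    total_cells: int
    mitotic_count: int
    apoptotic_count: int
    is_hotspot: bool


def _stage_rng(config: CohortConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(stage,))
    )


def _truncated_poisson_lambda(target_mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given mean (>= 1)."""
    if target_mean <= 1.0 + 1e-12:
        return 0.0

    def gap(lam: float) -> float:
        return lam / (1.0 - math.exp(-lam)) - target_mean

    return brentq(gap, 1e-10, 10.0 * target_mean)


def _sample_truncated_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    if lam == 0.0:
        return np.ones(size, dtype=int)
    out = np.empty(size, dtype=int)
    filled = 0
    while filled < size:
        draws = rng.poisson(lam, size=2 * (size - filled) + 8)
        draws = draws[draws >= 1]
        take = min(len(draws), size - filled)
        out[filled : filled + take] = draws[:take]
        filled += take
    return out


def generate_cohort(config: CohortConfig) -> list[TumorRecord]:
    """Draw the tumor-level cohort: detection weeks and necropsy masses.

    Expected tumor-bearing rats per strain = n_rats x incidence; expected
    necropsy mass = detection_threshold_g + slope x week_prior_to_end
    (linear model) with noise truncated below at the detection threshold,
    so no recorded tumor is lighter than the palpation limit.
    """
    rng = _stage_rng(config, _STAGE_COHORT)
    records: list[TumorRecord] = []
    for strain in config.strains:
        n_rats = config.n_rats_per_strain[strain]
        bearing = rng.binomial(1, config.incidence[strain], size=n_rats).astype(bool)
        lam = _truncated_poisson_lambda(config.multiplicity_mean[strain])
        counts = _sample_truncated_poisson(rng, lam, int(bearing.sum()))
        slope = config.slope_g_per_week[strain]
        thr = config.detection_threshold_g
        tumor_no = 0
        bearing_ids = np.flatnonzero(bearing)
        loc_cache: dict[int, float] = {}
        for rat_idx, n_tumors in zip(bearing_ids, counts):
            rat_id = f"{strain}-r{rat_idx + 1:03d}"
            for _ in range(int(n_tumors)):
                tumor_no += 1
                week = int(rng.integers(0, config.max_detection_week + 1))
                mu = _expected_mass(config, strain, week)
                if config.mass_noise_sd == 0 or mu <= thr:
                    # zero growth window: the tumor was first palpated at the
                    # detection threshold, so its mass is the threshold itself
                    mass = mu
                else:
                    if week not in loc_cache:
                        loc_cache[week] = _truncnorm_location(
                            mu, thr, config.mass_noise_sd
                        )
                    loc = loc_cache[week]
                    a = (thr - loc) / config.mass_noise_sd
                    mass = float(
                        truncnorm.rvs(
                            a, np.inf, loc=loc, scale=config.mass_noise_sd,
                            random_state=rng,
                        )
                    )
                records.append(
                    TumorRecord(
                        tumor_id=f"{strain}-t{tumor_no:03d}",
                        rat_id=rat_id,
                        strain=strain,
                        week_prior_to_end=week,
                        necropsy_mass_g=mass,
                    )
                )
    return records


def _truncnorm_location(target_mean: float, lower: float, sd: float) -> float:
    """Location of a normal truncated below at ``lower`` whose mean is
    ``target_mean``; keeps the mass model linear *in expectation* despite
    the detection-threshold truncation."""

    def gap(loc: float) -> float:
        a = (lower - loc) / sd
        return float(truncnorm.mean(a, np.inf, loc=loc, scale=sd)) - target_mean

    return brentq(gap, target_mean - 12.0 * sd, target_mean)


def _expected_mass(config: CohortConfig, strain: str, week: int) -> float:
    thr = config.detection_threshold_g
    slope = config.slope_g_per_week[strain]
    if config.growth_model == "linear":
        return thr + slope * week
    # Exponential (per-cell kinetics) mode: matched to the linear endpoint at
    # the maximum detection week so the two modes span the same mass range.
    w_max = max(config.max_detection_week, 1)
    end_mass = thr + slope * w_max
    rate = math.log(end_mass / thr) / w_max
    return thr * math.exp(rate * week)


def generate_field_counts(
    tumors: list[TumorRecord], config: CohortConfig
) -> list[FieldObservation]:
    """Draw per-field census and gamma-Poisson mitotic/apoptotic counts.

    For each field the latent Poisson rate is Gamma(shape=k, scale=mean/k),
    giving negative-binomial marginal counts with variance mean + mean^2/k.
    The first ceil(hotspot_percent% x n_fields) fields are flagged hotspots,
    mirroring the Ki67 capture rule.
    """
    if config.n_fields_per_tumor < 1:
        raise ConfigurationError("n_fields_per_tumor must be >= 1")
    if config.nb_dispersion <= 0:
        raise ConfigurationError("nb_dispersion must be > 0")
    rng = _stage_rng(config, _STAGE_FIELDS)
    k = config.nb_dispersion
    n_fields = config.n_fields_per_tumor
    n_hot = math.ceil(n_fields * config.hotspot_percent / 100.0)
    out: list[FieldObservation] = []
    for tumor in tumors:
        cells = rng.normal(config.cells_per_field_mean, config.cells_per_field_sd, n_fields)
        cells = np.clip(np.rint(cells), 500, 1500).astype(int)
        mit = _nb_draw(rng, config.mitotic_mean[tumor.strain], k, n_fields)
        apo = _nb_draw(rng, config.apoptotic_mean[tumor.strain], k, n_fields)
        mit = np.minimum(mit, cells)
        apo = np.minimum(apo, cells)
        for j in range(n_fields):
            out.append(
                FieldObservation(
                    tumor_id=tumor.tumor_id,
                    field_index=j,
                    total_cells=int(cells[j]),
                    mitotic_count=int(mit[j]),
                    apoptotic_count=int(apo[j]),
                    is_hotspot=j < n_hot,
                )
            )
    return out


def _nb_draw(rng: np.random.Generator, mean: float, k: float, size: int) -> np.ndarray:
    lam = rng.gamma(shape=k, scale=mean / k, size=size)
    return rng.poisson(lam)


def generate_ki67(tumors: list[TumorRecord], config: CohortConfig) -> pd.DataFrame:
    """Per-tumor Ki67 immunoreactive percent, truncated to (0, 100)."""
    for strain in config.strains:
        if not 0.0 < config.ki67_mean_pct[strain] < 100.0:
            raise ConfigurationError(f"ki67_mean_pct[{strain}] must lie in (0, 100)")
    rng = _stage_rng(config, _STAGE_KI67)
    rows = []
    for tumor in tumors:
        mu = config.ki67_mean_pct[tumor.strain]
        sd = config.ki67_sd_pct[tumor.strain]
        if sd == 0:
            pct = mu
        else:
            a, b = (0.0 - mu) / sd, (100.0 - mu) / sd
            pct = float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))
        rows.append({"tumor_id": tumor.tumor_id, "strain": tumor.strain, "ki67_pct": pct})
    return pd.DataFrame(rows, columns=["tumor_id", "strain", "ki67_pct"])


def generate_protein_panel(
    tumors: list[TumorRecord], config: CohortConfig
) -> pd.DataFrame:
    """Wide panel matrix: one row per tumor, one column per analyte.

    Each variable is drawn independently per strain from the configured
    Normal(mean, sd); the set of analytes must agree across strains.
    """
    analytes = config.panel_analytes
    for strain in config.strains:
        for name in ("panel_means", "panel_sds"):
            entries = getattr(config, name)[strain]
            if tuple(entries) != analytes and set(entries) != set(analytes):
                raise ConfigurationError(
                    f"{name}[{strain}] has {len(entries)} entries; expected the "
                    f"{len(analytes)} panel analytes"
                )
    rng = _stage_rng(config, _STAGE_PANEL)
    rows = []
    for tumor in tumors:
        means = config.panel_means[tumor.strain]
        sds = config.panel_sds[tumor.strain]
        values = {
            analyte: float(rng.normal(means[analyte], sds[analyte]))
            for analyte in analytes
        }
        rows.append({"tumor_id": tumor.tumor_id, "strain": tumor.strain, **values})
    return pd.DataFrame(rows, columns=["tumor_id", "strain", *analytes])


# -- tabular round-trips ----------------------------------------------------

TUMOR_COLUMNS = ["tumor_id", "rat_id", "strain", "week_prior_to_end", "necropsy_mass_g"]
FIELD_COLUMNS = [
    "tumor_id", "field_index", "total_cells", "mitotic_count", "apoptotic_count",
    "is_hotspot",
]


def tumors_to_frame(tumors: list[TumorRecord]) -> pd.DataFrame:
    return pd.DataFrame([t.__dict__ for t in tumors], columns=TUMOR_COLUMNS)


def frame_to_tumors(frame: pd.DataFrame) -> list[TumorRecord]:
    return [
        TumorRecord(
            tumor_id=str(r.tumor_id),
            rat_id=str(r.rat_id),
            strain=str(r.strain),
            week_prior_to_end=int(r.week_prior_to_end),
            necropsy_mass_g=float(r.necropsy_mass_g),
        )
        for r in frame.itertuples()
    ]


def fields_to_frame(fields: list[FieldObservation]) -> pd.DataFrame:
    return pd.DataFrame([f.__dict__ for f in fields], columns=FIELD_COLUMNS)


def write_cohort(config: CohortConfig, out_dir) -> dict[str, Path]:
    """Generate every table and write tumors/fields/ki67/panel CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tumors = generate_cohort(config)
    fields = generate_field_counts(tumors, config)
    ki67 = generate_ki67(tumors, config)
    panel = generate_protein_panel(tumors, config)
    paths = {
        "tumors": out / "tumors.csv",
        "fields": out / "fields.csv",
        "ki67": out / "ki67.csv",
        "panel": out / "panel.csv",
    }
    tumors_to_frame(tumors).to_csv(paths["tumors"], index=False)
    fields_to_frame(fields).to_csv(paths["fields"], index=False)
    ki67.to_csv(paths["ki67"], index=False)
    panel.to_csv(paths["panel"], index=False)
    return paths
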