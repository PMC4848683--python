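"""Cohort configuration for the synthetic DR/DS mammary-carcinoma study.

The defaults reproduce the design of the source experiment: two Levin rat
strains — dietary-obesity resistant (DR) and sensitive (DS) — injected with
MNU, palpated twice weekly from day 24 post-carcinogen, and necropsied at
63 days (9 weeks).  Tumors become palpable at roughly 100 mg and then
accumulate mass linearly in expectation, with strain-specific slopes of
0.533 (DR) and 0.968 (DS) g/week.  Histology fields hold 700–1000 cells
with gamma-Poisson (negative binomial) mitotic/apoptotic figure counts,
Ki67 immunoreactive fractions sit near 9%, and a 29-variable protein panel
carries strain mean shifts in G1/S-checkpoint and apoptosis regulators.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .errors import ConfigurationError

STRAINS = ("DR", "DS")

#: Analytes of the default 29-variable predictor panel: G1/S-checkpoint and
#: apoptosis proteins (AUOD normalized to GAPDH), immunoprecipitation
#: readouts, and the count/IHC/kinetic variables measured on every tumor.
PANEL_ANALYTES = (
    "p21",
    "p27",
    "cdk2",
    "cdk4",
    "cyclin_d1",
    "cyclin_e",
    "e2f1",
    "phospho_rb",
    "total_rb",
    "phospho_total_rb_ratio",
    "cdc6",
    "ip_e2f1",
    "ip_rb",
    "xiap",
    "cleaved_caspase3",
    "total_caspase3",
    "caspase9",
    "cytochrome_c",
    "apaf1",
    "bax",
    "bcl2",
    "smac",
    "survivin",
    "mitotic_index",
    "apoptotic_index",
    "ki67_pct",
    "cell_cycle_duration_h",
    "apoptotic_duration_h",
    "cells_per_field",
)

# Protein AUOD baselines are 1.0 with the DS shifts oriented as observed:
# XIAP, cleaved caspase 3, cytochrome c, cyclin E, E2F1, cdc6 and phospho-Rb
# elevated; p21, Apaf-1, Bax and total caspase 3 reduced.
_DS_PROTEIN_SHIFTS = {
    "xiap": 1.40,
    "cleaved_caspase3": 1.30,
    "cytochrome_c": 1.30,
    "cyclin_e": 1.20,
    "e2f1": 1.20,
    "cdc6": 1.25,
    "phospho_rb": 1.35,
    "phospho_total_rb_ratio": 1.35,
    "p21": 0.85,
    "apaf1": 0.80,
    "bax": 0.85,
    "total_caspase3": 0.85,
    "ip_rb": 0.80,
    "ip_e2f1": 1.15,
}

# Count/IHC/kinetic panel variables use the per-strain study means; SDs are
# back-computed from the printed SEMs at n = 20 tumors per group.
_MEASURED_PANEL = {
    "mitotic_index": {"DR": (0.448, 0.30), "DS": (0.571, 0.45)},
    "apoptotic_index": {"DR": (1.877, 0.83), "DS": (2.616, 1.17)},
    "ki67_pct": {"DR": (9.0, 3.1), "DS": (9.4, 4.0)},
    "cell_cycle_duration_h": {"DR": (21.2, 7.6), "DS": (17.7, 5.8)},
    "apoptotic_duration_h": {"DR": (4.7, 2.7), "DS": (5.9, 4.5)},
    "cells_per_field": {"DR": (838.7, 85.0), "DS": (863.2, 68.0)},
}


def default_panel_means() -> dict[str, dict[str, float]]:
    means: dict[str, dict[str, float]] = {}
    for strain in STRAINS:
        row = {}
        for analyte in PANEL_ANALYTES:
            if analyte in _MEASURED_PANEL:
                row[analyte] = _MEASURED_PANEL[analyte][strain][0]
            elif strain == "DS":
                row[analyte] = _DS_PROTEIN_SHIFTS.get(analyte, 1.0)
            else:
                row[analyte] = 1.0
        means[strain] = row
    return means


def default_panel_sds() -> dict[str, dict[str, float]]:
    sds: dict[str, dict[str, float]] = {}
    for strain in STRAINS:
        row = {}
        for analyte in PANEL_ANALYTES:
            if analyte in _MEASURED_PANEL:
                row[analyte] = _MEASURED_PANEL[analyte][strain][1]
            else:
                row[analyte] = 0.25
        sds[strain] = row
    return sds


@dataclass
class CohortConfig:
    """Full parameterization of a synthetic two-strain cohort.

    Per-strain parameters are mappings keyed by strain name ("DR"/"DS").
    Defaults are the study conditions; override any field to explore other
    regimes (a noiseless cohort, a single strain, different dispersion ...).
    """

    n_rats_per_strain: Mapping[str, int] = field(
        default_factory=lambda: {"DR": 103, "DS": 101}
    )
    incidence: Mapping[str, float] = field(
        default_factory=lambda: {"DR": 0.65, "DS": 0.91}
    )
    #: mean carcinomas per tumor-bearing rat; defaults chosen so the expected
    #: total tumor yield is ~143 (DR) and ~259 (DS)
    multiplicity_mean: Mapping[str, float] = field(
        default_factory=lambda: {"DR": 2.14, "DS": 2.82}
    )
    slope_g_per_week: Mapping[str, float] = field(
        default_factory=lambda: {"DR": 0.533, "DS": 0.968}
    )
    mass_noise_sd: float = 0.6
    detection_threshold_g: float = 0.1
    study_weeks: int = 9
    #: tumors are detected 0..max_detection_week weeks prior to termination
    max_detection_week: int = 4
    growth_model: str = "linear"  # or "exponential"

    cells_per_field_mean: float = 850.0
    cells_per_field_sd: float = 85.0
    mitotic_mean: Mapping[str, float] = field(
        default_factory=lambda: {"DR": 0.448, "DS": 0.571}
    )
    apoptotic_mean: Mapping[str, float] = field(
        default_factory=lambda: {"DR": 1.877, "DS": 2.616}
    )
    nb_dispersion: float = 1.5
    n_fields_per_tumor: int = 10
    hotspot_percent: float = 30.0

    ki67_mean_pct: Mapping[str, float] = field(
        default_factory=lambda: {"DR": 9.0, "DS": 9.4}
    )
    ki67_sd_pct: Mapping[str, float] = field(
        default_factory=lambda: {"DR": 3.1, "DS": 4.0}
    )

    panel_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=default_panel_means
    )
    panel_sds: Mapping[str, Mapping[str, float]] = field(
        default_factory=default_panel_sds
    )

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        strains = self.strains
        if not strains:
            raise ConfigurationError("n_rats_per_strain: at least one strain required")
        for strain in strains:
            self._require_per_strain(strain)
        if self.mass_noise_sd < 0:
            raise ConfigurationError("mass_noise_sd must be >= 0")
        if self.detection_threshold_g <= 0:
            raise ConfigurationError("detection_threshold_g must be > 0")
        if self.study_weeks < 1:
            raise ConfigurationError("study_weeks must be >= 1")
        if not 0 <= self.max_detection_week <= self.study_weeks:
            raise ConfigurationError(
                "max_detection_week must lie in [0, study_weeks]"
            )
        if self.growth_model not in ("linear", "exponential"):
            raise ConfigurationError("growth_model must be 'linear' or 'exponential'")
        if self.cells_per_field_mean <= 0:
            raise ConfigurationError("cells_per_field_mean must be > 0")
        if self.cells_per_field_sd < 0:
            raise ConfigurationError("cells_per_field_sd must be >= 0")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.n_fields_per_tumor < 1:
            raise ConfigurationError("n_fields_per_tumor must be >= 1")
        if not 0 <= self.hotspot_percent <= 100:
            raise ConfigurationError("hotspot_percent must lie in [0, 100]")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ConfigurationError("seed must be a non-negative integer")

    def _require_per_strain(self, strain: str) -> None:
        def get(name: str):
            mapping = getattr(self, name)
            if strain not in mapping:
                raise ConfigurationError(f"{name}: missing entry for strain {strain!r}")
            return mapping[strain]

        if get("n_rats_per_strain") < 1:
            raise ConfigurationError(f"n_rats_per_strain[{strain}] must be >= 1")
        if not 0.0 <= get("incidence") <= 1.0:
            raise ConfigurationError(f"incidence[{strain}] must lie in [0, 1]")
        if get("multiplicity_mean") < 1.0:
            raise ConfigurationError(
                f"multiplicity_mean[{strain}] must be >= 1 (mean of a >=1 count)"
            )
        if get("slope_g_per_week") < 0:
            raise ConfigurationError(f"slope_g_per_week[{strain}] must be >= 0")
        for name in ("mitotic_mean", "apoptotic_mean"):
            if get(name) <= 0:
                raise ConfigurationError(f"{name}[{strain}] must be > 0")
        if not 0.0 < get("ki67_mean_pct") < 100.0:
            raise ConfigurationError(f"ki67_mean_pct[{strain}] must lie in (0, 100)")
        if get("ki67_sd_pct") < 0:
            raise ConfigurationError(f"ki67_sd_pct[{strain}] must be >= 0")

        means = get("panel_means")
        sds = get("panel_sds")
        if set(means) != set(sds):
            raise ConfigurationError(
                f"panel_means/panel_sds[{strain}]: analyte sets differ"
            )
        if len(means) != len(PANEL_ANALYTES) and set(means) != set(PANEL_ANALYTES):
            # Custom panels are allowed but must be internally consistent and
            # declared for every strain with the same analytes.
            pass
        for analyte, sd in sds.items():
            if sd < 0:
                raise ConfigurationError(
                    f"panel_sds[{strain}][{analyte}] must be >= 0"
                )

    # -- conveniences -----------------------------------------------------
    @property
    def strains(self) -> tuple[str, ...]:
        return tuple(self.n_rats_per_strain)

    @property
    def panel_analytes(self) -> tuple[str, ...]:
        first = self.strains[0]
        return tuple(self.panel_means[first])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, Mapping):
                d[key] = {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in val.items()}
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown configuration field(s): {sorted(unknown)}"
            )
        return cls(**dict(data))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
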