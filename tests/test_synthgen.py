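"""Generator contracts: determinism, noiseless exactness, count moments."""

import numpy as np
import pytest

from tumorkinetics import (
    generate_cohort,
    generate_field_counts,
    generate_ki67,
    generate_protein_panel,
)
from tumorkinetics.config import PANEL_ANALYTES, CohortConfig
from tumorkinetics.errors import ConfigurationError
from tumorkinetics.synthgen import fields_to_frame, tumors_to_frame


def test_noiseless_mass_is_exactly_linear(make_config):
    cfg = make_config(
        mass_noise_sd=0.0,
        slope_g_per_week={"DR": 0.5, "DS": 0.5},
        detection_threshold_g=0.1,
        seed=1,
    )
    for tumor in generate_cohort(cfg):
        assert tumor.necropsy_mass_g == pytest.approx(
            0.1 + 0.5 * tumor.week_prior_to_end, abs=0.0
        )


def test_same_seed_gives_identical_outputs(make_config):
    cfg_a, cfg_b = make_config(seed=42), make_config(seed=42)
    tumors_a, tumors_b = generate_cohort(cfg_a), generate_cohort(cfg_b)
    assert tumors_a == tumors_b
    assert generate_field_counts(tumors_a, cfg_a) == generate_field_counts(tumors_b, cfg_b)
    assert generate_ki67(tumors_a, cfg_a).equals(generate_ki67(tumors_b, cfg_b))
    assert generate_protein_panel(tumors_a, cfg_a).equals(
        generate_protein_panel(tumors_b, cfg_b)
    )


def test_different_seeds_differ(make_config):
    masses_a = [t.necropsy_mass_g for t in generate_cohort(make_config(seed=1))]
    masses_b = [t.necropsy_mass_g for t in generate_cohort(make_config(seed=2))]
    assert masses_a != masses_b


def test_cohort_size_and_mass_floor(make_config):
    cfg = make_config(seed=5)
    tumors = generate_cohort(cfg)
    by_strain = {s: [t for t in tumors if t.strain == s] for s in ("DR", "DS")}
    # expected yields ~143 (DR) and ~259 (DS); allow generous sampling slack
    assert 100 <= len(by_strain["DR"]) <= 190
    assert 200 <= len(by_strain["DS"]) <= 320
    for t in tumors:
        assert t.necropsy_mass_g >= cfg.detection_threshold_g
        assert 0 <= t.week_prior_to_end <= cfg.max_detection_week


def test_mass_expectation_is_linear_in_week(make_config):
    """Mean-adjusted truncation keeps E[mass | week] on the configured line."""
    cfg = make_config(seed=9, n_rats_per_strain={"DR": 2000}, incidence={"DR": 1.0},
                      multiplicity_mean={"DR": 2.0}, slope_g_per_week={"DR": 0.533},
                      mitotic_mean={"DR": 0.448}, apoptotic_mean={"DR": 1.877},
                      ki67_mean_pct={"DR": 9.0}, ki67_sd_pct={"DR": 3.1},
                      panel_means={"DR": dict.fromkeys(PANEL_ANALYTES, 1.0)},
                      panel_sds={"DR": dict.fromkeys(PANEL_ANALYTES, 0.1)})
    frame = tumors_to_frame(generate_cohort(cfg))
    for week, grp in frame.groupby("week_prior_to_end"):
        expected = 0.1 + 0.533 * week
        assert grp["necropsy_mass_g"].mean() == pytest.approx(
            expected, abs=4 * 0.6 / np.sqrt(len(grp))
        )


@pytest.mark.parametrize(
    "field,value",
    [
        ("incidence", {"DR": 1.5, "DS": 0.9}),
        ("nb_dispersion", -1.0),
        ("n_fields_per_tumor", 0),
        ("study_weeks", 0),
        ("ki67_mean_pct", {"DR": 101.0, "DS": 9.4}),
        ("multiplicity_mean", {"DR": 0.5, "DS": 2.8}),
        ("mass_noise_sd", -0.1),
    ],
)
def test_invalid_config_raises_and_names_field(field, value):
    with pytest.raises(ConfigurationError) as exc:
        CohortConfig(**{field: value})
    assert field.split("[")[0] in str(exc.value)


def test_zero_fields_requested_rejected(make_config):
    cfg = make_config(seed=1)
    cfg.n_fields_per_tumor = 0  # bypass constructor validation
    with pytest.raises(ConfigurationError):
        generate_field_counts(generate_cohort(make_config(seed=1)), cfg)


class TestFieldCounts:
    def test_poisson_limit_variance_ratio(self, small_config):
        """At huge dispersion the gamma mixture collapses to Poisson."""
        cfg = small_config(
            seed=3,
            n_rats_per_strain={"DR": 1},
            multiplicity_mean={"DR": 1.0},
            incidence={"DR": 1.0},
            slope_g_per_week={"DR": 0.533},
            mitotic_mean={"DR": 0.448},
            apoptotic_mean={"DR": 1.877},
            ki67_mean_pct={"DR": 9.0},
            ki67_sd_pct={"DR": 3.1},
            panel_means={"DR": dict.fromkeys(PANEL_ANALYTES, 1.0)},
            panel_sds={"DR": dict.fromkeys(PANEL_ANALYTES, 0.1)},
            nb_dispersion=1e6,
            n_fields_per_tumor=100_000,
        )
        tumors = generate_cohort(cfg)[:1]
        fields = fields_to_frame(generate_field_counts(tumors, cfg))
        counts = fields["mitotic_count"].to_numpy()
        assert 0.98 <= counts.var(ddof=1) / counts.mean() <= 1.02

    @pytest.mark.parametrize("k", [0.5, 1.5, 5.0])
    def test_nb_variance_identity(self, small_config, k):
        """Sample variance matches mean + mean^2/k within 5% at 1e5 fields."""
        mean = 2.616
        cfg = small_config(
            seed=4,
            n_rats_per_strain={"DS": 1},
            multiplicity_mean={"DS": 1.0},
            incidence={"DS": 1.0},
            slope_g_per_week={"DS": 0.968},
            mitotic_mean={"DS": 0.571},
            apoptotic_mean={"DS": mean},
            ki67_mean_pct={"DS": 9.4},
            ki67_sd_pct={"DS": 4.0},
            panel_means={"DS": dict.fromkeys(PANEL_ANALYTES, 1.0)},
            panel_sds={"DS": dict.fromkeys(PANEL_ANALYTES, 0.1)},
            nb_dispersion=k,
            n_fields_per_tumor=100_000,
        )
        tumors = generate_cohort(cfg)[:1]
        fields = fields_to_frame(generate_field_counts(tumors, cfg))
        counts = fields["apoptotic_count"].to_numpy()
        expected_var = mean + mean**2 / k
        assert counts.var(ddof=1) == pytest.approx(expected_var, rel=0.05)
        assert counts.var(ddof=1) >= counts.mean()  # gamma-Poisson is overdispersed

    def test_census_and_hotspot_flags(self, small_config):
        cfg = small_config(seed=6, hotspot_percent=30.0, n_fields_per_tumor=10)
        tumors = generate_cohort(cfg)
        fields = generate_field_counts(tumors, cfg)
        frame = fields_to_frame(fields)
        assert frame["total_cells"].between(500, 1500).all()
        assert (frame["mitotic_count"] <= frame["total_cells"]).all()
        assert (frame["apoptotic_count"] <= frame["total_cells"]).all()
        per_tumor = frame.groupby("tumor_id")["is_hotspot"].sum()
        assert (per_tumor == 3).all()  # ceil(10 * 30%)


class TestKi67:
    def test_degenerate_sd_gives_exact_mean(self, small_config):
        cfg = small_config(seed=2, ki67_sd_pct={"DR": 0.0, "DS": 0.0})
        tumors = generate_cohort(cfg)
        ki67 = generate_ki67(tumors, cfg)
        dr = ki67[ki67["strain"] == "DR"]["ki67_pct"]
        assert (dr == 9.0).all()

    def test_group_mean_within_clt_band(self, small_config):
        """Cohort mean lands within 3 SEM of the configured mean (CLT)."""
        hits = 0
        for seed in range(200):
            cfg = small_config(seed=seed)
            tumors = [t for t in generate_cohort(cfg) if t.strain == "DR"][:20]
            vals = generate_ki67(tumors, cfg)["ki67_pct"].to_numpy()
            sem = vals.std(ddof=1) / np.sqrt(len(vals))
            hits += abs(vals.mean() - 9.0) <= 3 * sem
        assert hits >= 0.97 * 200

    def test_values_in_open_unit_percent_interval(self, small_config):
        cfg = small_config(seed=8, ki67_sd_pct={"DR": 30.0, "DS": 30.0})
        vals = generate_ki67(generate_cohort(cfg), cfg)["ki67_pct"]
        assert ((vals > 0) & (vals < 100)).all()


class TestPanel:
    def test_zero_sd_identical_means_no_group_difference(self, small_config):
        means = dict.fromkeys(PANEL_ANALYTES, 1.0)
        cfg = small_config(
            seed=3,
            panel_means={"DR": means, "DS": dict(means)},
            panel_sds={
                "DR": dict.fromkeys(PANEL_ANALYTES, 0.0),
                "DS": dict.fromkeys(PANEL_ANALYTES, 0.0),
            },
        )
        panel = generate_protein_panel(generate_cohort(cfg), cfg)
        grouped = panel.groupby("strain")[list(PANEL_ANALYTES)].mean()
        assert np.allclose(grouped.loc["DR"], grouped.loc["DS"])

    def test_dimension_mismatch_rejected(self, small_config):
        short = dict.fromkeys(PANEL_ANALYTES[:-1], 1.0)  # 28 entries
        cfg = small_config(seed=3)
        setattr(cfg, "panel_means", {"DR": short, "DS": short})
        with pytest.raises(ConfigurationError):
            generate_protein_panel(generate_cohort(small_config(seed=3)), cfg)

    def test_panel_has_29_variables_and_strain_labels(self, small_config):
        cfg = small_config(seed=3)
        panel = generate_protein_panel(generate_cohort(cfg), cfg)
        assert len(PANEL_ANALYTES) == 29
        assert panel.shape[1] == 31  # tumor_id + strain + 29 analytes
        assert set(panel["strain"]) == {"DR", "DS"}
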