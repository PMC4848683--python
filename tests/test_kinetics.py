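"""Cell-cycle / apoptotic-duration estimators, unit conversions, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tumorkinetics as tk
from tumorkinetics.errors import InsufficientDataError, UndefinedDurationError
from tumorkinetics.kinetics import (
    apoptotic_duration,
    cell_cycle_duration,
    cells_per_hour_to_grams_per_week,
    compute_kinetics,
    delta_s_rate,
    grams_per_week_to_cells_per_hour,
    percent_difference,
    summarize_kinetics,
)
from tumorkinetics.synthgen import fields_to_frame, tumors_to_frame


class TestCellCycleDuration:
    @pytest.mark.parametrize(
        "pn,mit,expected",
        [
            (9.0, 0.448, 20.09),  # DR group means
            (9.4, 0.571, 16.46),  # DS group means
            (10.0, 10.0, 1.0),
        ],
    )
    def test_group_mean_ratios(self, pn, mit, expected):
        assert cell_cycle_duration(pn, mit) == pytest.approx(expected, abs=0.005)

    def test_per_cell_mode_is_cells_times_longer(self):
        # 0.448 figures over 850 cells -> 0.0527% mitotic cells; durations on
        # the order of a week rather than a day
        published = cell_cycle_duration(9.0, 0.448)
        per_cell = cell_cycle_duration(9.0, 0.448, mode="per-cell", total_cells=850)
        assert per_cell == pytest.approx(published * 850 / 100)

    def test_zero_mitotic_index_undefined(self):
        with pytest.raises(UndefinedDurationError):
            cell_cycle_duration(9.0, 0.0)

    @given(
        pn=st.floats(0.5, 50), mit=st.floats(0.05, 5), delta=st.floats(0.01, 5)
    )
    @settings(max_examples=100, deadline=None)
    def test_monotonicity(self, pn, mit, delta):
        """Duration increases with proliferative fraction, decreases with
        mitotic index."""
        base = cell_cycle_duration(pn, mit)
        assert cell_cycle_duration(pn + delta, mit) > base
        assert cell_cycle_duration(pn, mit + delta) < base


class TestUnitConversions:
    @pytest.mark.parametrize(
        "g_per_week,cells_per_h",
        [(0.533, 3.172e6), (0.968, 5.762e6), (0.0, 0.0)],
    )
    def test_grams_per_week_to_cells_per_hour(self, g_per_week, cells_per_h):
        assert grams_per_week_to_cells_per_hour(g_per_week) == pytest.approx(
            cells_per_h, rel=5e-4
        )

    @given(rate=st.floats(0, 10))
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, rate):
        assert cells_per_hour_to_grams_per_week(
            grams_per_week_to_cells_per_hour(rate)
        ) == pytest.approx(rate, rel=1e-12, abs=1e-15)

    @pytest.mark.parametrize(
        "mass,hours,expected",
        [(1.0, 672.0, 1.488e6), (2.1, 672.0, 3.125e6), (0.0, 672.0, 0.0)],
    )
    def test_delta_s_rate(self, mass, hours, expected):
        assert delta_s_rate(mass, hours) == pytest.approx(expected, rel=5e-4)

    def test_zero_elapsed_hours_rejected(self):
        with pytest.raises(ValueError):
            delta_s_rate(1.0, 0.0)


class TestApoptoticDuration:
    def test_clean_arithmetic(self):
        # Dd = 2 / (10/20 - 0.25) = 8
        assert apoptotic_duration(2.0, 10.0, 20.0, 0.25, 1.0) == pytest.approx(8.0)

    def test_zero_denominator_flagged_undefined(self):
        # Pn/Pd == dS/n exactly
        assert math.isnan(apoptotic_duration(1.0, 10.0, 20.0, 0.5, 1.0))

    def test_negative_denominator_never_negative_duration(self):
        out = apoptotic_duration(1.0, 10.0, 20.0, 0.9, 1.0)
        assert math.isnan(out)

    @given(
        dn=st.floats(0.1, 5),
        ratio=st.floats(0.05, 0.44),
        bump=st.floats(0.01, 0.05),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_dn_and_growth(self, dn, ratio, bump):
        """While defined, Dd grows with the apoptotic index and with dS/n."""
        pn, pd_h = 10.0, 20.0  # Pn/Pd = 0.5, so ratio < 0.5 keeps Dd defined
        base = apoptotic_duration(dn, pn, pd_h, ratio, 1.0)
        assert apoptotic_duration(dn + bump, pn, pd_h, ratio, 1.0) > base
        assert apoptotic_duration(dn, pn, pd_h, ratio + bump, 1.0) > base

    def test_forward_inverse_consistency(self):
        """Values satisfying the balance identity exactly are recovered
        exactly."""
        rng = np.random.default_rng(11)
        for _ in range(50):
            pn = rng.uniform(5, 15)
            pd_h = rng.uniform(10, 30)
            dn = rng.uniform(0.5, 4)
            dd = rng.uniform(2, 10)
            n_rate = rng.uniform(1e6, 6e6)
            ds = n_rate * (pn / pd_h - dn / dd)
            assert apoptotic_duration(dn, pn, pd_h, ds, n_rate) == pytest.approx(
                dd, rel=1e-12
            )


class TestPercentDifference:
    @pytest.mark.parametrize(
        "ref,other,expected",
        [(21.2, 17.7, -16.5), (4.7, 5.9, 25.5), (3.0, 3.0, 0.0)],
    )
    def test_published_contrasts(self, ref, other, expected):
        assert percent_difference(ref, other) == pytest.approx(expected, abs=0.05)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference(0.0, 1.0)


def _cohort_estimates(cfg):
    tumors = tk.generate_cohort(cfg)
    return compute_kinetics(
        tumors_to_frame(tumors),
        fields_to_frame(tk.generate_field_counts(tumors, cfg)),
        tk.generate_ki67(tumors, cfg),
        {s: cfg.slope_g_per_week[s] for s in cfg.strains},
    )


class TestSummaries:
    def test_hand_arithmetic(self):
        est = pd.DataFrame(
            {
                "tumor_id": ["a", "b", "c", "d"],
                "strain": ["DR", "DR", "DS", "DS"],
                "pn_pct": [9.0, 9.0, 9.4, 9.4],
                "mitotic_index": [0.4, 0.4, 0.6, 0.6],
                "dn_index": [1.8, 1.8, 2.6, 2.6],
                "pd_hours": [20.0, 22.0, 17.0, 19.0],
                "delta_s_rate": [1e6] * 4,
                "n_rate": [3e6] * 4,
                "dd_hours": [5.0, 5.0, 6.0, 6.0],
                "dd_defined": [True] * 4,
            }
        )
        out = summarize_kinetics(est)
        dr = out["groups"]["DR"]["pd_hours"]
        assert dr["mean"] == pytest.approx(21.0)
        assert dr["sem"] == pytest.approx(1.0)
        assert out["groups"]["DS"]["dd_hours"]["sem"] == pytest.approx(0.0)

    def test_single_tumor_group_rejected(self):
        est = pd.DataFrame(
            {
                "tumor_id": ["a", "b", "c"],
                "strain": ["DR", "DR", "DS"],
                "pn_pct": [9.0] * 3,
                "mitotic_index": [0.4] * 3,
                "dn_index": [1.8] * 3,
                "pd_hours": [20.0] * 3,
                "delta_s_rate": [1e6] * 3,
                "n_rate": [3e6] * 3,
                "dd_hours": [5.0] * 3,
                "dd_defined": [True] * 3,
            }
        )
        with pytest.raises(InsufficientDataError):
            summarize_kinetics(est)

    def test_cohort_percent_difference_direction(self, small_config):
        """Across seeds the estimated DS-vs-DR cell-cycle shortening centers
        near the configured contrast (ratio of configured group means is
        about -18%); per-seed spread at n~20/group is wide because Ki67 and
        the per-tumor mitotic mean are both noisy."""
        diffs = []
        for seed in range(40):
            out = summarize_kinetics(_cohort_estimates(small_config(seed=5000 + seed)))
            diffs.append(out["percent_difference_vs_DR"]["DS"]["pd_hours"])
        diffs = np.asarray(diffs)
        assert -25.0 <= np.median(diffs) <= -8.0
        assert -25.0 <= diffs.mean() <= -8.0
        assert (diffs < 0).mean() >= 0.6

    def test_undefined_dd_excluded_and_counted(self, small_config):
        est = _cohort_estimates(small_config(seed=77))
        out = summarize_kinetics(est)
        for strain in ("DR", "DS"):
            grp = out["groups"][strain]
            assert grp["n_dd_undefined"] + grp["dd_hours"]["n"] == grp["n_tumors"]
            if grp["dd_hours"]["n"]:
                assert grp["dd_hours"]["mean"] > 0
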