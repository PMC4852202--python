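"""Dose-response, attributable fractions, scenarios, and avoided deaths."""

import numpy as np
import pandas as pd
import pytest

from atpa import hia_engine as hia
from atpa.hia_engine import (
    DeathRates, DoseResponse, EligibilityWindows, Scenario,
)


class TestRelativeRisk:
    @pytest.mark.parametrize("dose,expected", [
        (11.25, 0.90),
        (0.0, 1.0),
        (22.5, 0.81),
    ])
    def test_reference_values(self, dose, expected):
        assert hia.relative_risk(dose) == pytest.approx(expected)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            hia.relative_risk(-0.1)

    def test_strictly_decreasing_and_log_linear(self, rng):
        doses = np.sort(rng.uniform(0, 40, 50))
        rr = hia.relative_risk(doses)
        assert (np.diff(rr) < 0).all()
        # log RR is linear in dose
        slope = np.diff(np.log(rr)) / np.diff(doses)
        np.testing.assert_allclose(slope, np.log(0.9) / 11.25)

    def test_custom_parameters(self):
        dr = DoseResponse(base_rr=0.8, reference_dose=10.0)
        assert hia.relative_risk(10.0, dr) == pytest.approx(0.8)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            DoseResponse(base_rr=1.2)
        with pytest.raises(ValueError):
            DoseResponse(reference_dose=0.0)


class TestBenefitIntegral:
    def test_point_masses(self):
        assert hia.benefit_integral([0.0], [1.0]) == 0.0
        assert hia.benefit_integral([11.25], [1.0]) == pytest.approx(0.10)

    def test_mixture_linearity(self):
        b = hia.benefit_integral([0.0, 11.25], [0.5, 0.5])
        assert b == pytest.approx(0.05)

    def test_unnormalized_weights_rejected(self):
        with pytest.raises(ValueError):
            hia.benefit_integral([1.0, 2.0], [0.5, 0.6])


class TestAttributableFraction:
    def test_identical_distributions_give_zero_in_both_modes(self):
        f = ([3.0, 7.0], [0.4, 0.6])
        assert hia.attributable_fraction(f, f, formula_mode="pif") == 0.0
        assert hia.attributable_fraction(f, f, formula_mode="as_printed") == 0.0

    def test_zero_to_reference_dose(self):
        f_est = ([0.0], [1.0])
        f_cf = ([11.25], [1.0])
        assert hia.attributable_fraction(f_est, f_cf) == pytest.approx(0.10)
        assert hia.attributable_fraction(
            f_est, f_cf, formula_mode="as_printed"
        ) == pytest.approx(-0.10)

    def test_pif_monotone_in_counterfactual_dose(self):
        f_est = ([2.0], [1.0])
        values = [
            hia.attributable_fraction(f_est, ([d], [1.0]))
            for d in (2.0, 5.0, 10.0, 20.0)
        ]
        assert values == sorted(values)
        assert values[0] == 0.0


class TestEligibilityWindows:
    def test_components_windowed_independently(self):
        w = EligibilityWindows()
        # age 70: walking still counts, cycling does not
        assert w.windowed_dose(2.0, 3.0, 70) == pytest.approx(2.0)
        # age 50: both count
        assert w.windowed_dose(2.0, 3.0, 50) == pytest.approx(5.0)
        # age 80: neither counts
        assert w.windowed_dose(2.0, 3.0, 80) == pytest.approx(0.0)

    def test_wide_windows_reproduce_unrestricted(self):
        wide = EligibilityWindows(walk=(0, 200), bike=(0, 200))
        ages = np.array([5, 30, 80, 99])
        np.testing.assert_allclose(
            wide.windowed_dose(1.0, 2.0, ages), 3.0
        )


def _paired_cells(rows):
    return pd.DataFrame(
        rows,
        columns=["county", "block_group", "age", "sex", "persons",
                 "walk_est", "bike_est", "walk_cf", "bike_cf"],
    )


def _flat_rates(rate, counties=("c1",)):
    return DeathRates(pd.DataFrame(
        [(c, 0, 120, s, rate) for c in counties for s in ("male", "female")],
        columns=["county", "age_lo", "age_hi", "sex", "rate"],
    ))


class TestAvoidedMortality:
    def test_af_times_baseline_deaths(self):
        # AF = 0.10 (dose 0 -> 11.25), stratum with 250 baseline deaths
        rates = _flat_rates(0.025)  # 10,000 persons x 0.025 = 250 deaths
        cells = _paired_cells([("c1", "g", 50, "male", 10_000.0,
                                0.0, 0.0, 11.25, 0.0)])
        res = hia.avoided_mortality(cells, rates)
        assert res.total_deaths == pytest.approx(0.10 * 250, rel=1e-12)

    def test_outside_both_windows_contributes_nothing(self):
        rates = _flat_rates(0.05)
        cells = _paired_cells([("c1", "g", 80, "female", 5000.0,
                                0.0, 0.0, 11.25, 11.25)])
        res = hia.avoided_mortality(cells, rates)
        assert res.total_deaths == 0.0

    def test_totals_equal_hand_summed_strata(self):
        rates = DeathRates(pd.DataFrame(
            [("c1", 0, 120, "male", 0.01), ("c1", 0, 120, "female", 0.01),
             ("c2", 0, 120, "male", 0.02), ("c2", 0, 120, "female", 0.02)],
            columns=["county", "age_lo", "age_hi", "sex", "rate"],
        ))
        cells = _paired_cells([
            ("c1", "g1", 40, "male", 1000.0, 0.0, 0.0, 11.25, 0.0),
            ("c2", "g2", 60, "female", 2000.0, 0.0, 0.0, 11.25, 0.0),
        ])
        res = hia.avoided_mortality(cells, rates)
        hand = 0.10 * 0.01 * 1000 + 0.10 * 0.02 * 2000
        assert res.total_deaths == pytest.approx(hand, rel=1e-12)
        by_county = res.by("county").set_index("county")["avoided_deaths"]
        assert by_county["c1"] == pytest.approx(0.10 * 0.01 * 1000)
        assert by_county["c2"] == pytest.approx(0.10 * 0.02 * 2000)

    def test_additive_over_stratum_repartitioning(self):
        rates = _flat_rates(0.01)
        one = _paired_cells([("c1", "g", 40, "male", 2000.0,
                              1.0, 0.0, 5.0, 0.0)])
        split = _paired_cells([
            ("c1", "g", 40, "male", 800.0, 1.0, 0.0, 5.0, 0.0),
            ("c1", "g", 40, "male", 1200.0, 1.0, 0.0, 5.0, 0.0),
        ])
        assert hia.avoided_mortality(one, rates).total_deaths == \
            pytest.approx(hia.avoided_mortality(split, rates).total_deaths)

    def test_missing_rate_stratum_raises(self):
        rates = DeathRates(pd.DataFrame(
            [("c1", 0, 64, "male", 0.01)],
            columns=["county", "age_lo", "age_hi", "sex", "rate"],
        ))
        cells = _paired_cells([("c1", "g", 70, "male", 100.0,
                                0.0, 0.0, 2.0, 0.0)])
        with pytest.raises(ValueError):
            hia.avoided_mortality(cells, rates)


class TestCounterfactuals:
    @pytest.mark.parametrize("minutes,expected", [
        (37.4, 37.4 * 3.5 / 60),   # about 2.182 MET-h/week
        (0.0, 0.0),
        (60.0, 3.5),
    ])
    def test_fixed_walking_dose(self, minutes, expected):
        assert hia.counterfactual_fixed_walking(minutes) == \
            pytest.approx(expected)

    def test_fixed_walking_matches_met_conversion(self):
        from atpa.activity_estimator import met_hours
        assert hia.counterfactual_fixed_walking(60.0) == \
            pytest.approx(met_hours(60.0, 0.0))


class TestCombineElasticities:
    def test_transit_coverage_scenario(self):
        # one elasticity of 0.29 under a 50% coverage increase
        assert hia.combine_elasticities([("transit_coverage", 0.29)],
                                        [50.0]) == pytest.approx(14.5)

    def test_zero_changes_give_zero(self):
        e = [("a", 0.39), ("b", 0.15), ("c", 0.15)]
        assert hia.combine_elasticities(e, [0.0, 0.0, 0.0]) == 0.0

    def test_three_walking_elasticities_at_ten_percent(self):
        e = [("intersections", 0.39), ("diversity", 0.15),
             ("transit_stops", 0.15)]
        assert hia.combine_elasticities(e, [10.0] * 3) == pytest.approx(6.9)

    def test_multiplicative_mode(self):
        out = hia.combine_elasticities([("a", 0.5)], [21.0],
                                       mode="multiplicative")
        assert out == pytest.approx(100 * (1.21**0.5 - 1))


def _dose_cells():
    """One block group, two commute categories, full pairing columns."""
    return pd.DataFrame({
        "commute_category": ["private_vehicle", "walk"],
        "age": [40, 40], "sex": ["male", "male"],
        "race_ethnicity": ["nh_white", "nh_white"],
        "block_group": ["g", "g"], "county": ["c1", "c1"],
        "walk_met_wk": [0.5, 4.0], "bike_met_wk": [0.1, 0.2],
        "tpa_sd": [0.0, 0.0],
        "persons": [900.0, 100.0],
    })


class TestScenarioTransform:
    def test_zero_percent_scaling_is_identity(self):
        cells = _dose_cells()
        out = hia.scenario_transform(cells, Scenario("scale_walking",
                                                     percent=0.0))
        np.testing.assert_allclose(out["walk_cf"], out["walk_est"])
        np.testing.assert_allclose(out["bike_cf"], out["bike_est"])

    def test_full_driver_shift_empties_driver_cells(self):
        cells = _dose_cells()
        out = hia.scenario_transform(
            cells, Scenario("mode_shift", from_mode="private_vehicle",
                            to_mode="walk", share=1.0))
        drivers = out.loc[(out["commute_category"] == "private_vehicle")
                          & (out["walk_cf"] == out["walk_est"])]
        assert drivers["persons"].sum() == 0.0
        assert out["persons"].sum() == pytest.approx(1000.0)

    def test_half_shift_mean_dose_is_hand_weighted_mixture(self):
        cells = _dose_cells()
        out = hia.scenario_transform(
            cells, Scenario("mode_shift", from_mode="private_vehicle",
                            to_mode="walk", share=0.5))
        mean_cf = (out["persons"] * (out["walk_cf"] + out["bike_cf"])).sum() \
            / out["persons"].sum()
        # 450 drivers stay at 0.6, 450 re-read the walk cell's 4.2, 100
        # walkers stay at 4.2
        hand = (450 * 0.6 + 450 * 4.2 + 100 * 4.2) / 1000
        assert mean_cf == pytest.approx(hand)

    def test_population_conserved_under_shift(self):
        cells = _dose_cells()
        out = hia.scenario_transform(
            cells, Scenario("mode_shift", from_mode="private_vehicle",
                            to_mode="walk", share=0.2))
        assert out["persons"].sum() == pytest.approx(cells["persons"].sum())

    def test_share_above_one_rejected(self):
        with pytest.raises(ValueError):
            Scenario("mode_shift", from_mode="private_vehicle",
                     to_mode="walk", share=1.5)

    def test_fixed_walking_sets_point_mass(self):
        cells = _dose_cells()
        out = hia.scenario_transform(
            cells, Scenario("fixed_walk_minutes", minutes_per_week=60.0))
        np.testing.assert_allclose(out["walk_cf"], 3.5)
        np.testing.assert_allclose(out["bike_cf"], 0.0)

    def test_elasticity_scenario_scales_walking(self):
        cells = _dose_cells()
        sc = Scenario("elasticity",
                      elasticities=[("a", 0.39), ("b", 0.15), ("c", 0.15)],
                      pct_changes=[10.0, 10.0, 10.0])
        out = hia.scenario_transform(cells, sc)
        np.testing.assert_allclose(out["walk_cf"],
                                   out["walk_est"] * 1.069)


class TestMonteCarloCi:
    def test_zero_sds_give_zero_width_interval(self):
        cells = _dose_cells()
        rates = _flat_rates(0.01)
        out = hia.monte_carlo_ci(
            cells, Scenario("fixed_walk_minutes", minutes_per_week=37.4),
            rates, n_draws=100, seed=0)
        td = out["total_deaths"]
        assert td["ci_low"] == pytest.approx(td["point"], abs=1e-12)
        assert td["ci_high"] == pytest.approx(td["point"], abs=1e-12)

    def test_interval_contains_point_and_is_reproducible(self):
        cells = _dose_cells().assign(tpa_sd=[0.3, 0.8])
        rates = _flat_rates(0.01)
        sc = Scenario("fixed_walk_minutes", minutes_per_week=37.4)
        out1 = hia.monte_carlo_ci(cells, sc, rates, n_draws=150, seed=5)
        out2 = hia.monte_carlo_ci(cells, sc, rates, n_draws=150, seed=5)
        assert out1 == out2
        td = out1["total_deaths"]
        assert td["ci_low"] <= td["point"] <= td["ci_high"]
        assert td["ci_high"] > td["ci_low"]

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            hia.monte_carlo_ci(
                _dose_cells(),
                Scenario("fixed_walk_minutes", minutes_per_week=10.0),
                _flat_rates(0.01), n_draws=50)


class TestQuintileSummary:
    def _cells_for(self, n_bg, doses=None, rng=None):
        bgs = [f"g{i}" for i in range(n_bg)]
        cells = pd.DataFrame({
            "commute_category": "private_vehicle",
            "age": 40, "sex": "male", "race_ethnicity": "nh_white",
            "block_group": bgs, "county": "c1",
            "walk_met_wk": doses if doses is not None else 1.0,
            "bike_met_wk": 0.0, "tpa_sd": 0.0,
            "persons": 1000.0,
        })
        return cells

    def test_quintile_populations_sum_to_region(self):
        cells = self._cells_for(10)
        rates = _flat_rates(0.01)
        paired = hia.scenario_transform(
            cells, Scenario("fixed_walk_minutes", minutes_per_week=37.4))
        res = hia.avoided_mortality(paired, rates)
        dens = pd.Series(np.arange(10, dtype=float),
                         index=cells["block_group"])
        q = hia.quintile_summary(cells, res, dens)
        body = q.loc[q["quintile"] != "All"]
        assert body["population"].sum() == pytest.approx(10_000.0)
        assert q.loc[q["quintile"] == "All", "population"].iloc[0] == \
            pytest.approx(10_000.0)

    def test_monotone_density_dose_gradient_gives_monotone_quintiles(self):
        doses = np.linspace(0.5, 3.0, 10)  # dose rises with density
        cells = self._cells_for(10, doses=doses)
        rates = _flat_rates(0.01)
        paired = hia.scenario_transform(
            cells, Scenario("fixed_walk_minutes", minutes_per_week=37.4))
        res = hia.avoided_mortality(paired, rates)
        dens = pd.Series(np.linspace(100, 5000, 10),
                         index=cells["block_group"])
        q = hia.quintile_summary(cells, res, dens)
        body = q.loc[q["quintile"] != "All"]
        tpa = body["tpa_met_h_week"].tolist()
        assert tpa == sorted(tpa)
        # preventable mortality falls as baseline dose rises
        prev = body["preventable_per_100k"].tolist()
        assert prev == sorted(prev, reverse=True)

    def test_too_few_block_groups_rejected(self):
        cells = self._cells_for(3)
        rates = _flat_rates(0.01)
        paired = hia.scenario_transform(
            cells, Scenario("fixed_walk_minutes", minutes_per_week=37.4))
        res = hia.avoided_mortality(paired, rates)
        dens = pd.Series([1.0, 2.0, 3.0], index=cells["block_group"])
        with pytest.raises(ValueError):
            hia.quintile_summary(cells, res, dens)
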