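"""Stratified mortality, half-life arithmetic and planting scenarios."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from urbancarbon import (
    MortalityModel,
    PlantingScenario,
    apply_annual_mortality,
    compensation_analysis,
    population_half_life,
    run_planting_scenario,
)


class TestHalfLife:
    @pytest.mark.parametrize("rate,years", [(0.035, 20), (0.02, 35), (0.01, 69),
                                            (0.5, 1)])
    def test_reference_rates(self, rate, years):
        assert population_half_life(rate) == years

    def test_rate_one_or_more(self):
        assert population_half_life(1.0) == 1
        assert population_half_life(1.5) == 1

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            population_half_life(0.0)

    @given(st.floats(min_value=0.001, max_value=0.5))
    @settings(derandomize=True, max_examples=200, deadline=None)
    def test_matches_year_loop_oracle(self, rate):
        """Closed form equals brute-force expected-value survival stepping."""
        survivors, t = 1.0, 0
        while survivors > 0.5:
            survivors *= 1.0 - rate
            t += 1
        assert population_half_life(rate) == t


class TestApplyAnnualMortality:
    def test_zero_rates_noop(self, small_inventory):
        inv = small_inventory.copy()
        model = MortalityModel(0.0, 0.0, 0.0)
        _, dead = apply_annual_mortality(inv, model, year=1)
        assert len(dead) == 0 and inv["alive"].all()

    def test_rate_one_kills_everything(self, small_inventory):
        inv = small_inventory.copy()
        model = MortalityModel(0.999999999, 0.999999999, 0.999999999,
                               mode="expected_value")
        _, dead = apply_annual_mortality(inv, model, year=3)
        assert not inv["alive"].any()
        assert (inv["death_year"] == 3).all()
        assert len(dead) == len(inv)

    def test_expected_value_exact_counts(self, small_inventory):
        inv = small_inventory.copy()
        model = MortalityModel(mode="expected_value", seed=1)
        n_street = int((inv["land_use"] == "street").sum())
        _, dead = apply_annual_mortality(inv, model, year=1)
        got = int((dead["land_use"] == "street").sum())
        assert got == round(0.035 * n_street)

    def test_stochastic_binomial_mean(self, registry):
        """Mean deaths over replicates match the binomial expectation."""
        from urbancarbon import InventoryConfig, generate_inventory

        cfg = InventoryConfig(
            n_trees=10_000, seed=0,
            class_proportions={"street": 1.0, "mixed": 0.0, "park": 0.0})
        base = generate_inventory(cfg, registry)
        n, p, reps = 10_000, 0.035, 1_000
        rng = np.random.default_rng(123)
        deaths = []
        for _ in range(reps):
            inv = base.copy()
            _, dead = apply_annual_mortality(
                inv, MortalityModel(rate_street=p), year=1, rng=rng)
            deaths.append(len(dead))
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(np.mean(deaths) - n * p) < 3 * sigma / np.sqrt(reps)

    def test_never_resurrects(self, small_inventory):
        inv = small_inventory.copy()
        model = MortalityModel(mode="stochastic", seed=0)
        rng = np.random.default_rng(0)
        apply_annual_mortality(inv, model, year=1, rng=rng)
        dead_ids = set(inv.loc[~inv["alive"], "tree_id"])
        apply_annual_mortality(inv, model, year=2, rng=rng)
        assert dead_ids <= set(inv.loc[~inv["alive"], "tree_id"])
        # death years of the first wave untouched
        assert (inv.loc[inv["tree_id"].isin(dead_ids), "death_year"] == 1).all()

    def test_conservation_every_year(self, small_inventory):
        inv = small_inventory.copy()
        n0 = len(inv)
        model = MortalityModel(seed=5)
        rng = np.random.default_rng(5)
        for year in range(1, 31):
            apply_annual_mortality(inv, model, year, rng=rng)
            assert int(inv["alive"].sum()) + int(inv["death_year"].notna().sum()) == n0

    def test_unknown_land_use_names_tree(self, small_inventory):
        inv = small_inventory.copy()
        inv.loc[inv.index[0], "land_use"] = "orchard"
        with pytest.raises(ValueError, match="orchard"):
            apply_annual_mortality(inv, MortalityModel(), year=1)


class TestPlantingScenario:
    def test_zero_mortality_constant_count_growing_carbon(self, allometry, registry):
        scenario = PlantingScenario(n_trees=1_000, growth_horizon=30,
                                    mortality_rate=0.0)
        traj = run_planting_scenario(scenario, allometry, registry)
        assert (traj["alive_count"] == 1_000).all()
        assert np.all(np.diff(traj["alive_carbon_ktC"]) > 0)
        assert not traj["is_half_life_year"].any()

    @pytest.mark.parametrize("rate", [0.035, 0.02, 0.01])
    def test_expected_value_survival_closed_form(self, allometry, registry, rate):
        scenario = PlantingScenario(n_trees=100_000, mortality_rate=rate,
                                    mode="expected_value")
        traj = run_planting_scenario(scenario, allometry, registry)
        t = traj["year"].to_numpy()
        np.testing.assert_allclose(
            traj["alive_count"], 100_000 * (1 - rate) ** t, rtol=1e-9)

    def test_half_life_year_annotated(self, allometry, registry):
        traj = run_planting_scenario(
            PlantingScenario(mortality_rate=0.035), allometry, registry)
        assert traj.loc[traj["is_half_life_year"], "year"].tolist() == [20]

    def test_monotone_in_mortality(self, allometry, registry):
        low = run_planting_scenario(
            PlantingScenario(mortality_rate=0.01, mode="expected_value"),
            allometry, registry)
        high = run_planting_scenario(
            PlantingScenario(mortality_rate=0.035, mode="expected_value"),
            allometry, registry)
        assert np.all(high["alive_carbon_ktC"].to_numpy()[1:]
                      < low["alive_carbon_ktC"].to_numpy()[1:])

    def test_stochastic_tracks_expectation(self, allometry, registry):
        scenario = PlantingScenario(n_trees=100_000, mortality_rate=0.02,
                                    mode="stochastic", seed=4)
        traj = run_planting_scenario(scenario, allometry, registry)
        expected = 100_000 * 0.98 ** traj["year"].to_numpy()
        sigma = np.sqrt(expected * (1 - 0.98 ** traj["year"].to_numpy()))
        diff = np.abs(traj["alive_count"].to_numpy() - expected)
        assert np.all(diff[1:] < 5 * sigma[1:])


class TestCompensation:
    def _fake_report(self, values):
        rows = []
        for use, series in values.items():
            for year, carbon in series.items():
                rows.append({"year": year, "land_use": use, "alive_ktC": carbon})
        return pd.DataFrame(rows)

    def _fake_trajectory(self, horizon=70, carbon=1.0):
        years = np.arange(horizon + 1)
        return pd.DataFrame({"year": years,
                             "alive_carbon_ktC": np.full(len(years), carbon)})

    def test_zero_decline_zero_ratio(self):
        report = self._fake_report({
            "street": {0: 5.0, 20: 5.0}, "mixed": {0: 5.0, 35: 5.0},
            "park": {0: 5.0, 69: 5.0}})
        result = compensation_analysis(report, self._fake_trajectory())
        assert (result["compensation_ratio"] == 0).all()

    def test_equal_decline_ratio_one(self):
        report = self._fake_report({
            "street": {0: 6.0, 20: 5.0}, "mixed": {0: 6.0, 35: 5.0},
            "park": {0: 6.0, 69: 5.0}})
        result = compensation_analysis(report, self._fake_trajectory(carbon=1.0))
        np.testing.assert_allclose(result["compensation_ratio"], 1.0)

    def test_reported_magnitudes_give_ratio_above_four(self):
        # street loses 15.2 ktC over its 20-year half-life while the planted
        # cohort holds ~3.5 ktC at that point: the initiative must be >4x larger
        report = self._fake_report({
            "street": {0: 20.0, 20: 4.8}, "mixed": {0: 1.0, 35: 1.0},
            "park": {0: 1.0, 69: 1.0}})
        result = compensation_analysis(report, self._fake_trajectory(carbon=3.5))
        street = result[result["land_use"] == "street"].iloc[0]
        assert street["alive_carbon_decline_ktC"] == pytest.approx(15.2)
        assert street["compensation_ratio"] > 4

    def test_mismatched_period_errors(self):
        report = self._fake_report({"street": {0: 5.0, 10: 4.0},
                                    "mixed": {0: 5.0, 10: 4.0},
                                    "park": {0: 5.0, 10: 4.0}})
        with pytest.raises(ValueError, match="outside the compared period"):
            compensation_analysis(report, self._fake_trajectory(horizon=10))
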