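"""Vegetarian counterfactual and diversity statistic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ferroclim.eco2_model import simulate_losses
from ferroclim.errors import AlignmentError, DomainError, ScenarioError
from ferroclim.food_data_io import (
    NATIONAL,
    WOMEN_15_49,
    AnemiaTable,
    ECO2Category,
    FoodCatalog,
    FoodRecord,
    SupplyTable,
)
from ferroclim.iron_supply import compute_iron_supply
from ferroclim.scenarios_diversity import (
    DiversityPoint,
    diversity_anemia_fit,
    diversity_count,
    diversity_points,
    scenario_loss_delta,
    vegetarian_transform,
)


def _food(food_id, iron, kcal, animal=False, wild=False):
    return FoodRecord(
        food_id=food_id,
        food_name=food_id,
        genus_group="g",
        gdd_group=None,
        eco2_category=ECO2Category.ANIMAL if animal else ECO2Category.OTHER_VEGETAL,
        iron_density=iron,
        energy_density=kcal,
        is_animal_source=animal,
        is_wild_harvest=wild,
    )


def _energy(supply, catalog, country):
    vec = supply.for_country_group(country, NATIONAL)
    return sum(g * catalog[f].energy_density / 100.0 for f, g in vec.items())


class TestVegetarianTransform:
    def test_no_animal_foods_is_identity(self):
        catalog = FoodCatalog([_food("rice", 1.6, 360), _food("beans", 6.7, 340)])
        supply = SupplyTable.from_records(
            [("A", "rice", NATIONAL, 300.0), ("A", "beans", NATIONAL, 50.0)]
        )
        diet = vegetarian_transform(supply, catalog)
        assert diet.factors["A"] == pytest.approx(1.0)
        assert diet.supply.value("A", "rice", NATIONAL) == pytest.approx(300.0)

    def test_half_animal_calories_doubles_vegetal(self):
        catalog = FoodCatalog([_food("rice", 1.6, 360), _food("beef", 2.6, 360, animal=True)])
        supply = SupplyTable.from_records(
            [("A", "rice", NATIONAL, 100.0), ("A", "beef", NATIONAL, 100.0)]
        )
        diet = vegetarian_transform(supply, catalog)
        assert diet.factors["A"] == pytest.approx(2.0)
        assert diet.supply.value("A", "rice", NATIONAL) == pytest.approx(200.0)
        assert diet.supply.value("A", "beef", NATIONAL) == 0.0

    def test_energy_conserved_on_synthetic_world(self, world):
        diet = vegetarian_transform(world.supply, world.catalog)
        for country in world.supply.countries:
            before = _energy(world.supply, world.catalog, country)
            after = _energy(diet.supply, world.catalog, country)
            assert abs(after - before) / before < 1e-6

    def test_animal_supplies_exactly_zero(self, world):
        diet = vegetarian_transform(world.supply, world.catalog)
        for country, food_id, _g, value in diet.supply.entries():
            if world.catalog[food_id].is_animal_source:
                assert value == 0.0

    def test_all_animal_country_rejected(self):
        catalog = FoodCatalog([_food("beef", 2.6, 250, animal=True)])
        supply = SupplyTable.from_records([("A", "beef", NATIONAL, 200.0)])
        with pytest.raises(ScenarioError, match="A"):
            vegetarian_transform(supply, catalog)


class TestScenarioLossDelta:
    def test_identical_diets_give_zero(self):
        assert scenario_loss_delta({"A": 3.0}, {"A": 3.0}) == {"A": 0.0}

    def test_mismatched_countries_rejected(self):
        with pytest.raises(AlignmentError):
            scenario_loss_delta({"A": 3.0}, {"B": 3.0})

    def test_all_vegetarian_baseline_gives_zero_delta(self, world):
        diet = vegetarian_transform(world.supply, world.catalog)
        iron = compute_iron_supply(diet.supply, world.catalog)
        losses = simulate_losses(iron, world.catalog, world.effects, n_draws=40, seed=6)
        medians = {c: losses.median(c, NATIONAL) for c in diet.supply.countries}
        twice = vegetarian_transform(diet.supply, world.catalog)
        iron2 = compute_iron_supply(twice.supply, world.catalog)
        losses2 = simulate_losses(iron2, world.catalog, world.effects, n_draws=40, seed=6)
        medians2 = {c: losses2.median(c, NATIONAL) for c in diet.supply.countries}
        delta = scenario_loss_delta(medians, medians2)
        assert all(abs(d) < 1e-9 for d in delta.values())

    def test_delta_nonnegative_when_animal_iron_present(self, world):
        """Removing animal iron can only raise the affected share, so the
        scenario loss dominates the baseline in every country."""
        base_iron = compute_iron_supply(world.supply, world.catalog)
        diet = vegetarian_transform(world.supply, world.catalog)
        scen_iron = compute_iron_supply(diet.supply, world.catalog)
        base = simulate_losses(base_iron, world.catalog, world.effects, n_draws=80, seed=6)
        scen = simulate_losses(scen_iron, world.catalog, world.effects, n_draws=80, seed=6)
        for country in world.supply.countries:
            animal_share = sum(
                v
                for f, v in base_iron.vector(country, NATIONAL).items()
                if world.catalog[f].is_animal_source
            ) / base_iron.total(country, NATIONAL)
            if animal_share > 0:
                delta = scen.median(country, NATIONAL) - base.median(country, NATIONAL)
                assert delta >= -1e-9, country


class TestDiversityCount:
    def test_single_food(self):
        assert diversity_count({"rice": 2.0}) == 1

    def test_four_equal_foods_need_all_four(self):
        assert diversity_count({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0}, 0.99) == 4

    def test_dominant_food_excludes_trace_contributors(self):
        assert diversity_count({"staple": 99.5, "trace": 0.5}, 0.99) == 1

    def test_zero_iron_rejected(self):
        with pytest.raises(DomainError):
            diversity_count({"a": 0.0})

    @given(st.lists(st.floats(0.01, 100), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_brute_force_minimal_prefix(self, values):
        iron = {f"f{i:02d}": v for i, v in enumerate(values)}
        k = diversity_count(iron, 0.99)
        ordered = sorted(iron.items(), key=lambda kv: (-kv[1], kv[0]))
        total = sum(iron.values())
        best = None
        for j in range(1, len(ordered) + 1):
            if sum(v for _f, v in ordered[:j]) >= 0.99 * total - 1e-9 * total:
                best = j
                break
        assert k == best

    @given(st.lists(st.floats(0.01, 100), min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_threshold(self, values):
        iron = {f"f{i:02d}": v for i, v in enumerate(values)}
        assert diversity_count(iron, 0.9) <= diversity_count(iron, 0.99)


class TestDiversityAnemiaFit:
    def test_recovers_exact_logarithmic_law(self):
        # counts n = 30 - 5 log(anemia), with anemia = e, e^2, e^3, e^4 so
        # every count is an integer and the points sit exactly on the line
        a, b = 30.0, -5.0
        points = [
            DiversityPoint(f"c{i}", int(round(a + b * i)), math.exp(i), False)
            for i in range(1, 5)
        ]
        fit = diversity_anemia_fit(points)
        assert fit.intercept == pytest.approx(a, abs=1e-9)
        assert fit.slope == pytest.approx(b, abs=1e-9)

    def test_constant_counts_give_zero_slope(self):
        points = [DiversityPoint(f"c{i}", 12, 5.0 * (i + 1), False) for i in range(5)]
        fit = diversity_anemia_fit(points)
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_points_rejected(self):
        points = [DiversityPoint("a", 5, 10.0, False), DiversityPoint("b", 7, 20.0, False)]
        with pytest.raises(DomainError):
            diversity_anemia_fit(points)

    def test_wild_exclusion_drops_flagged_countries(self):
        points = [
            DiversityPoint("a", 5, 10.0, True),
            DiversityPoint("b", 7, 20.0, False),
            DiversityPoint("c", 9, 30.0, False),
            DiversityPoint("d", 11, 40.0, False),
        ]
        fit = diversity_anemia_fit(points, exclude_wild=True)
        assert fit.n_points == 3

    def test_synthetic_world_negative_slope_with_and_without_exclusion(
        self, world, world_iron
    ):
        points = diversity_points(
            world_iron, world.supply, world.catalog, world.anemia, WOMEN_15_49
        )
        for exclude in (False, True):
            fit = diversity_anemia_fit(points, exclude_wild=exclude)
            assert fit.slope < 0, f"exclude_wild={exclude}"
            assert fit.pearson_r < 0


def test_wild_flag_tracks_wild_energy_share():
    catalog = FoodCatalog(
        [_food("rice", 1.6, 360), _food("wild_greens", 2.2, 360, wild=True)]
    )
    heavy = SupplyTable.from_records(
        [("A", "rice", NATIONAL, 100.0), ("A", "wild_greens", NATIONAL, 50.0)]
    )
    light = SupplyTable.from_records(
        [("B", "rice", NATIONAL, 100.0), ("B", "wild_greens", NATIONAL, 1.0)]
    )
    anemia = AnemiaTable({("A", "F_15_49"): 30.0, ("B", "F_15_49"): 30.0})
    for supply, expected in ((heavy, True), (light, False)):
        group_supply = SupplyTable.from_records(
            [(c, f, WOMEN_15_49.token, v) for c, f, _g, v in supply.entries()]
        )
        iron = compute_iron_supply(group_supply, catalog)
        points = diversity_points(iron, supply, catalog, anemia, WOMEN_15_49)
        assert points[0].wild_harvest_flag is expected
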