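"""CO2-effect model: zero rule, pooling, skew-normal fits, Monte Carlo."""

import numpy as np
import pytest
from scipy.stats import skewnorm

from ferroclim.eco2_model import (
    EffectDistribution,
    apply_zero_effect_rule,
    build_effect_distributions,
    effect_for_food,
    expected_pct_change,
    fit_skew_normal,
    intake_uncertainty,
    pool_category,
    simulate_losses,
)
from ferroclim.errors import ConfigurationError, DomainError, FitError
from ferroclim.food_data_io import (
    ECO2Category,
    ECO2Effect,
    ECO2EffectTable,
    EffectLevel,
    FoodCatalog,
    FoodRecord,
    SupplyTable,
)
from ferroclim.iron_supply import compute_iron_supply


def _effect(target, mean, lo, hi, n=50, p=0.001, level=EffectLevel.CROP):
    return ECO2Effect(target, level, mean, lo, hi, n, p)


def _food(food_id, category, iron=3.0, animal=False):
    return FoodRecord(
        food_id=food_id,
        food_name=food_id,
        genus_group="g",
        gdd_group=None,
        eco2_category=category,
        iron_density=iron,
        energy_density=100.0,
        is_animal_source=animal,
    )


class TestZeroEffectRule:
    def test_sorghum_zeroed(self):
        effect = apply_zero_effect_rule(_effect("sorghum", -0.9, -3.1, 1.3, p=0.153))
        assert effect.mean_pct_change == 0.0
        assert effect.is_zero_width

    def test_potato_zeroed(self):
        effect = apply_zero_effect_rule(_effect("potato", -0.5, -2.5, 1.5, p=0.555))
        assert effect.mean_pct_change == 0.0

    def test_significant_effect_untouched(self):
        original = _effect("wheat", -5.1, -6.9, -3.3, p=0.001)
        assert apply_zero_effect_rule(original) is original


class TestPoolCategory:
    def test_sample_weighted_mean(self):
        pooled = pool_category(
            [_effect("a", -5, -7, -3, n=10), _effect("b", -10, -12, -8, n=30)]
        )
        assert pooled.mean_pct_change == pytest.approx(-8.75)
        assert pooled.n_samples == 40
        # interval pooled by the same weights
        assert pooled.ci_lo == pytest.approx((-7 * 10 + -12 * 30) / 40)

    def test_single_effect_is_identity(self):
        effect = _effect("a", -5, -7, -3)
        pooled = pool_category([effect])
        assert pooled.mean_pct_change == effect.mean_pct_change
        assert pooled.ci_lo == effect.ci_lo

    def test_equal_n_gives_arithmetic_mean(self):
        pooled = pool_category(
            [_effect("a", -4, -6, -2, n=20), _effect("b", -8, -10, -6, n=20)]
        )
        assert pooled.mean_pct_change == pytest.approx(-6.0)

    def test_empty_list_rejected(self):
        with pytest.raises(DomainError):
            pool_category([])


class TestFitSkewNormal:
    def test_symmetric_reduces_to_normal(self):
        params = fit_skew_normal(-5, -8, -2)
        assert params.shape == pytest.approx(0.0, abs=1e-4)
        assert params.location == pytest.approx(-5.0, abs=1e-6)
        assert params.scale == pytest.approx(3.0 / 1.959964, abs=1e-4)

    def test_asymmetric_reproduces_quantiles(self):
        params = fit_skew_normal(-5, -9, -2)
        assert params.shape < 0
        np.testing.assert_allclose(params.quantiles(), [-9, -5, -2], atol=1e-6)

    def test_median_outside_attainable_range_raises(self):
        # a skew-normal cannot put its median at 71.4% of its 95% interval
        with pytest.raises(FitError):
            fit_skew_normal(-5, -10, -3)

    def test_median_outside_interval_raises(self):
        with pytest.raises(FitError):
            fit_skew_normal(-11, -10, -3)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(DomainError):
            fit_skew_normal(-5, -3, -3)

    def test_self_consistency_refit(self):
        params = fit_skew_normal(-4.2, -7.9, -2.4)
        lo, med, hi = params.quantiles()
        refit = fit_skew_normal(med, lo, hi)
        assert refit.location == pytest.approx(params.location, abs=1e-6)
        assert refit.scale == pytest.approx(params.scale, abs=1e-6)
        assert refit.shape == pytest.approx(params.shape, abs=1e-4)


class TestEffectForFood:
    def _effects(self):
        return ECO2EffectTable(
            [
                _effect("wheat", -5.1, -6.9, -3.3),
                _effect("C3_GRAIN", -4.9, -6.5, -3.2, level=EffectLevel.CATEGORY),
                _effect("LEGUME", -4.0, -5.5, -2.6, level=EffectLevel.CATEGORY),
                _effect("sorghum", -0.9, -3.1, 1.3, p=0.153),
            ]
        )

    def test_crop_level_preferred(self):
        dist = effect_for_food(_food("wheat", ECO2Category.C3_GRAIN), self._effects())
        assert not dist.is_degenerate
        lo, med, hi = dist.params.quantiles()
        assert med == pytest.approx(-5.1, abs=1e-6)

    def test_animal_food_is_exact_zero(self):
        dist = effect_for_food(
            _food("beef", ECO2Category.ANIMAL, animal=True), self._effects()
        )
        assert dist.is_degenerate and dist.point == 0.0

    def test_legume_without_crop_row_uses_category(self):
        dist = effect_for_food(_food("lentils", ECO2Category.LEGUME), self._effects())
        lo, med, hi = dist.params.quantiles()
        assert med == pytest.approx(-4.0, abs=1e-6)

    def test_nonsignificant_crop_becomes_point_zero(self):
        dist = effect_for_food(_food("sorghum", ECO2Category.ZERO_EFFECT), self._effects())
        assert dist.is_degenerate and dist.point == 0.0

    def test_affected_food_without_any_row_is_config_error(self):
        with pytest.raises(ConfigurationError, match="maize"):
            effect_for_food(
                _food("maize", ECO2Category.MAIZE),
                ECO2EffectTable([_effect("wheat", -5.1, -6.9, -3.3)]),
            )

    def test_other_vegetal_without_crop_row_is_zero(self):
        dist = effect_for_food(_food("tomato", ECO2Category.OTHER_VEGETAL), self._effects())
        assert dist.is_degenerate and dist.point == 0.0


class TestSimulateLosses:
    def test_all_zero_effects_give_point_mass_zero(self):
        catalog = FoodCatalog(
            [
                _food("sorghum", ECO2Category.ZERO_EFFECT),
                _food("potato", ECO2Category.ZERO_EFFECT, iron=0.8),
            ]
        )
        effects = ECO2EffectTable(
            [
                _effect("sorghum", -0.9, -3.1, 1.3, p=0.153),
                _effect("potato", -0.5, -2.5, 1.5, p=0.555),
            ]
        )
        supply = SupplyTable.from_records(
            [("A", "sorghum", "NATIONAL", 150.0), ("A", "potato", "NATIONAL", 220.0)]
        )
        iron = compute_iron_supply(supply, catalog)
        dist = simulate_losses(iron, catalog, effects, n_draws=1000, seed=5)
        assert np.all(dist.loss("A", "NATIONAL") == 0.0)

    def test_single_degenerate_effect_forces_loss(self):
        catalog = FoodCatalog([_food("wheat", ECO2Category.C3_GRAIN)])
        effects = ECO2EffectTable([_effect("wheat", -5.0, -5.0, -5.0)])
        supply = SupplyTable.from_records([("A", "wheat", "NATIONAL", 100.0)])
        iron = compute_iron_supply(supply, catalog)
        dist = simulate_losses(iron, catalog, effects, n_draws=50, seed=1)
        assert np.all(dist.loss("A", "NATIONAL") == 5.0)

    def test_seeded_determinism(self, world, world_iron, world_disagg):
        uncertainty = intake_uncertainty(world_disagg, world.catalog, world.gdd)
        kwargs = dict(
            iron=world_iron,
            catalog=world.catalog,
            effects=world.effects,
            gdd_uncertainty=uncertainty,
            n_draws=60,
        )
        one = simulate_losses(seed=11, **kwargs)
        two = simulate_losses(seed=11, **kwargs)
        other = simulate_losses(seed=12, **kwargs)
        for key in one.draws:
            np.testing.assert_array_equal(one.draws[key], two.draws[key])
        assert any(
            not np.array_equal(one.draws[k], other.draws[k]) for k in one.draws
        )

    def test_convexity_bound_every_draw(self, world, world_iron):
        """Each country's loss is a convex combination of per-food losses."""
        dist = simulate_losses(
            world_iron, world.catalog, world.effects, n_draws=100, seed=2
        )
        for (country, group), losses in dist.draws.items():
            vec = world_iron.vector(country, group)
            cols = np.array(
                [dist.food_effect_col[f] for f in vec.index if vec[f] > 0]
            )
            per_food_loss = -dist.effect_draws[:, cols]
            lower = per_food_loss.min(axis=1)
            upper = per_food_loss.max(axis=1)
            assert np.all(losses >= lower - 1e-9)
            assert np.all(losses <= upper + 1e-9)

    def test_mc_mean_matches_analytic_expectation(self):
        """Iron-weighted mean of per-food expected changes, within 3 MC SE."""
        catalog = FoodCatalog(
            [
                _food("wheat", ECO2Category.C3_GRAIN, iron=3.5),
                _food("beans", ECO2Category.LEGUME, iron=6.7),
            ]
        )
        effects = ECO2EffectTable(
            [
                _effect("wheat", -5.1, -6.9, -3.3),
                _effect("beans", -4.0, -6.0, -2.5),
            ]
        )
        supply = SupplyTable.from_records(
            [("A", "wheat", "NATIONAL", 250.0), ("A", "beans", "NATIONAL", 40.0)]
        )
        iron = compute_iron_supply(supply, catalog)
        n = 20000
        dist = simulate_losses(iron, catalog, effects, n_draws=n, seed=7)
        losses = dist.loss("A", "NATIONAL")
        expected = expected_pct_change(catalog, effects)
        vec = iron.vector("A", "NATIONAL")
        analytic = -sum(vec[f] * expected[f] for f in vec.index) / vec.sum()
        se = losses.std(ddof=1) / np.sqrt(n)
        assert abs(losses.mean() - analytic) < 3 * se

    def test_increasing_affected_share_increases_expected_loss(self):
        catalog = FoodCatalog(
            [
                _food("wheat", ECO2Category.C3_GRAIN, iron=3.0),
                _food("tomato", ECO2Category.OTHER_VEGETAL, iron=3.0),
            ]
        )
        effects = ECO2EffectTable([_effect("wheat", -5.0, -5.0, -5.0)])

        def mean_loss(wheat_g):
            supply = SupplyTable.from_records(
                [("A", "wheat", "NATIONAL", wheat_g), ("A", "tomato", "NATIONAL", 100.0)]
            )
            iron = compute_iron_supply(supply, catalog)
            return simulate_losses(iron, catalog, effects, n_draws=10, seed=1).loss(
                "A", "NATIONAL"
            ).mean()

        assert mean_loss(200.0) > mean_loss(50.0)

    def test_zero_total_iron_rejected(self):
        catalog = FoodCatalog([_food("sugar", ECO2Category.OTHER_VEGETAL, iron=0.0)])
        supply = SupplyTable.from_records([("A", "sugar", "NATIONAL", 30.0)])
        iron = compute_iron_supply(supply, catalog)
        with pytest.raises(DomainError, match="zero"):
            simulate_losses(iron, catalog, ECO2EffectTable([]), n_draws=5, seed=0)

    def test_category_draws_shared_by_member_foods(self):
        """Two legumes without crop rows move together within each draw."""
        catalog = FoodCatalog(
            [
                _food("lentils", ECO2Category.LEGUME),
                _food("beans", ECO2Category.LEGUME),
            ]
        )
        effects = ECO2EffectTable(
            [_effect("LEGUME", -4.0, -5.5, -2.6, level=EffectLevel.CATEGORY)]
        )
        dists = build_effect_distributions(catalog, effects)
        assert dists["lentils"][0] == dists["beans"][0]

    def test_intake_uncertainty_only_for_gdd_matched(self, world, world_disagg):
        uncertainty = intake_uncertainty(world_disagg, world.catalog, world.gdd)
        for (country, food_id, token), (pert_key, cv) in uncertainty.items():
            assert world_disagg.provenance[(country, food_id, token)] == "GDD_MATCHED"
            record = world.catalog[food_id]
            row = world.gdd.lookup(country, record.gdd_group, token)
            assert cv == pytest.approx(row.factor_sd / row.factor)
            assert pert_key == (country, record.gdd_group, token)


def test_effect_distribution_mean_matches_scipy():
    dist = EffectDistribution(fit_skew_normal(-5, -9, -2))
    p = dist.params
    scipy_mean = skewnorm.mean(p.shape, loc=p.location, scale=p.scale)
    assert dist.mean() == pytest.approx(scipy_mean, rel=1e-9)
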