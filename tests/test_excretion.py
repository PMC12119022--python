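"""Digestion, feces/urine excretion and fiber partitioning."""

from __future__ import annotations

import pytest

from pigch4.excretion import (build_excreta, degradable_rf, digest_nutrients,
                              digested_rf, feces_mass, feces_mass_weaned,
                              fermentable_fiber, urine_nitrogen,
                              urine_nitrogen_balance, urine_volume)
from pigch4.feed_data import (DigestibilityRecord, FeedDataError,
                              FeedIngredient, FeedTable)
from pigch4.intake import IntakeResult


def toy_table() -> FeedTable:
    """Two all-OM ingredients with known digestibility (0.9 and 0.7)."""
    ingredients = {}
    digest = {}
    for name, d_om in (("high", 0.9), ("low", 0.7)):
        ingredients[name] = FeedIngredient(
            name=name, dm=1000, om=1000, cp=0, cf=0, starch=0, sugar=0,
            rf=1000, indf=0, nsp=0, snsp=0, ash=0)
        for cls in ("growing", "sow"):
            digest[(name, cls)] = DigestibilityRecord(
                ingredient=name, animal_class=cls, d_om=d_om, d_cp=0.8,
                d_cf=0.5, d_starch_sugar=0.999)
    return FeedTable(ingredients, digest)


class TestDigestNutrients:
    def test_two_ingredient_worked_example(self):
        # 100 g/d OM from each ingredient; digested = 90 + 70 = 160
        table = toy_table()
        intake = IntakeResult(feed_asfed=200, dmi=200,
                              nutrients={"om": 200.0})
        result = digest_nutrients(intake, (("high", 0.5), ("low", 0.5)),
                                  table, "growing")
        assert result.digested["om"] == pytest.approx(160.0)
        assert result.excreted["om"] == pytest.approx(40.0)

    @pytest.mark.parametrize("d, expected_excreted", [(1.0, 0.0), (0.0, 200.0)])
    def test_extreme_coefficients(self, d, expected_excreted):
        table = toy_table()
        for key in list(table.digestibility):
            rec = table.digestibility[key]
            table.digestibility[key] = DigestibilityRecord(
                rec.ingredient, rec.animal_class, d, d, d, d)
        intake = IntakeResult(feed_asfed=200, dmi=200, nutrients={"om": 200.0})
        result = digest_nutrients(intake, (("high", 0.5), ("low", 0.5)),
                                  table, "growing")
        assert result.excreted["om"] == pytest.approx(expected_excreted)

    def test_mass_balance_is_exact(self, feed_table, average_scenarios):
        from pigch4.feed_data import animal_class_for
        for cat, r in average_scenarios.items():
            d = digest_nutrients(r.intake, r.composition.dm_proportions,
                                 feed_table, animal_class_for(cat))
            for pool in ("om", "cp", "cf", "starch_sugar"):
                digested_plus_excreted = d.digested[pool] + d.excreted[pool]
                key = pool if pool != "starch_sugar" else None
                intake_pool = (r.intake.nutrient("starch") + r.intake.nutrient("sugar")
                               if key is None else r.intake.nutrient(key))
                assert digested_plus_excreted == pytest.approx(intake_pool, rel=1e-12)

    def test_missing_coefficient_names_ingredient(self):
        table = toy_table()
        del table.digestibility[("low", "growing")]
        intake = IntakeResult(feed_asfed=200, dmi=200, nutrients={"om": 200.0})
        with pytest.raises(FeedDataError, match="low"):
            digest_nutrients(intake, (("high", 0.5), ("low", 0.5)),
                             table, "growing")


class TestFiberArithmetic:
    def test_digested_rf_worked_example(self):
        assert digested_rf(800, 150, 30, 500) == 120

    def test_digested_rf_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            assert digested_rf(100, 80, 30, 20) == 0.0

    def test_fermentable_fiber_worked_example(self):
        assert fermentable_fiber(850, 160, 30, 520) == 140

    def test_ff_never_exceeds_diet_rf(self, average_scenarios, grower_diet_scenarios):
        for r in list(average_scenarios.values()) + list(grower_diet_scenarios.values()):
            assert r.excreta.ff <= r.composition.rf + 1e-9

    @pytest.mark.parametrize("rf, indf, expected", [(358, 143, 215), (100, 100, 0)])
    def test_degradable_rf(self, rf, indf, expected):
        assert degradable_rf(rf, indf) == expected

    def test_degradable_rf_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            assert degradable_rf(50, 60) == 0.0


class TestUrineNitrogen:
    def test_grower_average_prediction(self):
        assert urine_nitrogen(181, 2.141) == pytest.approx(24.78, abs=0.01)

    def test_nonpositive_prediction_advises_balance_route(self):
        with pytest.raises(FeedDataError, match="balance"):
            urine_nitrogen(0.1, 1e-9)

    def test_linearity_in_dmi(self):
        assert urine_nitrogen(181, 3.141) - urine_nitrogen(181, 2.141) == \
            pytest.approx(10.15)

    @pytest.mark.parametrize("args, expected", [((20, 5, 8), 7), ((10, 10, 0), 0)])
    def test_balance_route(self, args, expected):
        assert urine_nitrogen_balance(*args) == expected

    def test_infeasible_balance_raises(self):
        with pytest.raises(FeedDataError, match="infeasible"):
            urine_nitrogen_balance(5, 4, 3)


class TestFecesAndUrine:
    def test_feces_mass_worked_example(self):
        assert feces_mass(0.85, 2.141) == pytest.approx(1.123, abs=0.001)

    def test_feces_mass_decreases_with_digestibility(self):
        assert feces_mass(0.90, 2.141) < feces_mass(0.80, 2.141)

    def test_feces_mass_boundary_raises(self):
        with pytest.raises(FeedDataError, match="nonpositive"):
            feces_mass(0.857, 0.0)

    @pytest.mark.parametrize("dm, frac, expected", [(81, 0.25, 324), (100, 0.5, 200),
                                                    (0, 0.25, 0)])
    def test_weaned_feces_mass(self, dm, frac, expected):
        assert feces_mass_weaned(dm, frac) == pytest.approx(expected)

    def test_urine_volume_factors(self, managements):
        configs, _ = managements
        assert urine_volume(2.1409, configs["grower_finisher"]) == \
            pytest.approx(4.2818)
        assert urine_volume(5.522, configs["lactating_sow"]) == \
            pytest.approx(13.805)
        assert urine_volume(0.0, configs["weaned"]) == 0.0


class TestExcretaProfile:
    def test_feces_dm_below_dmi_and_composition_closes(self, average_scenarios):
        for r in average_scenarios.values():
            e = r.excreta
            assert e.feces_dm < r.intake.dmi
            fc = e.feces_composition
            assert fc["cp"] + fc["cf"] + fc["rf"] + fc["starch"] <= 1000.0
            assert fc["degradable_rf"] == pytest.approx(fc["rf"] - fc["indf"], abs=1e-6)

    def test_urea_and_vfa_constants(self, average_scenarios):
        for r in average_scenarios.values():
            e = r.excreta
            assert e.urea_n == pytest.approx(0.75 * e.urine_n)
            assert e.fecal_vfa == pytest.approx(2.87 * e.feces_mass / 1000.0)

    def test_grower_feces_dm_ordering_across_diets(self, grower_diet_scenarios):
        dm = {name: r.excreta.feces_dm for name, r in grower_diet_scenarios.items()}
        assert (dm["wheat"] < dm["average"] < dm["sugar_beet_pulp"]
                < dm["wheat_bran"] < dm["oat"])
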