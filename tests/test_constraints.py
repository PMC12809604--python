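import numpy as np
import pytest

import foodbudget as fb
from foodbudget.constraints import check_diet, convert_spec
from foodbudget.model import FoodModelError

MAN = fb.PersonProfile.man()
WOMAN = fb.PersonProfile.woman()


def spec(unit, value, target="free_sugars_g", bound="upper", applies_to="both"):
    return fb.ConstraintSpec(id="s", target=target, bound=bound, value=value,
                             unit=unit, applies_to=applies_to)


class TestPercentEnergy:
    def test_free_sugars_10pct_man(self):
        """10 % of 9.4 MJ at 17 kJ/g carbohydrate = 0.10 x 9400 / 17 g."""
        rhs = fb.convert_percent_energy(spec("%energy", 10.0), MAN)
        assert rhs == pytest.approx(0.10 * 9400.0 / 17.0)
        assert rhs == pytest.approx(55.29, abs=0.01)

    def test_zero_percent_is_zero_grams(self):
        assert fb.convert_percent_energy(spec("%energy", 0.0), MAN) == 0.0

    def test_woman_scales_by_energy_ratio(self):
        man = fb.convert_percent_energy(spec("%energy", 10.0), MAN)
        woman = fb.convert_percent_energy(spec("%energy", 10.0), WOMAN)
        assert man / woman == pytest.approx(9.4 / 7.55)

    def test_missing_energy_factor_names_nutrient(self):
        with pytest.raises(FoodModelError, match="calcium_mg"):
            fb.convert_percent_energy(spec("%energy", 10.0, target="calcium_mg"), MAN)


class TestBodyweightAndMegajoule:
    def test_protein_style_rule(self):
        rhs = fb.convert_bodyweight(spec("g/kg-bodyweight", 0.83, target="protein_g",
                                         bound="lower"), MAN)
        assert rhs == pytest.approx(0.83 * 82.0) == pytest.approx(68.06)

    def test_zero_value(self):
        assert fb.convert_bodyweight(spec("g/kg-bodyweight", 0.0), MAN) == 0.0

    def test_bodyweight_ratio(self):
        s = spec("g/kg-bodyweight", 0.83)
        assert (fb.convert_bodyweight(s, MAN) / fb.convert_bodyweight(s, WOMAN)
                == pytest.approx(82.0 / 66.0))

    def test_mg_per_mj(self):
        assert fb.convert_per_megajoule(spec("mg/MJ", 0.1), MAN) == pytest.approx(0.94)
        assert fb.convert_per_megajoule(spec("mg/MJ", 0.0), MAN) == 0.0
        ratio = (fb.convert_per_megajoule(spec("mg/MJ", 0.1), WOMAN)
                 / fb.convert_per_megajoule(spec("mg/MJ", 0.1), MAN))
        assert ratio == pytest.approx(7.55 / 9.4)

    @pytest.mark.parametrize("converter,unit", [
        (fb.convert_percent_energy, "%energy"),
        (fb.convert_bodyweight, "g/kg-bodyweight"),
        (fb.convert_per_megajoule, "mg/MJ"),
    ])
    def test_homogeneity_in_value(self, converter, unit):
        """Doubling the recommendation doubles the converted bound."""
        target = "free_sugars_g" if unit == "%energy" else "protein_g"
        one = converter(spec(unit, 1.7, target=target), MAN)
        two = converter(spec(unit, 3.4, target=target), MAN)
        assert two == pytest.approx(2.0 * one)


class TestFruitVeg:
    def test_mean_caloric_density_is_32(self):
        """2 fruit portions at 50 kcal + 3 vegetable portions at 20 kcal."""
        density = fb.fruit_veg_caloric_density(
            {"fruits": 2, "vegetables": 3}, {"fruits": 50, "vegetables": 20})
        assert density == pytest.approx((2 * 50 + 3 * 20) / 5) == pytest.approx(32.0)

    def test_lower_bound_man_about_491g(self, registry):
        codes = [g.code for g in registry]
        lower, upper = fb.build_fruit_veg_bounds(MAN, registry, codes)
        expected = 0.07 * (9.4 * 1000.0 / 4.184) / 0.32
        assert lower.rhs == pytest.approx(expected)
        assert lower.rhs == pytest.approx(491.46, abs=0.01)

    def test_upper_is_twice_lower(self, registry):
        codes = [g.code for g in registry]
        lower, upper = fb.build_fruit_veg_bounds(MAN, registry, codes)
        assert upper.rhs == pytest.approx(2.0 * lower.rhs)

    def test_coefficients_select_only_fruit_and_veg(self, registry):
        codes = [g.code for g in registry]
        lower, _ = fb.build_fruit_veg_bounds(MAN, registry, codes)
        fv = {g.code for g in registry if g.category in ("fruits", "vegetables")}
        for code, coeff in zip(codes, lower.coeffs):
            assert coeff == (1.0 if code in fv else 0.0)


class TestWater:
    def test_upper_is_130_percent_of_recommendation(self, toy_nutrients):
        codes = ["bread", "milk", "water"]
        lower, upper = fb.build_water_bounds(MAN, toy_nutrients, codes, 2500.0)
        assert lower.rhs == 2500.0
        assert upper.rhs == pytest.approx(1.3 * 2500.0)

    def test_water_accumulates_from_all_groups(self, toy_nutrients):
        """100 g of a food with 85 g water/100 g contributes 85 g of water."""
        codes = ["bread", "milk", "water"]
        lower, _ = fb.build_water_bounds(MAN, toy_nutrients, codes, 2500.0)
        diet = np.array([200.0, 100.0, 1000.0])
        expected = 200 * 0.35 + 100 * 0.85 + 1000 * 0.999
        assert lower.coeffs @ diet == pytest.approx(expected)

    def test_exact_recommendation_satisfies_lower_with_equality(self, toy_nutrients):
        codes = ["water"]
        lower, _ = fb.build_water_bounds(MAN, toy_nutrients, codes, 999.0)
        assert lower.satisfied_by(np.array([1000.0]))
        assert lower.slack(np.array([1000.0])) == pytest.approx(0.0, abs=1e-9)


class TestCaffeine:
    def test_four_cups_for_the_reference_man(self):
        assert fb.caffeine_cap_g(MAN) / 200.0 == pytest.approx(4.0)

    def test_man_cap_is_800_g(self):
        assert fb.caffeine_cap_g(MAN) == pytest.approx(800.0)

    def test_woman_cap_scaled_by_bodyweight(self):
        assert fb.caffeine_cap_g(WOMAN) == pytest.approx(800.0 * 66.0 / 82.0)
        assert fb.caffeine_cap_g(WOMAN) == pytest.approx(643.9, abs=0.05)

    def test_missing_codes_rejected(self, registry):
        with pytest.raises(FoodModelError, match="coffee/tea"):
            fb.build_caffeine_bounds(MAN, ["01.1.1.1"], ["zz"])


class TestAssemble:
    def test_empty_config_gives_no_bounds(self, bundle):
        codes = bundle.nutrients.codes
        bounds = fb.assemble_constraints({"specs": [], "food_rules": {}},
                                         MAN, bundle.nutrients, bundle.registry, codes)
        assert bounds == []

    def test_vitamin_d_floor_is_5_ug(self, bundle):
        codes = bundle.nutrients.codes
        bounds = fb.assemble_constraints(bundle.constraints, MAN, bundle.nutrients,
                                         bundle.registry, codes)
        vd = next(b for b in bounds if b.id == "vitamin_d_lower")
        assert vd.direction == ">=" and vd.rhs == pytest.approx(5.0)

    def test_g_day_spec_passes_through(self, bundle):
        codes = bundle.nutrients.codes
        s = fb.ConstraintSpec(id="fibre", target="fibre_g", bound="lower",
                              value=25.0, unit="g/day")
        b = convert_spec(s, MAN, bundle.nutrients, codes)
        assert b.rhs == 25.0 and b.direction == ">="

    def test_unit_conversion_between_mass_scales(self, bundle):
        codes = bundle.nutrients.codes
        s = fb.ConstraintSpec(id="vd", target="vitamin_d_ug", bound="lower",
                              value=0.005, unit="mg/day")
        assert convert_spec(s, MAN, bundle.nutrients, codes).rhs == pytest.approx(5.0)

    def test_unknown_nutrient_rejected(self, bundle):
        s = fb.ConstraintSpec(id="x", target="selenium_ug", bound="lower",
                              value=1.0, unit="µg/day")
        with pytest.raises(FoodModelError, match="selenium"):
            convert_spec(s, MAN, bundle.nutrients, bundle.nutrients.codes)

    def test_gender_specific_specs_filtered(self, bundle):
        codes = bundle.nutrients.codes
        for person, expected in [(MAN, 11.0), (WOMAN, 16.0)]:
            bounds = fb.assemble_constraints(bundle.constraints, person,
                                             bundle.nutrients, bundle.registry, codes)
            iron = [b for b in bounds if b.id.startswith("iron_lower")]
            assert len(iron) == 1 and iron[0].rhs == pytest.approx(expected)

    def test_builder_and_checker_agree_on_random_diets(self, bundle):
        """Bounds evaluated by matrix product and by plain accumulation agree."""
        codes = bundle.nutrients.codes
        bounds = fb.assemble_constraints(bundle.constraints, MAN, bundle.nutrients,
                                         bundle.registry, codes)
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.uniform(0, 400, size=len(codes))
            diet = dict(zip(codes, x))
            loop_violations = set(check_diet(diet, bounds, codes))
            vec_violations = {b.id for b in bounds if not b.satisfied_by(x)}
            assert loop_violations == vec_violations
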