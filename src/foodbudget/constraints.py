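"""Conversion of recommendations in native units into g-space linear bounds.

Every dietary recommendation — a nutrient reference value in g, mg or µg
per day, a %-of-energy range, a g-per-kg-bodyweight rule, an mg-per-MJ
rule, or a food-based rule on summed group mass — becomes one or two
:class:`~foodbudget.model.LinearBound` rows over the model's food groups:
``coeffs . X (>=|<=) rhs`` with per-gram coefficients.

Unit conversions use the reference person's recommended energy intake and
body weight, and the EC 90/496/EEC metabolisable-energy factors for
%-energy rules.
"""

from __future__ import annotations

import numpy as np

from .model import (
    ENERGY_FACTOR_OF_NUTRIENT,
    ENERGY_FACTORS_KJ_PER_G,
    ConstraintSpec,
    FoodGroup,
    FoodModelError,
    LinearBound,
    NutrientTable,
    PersonProfile,
)

_MASS_IN_G = {"g/day": 1.0, "mg/day": 1e-3, "µg/day": 1e-6}
_SUFFIX_IN_G = {"_g": 1.0, "_mg": 1e-3, "_ug": 1e-6}


def _nutrient_unit_in_g(nutrient: str) -> float:
    for suffix, grams in _SUFFIX_IN_G.items():
        if nutrient.endswith(suffix):
            return grams
    raise FoodModelError(f"nutrient {nutrient!r} has no mass-unit suffix (_g/_mg/_ug)")


def _direction(spec: ConstraintSpec) -> str:
    return ">=" if spec.bound == "lower" else "<="


def convert_percent_energy(
    spec: ConstraintSpec,
    person: PersonProfile,
    energy_factors_kj_per_g: dict[str, float] | None = None,
) -> float:
    """Convert a %-of-energy recommendation to g/day.

    RHS = (value/100 x rE in kJ) / energy factor (kJ/g) of the nutrient.
    """
    if spec.unit != "%energy":
        raise FoodModelError(f"{spec.id}: expected unit %energy, got {spec.unit}")
    factors = energy_factors_kj_per_g or ENERGY_FACTORS_KJ_PER_G
    factor_name = ENERGY_FACTOR_OF_NUTRIENT.get(spec.target)
    if factor_name is None or factor_name not in factors:
        raise FoodModelError(f"{spec.id}: no energy factor for nutrient {spec.target!r}")
    re_kj = person.energy_mj * 1000.0
    return (spec.value / 100.0) * re_kj / factors[factor_name]


def convert_bodyweight(spec: ConstraintSpec, person: PersonProfile) -> float:
    """Convert a g-per-kg-bodyweight recommendation to g/day."""
    if spec.unit != "g/kg-bodyweight":
        raise FoodModelError(f"{spec.id}: expected unit g/kg-bodyweight, got {spec.unit}")
    if person.bodyweight_kg <= 0:
        raise FoodModelError("body weight must be positive")
    return spec.value * person.bodyweight_kg


def convert_per_megajoule(spec: ConstraintSpec, person: PersonProfile) -> float:
    """Convert an mg-per-MJ recommendation to mg/day."""
    if spec.unit != "mg/MJ":
        raise FoodModelError(f"{spec.id}: expected unit mg/MJ, got {spec.unit}")
    return spec.value * person.energy_mj


def fruit_veg_caloric_density(portions: dict[str, float],
                              portion_kcal_per_100g: dict[str, float]) -> float:
    """Portion-weighted mean caloric density of fruit+veg, kcal per 100 g.

    With the recommended 2 fruit portions at 50 kcal/100 g and 3 vegetable
    portions at 20 kcal/100 g this is (2x50 + 3x20)/5 = 32 kcal/100 g.
    """
    total = sum(portions.values())
    if total <= 0:
        raise FoodModelError("portion counts must sum to a positive number")
    return sum(portions[k] * portion_kcal_per_100g[k] for k in portions) / total


def build_fruit_veg_bounds(
    person: PersonProfile,
    registry: list[FoodGroup],
    codes: list[str],
    lower_pct_energy: float = 7.0,
    upper_pct_energy: float = 14.0,
    portions: dict[str, float] | None = None,
    portion_kcal_per_100g: dict[str, float] | None = None,
    categories: tuple[str, ...] = ("fruits", "vegetables"),
) -> list[LinearBound]:
    """The fruit+vegetable energy-share rule as a pair of mass bounds.

    The 7-14 %-of-energy recommendation is converted to g/day via the mean
    caloric density (default 32 kcal/100 g = 0.32 kcal/g); both bounds sum
    the quantities of all fruit and vegetable groups.
    """
    portions = portions or {"fruits": 2, "vegetables": 3}
    portion_kcal_per_100g = portion_kcal_per_100g or {"fruits": 50, "vegetables": 20}
    density_kcal_per_g = fruit_veg_caloric_density(portions, portion_kcal_per_100g) / 100.0
    fv_codes = {g.code for g in registry if g.category in categories}
    coeffs = np.array([1.0 if c in fv_codes else 0.0 for c in codes])
    if not coeffs.any():
        raise FoodModelError("no fruit or vegetable groups present in the model")
    lower = lower_pct_energy / 100.0 * person.energy_kcal / density_kcal_per_g
    upper = upper_pct_energy / 100.0 * person.energy_kcal / density_kcal_per_g
    return [
        LinearBound(id="fruit_veg_lower", coeffs=coeffs, direction=">=", rhs=lower),
        LinearBound(id="fruit_veg_upper", coeffs=coeffs.copy(), direction="<=", rhs=upper),
    ]


def build_water_bounds(
    person: PersonProfile,
    nutrients: NutrientTable,
    codes: list[str],
    recommended_g_day: float,
    upper_multiplier: float = 1.3,
) -> list[LinearBound]:
    """Total-water rule: water from beverages and from food.

    Coefficients are the per-gram water contents of every group; the lower
    bound is the recommended amount, the upper bound caps total water at
    ``upper_multiplier`` times it (default +30 %) so beverages are not
    over-represented in the optimum.
    """
    if "water_g" not in nutrients.nutrients:
        raise FoodModelError("nutrient table has no water_g column")
    coeffs = nutrients.per_gram_vector("water_g", codes)
    return [
        LinearBound(id="water_lower", coeffs=coeffs, direction=">=", rhs=recommended_g_day),
        LinearBound(id="water_upper", coeffs=coeffs.copy(), direction="<=",
                    rhs=upper_multiplier * recommended_g_day),
    ]


def caffeine_cap_g(
    person: PersonProfile,
    safe_mg_day: float = 400.0,
    mg_per_cup: float = 100.0,
    cup_g: float = 200.0,
    scale_woman_by_bodyweight: bool = True,
    reference_bodyweight_kg: float = 82.0,
) -> float:
    """Mass cap (g/day) on coffee+tea implied by the safe caffeine intake.

    400 mg/day at just under 100 mg per 200-ml cup gives 4 cups = 800 g for
    the reference man; for other body weights the cap is scaled by the
    body-weight ratio (caffeine guidance is weight-based).
    """
    cups = safe_mg_day / mg_per_cup
    cap = cups * cup_g
    if scale_woman_by_bodyweight and person.bodyweight_kg != reference_bodyweight_kg:
        cap *= person.bodyweight_kg / reference_bodyweight_kg
    return cap


def build_caffeine_bounds(
    person: PersonProfile,
    codes: list[str],
    coffee_tea_codes: list[str],
    safe_mg_day: float = 400.0,
    mg_per_cup: float = 100.0,
    cup_g: float = 200.0,
    scale_woman_by_bodyweight: bool = True,
) -> list[LinearBound]:
    """Upper bound on summed coffee+tea mass from the caffeine safety limit."""
    present = [c for c in coffee_tea_codes if c in codes]
    if not present:
        raise FoodModelError(f"none of the coffee/tea codes {coffee_tea_codes} present in the model")
    coeffs = np.array([1.0 if c in set(present) else 0.0 for c in codes])
    cap = caffeine_cap_g(person, safe_mg_day, mg_per_cup, cup_g, scale_woman_by_bodyweight)
    return [LinearBound(id="caffeine_upper", coeffs=coeffs, direction="<=", rhs=cap)]


def convert_spec(
    spec: ConstraintSpec,
    person: PersonProfile,
    nutrients: NutrientTable,
    codes: list[str],
    energy_factors_kj_per_g: dict[str, float] | None = None,
) -> LinearBound:
    """Realise a single generic ConstraintSpec as a LinearBound over ``codes``."""
    if spec.is_food_rule:
        if spec.unit != "g/day":
            raise FoodModelError(f"{spec.id}: food-based rules must be in g/day, got {spec.unit}")
        targets = set(spec.target)
        missing = targets - set(codes)
        present = targets & set(codes)
        if not present:
            raise FoodModelError(f"{spec.id}: none of the target codes {sorted(missing)} in the model")
        coeffs = np.array([1.0 if c in targets else 0.0 for c in codes])
        return LinearBound(id=spec.id, coeffs=coeffs, direction=_direction(spec), rhs=spec.value)

    nutrient = spec.target
    if nutrient not in nutrients.nutrients:
        raise FoodModelError(f"{spec.id}: unknown nutrient {nutrient!r}")
    coeffs = nutrients.per_gram_vector(nutrient, codes)

    if spec.unit in _MASS_IN_G:
        rhs = spec.value * _MASS_IN_G[spec.unit] / _nutrient_unit_in_g(nutrient)
    elif spec.unit == "kcal/day":
        if not nutrient.endswith("_kcal"):
            raise FoodModelError(f"{spec.id}: kcal/day only applies to energy")
        rhs = spec.value
    elif spec.unit == "%energy":
        rhs = convert_percent_energy(spec, person, energy_factors_kj_per_g)
        rhs /= _nutrient_unit_in_g(nutrient)  # grams -> the nutrient's table unit
    elif spec.unit == "g/kg-bodyweight":
        rhs = convert_bodyweight(spec, person) / _nutrient_unit_in_g(nutrient)
    elif spec.unit == "mg/MJ":
        rhs = convert_per_megajoule(spec, person) * 1e-3 / _nutrient_unit_in_g(nutrient)
    else:
        raise FoodModelError(f"{spec.id}: unit {spec.unit!r} cannot be converted here")
    return LinearBound(id=spec.id, coeffs=coeffs, direction=_direction(spec), rhs=rhs)


def assemble_constraints(
    config: dict,
    person: PersonProfile,
    nutrients: NutrientTable,
    registry: list[FoodGroup],
    codes: list[str],
) -> list[LinearBound]:
    """Realise a full constraint configuration for one reference person.

    ``config`` is the structure returned by
    :func:`foodbudget.io.read_constraints`: generic specs plus the
    parametrised food rules (energy anchor, fruit/vegetable energy share,
    total water, caffeine). Range rules yield two bounds. Specs whose
    ``applies_to`` does not match the person's gender are skipped.
    """
    bounds: list[LinearBound] = []
    factors = config.get("energy_factors_kj_per_g") or None
    specs: list[ConstraintSpec] = list(config.get("specs", []))

    by_target_lower: dict = {}
    deferred: list[ConstraintSpec] = []
    for spec in specs:
        if not spec.applies(person.gender):
            continue
        if spec.unit == "multiplier-of-lower-bound":
            deferred.append(spec)
            continue
        lb = convert_spec(spec, person, nutrients, codes, factors)
        if spec.bound == "lower":
            by_target_lower[spec.target] = lb
        bounds.append(lb)
    for spec in deferred:
        base = by_target_lower.get(spec.target)
        if base is None:
            raise FoodModelError(f"{spec.id}: multiplier-of-lower-bound needs a lower bound on {spec.target!r}")
        bounds.append(LinearBound(id=spec.id, coeffs=base.coeffs.copy(),
                                  direction=_direction(spec), rhs=spec.value * base.rhs))

    rules = config.get("food_rules", {})
    if "energy" in rules:
        band = float(rules["energy"].get("band_fraction", 0.0))
        coeffs = nutrients.per_gram_vector("energy_kcal", codes)
        re_kcal = person.energy_kcal
        bounds.append(LinearBound(id="energy_lower", coeffs=coeffs, direction=">=",
                                  rhs=re_kcal * (1.0 - band)))
        bounds.append(LinearBound(id="energy_upper", coeffs=coeffs.copy(), direction="<=",
                                  rhs=re_kcal * (1.0 + band)))
    if "fruit_veg" in rules:
        fv = rules["fruit_veg"]
        bounds.extend(build_fruit_veg_bounds(
            person, registry, codes,
            lower_pct_energy=float(fv.get("lower_pct_energy", 7.0)),
            upper_pct_energy=float(fv.get("upper_pct_energy", 14.0)),
            portions=fv.get("portions"),
            portion_kcal_per_100g=fv.get("portion_kcal_per_100g"),
            categories=tuple(fv.get("categories", ("fruits", "vegetables"))),
        ))
    if "water" in rules:
        w = rules["water"]
        rec = w["recommended_g_day"]
        rec_value = float(rec[person.gender]) if isinstance(rec, dict) else float(rec)
        bounds.extend(build_water_bounds(
            person, nutrients, codes, rec_value,
            upper_multiplier=float(w.get("upper_multiplier", 1.3)),
        ))
    if "caffeine" in rules:
        cf = rules["caffeine"]
        bounds.extend(build_caffeine_bounds(
            person, codes, list(cf["codes"]),
            safe_mg_day=float(cf.get("safe_mg_day", 400.0)),
            mg_per_cup=float(cf.get("mg_per_cup", 100.0)),
            cup_g=float(cf.get("cup_g", 200.0)),
            scale_woman_by_bodyweight=bool(cf.get("scale_woman_by_bodyweight", True)),
        ))
    return bounds


def check_diet(quantities: dict[str, float], bounds: list[LinearBound],
               codes: list[str], tol: float = 1e-7) -> list[str]:
    """Independent feasibility check by direct accumulation.

    Recomputes each bound's left-hand side with a plain Python loop (no
    linear algebra shared with the builder) and returns the ids of violated
    bounds. Used as the oracle against the LP solution path.
    """
    violations = []
    for bound in bounds:
        lhs = 0.0
        for j, code in enumerate(codes):
            lhs += float(bound.coeffs[j]) * quantities[code]
        scale = max(1.0, abs(bound.rhs))
        if bound.direction == ">=":
            ok = lhs >= bound.rhs - tol * scale
        else:
            ok = lhs <= bound.rhs + tol * scale
        if not ok:
            violations.append(bound.id)
    return violations
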