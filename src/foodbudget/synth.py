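"""Synthetic fixture datasets with the statistical structure the pipeline assumes.

The licensed inputs (household-budget consumption means, the national food
composition database, consumer-price-index micro-prices, Eurostat price
level indices and incomes) cannot be bundled. This module generates an
internally consistent stand-in world:

* a 60-group registry (the shipped illustrative ECOICOP config),
* per-group nutrient vectors built from category templates with jitter,
  energy derived from the macronutrients via the EC 90/496/EEC factors,
* per country x gender consumption profiles whose energy shares follow a
  Dirichlet draw over category targets; an ``unhealthiness`` dial in [0,1]
  blends between a feasible-by-construction healthy diet (projected onto
  the constraint polytope with an auxiliary LP) and an over-sweet,
  over-fat, fruit/veg/fish-deficient one,
* right-skewed (log-normal) price observation sets per group for a base
  country, price level indices for the others (with an optional hold-out
  country to exercise the missing-PLI path), and incomes spanning a
  configured range.

Everything is driven by one integer seed; the same seed yields an
identical bundle.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as fio
from .constraints import assemble_constraints
from .lp import linearize, solve
from .model import (
    CATEGORIES,
    ConstraintSpec,
    ConsumptionProfile,
    FoodGroup,
    FoodModelError,
    NutrientTable,
    PersonProfile,
    default_person,
)
from .scaling import scale_to_energy

import pandas as pd

#: Groups whose daily grams are drawn directly (near-zero energy density
#: makes an energy-share allocation ill-posed for them).
DIRECT_GRAM_CODES = {
    "01.2.2.1": (700.0, 1300.0),   # mineral water
    "01.2.1.1": (200.0, 500.0),    # coffee (beverage-equivalent grams)
    "01.2.1.2": (50.0, 250.0),     # tea (beverage-equivalent grams)
}

#: Target category energy shares of the Dirichlet draw (beverage groups
#: with direct grams excluded). Healthy vs maximally unhealthy profiles;
#: the unhealthiness dial interpolates linearly between them.
HEALTHY_ENERGY_SHARES = {
    "carbohydrate_rich": 0.36, "fruits": 0.07, "vegetables": 0.05, "meat": 0.08,
    "fish": 0.05, "dairy": 0.14, "eggs": 0.02, "oils_fats": 0.09,
    "sweets_snacks": 0.06, "others": 0.08,
}
UNHEALTHY_ENERGY_SHARES = {
    "carbohydrate_rich": 0.30, "fruits": 0.025, "vegetables": 0.005, "meat": 0.12,
    "fish": 0.015, "dairy": 0.10, "eggs": 0.02, "oils_fats": 0.15,
    "sweets_snacks": 0.185, "others": 0.08,
}

#: Macronutrient templates per 100 g by category (jittered per group).
_MACRO_TEMPLATES = {
    "carbohydrate_rich": dict(protein_g=8, fat_g=3, satfat_g=1.0, pufa_g=0.8,
                              cholesterol_mg=5, carb_g=52, free_sugars_g=3,
                              fibre_g=4.5, water_g=28, salt_g=0.9),
    "fruits": dict(protein_g=0.9, fat_g=0.5, satfat_g=0.1, pufa_g=0.15,
                   cholesterol_mg=0, carb_g=11, free_sugars_g=1, fibre_g=2.3,
                   water_g=83, salt_g=0.01),
    "vegetables": dict(protein_g=2.0, fat_g=0.4, satfat_g=0.1, pufa_g=0.15,
                       cholesterol_mg=0, carb_g=4.5, free_sugars_g=0.3,
                       fibre_g=2.6, water_g=89, salt_g=0.05),
    "meat": dict(protein_g=19, fat_g=14, satfat_g=5.5, pufa_g=1.5,
                 cholesterol_mg=75, carb_g=0.6, free_sugars_g=0.1, fibre_g=0,
                 water_g=62, salt_g=1.4),
    "fish": dict(protein_g=18, fat_g=7, satfat_g=1.6, pufa_g=2.2,
                 cholesterol_mg=55, carb_g=0.5, free_sugars_g=0, fibre_g=0,
                 water_g=71, salt_g=0.8),
    "dairy": dict(protein_g=5.5, fat_g=4.5, satfat_g=2.8, pufa_g=0.2,
                  cholesterol_mg=14, carb_g=5.5, free_sugars_g=0.5, fibre_g=0,
                  water_g=80, salt_g=0.4),
    "eggs": dict(protein_g=12.5, fat_g=10.5, satfat_g=3.2, pufa_g=1.5,
                 cholesterol_mg=370, carb_g=1, free_sugars_g=0, fibre_g=0,
                 water_g=74, salt_g=0.35),
    "oils_fats": dict(protein_g=0.3, fat_g=82, satfat_g=25, pufa_g=30,
                      cholesterol_mg=45, carb_g=0.3, free_sugars_g=0, fibre_g=0,
                      water_g=15, salt_g=0.3),
    "sweets_snacks": dict(protein_g=5, fat_g=18, satfat_g=8, pufa_g=2.5,
                          cholesterol_mg=20, carb_g=62, free_sugars_g=38,
                          fibre_g=2, water_g=9, salt_g=0.6),
    "others": dict(protein_g=3.5, fat_g=8, satfat_g=1.8, pufa_g=2.5,
                   cholesterol_mg=10, carb_g=14, free_sugars_g=4, fibre_g=1,
                   water_g=65, salt_g=4.5),
}

_MICRO_TEMPLATES = {
    "carbohydrate_rich": dict(vitamin_c_mg=1, vitamin_d_ug=0, vitamin_b12_ug=0,
                              folate_ug=15, calcium_mg=25, iron_mg=1.5,
                              magnesium_mg=40, potassium_mg=160, zinc_mg=1.1),
    "fruits": dict(vitamin_c_mg=35, vitamin_d_ug=0, vitamin_b12_ug=0, folate_ug=8,
                   calcium_mg=20, iron_mg=0.5, magnesium_mg=15, potassium_mg=250, zinc_mg=0.2),
    "vegetables": dict(vitamin_c_mg=4, vitamin_d_ug=0, vitamin_b12_ug=0, folate_ug=90,
                       calcium_mg=50, iron_mg=1.5, magnesium_mg=25, potassium_mg=300, zinc_mg=0.5),
    "meat": dict(vitamin_c_mg=0, vitamin_d_ug=0.5, vitamin_b12_ug=2.5, folate_ug=5,
                 calcium_mg=10, iron_mg=2.0, magnesium_mg=22, potassium_mg=320, zinc_mg=3.2),
    "fish": dict(vitamin_c_mg=0, vitamin_d_ug=8, vitamin_b12_ug=4.5, folate_ug=12,
                 calcium_mg=40, iron_mg=1.0, magnesium_mg=30, potassium_mg=350, zinc_mg=1.0),
    "dairy": dict(vitamin_c_mg=0.5, vitamin_d_ug=0.8, vitamin_b12_ug=0.6, folate_ug=5,
                  calcium_mg=170, iron_mg=0.1, magnesium_mg=12, potassium_mg=160, zinc_mg=0.5),
    "eggs": dict(vitamin_c_mg=0, vitamin_d_ug=2.9, vitamin_b12_ug=1.9, folate_ug=45,
                 calcium_mg=55, iron_mg=1.8, magnesium_mg=12, potassium_mg=130, zinc_mg=1.3),
    "oils_fats": dict(vitamin_c_mg=0, vitamin_d_ug=5, vitamin_b12_ug=0, folate_ug=2,
                      calcium_mg=5, iron_mg=0.1, magnesium_mg=2, potassium_mg=20, zinc_mg=0.1),
    "sweets_snacks": dict(vitamin_c_mg=1, vitamin_d_ug=0.3, vitamin_b12_ug=0.1, folate_ug=8,
                          calcium_mg=50, iron_mg=1.2, magnesium_mg=35, potassium_mg=180, zinc_mg=0.6),
    "others": dict(vitamin_c_mg=1, vitamin_d_ug=0.2, vitamin_b12_ug=0.1, folate_ug=5,
                   calcium_mg=25, iron_mg=0.6, magnesium_mg=12, potassium_mg=110, zinc_mg=0.3),
}

#: Per-code overrides replacing the category template (mostly beverages).
_CODE_OVERRIDES: dict[str, dict[str, float]] = {
    "01.2.2.1": dict(protein_g=0, fat_g=0, satfat_g=0, pufa_g=0, cholesterol_mg=0,
                     carb_g=0, free_sugars_g=0, fibre_g=0, water_g=99.9, salt_g=0.01,
                     vitamin_c_mg=0, vitamin_d_ug=0, vitamin_b12_ug=0, folate_ug=0,
                     calcium_mg=15, iron_mg=0, magnesium_mg=8, potassium_mg=2, zinc_mg=0),
    "01.2.1.1": dict(protein_g=0.2, fat_g=0, satfat_g=0, pufa_g=0, cholesterol_mg=0,
                     carb_g=0.3, free_sugars_g=0, fibre_g=0, water_g=99, salt_g=0,
                     vitamin_c_mg=0, vitamin_d_ug=0, vitamin_b12_ug=0, folate_ug=1,
                     calcium_mg=4, iron_mg=0.1, magnesium_mg=8, potassium_mg=90, zinc_mg=0),
    "01.2.1.2": dict(protein_g=0.1, fat_g=0, satfat_g=0, pufa_g=0, cholesterol_mg=0,
                     carb_g=0.2, free_sugars_g=0, fibre_g=0, water_g=99.5, salt_g=0,
                     vitamin_c_mg=0, vitamin_d_ug=0, vitamin_b12_ug=0, folate_ug=2,
                     calcium_mg=2, iron_mg=0, magnesium_mg=2, potassium_mg=25, zinc_mg=0),
    "01.2.2.2": dict(protein_g=0, fat_g=0, satfat_g=0, pufa_g=0, cholesterol_mg=0,
                     carb_g=10, free_sugars_g=10, fibre_g=0, water_g=89, salt_g=0.02,
                     vitamin_c_mg=0, vitamin_d_ug=0, vitamin_b12_ug=0, folate_ug=0,
                     calcium_mg=4, iron_mg=0, magnesium_mg=1, potassium_mg=5, zinc_mg=0),
    "01.2.2.3": dict(protein_g=0.5, fat_g=0.1, satfat_g=0, pufa_g=0, cholesterol_mg=0,
                     carb_g=10, free_sugars_g=9, fibre_g=0.2, water_g=88, salt_g=0.01,
                     vitamin_c_mg=3, vitamin_d_ug=0, vitamin_b12_ug=0, folate_ug=10,
                     calcium_mg=10, iron_mg=0.2, magnesium_mg=10, potassium_mg=150, zinc_mg=0.1),
    "01.2.1.3": dict(protein_g=20, fat_g=12, satfat_g=7, pufa_g=0.5, cholesterol_mg=0,
                     carb_g=35, free_sugars_g=1, fibre_g=15, water_g=4, salt_g=0.1,
                     vitamin_c_mg=0, vitamin_d_ug=0, vitamin_b12_ug=0, folate_ug=30,
                     calcium_mg=120, iron_mg=10, magnesium_mg=400, potassium_mg=1500, zinc_mg=6),
    "01.1.4.5": dict(protein_g=24, fat_g=28, satfat_g=18, pufa_g=1, cholesterol_mg=90,
                     carb_g=2, free_sugars_g=0, fibre_g=0, water_g=42, salt_g=1.8,
                     vitamin_c_mg=0, vitamin_d_ug=1.0, vitamin_b12_ug=2.1, folate_ug=25,
                     calcium_mg=750, iron_mg=0.3, magnesium_mg=30, potassium_mg=100, zinc_mg=3.5),
    "01.1.5.3": dict(protein_g=0, fat_g=99, satfat_g=14, pufa_g=9, cholesterol_mg=0,
                     carb_g=0, free_sugars_g=0, fibre_g=0, water_g=0.1, salt_g=0,
                     vitamin_c_mg=0, vitamin_d_ug=0, vitamin_b12_ug=0, folate_ug=0,
                     calcium_mg=1, iron_mg=0.1, magnesium_mg=0.1, potassium_mg=1, zinc_mg=0),
}

#: Median retail price per kg by category (EUR/kg; beverages are priced
#: per kg of beverage-equivalent mass, matching the consumption unit).
_PRICE_MEDIANS = {
    "carbohydrate_rich": 1.8, "fruits": 2.2, "vegetables": 2.0, "meat": 7.5,
    "fish": 11.0, "dairy": 3.5, "eggs": 3.0, "oils_fats": 4.5,
    "sweets_snacks": 6.0, "others": 2.5,
}
_PRICE_CODE_OVERRIDES = {
    "01.2.2.1": 0.4, "01.2.1.1": 1.5, "01.2.1.2": 1.0,
    "01.2.2.2": 1.0, "01.2.2.3": 1.3, "01.1.4.5": 8.0, "01.1.5.3": 7.0,
}

SWEETS_CODES_PREFIX = "01.1.8"


@dataclass
class SynthConfig:
    """Knobs of the synthetic world; defaults are the study conditions."""

    seed: int = 0
    n_countries: int = 4
    n_groups: int = 60
    unhealthiness: float = 0.5
    energy_factor_mean: float = 1.05
    energy_factor_sd: float = 0.08
    dirichlet_concentration: float = 150.0
    nutrient_jitter_sd: float = 0.12
    price_sigma: float = 0.35
    price_median_jitter_sd: float = 0.25
    n_price_obs: int = 60
    income_range: tuple[float, float] = (3284.0, 34472.0)
    pli_spread: float = 0.15
    pli_code_jitter_sd: float = 0.05
    pli_holdout: str | None = None
    absent_group_country: str | None = None
    absent_group_code: str = "01.1.7.9"
    constraint_config: dict | None = None
    projection_floor: float = 0.10
    max_retries: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.unhealthiness <= 1.0:
            raise FoodModelError("unhealthiness must lie in [0, 1]")
        for name in ("energy_factor_sd", "price_sigma", "pli_spread",
                     "nutrient_jitter_sd", "pli_code_jitter_sd"):
            if getattr(self, name) < 0:
                raise FoodModelError(f"{name} must be >= 0")
        if self.n_groups < len(CATEGORIES):
            raise FoodModelError(
                f"n_groups must be at least the {len(CATEGORIES)} categories"
            )


@dataclass
class Bundle:
    """A complete synthetic dataset bundle, ready for the pipeline."""

    config: SynthConfig
    registry: list[FoodGroup]
    registry_config: dict
    nutrients: NutrientTable
    profiles: list[ConsumptionProfile]
    prices: dict[str, np.ndarray]
    price_medians: dict[str, float]
    pli: dict[str, dict[str, float]]
    incomes: dict[str, float]
    constraints: dict
    base_country: str
    countries: list[str] = field(default_factory=list)

    def profile(self, country: str, gender: str) -> ConsumptionProfile:
        for p in self.profiles:
            if p.country == country and p.gender == gender:
                return p
        raise FoodModelError(f"no profile for {country}/{gender}")

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write the whole bundle as the plain-text interchange formats."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {
            "consumption": directory / "consumption.csv",
            "nutrients": directory / "nutrients.csv",
            "prices": directory / "prices.csv",
            "pli": directory / "pli.csv",
            "incomes": directory / "incomes.csv",
            "registry": directory / "registry.yaml",
            "constraints": directory / "constraints.yaml",
        }
        fio.write_consumption(self.profiles, paths["consumption"])
        fio.write_nutrients(self.nutrients, paths["nutrients"])
        fio.write_prices(self.prices, paths["prices"])
        fio.write_pli(self.pli, paths["pli"])
        fio.write_incomes(self.incomes, paths["incomes"])
        with open(paths["registry"], "w") as fh:
            yaml.safe_dump(self.registry_config, fh, sort_keys=False)
        constraints_yaml = {
            "energy_factors_kj_per_g": self.constraints["energy_factors_kj_per_g"],
            "constraints": [
                {"id": s.id,
                 "target": s.target if isinstance(s.target, str) else list(s.target),
                 "bound": s.bound, "value": s.value, "unit": s.unit,
                 "applies_to": s.applies_to, "notes": s.notes}
                for s in self.constraints["specs"]
            ],
            "food_rules": self.constraints["food_rules"],
        }
        with open(paths["constraints"], "w") as fh:
            yaml.safe_dump(constraints_yaml, fh, sort_keys=False)
        return paths


def _select_groups(registry: list[FoodGroup], n_groups: int) -> list[FoodGroup]:
    if n_groups > len(registry):
        raise FoodModelError(f"n_groups {n_groups} exceeds the registry size {len(registry)}")
    required = set(DIRECT_GRAM_CODES)
    chosen: dict[str, FoodGroup] = {g.code: g for g in registry if g.code in required}
    for cat in CATEGORIES:
        members = [g for g in registry if g.category == cat]
        if members and not any(g.category == cat for g in chosen.values()):
            chosen[members[0].code] = members[0]
    for g in registry:
        if len(chosen) >= n_groups:
            break
        chosen.setdefault(g.code, g)
    if len(chosen) > n_groups:
        raise FoodModelError(
            f"n_groups {n_groups} too small to keep every category and beverage group"
        )
    return sorted(chosen.values(), key=lambda g: g.code)


def _make_nutrients(rng: np.random.Generator, groups: list[FoodGroup],
                    jitter_sd: float) -> NutrientTable:
    rows = {}
    for g in groups:
        if g.code in _CODE_OVERRIDES:
            base = dict(_CODE_OVERRIDES[g.code])
        else:
            base = dict(_MACRO_TEMPLATES[g.category]) | dict(_MICRO_TEMPLATES[g.category])
        vec = {}
        for key, value in base.items():
            jitter = float(np.exp(rng.normal(0.0, jitter_sd))) if value > 0 else 1.0
            vec[key] = value * jitter
        # structural consistency: fat fractions and sugars within carbs
        vec["satfat_g"] = min(vec["satfat_g"], 0.85 * vec["fat_g"])
        vec["pufa_g"] = min(vec["pufa_g"], max(vec["fat_g"] - vec["satfat_g"], 0.0))
        vec["free_sugars_g"] = min(vec["free_sugars_g"], vec["carb_g"])
        macro_mass = (vec["protein_g"] + vec["fat_g"] + vec["carb_g"]
                      + vec["fibre_g"] + vec["salt_g"])
        if macro_mass > 100.0:
            scale = 100.0 / macro_mass
            for key in ("protein_g", "fat_g", "satfat_g", "pufa_g", "carb_g",
                        "free_sugars_g", "fibre_g", "salt_g"):
                vec[key] *= scale
            macro_mass = 100.0
        vec["water_g"] = min(vec["water_g"], 100.0 - macro_mass)
        # energy from the EC 90/496/EEC factors, so declared and derived agree
        kj = (vec["protein_g"] * 17.0 + vec["carb_g"] * 17.0
              + vec["fat_g"] * 37.0 + vec["fibre_g"] * 8.0)
        vec["energy_kcal"] = kj / 4.184
        rows[g.code] = vec
    return NutrientTable(pd.DataFrame.from_dict(rows, orient="index"))


def _draw_diet(rng: np.random.Generator, groups: list[FoodGroup],
               nutrients: NutrientTable, shares_by_cat: dict[str, float],
               target_energy_kcal: float, concentration: float) -> dict[str, float]:
    """Draw grams per group from category energy shares + direct beverages."""
    quantities: dict[str, float] = {}
    beverage_energy = 0.0
    for code, (lo, hi) in DIRECT_GRAM_CODES.items():
        if any(g.code == code for g in groups):
            grams = float(rng.uniform(lo, hi))
            quantities[code] = grams
            beverage_energy += grams / 100.0 * nutrients.per_100g(code, "energy_kcal")
    share_groups = [g for g in groups if g.code not in quantities]
    alphas = []
    for g in share_groups:
        members = sum(1 for h in share_groups if h.category == g.category)
        alphas.append(max(shares_by_cat[g.category] / members, 1e-3) * concentration)
    shares = rng.dirichlet(np.asarray(alphas))
    food_energy = max(target_energy_kcal - beverage_energy, 100.0)
    for g, share in zip(share_groups, shares):
        density_per_g = nutrients.per_100g(g.code, "energy_kcal") / 100.0
        if density_per_g <= 1e-9:
            quantities[g.code] = 10.0
        else:
            quantities[g.code] = float(share * food_energy / density_per_g)
    return quantities


def _project_to_polytope(profile: ConsumptionProfile, nutrients: NutrientTable,
                         person: PersonProfile, registry: list[FoodGroup],
                         constraints_cfg: dict, floor: float) -> ConsumptionProfile | None:
    """Project a diet onto the constraint polytope via the auxiliary LP.

    The diet is scaled to the recommended energy, optimised, and mapped
    back to the observed energy level, so re-scaling the result reproduces
    the feasible optimum exactly (TDMI 0 by construction). Returns None if
    the LP is infeasible.
    """
    ce = profile.energy(nutrients)
    scaled = scale_to_energy(profile, nutrients, person)
    codes = [c for c in scaled.codes if scaled.quantities[c] > 0]
    bounds = assemble_constraints(constraints_cfg, person, nutrients, registry, codes)
    sc = np.array([scaled.quantities[c] for c in codes])
    solution = solve(linearize(sc, bounds, floor, codes=codes))
    if not solution.solved:
        return None
    back = ce / person.energy_kcal
    return ConsumptionProfile(
        country=profile.country, gender=person.gender,
        quantities={c: x * back for c, x in solution.quantities.items()},
    )


def _mix_shares(u: float) -> dict[str, float]:
    return {cat: (1 - u) * HEALTHY_ENERGY_SHARES[cat] + u * UNHEALTHY_ENERGY_SHARES[cat]
            for cat in CATEGORIES}


def generate(config: SynthConfig) -> Bundle:
    """Generate a full dataset bundle; the same config yields the same bundle."""
    rng = np.random.default_rng(config.seed)
    registry_config = copy.deepcopy(fio.default_registry_config())
    full_registry = fio.build_group_registry(registry_config)
    groups = _select_groups(full_registry, config.n_groups)
    nutrients = _make_nutrients(rng, groups, config.nutrient_jitter_sd)
    constraints_cfg = config.constraint_config or fio.default_constraint_config()

    countries = [f"C{i + 1:02d}" for i in range(config.n_countries)]
    profiles: list[ConsumptionProfile] = []
    for country in countries:
        for gender in ("man", "woman"):
            person = default_person(gender)
            factor = float(np.exp(rng.normal(np.log(config.energy_factor_mean),
                                             config.energy_factor_sd)))
            ce = person.energy_kcal * factor
            healthy = None
            for attempt in range(config.max_retries):
                raw = _draw_diet(rng, groups, nutrients, _mix_shares(0.0), ce,
                                 config.dirichlet_concentration)
                candidate = ConsumptionProfile(country=country, gender=gender, quantities=raw)
                healthy = _project_to_polytope(candidate, nutrients, person, groups,
                                               constraints_cfg, config.projection_floor)
                if healthy is not None:
                    break
            if healthy is None:
                raise FoodModelError(
                    f"{country}/{gender}: no feasible healthy diet after "
                    f"{config.max_retries} draws; constraint set may be contradictory"
                )
            u = config.unhealthiness
            if u > 0:
                unhealthy = _draw_diet(rng, groups, nutrients, _mix_shares(1.0), ce,
                                       config.dirichlet_concentration)
                quantities = {c: (1 - u) * healthy.quantities[c] + u * unhealthy[c]
                              for c in healthy.quantities}
            else:
                quantities = dict(healthy.quantities)
            if country == config.absent_group_country:
                quantities.pop(config.absent_group_code, None)
            profiles.append(ConsumptionProfile(country=country, gender=gender,
                                               quantities=quantities))

    prices: dict[str, np.ndarray] = {}
    price_medians: dict[str, float] = {}
    for g in groups:
        median = _PRICE_CODE_OVERRIDES.get(g.code, _PRICE_MEDIANS[g.category])
        median *= float(np.exp(rng.normal(0.0, config.price_median_jitter_sd)))
        obs = median * np.exp(rng.normal(0.0, config.price_sigma, size=config.n_price_obs))
        prices[g.code] = obs
        price_medians[g.code] = median

    base_country = countries[0]
    pli: dict[str, dict[str, float]] = {}
    for country in countries:
        if country == config.pli_holdout:
            continue
        level = 1.0 if country == base_country else float(np.exp(rng.normal(0.0, config.pli_spread)))
        by_code = {}
        for g in groups:
            jitter = 1.0 if country == base_country else float(
                np.exp(rng.normal(0.0, config.pli_code_jitter_sd)))
            by_code[g.code] = level * jitter
        pli[country] = by_code

    low, high = config.income_range
    if config.n_countries == 1:
        incomes = {countries[0]: (low + high) / 2.0}
    else:
        grid = np.linspace(low, high, config.n_countries)
        spacing = (high - low) / (config.n_countries - 1)
        jitter = rng.uniform(-0.1, 0.1, size=config.n_countries) * spacing
        jitter[0] = jitter[-1] = 0.0  # keep the configured span exact
        incomes = {c: float(v) for c, v in zip(countries, grid + jitter)}

    return Bundle(
        config=config, registry=groups, registry_config=registry_config,
        nutrients=nutrients, profiles=profiles, prices=prices,
        price_medians=price_medians, pli=pli, incomes=incomes,
        constraints=constraints_cfg, base_country=base_country, countries=countries,
    )


def make_infeasible_case(target_floor: float, seed: int = 0,
                         max_retries: int = 10) -> Bundle:
    """Construct a bundle whose LP first becomes feasible at ``target_floor``.

    Starting from a feasible healthy bundle, a mass cap on the sweets
    groups is placed between ``target_floor`` and the next 1 %-step above
    it, so the relaxation loop fails at every higher floor and succeeds
    exactly at the target. The property is verified per gender by
    independent solves at generation time.
    """
    if not 0.0 <= target_floor <= 0.10:
        raise FoodModelError("target_floor must lie in [0, 0.10]")
    step = 0.01
    for attempt in range(max_retries):
        config = SynthConfig(seed=seed + 1000 * attempt, n_countries=1,
                             unhealthiness=0.0)
        bundle = generate(config)
        if target_floor >= 0.10 - 1e-12:
            return bundle  # boundary: the plain feasible case
        country = bundle.countries[0]
        constraints_cfg = copy.deepcopy(bundle.constraints)
        sweets_codes = tuple(sorted(
            g.code for g in bundle.registry if g.code.startswith(SWEETS_CODES_PREFIX)))
        for gender in ("man", "woman"):
            person = default_person(gender)
            scaled = scale_to_energy(bundle.profile(country, gender),
                                     bundle.nutrients, person)
            total = sum(scaled.quantities[c] for c in sweets_codes)
            cap = (target_floor + step / 2.0) * total
            constraints_cfg["specs"].append(ConstraintSpec(
                id=f"sweets_cap_{gender}", target=sweets_codes, bound="upper",
                value=cap, unit="g/day", applies_to=gender,
                notes="engineered cap forcing floor relaxation",
            ))
        bundle = Bundle(**{**bundle.__dict__, "constraints": constraints_cfg})
        if _verify_infeasible_case(bundle, target_floor, step):
            return bundle
    raise FoodModelError(
        f"could not construct an instance switching feasibility at floor {target_floor} "
        f"after {max_retries} attempts"
    )


def _verify_infeasible_case(bundle: Bundle, target_floor: float, step: float) -> bool:
    """Independent per-floor solves certifying the feasibility switch point."""
    country = bundle.countries[0]
    for gender in ("man", "woman"):
        person = default_person(gender)
        scaled = scale_to_energy(bundle.profile(country, gender), bundle.nutrients, person)
        codes = [c for c in scaled.codes if scaled.quantities[c] > 0]
        bounds = assemble_constraints(bundle.constraints, person, bundle.nutrients,
                                      bundle.registry, codes)
        sc = np.array([scaled.quantities[c] for c in codes])
        floor = 0.10
        while floor > target_floor + 1e-12:
            if solve(linearize(sc, bounds, floor, codes=codes)).solved:
                return False
            floor -= step
        if not solve(linearize(sc, bounds, target_floor, codes=codes)).solved:
            return False
    return True
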