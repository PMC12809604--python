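"""Domain types shared by every stage of the food-reference-budget pipeline.

The pipeline operates on a fixed registry of food groups (ECOICOP 5-digit
leaves), per-group nutrient contents per 100 g, per-country mean consumption
in g/person/day, and reference persons (adult man / woman at PAL 1.4) whose
recommended energy intake anchors the optimisation.

Units are normalised exactly once, at read time: quantities are g/day per
person, nutrient contents are per 100 g in each nutrient's canonical unit
(the ``_g`` / ``_mg`` / ``_ug`` suffix of its key), prices are EUR/kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: 1 kcal = 4.184 kJ; the single conversion constant used everywhere.
KJ_PER_KCAL = 4.184

#: The ten analysis categories used for aggregation and reporting.
CATEGORIES = (
    "carbohydrate_rich",
    "fruits",
    "vegetables",
    "meat",
    "fish",
    "dairy",
    "eggs",
    "oils_fats",
    "sweets_snacks",
    "others",
)

#: Canonical nutrient keys. The suffix declares the per-100 g unit.
MACRO_NUTRIENTS = (
    "energy_kcal",
    "protein_g",
    "fat_g",
    "satfat_g",
    "pufa_g",
    "cholesterol_mg",
    "carb_g",
    "free_sugars_g",
    "fibre_g",
    "water_g",
    "salt_g",
)

#: Metabolisable-energy factors (kJ per g) per EC Directive 90/496/EEC.
ENERGY_FACTORS_KJ_PER_G = {
    "protein": 17.0,
    "carbohydrate": 17.0,
    "fat": 37.0,
    "fibre": 8.0,
    "alcohol": 29.0,
}

#: Which energy factor applies when a %-of-energy recommendation is
#: converted to grams for a given nutrient key.
ENERGY_FACTOR_OF_NUTRIENT = {
    "protein_g": "protein",
    "carb_g": "carbohydrate",
    "free_sugars_g": "carbohydrate",
    "fat_g": "fat",
    "satfat_g": "fat",
    "pufa_g": "fat",
    "fibre_g": "fibre",
}

CONSTRAINT_UNITS = (
    "g/day",
    "mg/day",
    "µg/day",
    "kcal/day",
    "%energy",
    "g/kg-bodyweight",
    "mg/MJ",
    "multiplier-of-lower-bound",
)


class FoodModelError(ValueError):
    """Raised for invalid inputs anywhere in the pipeline."""


@dataclass(frozen=True, order=True)
class FoodGroup:
    """One ECOICOP 5-digit food group with its analysis category."""

    code: str
    name: str = field(compare=False)
    category: str = field(compare=False)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise FoodModelError(
                f"unknown category {self.category!r} for group {self.code}; "
                f"must be one of {CATEGORIES}"
            )


@dataclass(frozen=True)
class PersonProfile:
    """Reference adult (25-49 y) whose recommendations parameterise the model.

    Defaults follow the EFSA reference values used throughout: body weight
    82 kg (man) / 66 kg (woman), PAL 1.4, recommended energy intake 9.4 MJ
    (man) / 7.55 MJ (woman).
    """

    gender: str
    bodyweight_kg: float
    pal: float = 1.4
    energy_mj: float = 0.0

    def __post_init__(self) -> None:
        if self.gender not in ("man", "woman"):
            raise FoodModelError(f"gender must be man|woman, got {self.gender!r}")
        if self.energy_mj <= 0:
            raise FoodModelError("recommended energy intake must be positive")
        if self.bodyweight_kg <= 0:
            raise FoodModelError("body weight must be positive")

    @property
    def energy_kcal(self) -> float:
        """Recommended energy intake in kcal/day (1 kcal = 4.184 kJ)."""
        return self.energy_mj * 1000.0 / KJ_PER_KCAL

    @classmethod
    def man(cls) -> "PersonProfile":
        return cls(gender="man", bodyweight_kg=82.0, pal=1.4, energy_mj=9.4)

    @classmethod
    def woman(cls) -> "PersonProfile":
        return cls(gender="woman", bodyweight_kg=66.0, pal=1.4, energy_mj=7.55)


def default_person(gender: str) -> PersonProfile:
    if gender == "man":
        return PersonProfile.man()
    if gender == "woman":
        return PersonProfile.woman()
    raise FoodModelError(f"gender must be man|woman, got {gender!r}")


class NutrientTable:
    """Per-group nutrient contents per 100 g.

    Thin wrapper over a wide :class:`pandas.DataFrame` (index: group code,
    columns: canonical nutrient keys). Provides per-gram coefficient vectors
    for constraint building and diet-energy evaluation.
    """

    def __init__(self, frame: pd.DataFrame):
        if "energy_kcal" not in frame.columns:
            raise FoodModelError("nutrient table must contain energy_kcal")
        if (frame.to_numpy() < 0).any():
            bad = frame.index[(frame < 0).any(axis=1)].tolist()
            raise FoodModelError(f"negative nutrient contents for groups {bad}")
        self.frame = frame.sort_index()

    @property
    def codes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def nutrients(self) -> list[str]:
        return list(self.frame.columns)

    def __contains__(self, code: str) -> bool:
        return code in self.frame.index

    def per_100g(self, code: str, nutrient: str) -> float:
        try:
            return float(self.frame.at[code, nutrient])
        except KeyError as exc:
            raise FoodModelError(f"no nutrient value for {nutrient!r} in group {code!r}") from exc

    def per_gram_vector(self, nutrient: str, codes: list[str]) -> np.ndarray:
        """Per-gram contents of ``nutrient`` for each code, in table units."""
        if nutrient not in self.frame.columns:
            raise FoodModelError(f"unknown nutrient {nutrient!r}")
        missing = [c for c in codes if c not in self.frame.index]
        if missing:
            raise FoodModelError(f"groups without nutrient data: {missing}")
        return self.frame.loc[codes, nutrient].to_numpy(dtype=float) / 100.0

    def energy_of(self, quantities: dict[str, float]) -> float:
        """Energy (kcal/day) of a diet given as g/day per group code."""
        return float(
            sum(q / 100.0 * self.per_100g(code, "energy_kcal") for code, q in quantities.items())
        )

    def validate(self, energy_rtol: float = 0.25) -> list[str]:
        """Consistency warnings: mass closure and macro-derived energy.

        Water plus macronutrient mass must not exceed 100 g per 100 g;
        declared energy should agree with the energy computed from the
        EC 90/496/EEC factors within ``energy_rtol`` (warning only — real
        composition tables carry alcohol, organic acids and polyols that
        the macro columns do not capture).
        """
        warnings: list[str] = []
        f = self.frame
        mass_cols = [c for c in ("protein_g", "fat_g", "carb_g", "fibre_g", "water_g", "salt_g") if c in f.columns]
        mass = f[mass_cols].sum(axis=1)
        for code in f.index[mass > 100.0 + 1e-6]:
            warnings.append(f"{code}: water + macronutrient mass {mass[code]:.1f} g > 100 g")
        kj = (
            f.get("protein_g", 0.0) * ENERGY_FACTORS_KJ_PER_G["protein"]
            + f.get("carb_g", 0.0) * ENERGY_FACTORS_KJ_PER_G["carbohydrate"]
            + f.get("fat_g", 0.0) * ENERGY_FACTORS_KJ_PER_G["fat"]
            + f.get("fibre_g", 0.0) * ENERGY_FACTORS_KJ_PER_G["fibre"]
        )
        derived_kcal = kj / KJ_PER_KCAL
        for code in f.index:
            declared = f.at[code, "energy_kcal"]
            derived = derived_kcal[code]
            if declared > 5.0 and not math.isclose(declared, derived, rel_tol=energy_rtol):
                warnings.append(
                    f"{code}: declared energy {declared:.0f} kcal/100g vs "
                    f"macro-derived {derived:.0f} kcal/100g"
                )
        return warnings


@dataclass
class ConsumptionProfile:
    """Observed mean at-home diet of one country x gender, g/person/day.

    Groups with no consumption record are *absent* from ``quantities``
    (they drop out of the model dimension); they are never imputed as zero.
    """

    country: str
    gender: str
    quantities: dict[str, float]

    def __post_init__(self) -> None:
        neg = {c: q for c, q in self.quantities.items() if q < 0}
        if neg:
            raise FoodModelError(f"negative consumption quantities: {neg}")

    @property
    def codes(self) -> list[str]:
        return sorted(self.quantities)

    def energy(self, nutrients: NutrientTable) -> float:
        """Observed mean energy intake cE in kcal/day."""
        return nutrients.energy_of(self.quantities)

    def missing_groups(self, registry: list[FoodGroup]) -> list[str]:
        return [g.code for g in registry if g.code not in self.quantities]


@dataclass
class ScaledProfile:
    """Observed diet rescaled so its total energy equals the recommended rE."""

    country: str
    gender: str
    quantities: dict[str, float]
    re_kcal: float
    factor: float

    @property
    def codes(self) -> list[str]:
        return sorted(self.quantities)

    def as_vector(self, codes: list[str] | None = None) -> np.ndarray:
        codes = codes if codes is not None else self.codes
        return np.array([self.quantities[c] for c in codes], dtype=float)


@dataclass
class ConstraintSpec:
    """One recommendation in its native unit, awaiting conversion to g-space.

    ``target`` is either a canonical nutrient key (nutrient rule) or a
    tuple/list of food-group codes (food-based rule on summed mass).
    """

    id: str
    target: str | tuple[str, ...]
    bound: str
    value: float
    unit: str
    applies_to: str = "both"
    notes: str = ""

    def __post_init__(self) -> None:
        if self.bound not in ("lower", "upper"):
            raise FoodModelError(f"{self.id}: bound must be lower|upper")
        if self.value < 0:
            raise FoodModelError(f"{self.id}: value must be >= 0")
        if self.unit not in CONSTRAINT_UNITS:
            raise FoodModelError(f"{self.id}: unknown unit {self.unit!r}; must be one of {CONSTRAINT_UNITS}")
        if self.applies_to not in ("man", "woman", "both"):
            raise FoodModelError(f"{self.id}: applies_to must be man|woman|both")
        if not isinstance(self.target, str):
            self.target = tuple(self.target)

    @property
    def is_food_rule(self) -> bool:
        return not isinstance(self.target, str)

    def applies(self, gender: str) -> bool:
        return self.applies_to in ("both", gender)


@dataclass
class LinearBound:
    """A recommendation realised in g-space: coeffs . X (>=|<=) rhs.

    ``coeffs`` holds the per-gram contribution of each food group, in the
    order of the model's code list; ``rhs`` is in the coefficient's natural
    unit (g, mg, µg or kcal per day).
    """

    id: str
    coeffs: np.ndarray
    direction: str
    rhs: float

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.direction not in (">=", "<="):
            raise FoodModelError(f"{self.id}: direction must be >= or <=")
        if not np.isfinite(self.rhs):
            raise FoodModelError(f"{self.id}: non-finite right-hand side")

    def satisfied_by(self, x: np.ndarray, tol: float = 1e-7) -> bool:
        lhs = float(self.coeffs @ np.asarray(x, dtype=float))
        scale = max(1.0, abs(self.rhs))
        if self.direction == ">=":
            return lhs >= self.rhs - tol * scale
        return lhs <= self.rhs + tol * scale

    def slack(self, x: np.ndarray) -> float:
        lhs = float(self.coeffs @ np.asarray(x, dtype=float))
        return lhs - self.rhs if self.direction == ">=" else self.rhs - lhs


@dataclass
class DietSolution:
    """Optimised diet for one country x gender with solver diagnostics."""

    country: str
    gender: str
    quantities: dict[str, float]
    scaled: dict[str, float]
    tdmi: float
    floor: float
    status: str
    binding: list[str] = field(default_factory=list)
    trace: list[tuple[float, str]] = field(default_factory=list)

    @property
    def solved(self) -> bool:
        return self.status == "optimal"


@dataclass(frozen=True)
class BudgetResult:
    """Cost of one optimised basket at one price percentile, plus income share."""

    country: str
    gender: str
    percentile: float
    cost_eur_day: float
    annual_cost_eur: float
    income_share_pct: float | None
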