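"""Readers and writers for the plain-text interchange formats.

All tabular inputs are delimiter-separated text with a declared header;
configuration (food-group registry, constraint sets) is YAML. Unit
conversions happen here, exactly once: quantities to g/day, prices to
EUR/kg, nutrient contents to per-100 g canonical units.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import (
    ConstraintSpec,
    ConsumptionProfile,
    DietSolution,
    FoodGroup,
    FoodModelError,
    NutrientTable,
)

log = logging.getLogger(__name__)

_DATA_DIR = Path(__file__).parent / "data"


# ---------------------------------------------------------------- registry

def build_group_registry(config: str | Path | dict) -> list[FoodGroup]:
    """Build the ordered food-group registry from a classification config.

    The config lists every 5-digit ECOICOP group with its analysis category
    plus an exclusion list (groups out of scope, e.g. alcoholic beverages
    and baby food). Excluded groups are removed; the registry is ordered
    stably by code.
    """
    cfg = _load_yaml(config)
    try:
        groups = cfg["groups"]
    except (KeyError, TypeError) as exc:
        raise FoodModelError("registry config must contain a 'groups' list") from exc
    exclusions = set(cfg.get("exclusions") or [])
    unknown_excl = exclusions - {g["code"] for g in groups}
    if unknown_excl:
        raise FoodModelError(f"exclusion list names unknown codes: {sorted(unknown_excl)}")
    registry: list[FoodGroup] = []
    seen: set[str] = set()
    for g in groups:
        code = str(g["code"])
        if code in seen:
            raise FoodModelError(f"duplicate group code {code!r}")
        seen.add(code)
        if code in exclusions:
            continue
        if not g.get("category"):
            raise FoodModelError(f"retained group {code!r} has no category")
        registry.append(FoodGroup(code=code, name=str(g.get("name", code)), category=g["category"]))
    return sorted(registry, key=lambda g: g.code)


def default_registry_config() -> dict:
    """The shipped illustrative 62-group ECOICOP registry config."""
    return _load_yaml(_DATA_DIR / "registry_default.yaml")


def default_registry() -> list[FoodGroup]:
    return build_group_registry(default_registry_config())


# ------------------------------------------------------------- consumption

def read_consumption(path: str | Path, registry: list[FoodGroup] | None = None) -> list[ConsumptionProfile]:
    """Read per-country mean consumption (g/person/day) into profiles.

    Expects columns ``country``, ``code``, ``quantity_g_day`` and optionally
    ``gender``. One profile is returned per country x gender. Codes are
    validated against the registry when given; groups missing from a
    country's rows are recorded as absent (not zero) and logged.
    """
    df = pd.read_csv(path, dtype={"code": str}, float_precision="round_trip")
    required = {"country", "code", "quantity_g_day"}
    if not required.issubset(df.columns):
        raise FoodModelError(f"consumption file must have columns {sorted(required)}")
    if "gender" not in df.columns:
        df["gender"] = "both"
    if registry is not None:
        known = {g.code for g in registry}
        offenders = sorted(set(df["code"]) - known)
        if offenders:
            raise FoodModelError(f"unknown food-group codes in consumption file: {offenders}")
    neg = df[df["quantity_g_day"] < 0]
    if not neg.empty:
        rows = [f"row {i}: {r.country}/{r.code} = {r.quantity_g_day}" for i, r in neg.iterrows()]
        raise FoodModelError("negative quantities: " + "; ".join(rows))

    profiles = []
    for (country, gender), sub in df.groupby(["country", "gender"], sort=True):
        dup = sub["code"][sub["code"].duplicated()]
        if not dup.empty:
            raise FoodModelError(f"{country}/{gender}: duplicate codes {sorted(set(dup))}")
        prof = ConsumptionProfile(
            country=str(country),
            gender=str(gender),
            quantities=dict(zip(sub["code"], sub["quantity_g_day"].astype(float))),
        )
        if registry is not None:
            absent = prof.missing_groups(registry)
            if absent:
                log.warning("%s/%s: no consumption record for groups %s (treated as absent)",
                            country, gender, absent)
        profiles.append(prof)
    return profiles


def write_consumption(profiles: list[ConsumptionProfile], path: str | Path) -> None:
    rows = [
        {"country": p.country, "gender": p.gender, "code": c, "quantity_g_day": q}
        for p in profiles
        for c, q in sorted(p.quantities.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------- nutrients

def read_nutrients(path: str | Path) -> NutrientTable:
    """Read the long-format nutrient table (code, nutrient, per100g, unit).

    The optional ``unit`` column is checked against each nutrient key's
    canonical unit suffix (``_g``/``_mg``/``_ug``, kcal for energy).
    """
    df = pd.read_csv(path, dtype={"code": str}, float_precision="round_trip")
    required = {"code", "nutrient", "per100g"}
    if not required.issubset(df.columns):
        raise FoodModelError(f"nutrient file must have columns {sorted(required)}")
    if "unit" in df.columns:
        for _, row in df.iterrows():
            expected = _canonical_unit(row["nutrient"])
            if expected and str(row["unit"]) not in expected:
                raise FoodModelError(
                    f"nutrient {row['nutrient']!r} declared in {row['unit']!r}, "
                    f"expected {expected}"
                )
    wide = df.pivot_table(index="code", columns="nutrient", values="per100g", aggfunc="first")
    if wide.isna().any().any():
        holes = [(c, n) for c in wide.index for n in wide.columns if pd.isna(wide.at[c, n])]
        raise FoodModelError(f"nutrient table has missing cells: {holes[:10]}")
    return NutrientTable(wide)


def write_nutrients(table: NutrientTable, path: str | Path) -> None:
    rows = [
        {"code": code, "nutrient": nut, "per100g": table.frame.at[code, nut],
         "unit": _canonical_unit(nut)[0]}
        for code in table.frame.index
        for nut in table.frame.columns
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _canonical_unit(nutrient: str) -> tuple[str, ...]:
    if nutrient.endswith("_kcal"):
        return ("kcal",)
    if nutrient.endswith("_ug"):
        return ("ug", "µg")
    if nutrient.endswith("_mg"):
        return ("mg",)
    if nutrient.endswith("_g"):
        return ("g",)
    return ()


# ------------------------------------------------------------- constraints

def read_constraints(config: str | Path | dict) -> dict:
    """Read a constraint configuration.

    Returns a dict with keys ``specs`` (list of :class:`ConstraintSpec`),
    ``energy_factors_kj_per_g`` and ``food_rules`` (parameters of the
    fruit/vegetable, water and caffeine rules).
    """
    cfg = _load_yaml(config)
    specs = [
        ConstraintSpec(
            id=str(c["id"]),
            target=c["target"] if isinstance(c["target"], str) else tuple(c["target"]),
            bound=c["bound"],
            value=float(c["value"]),
            unit=str(c["unit"]),
            applies_to=c.get("applies_to", "both"),
            notes=c.get("notes", ""),
        )
        for c in cfg.get("constraints", [])
    ]
    return {
        "specs": specs,
        "energy_factors_kj_per_g": dict(cfg.get("energy_factors_kj_per_g", {})),
        "food_rules": dict(cfg.get("food_rules", {})),
    }


def default_constraint_config() -> dict:
    """The shipped EFSA-2017-style illustrative constraint set."""
    return read_constraints(_DATA_DIR / "constraints_default.yaml")


# ---------------------------------------------------------------- pricing

def read_prices(path: str | Path) -> dict[str, np.ndarray]:
    """Read price observations (code, price_eur_per_kg) into per-group arrays."""
    df = pd.read_csv(path, dtype={"code": str}, float_precision="round_trip")
    if not {"code", "price_eur_per_kg"}.issubset(df.columns):
        raise FoodModelError("price file must have columns code, price_eur_per_kg")
    if (df["price_eur_per_kg"] <= 0).any():
        raise FoodModelError("all price observations must be positive")
    return {
        code: sub["price_eur_per_kg"].to_numpy(dtype=float)
        for code, sub in df.groupby("code", sort=True)
    }


def write_prices(prices: dict[str, np.ndarray], path: str | Path) -> None:
    rows = [{"code": c, "price_eur_per_kg": p} for c, obs in sorted(prices.items()) for p in obs]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_pli(path: str | Path) -> dict[str, dict[str, float]]:
    """Read price level indices (country, code, index) per country per group."""
    df = pd.read_csv(path, dtype={"code": str}, float_precision="round_trip")
    if not {"country", "code", "index"}.issubset(df.columns):
        raise FoodModelError("PLI file must have columns country, code, index")
    if (df["index"] <= 0).any():
        raise FoodModelError("price level indices must be positive")
    return {
        str(country): dict(zip(sub["code"], sub["index"].astype(float)))
        for country, sub in df.groupby("country", sort=True)
    }


def write_pli(pli: dict[str, dict[str, float]], path: str | Path) -> None:
    rows = [
        {"country": country, "code": code, "index": idx}
        for country, by_code in sorted(pli.items())
        for code, idx in sorted(by_code.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_incomes(path: str | Path) -> dict[str, float]:
    """Read median equivalised net incomes (country, income EUR/year)."""
    df = pd.read_csv(path, float_precision="round_trip")
    if not {"country", "median_equiv_net_income_eur_year"}.issubset(df.columns):
        raise FoodModelError("income file must have columns country, median_equiv_net_income_eur_year")
    return dict(zip(df["country"].astype(str), df["median_equiv_net_income_eur_year"].astype(float)))


def write_incomes(incomes: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        [{"country": c, "median_equiv_net_income_eur_year": v} for c, v in sorted(incomes.items())]
    ).to_csv(path, index=False)


# --------------------------------------------------------------- solutions

def write_solution(solution: DietSolution, path: str | Path,
                   registry: list[FoodGroup] | None = None) -> None:
    """Write an optimised diet as CSV with a commented metadata header.

    Rows carry code, name, category, scaled g/day, optimised g/day and the
    percentage change; the header records country, gender, the consumption
    floor actually used, the objective value and the solver status.
    """
    if not solution.solved:
        raise FoodModelError(f"cannot write unsolved solution (status {solution.status!r})")
    if not solution.quantities:
        raise FoodModelError("cannot write a solution with an empty group set")
    names = {g.code: g for g in registry} if registry else {}
    header = (
        f"# country={solution.country} gender={solution.gender} "
        f"floor={solution.floor:.6g} tdmi={solution.tdmi:.12g} status={solution.status}\n"
    )
    rows = []
    for code in sorted(solution.quantities):
        sc, x = solution.scaled[code], solution.quantities[code]
        rows.append({
            "code": code,
            "name": names[code].name if code in names else code,
            "category": names[code].category if code in names else "",
            "scaled_g_day": repr(float(sc)),
            "optimised_g_day": repr(float(x)),
            "change_pct": repr(float((x - sc) / sc * 100.0)) if sc > 0 else "",
        })
    with open(path, "w") as fh:
        fh.write(header)
        pd.DataFrame(rows).to_csv(fh, index=False)


def read_solution(path: str | Path) -> DietSolution:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FoodModelError("solution file lacks the metadata header")
        meta = dict(tok.split("=", 1) for tok in header[1:].split())
        df = pd.read_csv(fh, dtype={"code": str}, float_precision="round_trip")
    return DietSolution(
        country=meta["country"],
        gender=meta["gender"],
        quantities=dict(zip(df["code"], df["optimised_g_day"].astype(float))),
        scaled=dict(zip(df["code"], df["scaled_g_day"].astype(float))),
        tdmi=float(meta["tdmi"]),
        floor=float(meta["floor"]),
        status=meta["status"],
    )


# ------------------------------------------------------------------- misc

def _load_yaml(config: str | Path | dict) -> dict:
    if isinstance(config, dict):
        return config
    with open(config) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise FoodModelError(f"config {config} did not parse to a mapping")
    return loaded
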