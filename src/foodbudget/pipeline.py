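"""End-to-end orchestration: scale, constrain, solve, price, analyse.

The pipeline proper is deterministic: all randomness lives in the
synthetic-data generator. Countries are processed independently and
sequentially; a per-country solver failure is recorded and the run
continues. Every run emits a machine-readable manifest (input checksums,
configuration, floors used) that fully determines the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .analysis import category_change_table, correlation_table
from .constraints import assemble_constraints
from .lp import solve_with_relaxation
from .model import (
    BudgetResult,
    ConsumptionProfile,
    DietSolution,
    FoodGroup,
    FoodModelError,
    NutrientTable,
    default_person,
)
from .pricing import budgets_for_solution
from .scaling import scale_to_energy

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of a full pipeline run."""

    consumption: str
    nutrients: str
    constraints: str
    registry: str
    prices: str | None = None
    pli: str | None = None
    incomes: str | None = None
    base_country: str | None = None
    genders: tuple[str, ...] = ("man", "woman")
    floor: float = 0.10
    step: float = 0.01
    min_floor: float = 0.0
    percentiles: tuple[float, ...] = (20, 30, 40, 50)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        ps = tuple(self.percentiles)
        if any(not 0 < p < 100 for p in ps) or list(ps) != sorted(ps):
            raise FoodModelError("percentiles must lie in (0,100) and be sorted ascending")


@dataclass
class RunResult:
    solutions: list[DietSolution]
    budgets: list[BudgetResult]
    change_table: pd.DataFrame | None
    corr_table: pd.DataFrame | None
    manifest: dict
    failures: list[tuple[str, str, str]] = field(default_factory=list)


def optimise_profile(
    profile: ConsumptionProfile,
    nutrients: NutrientTable,
    constraints_cfg: dict,
    registry: list[FoodGroup],
    gender: str,
    floor: float = 0.10,
    step: float = 0.01,
    min_floor: float = 0.0,
) -> DietSolution:
    """Scale one observed diet and solve its LP with floor relaxation."""
    person = default_person(gender)
    scaled = scale_to_energy(profile, nutrients, person)
    codes = [c for c in scaled.codes if scaled.quantities[c] > 0]
    if not codes:
        raise FoodModelError(f"{profile.country}: empty diet")
    bounds = assemble_constraints(constraints_cfg, person, nutrients, registry, codes)
    sc = np.array([scaled.quantities[c] for c in codes])
    return solve_with_relaxation(
        sc, bounds, start_floor=floor, step=step, min_floor=min_floor,
        codes=codes, country=profile.country, gender=gender,
    )


def run_bundle(
    profiles: list[ConsumptionProfile],
    nutrients: NutrientTable,
    constraints_cfg: dict,
    registry: list[FoodGroup],
    prices: dict[str, np.ndarray] | None = None,
    pli: dict[str, dict[str, float]] | None = None,
    incomes: dict[str, float] | None = None,
    base_country: str | None = None,
    genders: tuple[str, ...] = ("man", "woman"),
    floor: float = 0.10,
    step: float = 0.01,
    min_floor: float = 0.0,
    percentiles: tuple[float, ...] = (20, 30, 40, 50),
    manifest_extra: dict | None = None,
) -> RunResult:
    """Run the full method on in-memory inputs.

    For every country x gender: scale the observed diet to the recommended
    energy, assemble the constraint rows, solve with floor relaxation, then
    (when price data are given) cost the basket at each percentile and
    relate it to income. Analysis tables are built over all solved diets.
    """
    _validate_inputs(profiles, nutrients, registry)
    by_country: dict[str, dict[str, ConsumptionProfile]] = {}
    for p in profiles:
        by_country.setdefault(p.country, {})[p.gender] = p

    solutions: list[DietSolution] = []
    budgets: list[BudgetResult] = []
    failures: list[tuple[str, str, str]] = []
    floors_used: dict[str, float] = {}
    for country in sorted(by_country):
        for gender in genders:
            profile = by_country[country].get(gender) or by_country[country].get("both")
            if profile is None:
                continue
            try:
                solution = optimise_profile(profile, nutrients, constraints_cfg, registry,
                                            gender, floor, step, min_floor)
            except FoodModelError as exc:
                failures.append((country, gender, str(exc)))
                log.error("%s/%s failed: %s", country, gender, exc)
                continue
            if not solution.solved:
                failures.append((country, gender, "infeasible at every floor"))
                continue
            solutions.append(solution)
            floors_used[f"{country}/{gender}"] = solution.floor
            if prices is not None:
                budgets.extend(budgets_for_solution(
                    solution, prices, percentiles=tuple(percentiles), pli=pli,
                    base_country=base_country,
                    income_eur_year=(incomes or {}).get(country),
                ))

    change = category_change_table(solutions, registry) if solutions else None
    corr = None
    if solutions:
        n_countries = len({s.country for s in solutions})
        if n_countries >= 3:
            corr = correlation_table(solutions, registry)
    manifest = {
        "config": {
            "genders": list(genders), "floor": floor, "step": step,
            "min_floor": min_floor, "percentiles": list(percentiles),
            "base_country": base_country,
        },
        "floors_used": floors_used,
        "n_solutions": len(solutions),
        "n_budget_rows": len(budgets),
        "failures": [list(f) for f in failures],
    }
    manifest.update(manifest_extra or {})
    return RunResult(solutions=solutions, budgets=budgets, change_table=change,
                     corr_table=corr, manifest=manifest, failures=failures)


def run_all(config: RunConfig) -> RunResult:
    """File-based entry point: read all inputs, run, optionally write outputs."""
    registry = fio.build_group_registry(config.registry)
    nutrients = fio.read_nutrients(config.nutrients)
    profiles = fio.read_consumption(config.consumption, registry=registry)
    constraints_cfg = fio.read_constraints(config.constraints)
    prices = fio.read_prices(config.prices) if config.prices else None
    pli = fio.read_pli(config.pli) if config.pli else None
    incomes = fio.read_incomes(config.incomes) if config.incomes else None

    checksums = {
        name: _sha256(path)
        for name, path in [
            ("consumption", config.consumption), ("nutrients", config.nutrients),
            ("constraints", config.constraints), ("registry", config.registry),
            ("prices", config.prices), ("pli", config.pli), ("incomes", config.incomes),
        ] if path
    }
    result = run_bundle(
        profiles, nutrients, constraints_cfg, registry,
        prices=prices, pli=pli, incomes=incomes, base_country=config.base_country,
        genders=config.genders, floor=config.floor, step=config.step,
        min_floor=config.min_floor, percentiles=config.percentiles,
        manifest_extra={"input_checksums": checksums},
    )
    if config.out_dir:
        write_outputs(result, config.out_dir, registry)
    return result


def write_outputs(result: RunResult, out_dir: str | Path,
                  registry: list[FoodGroup]) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in result.solutions:
        fio.write_solution(s, out / f"solution_{s.country}_{s.gender}.csv", registry)
    if result.budgets:
        pd.DataFrame([{
            "country": b.country, "gender": b.gender, "percentile": b.percentile,
            "cost_eur_day": round(b.cost_eur_day, 2),
            "annual_cost_eur": round(b.annual_cost_eur, 2),
            "income_share_pct": (round(b.income_share_pct, 2)
                                 if b.income_share_pct is not None else ""),
        } for b in result.budgets]).to_csv(out / "budgets.csv", index=False)
    if result.change_table is not None:
        result.change_table.to_csv(out / "category_changes.csv", index=False)
    if result.corr_table is not None:
        result.corr_table.to_csv(out / "category_correlations.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)


def _validate_inputs(profiles: list[ConsumptionProfile], nutrients: NutrientTable,
                     registry: list[FoodGroup]) -> None:
    """Cross-file consistency, checked before any solve."""
    known = {g.code for g in registry}
    for p in profiles:
        stray = sorted(set(p.quantities) - known)
        if stray:
            raise FoodModelError(f"{p.country}/{p.gender}: codes not in registry: {stray}")
        unnourished = sorted(set(p.quantities) - set(nutrients.codes))
        if unnourished:
            raise FoodModelError(
                f"{p.country}/{p.gender}: no nutrient data for: {unnourished}")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
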