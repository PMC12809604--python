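"""Basket costing at lower price percentiles and affordability measures.

Per-group price observations (EUR/kg, collected in the reference country)
are summarised at lower percentiles (20th-50th) to reflect price-conscious
shopping; prices for other countries are derived by multiplying with the
ratio of their price level indices (PLI) to the reference country's. An
optimised basket is costed in EUR/day, annualised over 365 days, and
expressed as a share of median equivalised net income.
"""

from __future__ import annotations

import logging

import numpy as np

from .model import BudgetResult, DietSolution, FoodModelError

log = logging.getLogger(__name__)

DAYS_PER_YEAR = 365


def percentile_price(observations: np.ndarray, q: float) -> float:
    """Order-statistic percentile of a price observation set (EUR/kg).

    Linear interpolation between closest order statistics (the common
    "type 7" convention, where the 50th percentile is the median).
    """
    obs = np.asarray(observations, dtype=float)
    if obs.size == 0:
        raise FoodModelError("cannot take a percentile of an empty observation set")
    if not 0.0 < q < 100.0:
        raise FoodModelError(f"percentile must lie in (0, 100), got {q}")
    return float(np.quantile(obs, q / 100.0, method="linear"))


def percentile_prices(
    prices: dict[str, np.ndarray], q: float, codes: list[str] | None = None
) -> dict[str, float]:
    """Percentile price per group over the pooled observations of each group."""
    codes = codes if codes is not None else sorted(prices)
    missing = [c for c in codes if c not in prices]
    if missing:
        raise FoodModelError(f"groups without price observations: {missing}")
    return {c: percentile_price(prices[c], q) for c in codes}


def transfer_price(base_price: float, pli_target: float, pli_base: float) -> float:
    """Transfer a price between countries via their price level indices."""
    if pli_target <= 0 or pli_base <= 0:
        raise FoodModelError("price level indices must be positive")
    return base_price * pli_target / pli_base


def cost_of_basket(solution: DietSolution | dict[str, float],
                   prices_eur_per_kg: dict[str, float]) -> float:
    """Cost of a basket in EUR/day: sum_i X_i(g)/1000 x price_i(EUR/kg)."""
    quantities = solution.quantities if isinstance(solution, DietSolution) else solution
    unpriced = sorted(set(quantities) - set(prices_eur_per_kg))
    if unpriced:
        raise FoodModelError(f"groups without a price: {unpriced}")
    return float(sum(q / 1000.0 * prices_eur_per_kg[c] for c, q in quantities.items()))


def income_share(cost_eur_day: float, income_eur_year: float) -> float:
    """Annualised basket cost as a percentage of yearly income."""
    if income_eur_year <= 0:
        raise FoodModelError("income must be positive")
    return cost_eur_day * DAYS_PER_YEAR / income_eur_year * 100.0


def benchmark_against_allowance(costs_by_percentile: dict[float, float],
                                allowance_eur_day: float) -> float | None:
    """Highest percentile whose basket cost fits within a daily allowance.

    E.g. against the German food allowance of 4.75 EUR/day: returns the
    largest percentile with cost <= allowance, or None if even the lowest
    percentile is unaffordable.
    """
    if not costs_by_percentile:
        raise FoodModelError("empty percentile grid")
    if allowance_eur_day <= 0:
        raise FoodModelError("allowance must be positive")
    affordable = [p for p, cost in costs_by_percentile.items() if cost <= allowance_eur_day]
    return max(affordable) if affordable else None


def budgets_for_solution(
    solution: DietSolution,
    price_observations: dict[str, np.ndarray],
    percentiles: tuple[float, ...] = (20, 30, 40, 50),
    pli: dict[str, dict[str, float]] | None = None,
    base_country: str | None = None,
    income_eur_year: float | None = None,
) -> list[BudgetResult]:
    """Cost one optimised basket at each percentile for its country.

    Percentile prices are computed in the reference country and, when the
    solution's country differs, transferred group-by-group via the PLI
    ratio. Countries missing from the PLI table cannot be priced and yield
    an empty list with a logged warning (the Croatia path).
    """
    if not solution.solved:
        raise FoodModelError("cannot price an unsolved diet")
    codes = sorted(solution.quantities)
    needs_transfer = pli is not None and base_country is not None and solution.country != base_country
    if needs_transfer:
        if solution.country not in pli:
            log.warning("%s: no price level indices; basket left unpriced", solution.country)
            return []
        pli_t, pli_b = pli[solution.country], pli[base_country]
        missing = [c for c in codes if c not in pli_t or c not in pli_b]
        if missing:
            raise FoodModelError(f"{solution.country}: PLI missing for groups {missing}")
    results = []
    for q in percentiles:
        base = percentile_prices(price_observations, q, codes)
        if needs_transfer:
            prices = {c: transfer_price(base[c], pli_t[c], pli_b[c]) for c in codes}
        else:
            prices = base
        cost = cost_of_basket(solution, prices)
        share = income_share(cost, income_eur_year) if income_eur_year else None
        results.append(BudgetResult(
            country=solution.country, gender=solution.gender, percentile=q,
            cost_eur_day=cost, annual_cost_eur=cost * DAYS_PER_YEAR,
            income_share_pct=share,
        ))
    return results
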