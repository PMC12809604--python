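"""Descriptive analytics comparing observed and optimised diets.

Covers the reporting the method is judged by: aggregation of group
quantities into the ten analysis categories, observed-vs-optimised
percentage changes (averaged as mean-of-per-country-changes, never the
change of means), cross-country Pearson correlations with 5 %/1 %
significance, and above/below-bisector classification of countries in an
observed-vs-optimised scatter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import CATEGORIES, DietSolution, FoodGroup, FoodModelError


def aggregate_categories(quantities: dict[str, float],
                         registry: list[FoodGroup]) -> dict[str, float]:
    """Sum group quantities (g/day) into the ten analysis categories."""
    category_of = {g.code: g.category for g in registry}
    unmapped = sorted(set(quantities) - set(category_of))
    if unmapped:
        raise FoodModelError(f"groups without a category mapping: {unmapped}")
    totals = dict.fromkeys(CATEGORIES, 0.0)
    for code, q in quantities.items():
        totals[category_of[code]] += q
    return totals


def percent_change(observed: float, optimised: float) -> float | None:
    """(optimised - observed)/observed x 100; None when observed is zero."""
    if observed < 0:
        raise FoodModelError("observed quantity must be nonnegative")
    if observed == 0:
        return None
    return (optimised - observed) / observed * 100.0


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    significant_5pct: bool
    significant_1pct: bool
    n: int
    valid: bool = True


def cross_country_correlation(observed, optimised) -> CorrelationResult:
    """Pearson correlation of per-country observed vs optimised quantities.

    Two-sided significance from the exact t-transform with n-2 degrees of
    freedom. Zero variance in either vector leaves r undefined (flagged).
    """
    obs = np.asarray(observed, dtype=float)
    opt = np.asarray(optimised, dtype=float)
    if obs.shape != opt.shape:
        raise FoodModelError("paired vectors must have equal length")
    n = obs.size
    if n < 3:
        raise FoodModelError("need at least 3 paired observations")
    if np.ptp(obs) == 0 or np.ptp(opt) == 0:
        return CorrelationResult(float("nan"), float("nan"), False, False, n, valid=False)
    r, p = stats.pearsonr(obs, opt)
    return CorrelationResult(float(r), float(p), p < 0.05, p < 0.01, n)


def bisector_classification(observed: float, optimised: float,
                            tol: float = 1e-9) -> str:
    """Position relative to the angle bisector of an observed/optimised plot.

    ``above`` means the optimised quantity exceeds the observed one (the
    country must eat more of this category), ``below`` the reverse, ``on``
    within tolerance.
    """
    diff = optimised - observed
    band = tol * max(1.0, abs(observed), abs(optimised))
    if diff > band:
        return "above"
    if diff < -band:
        return "below"
    return "on"


def category_change_table(solutions: list[DietSolution],
                          registry: list[FoodGroup]) -> pd.DataFrame:
    """Mean percentage change and mean optimised g/day per category.

    Percentage changes are computed per country first and averaged across
    countries afterwards. Genders are never pooled: pass solutions of one
    gender, or get one row block per gender.
    """
    if not solutions:
        raise FoodModelError("no solutions to analyse")
    rows = []
    for gender in sorted({s.gender for s in solutions}):
        subset = [s for s in solutions if s.gender == gender]
        changes: dict[str, list[float]] = {c: [] for c in CATEGORIES}
        optimised: dict[str, list[float]] = {c: [] for c in CATEGORIES}
        for s in subset:
            sc_cat = aggregate_categories(s.scaled, registry)
            x_cat = aggregate_categories(s.quantities, registry)
            for cat in CATEGORIES:
                change = percent_change(sc_cat[cat], x_cat[cat])
                if change is not None:
                    changes[cat].append(change)
                optimised[cat].append(x_cat[cat])
        for cat in CATEGORIES:
            rows.append({
                "category": cat,
                "gender": gender,
                "mean_change_pct": float(np.mean(changes[cat])) if changes[cat] else np.nan,
                "mean_optimised_g_day": float(np.mean(optimised[cat])),
                "n_countries": len(subset),
            })
    return pd.DataFrame(rows)


def correlation_table(solutions: list[DietSolution],
                      registry: list[FoodGroup],
                      pool_genders: bool = False) -> pd.DataFrame:
    """Cross-country correlation of observed vs optimised per category.

    By default computed separately per gender; ``pool_genders`` stacks the
    country x gender pairs into one vector per category instead.
    """
    if not solutions:
        raise FoodModelError("no solutions to analyse")
    genders = ["pooled"] if pool_genders else sorted({s.gender for s in solutions})
    rows = []
    for gender in genders:
        subset = solutions if pool_genders else [s for s in solutions if s.gender == gender]
        for cat in CATEGORIES:
            obs, opt = [], []
            for s in subset:
                obs.append(aggregate_categories(s.scaled, registry)[cat])
                opt.append(aggregate_categories(s.quantities, registry)[cat])
            res = cross_country_correlation(obs, opt)
            rows.append({
                "category": cat,
                "gender": gender,
                "r": res.r,
                "p_value": res.p_value,
                "stars": "**" if res.significant_1pct else ("*" if res.significant_5pct else ""),
                "n": res.n,
                "valid": res.valid,
            })
    return pd.DataFrame(rows)


def plot_category_scatter(solutions: list[DietSolution], registry: list[FoodGroup],
                          category: str, path) -> None:
    """Observed-vs-optimised scatter for one category with the bisector."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    obs = [aggregate_categories(s.scaled, registry)[category] for s in solutions]
    opt = [aggregate_categories(s.quantities, registry)[category] for s in solutions]
    fig, ax = plt.subplots(figsize=(5, 5))
    markers = {"man": "o", "woman": "s"}
    for gender in sorted({s.gender for s in solutions}):
        xs = [o for s, o in zip(solutions, obs) if s.gender == gender]
        ys = [o for s, o in zip(solutions, opt) if s.gender == gender]
        ax.scatter(xs, ys, marker=markers.get(gender, "o"), label=gender, alpha=0.7)
    lim = max(max(obs, default=1.0), max(opt, default=1.0)) * 1.05
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="bisector")
    ax.set_xlabel("observed (scaled) g/day")
    ax.set_ylabel("optimised g/day")
    ax.set_title(category)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
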