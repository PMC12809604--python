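"""The goal-programming diet LP and its floor-relaxation loop.

The objective is the total departure of mean food intake,

    TDMI = sum_i |X_i - sC_i| / sC_i,

the summed relative deviation of the optimised quantities X from the
scaled observed diet sC. The absolute values are linearised with paired
nonnegative deviation variables p_i, q_i via

    X_i = sC_i (1 + p_i - q_i),    minimise sum_i (p_i + q_i),

which equals TDMI at any optimum (p_i and q_i cannot both be positive
there, since both carry cost). Health-related bounds enter as linear rows
over X; consumption floors X_i >= floor x sC_i keep every consumed group
in the basket. When the model is infeasible at the 10 % floor, the floor
is lowered in 1 % steps until a solution exists (the relaxation loop).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import DietSolution, FoodModelError, LinearBound

#: Absolute slack below which a constraint is reported as binding.
BINDING_TOL = 1e-7

#: Agreement required between the LP objective and the recomputed TDMI.
OBJECTIVE_TOL = 1e-6


def tdmi(x: np.ndarray, sc: np.ndarray) -> float:
    """Total departure of mean food intake: sum_i |x_i - sc_i| / sc_i."""
    x = np.asarray(x, dtype=float)
    sc = np.asarray(sc, dtype=float)
    if x.shape != sc.shape:
        raise FoodModelError(f"shape mismatch: {x.shape} vs {sc.shape}")
    if (sc <= 0).any():
        bad = np.nonzero(sc <= 0)[0].tolist()
        raise FoodModelError(
            f"sC must be strictly positive (zero-consumption groups are dropped upstream); "
            f"offending indices {bad}"
        )
    return float(np.sum(np.abs(x - sc) / sc))


@dataclass
class LPModel:
    """Linearised diet problem over 3n variables (X_i, p_i, q_i)."""

    codes: list[str]
    sc: np.ndarray
    constraint_rows: list[LinearBound]
    floor: float
    c: np.ndarray = field(repr=False, default=None)
    A_ub: np.ndarray = field(repr=False, default=None)
    b_ub: np.ndarray = field(repr=False, default=None)
    A_eq: np.ndarray = field(repr=False, default=None)
    b_eq: np.ndarray = field(repr=False, default=None)
    var_bounds: list = field(repr=False, default=None)

    @property
    def n_groups(self) -> int:
        return len(self.codes)

    @property
    def n_variables(self) -> int:
        return 3 * self.n_groups


def linearize(
    sc: np.ndarray,
    bounds: list[LinearBound],
    floor: float,
    codes: list[str] | None = None,
) -> LPModel:
    """Build the linearised LP for a scaled diet and assembled bounds.

    Variables are ordered [X_1..X_n, p_1..p_n, q_1..q_n]; the deviation
    identity X_i - sC_i p_i + sC_i q_i = sC_i ties them together and the
    objective is sum(p + q). Floors become lower variable bounds on X.
    """
    sc = np.asarray(sc, dtype=float)
    n = sc.size
    if n == 0:
        raise FoodModelError("cannot build an LP over an empty group set")
    if (sc <= 0).any():
        raise FoodModelError("all sC_i must be strictly positive")
    if not 0.0 <= floor < 1.0:
        raise FoodModelError(f"floor must be in [0, 1), got {floor}")
    codes = list(codes) if codes is not None else [f"g{i}" for i in range(n)]
    if len(codes) != n:
        raise FoodModelError("codes length must match sC")
    for b in bounds:
        if b.coeffs.size != n:
            raise FoodModelError(f"bound {b.id}: coefficient length {b.coeffs.size} != {n} groups")

    c = np.concatenate([np.zeros(n), np.ones(n), np.ones(n)])
    # X_i - sc_i p_i + sc_i q_i = sc_i
    A_eq = np.hstack([np.eye(n), -np.diag(sc), np.diag(sc)])
    b_eq = sc.copy()
    rows, rhs = [], []
    for b in bounds:
        coeff = np.concatenate([b.coeffs, np.zeros(2 * n)])
        if b.direction == "<=":
            rows.append(coeff)
            rhs.append(b.rhs)
        else:
            rows.append(-coeff)
            rhs.append(-b.rhs)
    A_ub = np.vstack(rows) if rows else np.empty((0, 3 * n))
    b_ub = np.array(rhs)
    var_bounds = [(floor * s, None) for s in sc] + [(0, None)] * (2 * n)
    return LPModel(codes=codes, sc=sc, constraint_rows=list(bounds), floor=floor,
                   c=c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, var_bounds=var_bounds)


def solve(model: LPModel, country: str = "", gender: str = "") -> DietSolution:
    """Solve the linearised LP with HiGHS (deterministic dual simplex).

    Returns an ``optimal`` solution whose objective equals the recomputed
    TDMI within 1e-6, or an ``infeasible`` result; any other solver outcome
    raises with the solver message.
    """
    res = linprog(
        model.c, A_ub=model.A_ub, b_ub=model.b_ub, A_eq=model.A_eq, b_eq=model.b_eq,
        bounds=model.var_bounds, method="highs-ds",
    )
    if res.status == 2:
        return DietSolution(
            country=country, gender=gender, quantities={}, scaled=dict(zip(model.codes, model.sc)),
            tdmi=float("nan"), floor=model.floor, status="infeasible",
        )
    if res.status != 0:
        raise FoodModelError(f"LP solver failure (status {res.status}): {res.message}")
    n = model.n_groups
    x = res.x[:n]
    value = tdmi(x, model.sc)
    if abs(value - res.fun) > OBJECTIVE_TOL * max(1.0, value):
        raise FoodModelError(
            f"objective {res.fun} disagrees with recomputed TDMI {value}; solver output suspect"
        )
    binding = [b.id for b in model.constraint_rows if abs(b.slack(x)) <= BINDING_TOL]
    binding += [
        f"floor:{code}" for code, xi, si in zip(model.codes, x, model.sc)
        if abs(xi - model.floor * si) <= BINDING_TOL
    ]
    return DietSolution(
        country=country, gender=gender,
        quantities={c: float(v) for c, v in zip(model.codes, x)},
        scaled={c: float(v) for c, v in zip(model.codes, model.sc)},
        tdmi=value, floor=model.floor, status="optimal", binding=binding,
    )


def solve_with_relaxation(
    sc: np.ndarray,
    bounds: list[LinearBound],
    start_floor: float = 0.10,
    step: float = 0.01,
    min_floor: float = 0.0,
    codes: list[str] | None = None,
    country: str = "",
    gender: str = "",
) -> DietSolution:
    """Solve with the consumption floor relaxed in steps until feasible.

    Floors start at ``start_floor`` (default 10 % of the scaled diet) and
    are lowered by ``step`` (default 1 percentage point) down to
    ``min_floor``. The first feasible floor wins and is recorded on the
    solution together with the full attempt trace; if every floor fails the
    result is infeasible with the complete trace.
    """
    if step <= 0:
        raise FoodModelError(f"relaxation step must be positive, got {step}")
    trace: list[tuple[float, str]] = []
    floor = start_floor
    while floor >= min_floor - 1e-12:
        model = linearize(sc, bounds, max(floor, 0.0), codes=codes)
        solution = solve(model, country=country, gender=gender)
        trace.append((model.floor, solution.status))
        if solution.solved:
            solution.trace = trace
            return solution
        floor -= step
    last = DietSolution(
        country=country, gender=gender, quantities={},
        scaled=dict(zip(codes or [f"g{i}" for i in range(len(sc))], np.asarray(sc, dtype=float))),
        tdmi=float("nan"), floor=trace[-1][0], status="infeasible", trace=trace,
    )
    return last


def verify_solution(solution: DietSolution, bounds: list[LinearBound],
                    tol: float = 1e-6) -> list[str]:
    """Re-check a solution against bounds and floors by direct arithmetic.

    Independent of the solver path: accumulates each row with a plain loop
    and checks the floor on every group. Returns violation descriptions
    (empty when feasible).
    """
    if not solution.solved:
        raise FoodModelError("cannot verify an unsolved solution")
    codes = sorted(solution.quantities)
    problems = []
    for b in bounds:
        lhs = 0.0
        for j, code in enumerate(codes):
            lhs += float(b.coeffs[j]) * solution.quantities[code]
        scale = max(1.0, abs(b.rhs))
        if b.direction == ">=" and lhs < b.rhs - tol * scale:
            problems.append(f"{b.id}: {lhs} < {b.rhs}")
        elif b.direction == "<=" and lhs > b.rhs + tol * scale:
            problems.append(f"{b.id}: {lhs} > {b.rhs}")
    for code in codes:
        lo = solution.floor * solution.scaled[code]
        if solution.quantities[code] < lo - tol * max(1.0, lo):
            problems.append(f"floor:{code}: {solution.quantities[code]} < {lo}")
    return problems


def dump_lp(model: LPModel, path) -> None:
    """Write the model in CPLEX LP text format (debugging aid)."""
    n = model.n_groups
    names = [f"X_{c.replace('.', '_')}" for c in model.codes] + \
            [f"p_{i}" for i in range(n)] + [f"q_{i}" for i in range(n)]
    lines = ["Minimize", " obj: " + " + ".join(names[n:]), "Subject To"]
    for k, b in enumerate(model.constraint_rows):
        terms = " + ".join(
            f"{b.coeffs[j]:.12g} {names[j]}" for j in range(n) if b.coeffs[j] != 0.0
        )
        op = ">=" if b.direction == ">=" else "<="
        lines.append(f" {b.id or f'r{k}'}: {terms} {op} {b.rhs:.12g}")
    for i in range(n):
        lines.append(
            f" dev{i}: {names[i]} - {model.sc[i]:.12g} {names[n + i]} "
            f"+ {model.sc[i]:.12g} {names[2 * n + i]} = {model.sc[i]:.12g}"
        )
    lines.append("Bounds")
    for i in range(n):
        lines.append(f" {model.floor * model.sc[i]:.12g} <= {names[i]}")
    lines.append("End")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
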