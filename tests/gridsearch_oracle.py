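"""Exhaustive 1 g-grid oracle for small diet LPs.

Enumerates every integer-gram basket inside the instance's box, keeps the
feasible ones, and minimises the total departure of mean food intake
directly — no linear programming involved. Used to certify the linearised
LP on randomly generated 4-6-group instances.
"""

import numpy as np

import foodbudget as fb


def brute_force_tdmi(sc, bounds, floor, box_upper, step=1.0):
    """Minimum TDMI over the feasible integer-gram grid, or None if empty.

    Evaluation is chunked over the first axis to bound memory.
    """
    sc = np.asarray(sc, dtype=float)
    axes = [
        np.arange(np.ceil(floor * s - 1e-9), hi + 1e-9, step)
        for s, hi in zip(sc, box_upper)
    ]
    rest = np.stack(np.meshgrid(*axes[1:], indexing="ij"), axis=-1).reshape(-1, sc.size - 1)
    best = None
    for x0 in axes[0]:
        pts = np.empty((len(rest), sc.size))
        pts[:, 0] = x0
        pts[:, 1:] = rest
        feasible = np.ones(len(pts), dtype=bool)
        for b in bounds:
            lhs = pts @ b.coeffs
            if b.direction == ">=":
                feasible &= lhs >= b.rhs - 1e-9
            else:
                feasible &= lhs <= b.rhs + 1e-9
        if feasible.any():
            value = float(((np.abs(pts[feasible] - sc) / sc).sum(axis=1)).min())
            best = value if best is None else min(best, value)
    return best


def random_instance(rng, n_groups, sc_low=5, sc_high=13, box_factor=2.0):
    """A small LP instance with a known feasible integer point.

    Quantities live in an explicit box [floor x sC, box_upper] (the box is
    part of the instance, expressed as bounds, so the LP and the grid
    search the same region). 1-3 random constraint rows are anchored on a
    feasible integer point Z with a +/-5 % band, so the grid always
    contains feasible points.
    """
    floor = 0.10
    sc = rng.integers(sc_low, sc_high, size=n_groups).astype(float)
    box_upper = np.ceil(box_factor * sc)
    z = rng.integers(np.ceil(floor * sc), box_upper + 1).astype(float)
    bounds = []
    for k in range(int(rng.integers(1, 4))):
        coeffs = rng.uniform(0.1, 2.0, size=n_groups)
        anchor = float(coeffs @ z)
        if rng.random() < 0.5:
            bounds.append(fb.LinearBound(id=f"lo{k}", coeffs=coeffs, direction=">=",
                                         rhs=0.95 * anchor))
        else:
            bounds.append(fb.LinearBound(id=f"up{k}", coeffs=coeffs, direction="<=",
                                         rhs=1.05 * anchor))
    for i in range(n_groups):
        e = np.zeros(n_groups)
        e[i] = 1.0
        bounds.append(fb.LinearBound(id=f"box{i}", coeffs=e, direction="<=",
                                     rhs=float(box_upper[i])))
    return sc, bounds, floor, box_upper


#: The instance mix used to certify the LP: 50+ instances across 4-6 groups,
#: sized so the full grid stays enumerable.
ORACLE_INSTANCE_MIX = (
    (4, dict(sc_low=5, sc_high=13, box_factor=2.0), 32),
    (5, dict(sc_low=4, sc_high=10, box_factor=1.8), 14),
    (6, dict(sc_low=4, sc_high=8, box_factor=1.6), 6),
)
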