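import numpy as np
import pytest

import foodbudget as fb
from foodbudget.model import FoodModelError
from gridsearch_oracle import brute_force_tdmi, random_instance


class TestTdmi:
    def test_zero_departure(self):
        sc = np.array([100.0, 200.0])
        assert fb.tdmi(sc, sc) == 0.0

    def test_hand_sum(self):
        assert fb.tdmi(np.array([150.0, 100.0]), np.array([100.0, 200.0])) == pytest.approx(1.0)

    def test_scale_invariance(self):
        x, sc = np.array([150.0, 100.0]), np.array([100.0, 200.0])
        for k in (0.5, 3.0, 100.0):
            assert fb.tdmi(k * x, k * sc) == pytest.approx(fb.tdmi(x, sc))

    def test_zero_reference_rejected(self):
        with pytest.raises(FoodModelError, match="positive"):
            fb.tdmi(np.array([1.0]), np.array([0.0]))


class TestLinearize:
    def test_three_variables_per_group(self):
        sc = np.array([10.0, 20.0, 30.0, 40.0])
        model = fb.linearize(sc, [], 0.1)
        assert model.n_variables == 3 * 4
        assert model.A_eq.shape == (4, 12)

    def test_floor_at_least_one_rejected(self):
        with pytest.raises(FoodModelError, match="floor"):
            fb.linearize(np.array([1.0]), [], 1.0)

    def test_empty_group_set_rejected(self):
        with pytest.raises(FoodModelError, match="empty"):
            fb.linearize(np.array([]), [], 0.1)


class TestSolve:
    def test_feasible_start_returns_identity(self):
        """Bounds already satisfied by sC: optimum is sC itself, TDMI 0."""
        sc = np.array([100.0, 50.0, 200.0])
        bounds = [
            fb.LinearBound(id="lo", coeffs=np.array([1.0, 1.0, 1.0]), direction=">=", rhs=300.0),
            fb.LinearBound(id="up", coeffs=np.array([1.0, 0.0, 0.0]), direction="<=", rhs=150.0),
        ]
        sol = fb.solve(fb.linearize(sc, bounds, 0.1))
        assert sol.solved
        assert sol.tdmi == 0.0
        assert list(sol.quantities.values()) == pytest.approx(list(sc))

    def test_contradictory_bounds_certified_infeasible(self):
        sc = np.array([100.0])
        bounds = [
            fb.LinearBound(id="lo", coeffs=np.array([1.0]), direction=">=", rhs=500.0),
            fb.LinearBound(id="up", coeffs=np.array([1.0]), direction="<=", rhs=400.0),
        ]
        sol = fb.solve(fb.linearize(sc, bounds, 0.1))
        assert sol.status == "infeasible"
        assert sol.quantities == {}

    def test_bitwise_determinism(self):
        rng = np.random.default_rng(11)
        sc, bounds, floor, _ = random_instance(rng, 5)
        a = fb.solve(fb.linearize(sc, bounds, floor))
        b = fb.solve(fb.linearize(sc, bounds, floor))
        assert a.quantities == b.quantities
        assert a.tdmi == b.tdmi

    def test_small_instance_matches_grid_oracle(self):
        """3-group toy with a violated upper bound: LP matches brute force."""
        sc = np.array([10.0, 8.0, 6.0])
        coeffs = np.array([1.0, 1.0, 1.0])
        bounds = [
            fb.LinearBound(id="cap", coeffs=coeffs, direction="<=", rhs=15.0),
            fb.LinearBound(id="b0", coeffs=np.eye(3)[0], direction="<=", rhs=20.0),
            fb.LinearBound(id="b1", coeffs=np.eye(3)[1], direction="<=", rhs=16.0),
            fb.LinearBound(id="b2", coeffs=np.eye(3)[2], direction="<=", rhs=12.0),
        ]
        sol = fb.solve(fb.linearize(sc, bounds, 0.1))
        grid = brute_force_tdmi(sc, bounds, 0.1, [20, 16, 12])
        assert sol.solved and grid is not None
        resolution = sum(1.0 / s for s in sc)
        assert sol.tdmi <= grid + 1e-9
        assert grid - sol.tdmi <= resolution

    def test_binding_constraints_reported(self):
        sc = np.array([100.0, 50.0])
        cap = fb.LinearBound(id="cap", coeffs=np.array([1.0, 0.0]), direction="<=", rhs=80.0)
        sol = fb.solve(fb.linearize(sc, [cap], 0.1))
        assert "cap" in sol.binding

    def test_solution_feasible_by_independent_checker(self):
        rng = np.random.default_rng(23)
        for n in (4, 5, 6):
            sc, bounds, floor, _ = random_instance(rng, n)
            sol = fb.solve(fb.linearize(sc, bounds, floor))
            if sol.solved:
                assert fb.verify_solution(sol, bounds) == []


class TestMonotonicity:
    def test_tightening_never_decreases_tdmi(self):
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 10:
            sc, bounds, floor, _ = random_instance(rng, 4)
            base = fb.solve(fb.linearize(sc, bounds, floor))
            if not base.solved:
                continue
            tightened = []
            for b in bounds:
                factor = 1.02 if b.direction == ">=" else 0.98
                tightened.append(fb.LinearBound(id=b.id, coeffs=b.coeffs.copy(),
                                                direction=b.direction, rhs=b.rhs * factor))
            tight = fb.solve(fb.linearize(sc, tightened, floor))
            if tight.solved:
                assert tight.tdmi >= base.tdmi - 1e-9
            checked += 1

    def test_tdmi_non_increasing_as_floor_drops(self):
        rng = np.random.default_rng(6)
        sc, bounds, _, _ = random_instance(rng, 5)
        values = []
        for floor in (0.10, 0.05, 0.0):
            sol = fb.solve(fb.linearize(sc, bounds, floor))
            assert sol.solved
            values.append(sol.tdmi)
        assert values == sorted(values, reverse=True) or np.allclose(values, values[0])


class TestRelaxation:
    def test_feasible_at_start_floor_single_attempt(self):
        sc = np.array([100.0, 100.0])
        sol = fb.solve_with_relaxation(sc, [], start_floor=0.10)
        assert sol.floor == pytest.approx(0.10)
        assert sol.trace == [(0.10, "optimal")]

    def test_one_percent_steps_down_to_eight(self):
        """Cap between 8 % and 9 % of total: three attempts, solved at 8 %."""
        sc = np.array([100.0, 100.0])
        cap = fb.LinearBound(id="cap", coeffs=np.array([1.0, 1.0]), direction="<=",
                             rhs=0.085 * 200.0)
        sol = fb.solve_with_relaxation(sc, [cap])
        assert sol.solved
        assert sol.floor == pytest.approx(0.08)
        assert [status for _, status in sol.trace] == ["infeasible", "infeasible", "optimal"]
        # oracle: per-floor feasibility by independent solves
        for floor, status in sol.trace:
            independent = fb.solve(fb.linearize(sc, [cap], floor))
            assert independent.status == ("optimal" if status == "optimal" else "infeasible")

    def test_exhaustion_returns_full_trace(self):
        sc = np.array([100.0])
        impossible = fb.LinearBound(id="neg", coeffs=np.array([1.0]), direction="<=", rhs=-1.0)
        sol = fb.solve_with_relaxation(sc, [impossible])
        assert sol.status == "infeasible"
        assert len(sol.trace) == 11  # floors 10 %, 9 %, ..., 0 %

    def test_nonpositive_step_rejected(self):
        with pytest.raises(FoodModelError, match="step"):
            fb.solve_with_relaxation(np.array([1.0]), [], step=0.0)


def test_parameter_recovery_single_seed():
    """A perturbed healthy diet is optimised back inside the polytope,
    never ending farther from the perturbed start than the healthy diet."""
    rng = np.random.default_rng(42)
    person = fb.PersonProfile.man()
    healthy_bundle = fb.generate(fb.SynthConfig(seed=9, n_countries=1, unhealthiness=0.0))
    profile = healthy_bundle.profile(healthy_bundle.countries[0], "man")
    scaled_h = fb.scale_to_energy(profile, healthy_bundle.nutrients, person)
    codes = [c for c in scaled_h.codes if scaled_h.quantities[c] > 0]
    h = np.array([scaled_h.quantities[c] for c in codes])

    noisy = {c: q * float(rng.lognormal(0.0, 0.25)) for c, q in profile.quantities.items()}
    noisy_profile = fb.ConsumptionProfile(profile.country, "man", noisy)
    scaled_n = fb.scale_to_energy(noisy_profile, healthy_bundle.nutrients, person)
    sc = np.array([scaled_n.quantities[c] for c in codes])

    bounds = fb.assemble_constraints(healthy_bundle.constraints, person,
                                     healthy_bundle.nutrients, healthy_bundle.registry, codes)
    sol = fb.solve(fb.linearize(sc, bounds, 0.10, codes=codes))
    assert sol.solved
    assert fb.verify_solution(sol, bounds) == []
    x = np.array([sol.quantities[c] for c in codes])
    assert fb.tdmi(x, sc) <= fb.tdmi(h, sc) + 1e-9
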