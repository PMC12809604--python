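import numpy as np
import pytest

import foodbudget as fb
from foodbudget.model import CATEGORIES, FoodModelError


class TestDeterminism:
    def test_same_seed_identical_bundles(self):
        cfg = fb.SynthConfig(seed=17, n_countries=2)
        a, b = fb.generate(cfg), fb.generate(cfg)
        assert a.nutrients.frame.equals(b.nutrients.frame)
        for pa, pb in zip(a.profiles, b.profiles):
            assert pa.quantities == pb.quantities
        for code in a.prices:
            np.testing.assert_array_equal(a.prices[code], b.prices[code])
        assert a.pli == b.pli
        assert a.incomes == b.incomes

    def test_different_seeds_differ(self):
        a = fb.generate(fb.SynthConfig(seed=1, n_countries=1))
        b = fb.generate(fb.SynthConfig(seed=2, n_countries=1))
        assert a.profiles[0].quantities != b.profiles[0].quantities


class TestStructure:
    def test_default_bundle_shape(self, bundle):
        assert len(bundle.registry) == 60
        assert len(bundle.profiles) == 3 * 2
        assert all(len(obs) >= 30 for obs in bundle.prices.values())
        assert set(bundle.incomes) == set(bundle.countries)

    def test_quantities_strictly_positive(self, bundle):
        for p in bundle.profiles:
            assert all(q > 0 for q in p.quantities.values())

    def test_nutrient_mass_closure(self, bundle):
        f = bundle.nutrients.frame
        mass = f[["protein_g", "fat_g", "carb_g", "fibre_g", "water_g", "salt_g"]].sum(axis=1)
        assert (mass <= 100.0 + 1e-9).all()
        assert bundle.nutrients.validate() == []

    def test_every_constrained_nutrient_covered(self, bundle):
        targets = {s.target for s in bundle.constraints["specs"] if isinstance(s.target, str)}
        assert targets <= set(bundle.nutrients.nutrients)

    def test_income_span_matches_configured_range(self, bundle):
        values = sorted(bundle.incomes.values())
        low, high = bundle.config.income_range
        assert values[0] == pytest.approx(low)
        assert values[-1] == pytest.approx(high)
        assert (low, high) == (3284.0, 34472.0)

    def test_too_few_groups_rejected(self):
        with pytest.raises(FoodModelError, match="categories"):
            fb.SynthConfig(seed=0, n_groups=5)

    def test_subset_keeps_every_category(self):
        small = fb.generate(fb.SynthConfig(seed=0, n_countries=1, n_groups=20))
        assert {g.category for g in small.registry} == set(CATEGORIES)
        assert len(small.registry) == 20

    def test_pli_holdout_country_missing(self):
        b = fb.generate(fb.SynthConfig(seed=4, n_countries=3, pli_holdout="C03"))
        assert "C03" not in b.pli
        assert set(b.pli) == {"C01", "C02"}

    def test_absent_group_country(self):
        b = fb.generate(fb.SynthConfig(seed=4, n_countries=2,
                                       absent_group_country="C02"))
        assert "01.1.7.9" in b.profile("C01", "man").quantities
        assert "01.1.7.9" not in b.profile("C02", "man").quantities
        assert len(b.profile("C02", "man").quantities) == 59


class TestStatisticalShape:
    def test_price_observations_right_skewed_with_configured_median(self):
        """Across many seeds the sample median tracks the generator median."""
        ratios, skews = [], []
        for seed in range(8):
            b = fb.generate(fb.SynthConfig(seed=seed, n_countries=1, n_price_obs=200))
            for code, obs in b.prices.items():
                ratios.append(np.median(obs) / b.price_medians[code])
                skews.append(np.mean(obs) > np.median(obs))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.02)
        assert np.mean(skews) > 0.9  # log-normal: mean above median

    def test_unhealthiness_zero_is_feasible_with_zero_departure(self):
        b = fb.generate(fb.SynthConfig(seed=11, n_countries=2, unhealthiness=0.0))
        result = fb.run_bundle(b.profiles, b.nutrients, b.constraints, b.registry)
        assert len(result.solutions) == 4
        for s in result.solutions:
            assert s.floor == pytest.approx(0.10)
            assert s.tdmi == pytest.approx(0.0, abs=1e-7)

    def test_unhealthier_diets_depart_more(self):
        """Mean optimal TDMI increases with the unhealthiness dial."""
        means = []
        for u in (0.2, 0.5, 0.8):
            values = []
            for seed in range(4):
                b = fb.generate(fb.SynthConfig(seed=seed, n_countries=1, unhealthiness=u))
                r = fb.run_bundle(b.profiles, b.nutrients, b.constraints, b.registry)
                values += [s.tdmi for s in r.solutions]
            means.append(np.mean(values))
        assert means[0] < means[1] < means[2]


class TestInfeasibleCase:
    def test_relaxation_stops_exactly_at_target(self):
        b = fb.make_infeasible_case(0.08, seed=2)
        result = fb.run_bundle(b.profiles, b.nutrients, b.constraints, b.registry)
        assert len(result.solutions) == 2
        for s in result.solutions:
            assert s.floor == pytest.approx(0.08)
            assert [st for _, st in s.trace] == ["infeasible", "infeasible", "optimal"]

    def test_certificate_reverified_by_independent_solves(self):
        """Feasibility at 10/9/8 % floors re-checked outside the loop."""
        b = fb.make_infeasible_case(0.08, seed=2)
        person = fb.PersonProfile.man()
        scaled = fb.scale_to_energy(b.profile(b.countries[0], "man"), b.nutrients, person)
        codes = sorted(scaled.quantities)
        bounds = fb.assemble_constraints(b.constraints, person, b.nutrients,
                                         b.registry, codes)
        sc = np.array([scaled.quantities[c] for c in codes])
        outcomes = {f: fb.solve(fb.linearize(sc, bounds, f, codes=codes)).status
                    for f in (0.10, 0.09, 0.08)}
        assert outcomes == {0.10: "infeasible", 0.09: "infeasible", 0.08: "optimal"}

    def test_target_at_boundary_is_plain_feasible_case(self):
        b = fb.make_infeasible_case(0.10, seed=1)
        result = fb.run_bundle(b.profiles, b.nutrients, b.constraints, b.registry)
        for s in result.solutions:
            assert s.floor == pytest.approx(0.10)
            assert s.trace == [(0.10, "optimal")]
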