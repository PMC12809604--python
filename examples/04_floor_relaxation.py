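"""The consumption-floor relaxation loop.

Every consumed food group must keep at least 10 % of its scaled observed
quantity, so the optimised basket stays socially recognisable. When that
makes the LP infeasible, the floor is lowered in 1 %-steps until a
solution exists. This example constructs such a case (feasible only from
8 % downward) and shows the attempt trace.
"""

import foodbudget as fb

bundle = fb.make_infeasible_case(target_floor=0.08, seed=2)
result = fb.run_bundle(bundle.profiles, bundle.nutrients, bundle.constraints,
                       bundle.registry)

for sol in result.solutions:
    print(f"{sol.country}/{sol.gender}: solved at floor {sol.floor:.0%}, "
          f"TDMI = {sol.tdmi:.2f}")
    for floor, status in sol.trace:
        print(f"   floor {floor:.0%}: {status}")
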