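"""Price an optimised basket at lower price percentiles.

Costs the healthy basket of a synthetic country at the 20th-50th price
percentiles, relates the daily cost to median income, and checks which
percentile a fixed daily food allowance of 4.75 EUR could afford.
"""

import foodbudget as fb

bundle = fb.generate(fb.SynthConfig(seed=7, n_countries=2, unhealthiness=0.5))
result = fb.run_bundle(
    bundle.profiles, bundle.nutrients, bundle.constraints, bundle.registry,
    prices=bundle.prices, pli=bundle.pli, incomes=bundle.incomes,
    base_country=bundle.base_country,
)

print("cost of the healthy basket (EUR/day) and income share:")
for b in result.budgets:
    print(f"  {b.country} {b.gender:6s} p{b.percentile:.0f}: "
          f"{b.cost_eur_day:5.2f} EUR/day = {b.income_share_pct:5.2f} % of income")

costs = {b.percentile: b.cost_eur_day
         for b in result.budgets
         if (b.country, b.gender) == (bundle.base_country, "man")}
best = fb.benchmark_against_allowance(costs, 4.75)
print(f"\nwith a 4.75 EUR/day food allowance the reference man in "
      f"{bundle.base_country} can shop at the "
      f"{'no' if best is None else f'{best:.0f}th'} price percentile")
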