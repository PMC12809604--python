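# foodbudget

Food Reference Budgets by linear programming: how much money does a healthy
diet cost, and can people afford it?

A Food Reference Budget is the minimum amount needed to buy a food basket
that is both *healthy* (meets nutrient and food-based recommendations) and
*socially acceptable* (stays close to what the population actually eats).
`foodbudget` implements the survey-led route to such budgets: start from a
country's observed mean diet, transform it into the closest diet that
satisfies the recommendations, price the optimised basket at lower price
percentiles, and express the cost as a share of median income. It is aimed
at researchers in public-health economics and computational nutrition.

## The model

For food groups *i = 1…n* with observed mean consumption *C&#7522;* (g/person/day),
the diet is first anchored to the reference person's recommended energy
intake *rE* (9.4 MJ/day for the adult man, 7.55 MJ/day for the woman, PAL 1.4):

```
sC_i = C_i · rE / cE
```

where *cE* is the observed energy of the diet — a single factor that
preserves the percentage energy structure between groups. The optimised
quantities *X&#7522;* minimise the **total departure of mean food intake**

```
TDMI = Σ_i |X_i − sC_i| / sC_i
```

subject to linear recommendation rows over the *X&#7522;* (nutrient reference
values, a 7–14 %-of-energy fruit/vegetable band, total water with a +30 %
cap, a caffeine-motivated mass cap on coffee and tea) and consumption
floors *X&#7522; ≥ 0.10 · sC&#7522;* that keep every consumed group in the basket.
The absolute values are linearised with paired deviation variables
*X&#7522; = sC&#7522;(1 + p&#7522; − q&#7522;)*, *p&#7522;, q&#7522; ≥ 0*, giving an ordinary LP (goal
programming). If the model is infeasible at the 10 % floor, the floor is
lowered in 1 %-steps until it solves.

The optimised basket is then costed, Σ&#7522; X&#7522;/1000 · price&#7522;, at the 20th–50th
percentiles of per-group price observations; prices for countries without
their own observations are derived via price-level-index ratios, and the
annualised cost is divided by median equivalised net income.

The licensed survey, food-composition and consumer-price inputs cannot be
redistributed, so the package ships a seeded synthetic generator
(`foodbudget.synth`) producing complete, internally consistent stand-in
datasets with the same structure: ~60 ECOICOP food groups, per-group
nutrient vectors, right-skewed price observation sets, price level
indices and incomes.

## Worked example

```python
import foodbudget as fb

bundle = fb.generate(fb.SynthConfig(seed=42, n_countries=1, unhealthiness=0.6))
solution = fb.optimise_profile(bundle.profile("C01", "man"), bundle.nutrients,
                               bundle.constraints, bundle.registry, gender="man")
print(solution.floor, round(solution.tdmi, 2))
```

prints `0.1 11.58`: the LP solved at the 10 % floor and the healthy basket
departs from the observed diet by a summed relative deviation of 11.58.
The category table for the same run
(`fb.category_change_table([solution], bundle.registry)`) shows what has
to change — e.g. fruits `+111.6 %`, vegetables `+134.1 %`, oils and fats
`−49.3 %` — and the binding constraints name the recommendations driving
it (saturated fat, salt, folate, calcium, the energy anchor and the
fruit/vegetable band).

The relaxation loop in action (`examples/04_floor_relaxation.py`):

```
C01/man: solved at floor 8%, TDMI = 4.78
   floor 10%: infeasible
   floor 9%: infeasible
   floor 8%: optimal
```

The other `examples/` scripts price baskets and compare affordability
across countries and run the full cross-country analysis (percentage
changes, observed-vs-optimised correlations).

A thin CLI mirrors the library: `foodbudget synth --seed 1 --out data/`
writes a full dataset bundle, `foodbudget run-all ...` optimises, prices
and analyses it, writing CSV tables and a JSON run manifest.

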