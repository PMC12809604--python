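# Methods

This note documents the model implemented by `foodbudget`, the defaults it
ships, the numerical choices made, what the synthetic data generator does
and does not emulate, and the design decisions taken where the design was
genuinely open.

## Model and assumptions

The pipeline treats a national diet as a vector of mean at-home
consumption quantities over ~60 commodity-based food groups (ECOICOP
5-digit leaves), one vector per country. Recommendations are evaluated for
a single reference adult per gender; household structure, age bands other
than 25–49, and out-of-home consumption are outside the model.

**Energy scaling.** Observed energy intake cE generally deviates from the
recommended intake rE, so every quantity is multiplied by the single
factor rE/cE before optimisation. This preserves the percentage energy
structure between groups — the model's operationalisation of "current
eating habits" — and makes the energy anchor feasible by construction.
Zero-energy groups (e.g. mineral water) are scaled with the same factor:
the proportional rule is applied literally to the whole diet.

**Objective.** The total departure of mean food intake,
TDMI = Σ_i |X_i − sC_i| / sC_i, standardises deviations by group size so
that a 10 g change in a 20 g/day group counts as much as a 150 g change in
a 300 g/day group. The linearisation uses paired nonnegative deviation
variables, X_i = sC_i(1 + p_i − q_i) with objective Σ(p_i + q_i); at any
optimum p_i·q_i = 0 because both directions carry positive cost, so the
objective equals TDMI exactly. Model dimension is 3n variables for n
groups. No deviation caps are imposed.

**Groups with zero or absent consumption.** A group with no consumption
record is *absent* (dropped from the model dimension), never imputed as
zero: TDMI divides by sC_i, and a group the population does not buy cannot
carry a consumption floor. The same applies to recorded zeros.

**Consumption floors and relaxation.** Floors X_i ≥ floor·sC_i (default
10 %) keep every consumed group in the basket. Floors apply to the
*scaled* diet sC, the model's reference vector, not the raw C (the two
differ only by the common factor, so the set of retained groups is
identical; the bound level follows the optimisation's reference). When a
model is infeasible at 10 %, the floor is lowered in 1 %-steps (default
down to 0 %) and the first feasible floor is recorded along with the full
attempt trace. No uniform per-group upper limits are imposed; the water
cap and the coffee/tea cap act as de-facto upper bounds on beverages.

## Constraint conversions

All recommendations are realised as linear rows over grams with per-gram
nutrient coefficients (per-100 g contents / 100). Native units convert as:

| unit | conversion |
|---|---|
| g/day, mg/day, µg/day | rescaled to the nutrient's canonical table unit |
| % of energy | (value/100 × rE in kJ) / energy factor (kJ/g) |
| g/kg body weight | value × body weight (82 kg man / 66 kg woman) |
| mg/MJ | value × rE in MJ |
| kcal/day | direct (energy rows only) |

Energy factors are the EC Directive 90/496/EEC values (kJ/g): protein 17,
carbohydrate 17, fat 37, fibre 8, alcohol 29; %-energy rules for free
sugars use the carbohydrate factor. 1 kcal = 4.184 kJ throughout, applied
exactly once.

Food-based rules:

* **Energy anchor.** Total energy is constrained to rE (band fraction 0 by
  default, i.e. an equality expressed as a ≥/≤ pair). The `kcal/day` unit
  exists so users can express energy rows directly in a constraint file.
* **Fruit + vegetables.** The 7–14 %-of-energy band is converted to grams
  with a portion-weighted mean caloric density: 2 fruit portions at
  50 kcal/100 g and 3 vegetable portions at 20 kcal/100 g give
  32 kcal/100 g, hence for the man a lower bound of
  0.07 × 2246.7 kcal / 0.32 kcal·g⁻¹ ≈ 491 g/day and an upper bound of
  exactly twice that. Both rows sum mass over all fruit and vegetable
  groups.
* **Water.** Coefficients are per-gram water contents of *all* groups
  (water from beverages and from food); lower bound at the recommended
  amount (defaults 2500 g man / 2000 g woman), upper bound at 1.3× so
  beverages are not over-represented.
* **Caffeine.** No caffeine column exists in composition tables at this
  aggregation, so the 400 mg/day safety limit is modelled as a mass cap on
  coffee + tea: at just under 100 mg per 200-ml cup, 4 cups = 800 g/day
  for the reference man. The woman's cap is scaled by the body-weight
  ratio 66/82 ≈ 643.9 g/day (caffeine guidance is weight-based; the exact
  scaling rule is an open choice and the mass-ratio is flagged here as the
  implemented one).
* **Vitamin D.** Because of endogenous synthesis, a 5 µg/day floor is used
  instead of the full dietary reference value.
* **Cholesterol.** Ships as a 300 mg/day upper bound, overridable.

The shipped default constraint file is **EFSA-2017-style illustrative**:
representative adult (25–49 y) reference values for the macronutrient
bands and nine micronutrients. A faithful national application must
replace it (and the illustrative 62-group registry) with the authoritative
values; both are ordinary YAML files.

## Numerical choices

* Solver: `scipy.optimize.linprog` with HiGHS dual simplex
  (`highs-ds`), single-threaded — repeated solves are bitwise identical;
  LP degeneracy is resolved by the solver's deterministic pivoting.
* The LP objective must agree with the recomputed TDMI within 1e-6
  relative; a discrepancy raises rather than returning a suspect solution.
* Binding constraints are reported at 1e-7 absolute slack.
* Solutions are independently re-verified by a plain accumulation loop
  (`verify_solution` / `check_diet`), separate from the matrix path.
* Percentiles: linear interpolation between closest order statistics
  ("type 7", the numpy default), so the 50th percentile is the median.
  The estimator is configurable in principle; percentiles are computed on
  the pooled observations per group.
* Price transfer happens on percentile prices, not raw observations
  (per-country observation sets do not exist in this design); countries
  without price level indices are skipped with a warning, not imputed.
* Annualisation uses 365 days. Costs are reported to 2 decimals in output
  files; internal precision is full, and file round-trips use
  `repr`-precision floats with round-trip parsing.
* Pearson significance uses the exact t-transform with n−2 degrees of
  freedom, two-sided, at the 5 % and 1 % levels. Gender-specific analyses
  are never pooled unless explicitly requested.

## The synthetic data generator

`foodbudget.synth` emulates the statistical structure of the licensed
inputs so every stage runs without a download:

* **Nutrients:** per-group vectors from ten category templates with
  log-normal jitter; energy is derived from the macronutrients via the
  EC factors (so declared and derived energy agree), mass closure
  (water + macros ≤ 100 g/100 g) is enforced, and the micronutrient
  geography is deliberately sharp — vitamin C concentrated in fruit,
  folate in vegetables, calcium in dairy, B12 in animal groups — because
  that sharpness is what couples specific food categories to specific
  recommendations, as in real composition data.
* **Diets:** category energy shares follow a Dirichlet draw around target
  shares; grams follow from group energy densities. Water, coffee and tea
  get grams directly (energy-share allocation is ill-posed at ~0 kcal).
  The `unhealthiness` dial u ∈ [0,1] interpolates between a healthy
  profile *projected onto the constraint polytope* by an auxiliary LP
  (guaranteeing that u = 0 scales to a feasible diet with TDMI 0) and an
  over-sweet, over-fat, fruit/veg/fish-deficient profile. Mean optimal
  TDMI increases with u. Per-country energy intake is drawn around rE
  (mean factor 1.05, log-sd 0.08).
* **Prices:** log-normal observations per group (right-skewed, as retail
  prices are), ≥ 30 per group, around category-level medians; beverages
  are priced per kg of beverage-equivalent mass, matching the consumption
  unit.
* **PLIs and incomes:** country-level PLI factors with per-group jitter
  (base country exactly 1), an optional hold-out country without PLIs to
  exercise the skip path, and incomes spanning 3 284–34 472 EUR/year with
  exact endpoints.
* `make_infeasible_case(target_floor)` engineers a feasibility switch
  point by capping sweets mass between the target floor and the next
  1 %-step, then *verifies the certificate at generation time* by
  independent solves at every floor, retrying with fresh seeds on failure.

What it does **not** emulate: household-level microdata, survey weighting,
the equivalence-scale computation (data are generated per-capita), any
specific country's actual consumption pattern, seasonal or outlet price
structure, and cross-group price correlation. Passing tests therefore
demonstrate the *method's* correctness and its structural properties —
not the numerical values a licensed national dataset would produce.

## Problem sizes

The test suite certifies the LP against an exhaustive 1 g-grid search on
52 random instances of 4–6 groups (the grid is the package's independent
oracle; boxes are sized so the full grid stays enumerable), runs the
healthy-diet recovery property over 20 seeds, and exercises the full
pipeline on 2–3-country worlds of 60 groups. The acceptance script runs a
six-country world. These sizes were chosen so the whole suite completes in
seconds while every property is exercised at full model dimension (60
groups, 3n = 180 LP variables).

## Known limitations

* The shipped registry and constraint set are illustrative stand-ins, not
  the authoritative national lists.
* Commodity-level groups cannot distinguish wholegrain from refined
  products; nutrient vectors are category means.
* The LP may have alternative optima; determinism is guaranteed per
  solver configuration, not across solver versions.
* Only the L1 (TDMI) objective is implemented; L2 or max-deviation norms
  and integer constraints are out of scope.
* Affordability uses median equivalised income and a fixed 365-day year;
  no inflation adjustment across years.
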