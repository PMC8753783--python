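# Methods

## The diet linear program

For each country × demographic group × scenario cell we solve

min Σᵢ pᵢ·qᵢ subject to Σᵢ aᵢₑ·qᵢ = EER, Σᵢ aᵢₙ·qᵢ ≥ LBₙ, Σᵢ aᵢₙ·qᵢ ≤ UBₙ, qᵢ ≥ 0.

Energy is an *equality*, not a range: the model prices exact energy balance,
which is what makes the energy dual interpretable (it can be negative when
cheap dense calories relax the nutrient constraints). Decision variables are
internally in units of 100 g edible portion — the native unit of food
composition tables — and reported in grams/day. The two unit conventions of
the inputs (composition per 100 g edible, prices per kg as purchased) meet
only in the cost coefficient, `price / (10 × edible_fraction)`.

The constraint system for the default nutrient registry has 37 rows: the
energy equality; 19 lower bounds (carbohydrate, protein, fat via AMDR and/or
gram requirements, plus 16 micronutrients); and 17 upper bounds (3 AMDR,
13 ULs, sodium CDRR). Sodium has no lower bound; vitamin B12, riboflavin and
thiamine have no upper bound; vitamin A's lower-bound row reads the RAE
composition column while its upper-bound row reads preformed retinol only.

### Requirement-construction rules

* Scenario `EAR` uses estimated average requirements; `RDA` the recommended
  dietary allowances. RDA ≥ EAR row-wise, so RDA-scenario costs dominate
  EAR-scenario costs (a tested invariant).
* Iron and zinc use `max(HAR, scenario value)`. The harmonised average
  requirement encodes low bioavailability from plant-dominated diets;
  keeping the max under the RDA scenario preserves that adjustment when the
  generic bound is tightened. (The alternative — letting RDA replace HAR —
  could *loosen* an iron bound while every other bound tightens.)
* Macronutrient AMDR fractions convert to grams/day at 4 kcal/g
  (carbohydrate, protein) and 9 kcal/g (fat). Where a gram-denominated
  requirement also exists (carbohydrate, protein) the lower bound is the max
  of the two — imposing both constraints is equivalent to imposing the max.
* Bounds are validated LB ≤ UB at construction; a violation is an input
  error, reported with the offending group and nutrient, not an infeasible
  LP.

### Solver and numerics

scipy's HiGHS **dual simplex** (`method="highs-ds"`) solves every LP. A
simplex method is a requirement, not a preference: downstream analysis needs
(a) exact dual values for shadow prices and (b) vertex (basic) optima so
that the "foods selected = binding constraints" identity holds at
non-degenerate optima. Feasibility tolerances are set to 1e-9; a constraint
is classified binding when `|achieved − bound| ≤ 1e-6 · max(1, |bound|)`
(equality rows always). Duals are re-oriented so every shadow price is
d(cost)/d(bound) in the bound's natural direction: lower-bound duals ≥ 0,
upper-bound duals ≤ 0, energy free-signed. Ties among alternate optima are
solver-dependent; tests assert objective values and feasibility, never the
specific food mix, except on fixtures with provably unique optima.

An independent **vertex-enumeration oracle** (`lp_core.brute_force_solve`)
solves small instances by enumerating all basic solutions. It verifies the
production solver on randomized instances (≤ 4 foods) and computes the
stored optimum of the 4-food analytic fixture at build time. It is
exponential and never used in the pipeline.

### Sensitivity

Headline elasticities are dual-based: e = sp·bound/CoNA, exact and local.
A literal re-solve at bound×(1±δ) (central difference, δ = 0.01 by default,
matching the "1% change" definition) serves as a verification oracle; the
two agree to solver precision whenever no basis change occurs inside the
interval, because the LP value is piecewise linear in any single bound. At
degenerate optima duals are non-unique; we report the solver's dual and the
finite-difference oracle exposes any disagreement beyond tolerance rather
than silently averaging. Upper-bound elasticities are negative (relaxing a
cap lowers cost); reporting uses their magnitude with the signed value
retained. An elasticity at a zero bound is undefined and returned as NaN.

## Statistics

Box-plot summaries report median, quartiles (linear-interpolation quantile
convention — the common default; stated because several conventions exist)
and the notch half-width 1.58·IQR/√N. Group comparisons regress the outcome
on one indicator per demographic group plus one indicator per country
(the saturated group parameterization spans the same space as sex × age
interactions); adjusted means are predictions at the grand mean of the
country effects, with classical homoskedastic 95% CIs. Country fixed
effects absorb all cross-country level differences — including artifacts
like short price lists inflating costs — so the group contrasts isolate
requirement differences. The income-class contrast uses the same design
with income-class indicators and demographic-group fixed effects. No
multiple-testing correction is applied; estimates are reported as plain
95% CIs.

## Synthetic worlds

`generate_world` emulates the structure of an international retail price
collection without copying any real database:

* a master list of `n_master_items` (default 200) foods across six
  categories, with fixed category shares;
* per-country availability drawn around `availability_prob` (default 0.625,
  giving a mean of ~125 priced items per country, with cross-country spread
  from a Beta distribution); every country is guaranteed ≥ 1 item per
  category (resampled with a bounded retry otherwise);
* nutrient densities per item drawn log-normally around category means that
  encode the economics of the problem: cheap calories in starchy staples,
  calcium and B12 concentrated in (dairy-like) animal-source foods, iron
  and folate in pulses, vitamins C and A (as carotenoids) in fruits and
  vegetables, vitamin E in oils. Preformed retinol is capped at total RAE;
* log-normal prices combining a category median (in international $/kg,
  calibrated so least-cost adequate diets land in a realistic $1.5–3/day
  range), an item factor, a country price level, a currency scale (the PPP
  factor is their product, so converted costs are comparable), idiosyncratic
  noise, and an income-class multiplier making animal-source foods
  relatively cheap in high-income countries — which reproduces, by
  construction of prices rather than of diets, the substitution toward
  pulses and produce in low-income settings;
* a deterministic synthetic DRI table covering all 20 groups: adult
  anchors scaled by age/sex/reproductive-status multipliers, EAR ≤ RDA ≤ UL
  everywhere, HAR for iron and zinc only, CDRR of 1500/1800/2300 mg sodium
  by age. The magnesium, niacin and folate upper levels are deliberately
  set above their published supplemental-form counterparts, which apply to
  supplements/fortificants and would render ordinary food-based diets
  infeasible if imposed on total intake. All values are *synthetic*:
  plausible in range, reproducing no published table.

Everything is a pure function of the spec's seed; CSV output is
byte-identical across runs.

What the generator does **not** emulate: real price levels per country,
item-level identity with any real food list, within-country or seasonal
price variation, correlated nutrient profiles beyond the category
structure, and measurement error in composition. Passing tests on synthetic
worlds therefore demonstrate the correctness and invariances of the
*method* (optimality, duality, monotonicity, statistical recovery), not any
empirical claim about real diet costs.

## Problem sizes and defaults

The default `WorldSpec` mirrors the structure of the real collection
(172 countries × 200 master items). Tests and the acceptance script run
the full pipeline on 3–20-country worlds — 120–800 LPs per scenario —
which exercises every code path while keeping the suite fast; a
20-country × 20-group × 2-scenario run solves 800 LPs in a few seconds on
one core. Analytic fixtures: `fixtureA` (2 foods, energy + one nutrient
bound) has the closed-form optimum 7/6 LCU/day with duals 1/6000 (energy)
and 1/120 (nutrient) and elasticities 2/7 and 5/7; `fixtureB` (4 foods,
two lower bounds + a binding sodium cap) stores its enumeration-computed
optimum alongside the data.

## Known limitations

* The LP prices nutrients only: no palatability, cultural acceptability,
  meal structure or preparation-cost constraints, so CoNA is a lower bound
  on the cost of any realistic adequate diet.
* Per-cell infeasibility (possible with short food lists or tight sodium
  caps) is recorded and carried through summaries, not dropped.
* Duals at degenerate vertices depend on the solver's basis choice.
* The fixed-effects CIs assume homoskedastic errors; clustering by country
  is not applied (point estimates would be unchanged).
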