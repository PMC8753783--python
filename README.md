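# cona — least-cost nutrient-adequate diets

`cona` computes the **Cost of Nutrient Adequacy (CoNA)**: the cheapest daily
diet that can be assembled from the foods priced in a country's markets while
meeting the full set of essential-nutrient requirements for a given person.
It is aimed at food-policy and nutrition researchers who want to measure how
affordable nutrient adequacy is — and for whom it is hardest to afford —
across countries and across demographic groups (age, sex, pregnancy,
lactation), when nationally representative food price collections are
available.

## The model

For country *c* and demographic group *g*, CoNA is the optimum of a linear
program over non-negative food quantities *q*<sub>icg</sub>:

```
min   Σ_i p_ic · q_icg                       (diet cost, LCU/day)
s.t.  Σ_i a_ie · q_icg  =  EER_g             (energy balance, equality)
      Σ_i a_in · q_icg  ≥  LB_ng             (19 nutrient lower bounds)
      Σ_i a_in · q_icg  ≤  UB_ng             (17 nutrient upper bounds)
      q_icg ≥ 0
```

where *p*<sub>ic</sub> is the local price, *a*<sub>ie</sub> and
*a*<sub>in</sub> are energy and nutrient densities per 100 g edible portion,
and the bounds come from dietary reference intakes: EAR (or RDA in a
restrictive scenario) lower bounds for 16 micronutrients, harmonised average
requirements (HAR) for iron and zinc, AMDR ranges for the three
macronutrients, tolerable upper levels (UL) for 13 micronutrients, a CDRR
cap for sodium, and a split treatment of vitamin A (adequacy in RAE, the
upper bound in preformed retinol). Energy and 20 nutrients give 37
constraint rows; 20 demographic groups × the country list gives one LP per
cell (3,440 per scenario at 172 countries).

Each constraint's dual value is its **shadow price** (marginal cost of the
requirement), reported as the dimensionless **shadow-price elasticity**
e<sub>sp</sub> = sp·bound/CoNA — the % change in diet cost per 1% change in
the requirement. Costs are normalized to international dollars by PPP
factors, per 1000 kcal, and against observed food spending; diets are
summarized over six food categories; and differences across groups are
estimated by regressions with country fixed effects.

Because the underlying international price collections are
access-restricted, the package ships a synthetic world generator
(`cona.generate_world`) that reproduces their *structure* — item
availability per country, log-normal price dispersion, category-structured
nutrient densities — plus exact analytic fixtures with closed-form optima,
so the whole pipeline is testable offline.

## Worked example

```python
import cona
from cona.requirements import build_requirement_set

world = cona.generate_world(cona.WorldSpec(seed=7, n_countries=10))
group = cona.enumerate_groups()[2]          # male, 14-18 y
reqs = build_requirement_set(group, world.dri, scenario="EAR")
problem = cona.assemble_lp(world.prices_for("c003"), world.foods, reqs,
                           country_id="c003")
diet = cona.solve_cona(problem)

country = world.countries["c003"]
usd = cona.to_usd_ppp(diet.cona_lcu, country.ppp_factor)
print(f"CoNA: {diet.cona_lcu:.2f} LCU/day = ${usd:.2f}/day "
      f"= ${cona.cost_per_1000kcal(usd, reqs.eer):.2f} per 1000 kcal")
```

prints (with the shadow prices, elasticities and composition shown by the
longer version of this script):

```
group: male_14-18 (EER 3152 kcal/day)
status: optimal, foods selected: 7, binding constraints: 7
CoNA: 1.57 LCU/day = $3.11/day = $0.99 per 1000 kcal
affordability ratio: 1.04
        calcium:lb: shadow price    0.0011, elasticity +0.781
   carbohydrate:lb: shadow price    0.0005, elasticity +0.118
      vitamin_a:lb: shadow price    0.0002, elasticity +0.089
  starchy staples               113 g/day  (13% of energy)
  pulses, nuts, and seeds       577 g/day  (76% of energy)
  animal-source foods           118 g/day  (6% of energy)
  fruits and vegetables         276 g/day  (5% of energy)
  oils and fats                   1 g/day  (0% of energy)
```

Read: for an adolescent boy in this synthetic country, the cheapest
nutrient-adequate diet costs $3.11/day — 1.04× what the average person
there actually spends on food — it is pulse-heavy, and its cost is most
sensitive to the calcium requirement (a 1% higher calcium bound raises the
cost by 0.78%). The number of foods selected equals the number of binding
constraints, as expected at a non-degenerate LP vertex.

The same analysis end-to-end from the shell:

```bash
cona synth --seed 7 --countries 10 --out world/
cona run --foods world/foods.csv --prices world/prices.csv \
         --countries world/countries.csv --dri world/dri.csv \
         --scenario both --out results/
```

which writes `cona_results.csv` (one row per country × group × scenario),
`sensitivity.csv` (shadow prices and elasticities per constraint),
`composition.csv` (grams/kcal per food category), `group_effects.csv`
(country-fixed-effects adjusted group means with 95% CIs) and `run_log.txt`.

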