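"""Cost normalizations, affordability benchmarks, and diet composition.

Costs are solved in local currency units per day, converted to 2017
international dollars with purchasing-power-parity (PPP) factors, and
normalized per 1000 kcal so diets for groups with very different energy
needs can be compared on composition. Affordability is the ratio of the
least-cost diet to observed national food expenditure per capita per day;
a ratio above 1 means nutrient adequacy costs more than what the average
person actually spends on food.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .data_model import Country, FoodItem
from .errors import SolverStateError, ValidationError
from .lp_core import DietSolution
from .nutrients import FOOD_CATEGORIES
from .requirements import RequirementSet

#: Default external benchmarks: $2.10/day poverty line, of which 63%
#: can credibly be reserved for food.
DEFAULT_POVERTY_LINE_USD = 2.10
DEFAULT_FOOD_SHARE = 0.63


def to_usd_ppp(cona_lcu: float, ppp_factor: float) -> float:
    """LCU/day -> international $/day via the PPP conversion factor."""
    if ppp_factor <= 0:
        raise ValueError("ppp_factor must be > 0")
    return cona_lcu / ppp_factor


def cost_per_1000kcal(cona_usd_day: float, eer: float) -> float:
    """$/day -> $/1000 kcal at the group's energy requirement."""
    if eer <= 0:
        raise ValueError("eer must be > 0")
    return cona_usd_day / (eer / 1000.0)


def affordability_ratio(cona_usd_day: float,
                        food_expenditure_per_capita_day: float) -> float:
    """Diet cost over observed food spending; > 1 means unaffordable."""
    if food_expenditure_per_capita_day <= 0:
        raise ValueError("food expenditure must be > 0")
    return cona_usd_day / food_expenditure_per_capita_day


def poverty_food_budget(poverty_line_usd_day: float = DEFAULT_POVERTY_LINE_USD,
                        food_share: float = DEFAULT_FOOD_SHARE) -> float:
    """Food budget at the poverty line, rounded to cents for reporting."""
    if poverty_line_usd_day <= 0 or food_share <= 0:
        raise ValueError("arguments must be positive")
    if food_share > 1:
        raise ValueError("food_share must be <= 1")
    return round(poverty_line_usd_day * food_share, 2)


def scenario_percent_change(median_base: float, median_alt: float) -> float:
    """Percent change between two scenario medians, to 1 decimal."""
    if median_base <= 0:
        raise ValueError("median_base must be > 0")
    return round(100.0 * (median_alt - median_base) / median_base, 1)


@dataclass(frozen=True)
class CostRecord:
    """Normalized costs for one solved (country, group, scenario) cell."""

    country_id: str
    group_id: str
    scenario: str
    cona_lcu_day: float
    cona_usd_day: float
    cona_usd_per_1000kcal: float
    affordability_ratio: float


def cost_record(solution: DietSolution, country: Country,
                reqs: RequirementSet) -> CostRecord:
    if not solution.is_optimal:
        raise SolverStateError("cost_record requires an optimal solution")
    usd = to_usd_ppp(solution.cona_lcu, country.ppp_factor)
    return CostRecord(
        country_id=country.country_id,
        group_id=solution.group_id,
        scenario=reqs.scenario,
        cona_lcu_day=solution.cona_lcu,
        cona_usd_day=usd,
        cona_usd_per_1000kcal=cost_per_1000kcal(usd, reqs.eer),
        affordability_ratio=affordability_ratio(
            usd, country.food_expenditure_per_capita_day
        ),
    )


@dataclass(frozen=True)
class CompositionSummary:
    """Diet weight and energy aggregated over the six food categories."""

    grams_day: Mapping[str, float]
    kcal_day: Mapping[str, float]
    weight_share: Mapping[str, float]
    energy_share: Mapping[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "category": list(FOOD_CATEGORIES),
            "grams_day": [self.grams_day[c] for c in FOOD_CATEGORIES],
            "kcal_day": [self.kcal_day[c] for c in FOOD_CATEGORIES],
            "weight_share": [self.weight_share[c] for c in FOOD_CATEGORIES],
            "energy_share": [self.energy_share[c] for c in FOOD_CATEGORIES],
        })


def summarize_composition(solution: DietSolution,
                          foods: Mapping[str, FoodItem]) -> CompositionSummary:
    """Aggregate an optimal diet into the six reporting categories.

    Shares are normalized by total diet weight and total dietary energy
    and each sum to 1 over the categories.
    """
    if not solution.is_optimal:
        raise SolverStateError(
            "composition requires an optimal solution, got "
            f"{solution.status!r}"
        )
    grams = {c: 0.0 for c in FOOD_CATEGORIES}
    kcal = {c: 0.0 for c in FOOD_CATEGORIES}
    for item_id, g in solution.quantities.items():
        food = foods.get(item_id)
        if food is None or food.category not in grams:
            raise ValidationError(
                f"item {item_id!r} has no known food category"
            )
        grams[food.category] += g
        kcal[food.category] += (g / 100.0) * food.energy_per_100g
    tot_g = sum(grams.values())
    tot_k = sum(kcal.values())
    if tot_g <= 0 or tot_k <= 0:
        raise ValidationError("optimal diet has zero weight or energy")
    return CompositionSummary(
        grams_day=grams,
        kcal_day=kcal,
        weight_share={c: grams[c] / tot_g for c in grams},
        energy_share={c: kcal[c] / tot_k for c in kcal},
    )
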