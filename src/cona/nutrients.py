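"""Registry of the nutrients constrained in the least-cost diet model.

The diet problem constrains dietary energy (as an equality) plus 20
nutrients: the three macronutrients (carbohydrate, protein, fat) bounded on
both sides by the acceptable macronutrient distribution range (AMDR), and 17
micronutrients. Micronutrient lower bounds are average requirements (EAR, or
the harmonised average requirement HAR for iron and zinc, reflecting low
bioavailability from plant-dominated diets); upper bounds are tolerable
upper intake levels (UL) for 13 of them, plus the chronic disease risk
reduction (CDRR) cap for sodium. Vitamin B12, riboflavin and thiamine carry
no upper bound. Sodium carries no lower bound.

Vitamin A is a single nutrient concept with two composition columns: the
adequacy (lower-bound) row is accounted in retinol activity equivalents
(RAE), while the toxicity upper bound applies to preformed retinol only, so
its LP rows read different columns of the food table.
"""

from __future__ import annotations

from dataclasses import dataclass


#: The six reporting food categories.
FOOD_CATEGORIES: tuple[str, ...] = (
    "starchy staples",
    "pulses, nuts, and seeds",
    "animal-source foods",
    "fruits and vegetables",
    "oils and fats",
    "sweets and beverages",
)

#: kcal supplied per gram of each macronutrient (Atwater factors).
KCAL_PER_GRAM = {"carbohydrate": 4.0, "protein": 4.0, "fat": 9.0}


@dataclass(frozen=True)
class NutrientDefinition:
    """How one nutrient enters the constraint system.

    ``lower_key``/``upper_key`` name the food-composition columns feeding
    the lower- and upper-bound rows; they default to ``nutrient_id`` and
    differ only for vitamin A (RAE vs preformed retinol).
    """

    nutrient_id: str
    name: str
    unit: str
    has_lower_bound: bool
    has_upper_bound: bool
    lower_bound_kind: str = "none"  # EAR | HAR | AMDR | none
    upper_bound_kind: str = "none"  # UL | CDRR | AMDR | none
    kcal_per_gram: float | None = None
    lower_key: str = ""
    upper_key: str = ""

    def __post_init__(self) -> None:
        if not self.lower_key:
            object.__setattr__(self, "lower_key", self.nutrient_id)
        if not self.upper_key:
            object.__setattr__(self, "upper_key", self.nutrient_id)

    @property
    def composition_keys(self) -> tuple[str, ...]:
        keys = []
        if self.has_lower_bound:
            keys.append(self.lower_key)
        if self.has_upper_bound and self.upper_key not in keys:
            keys.append(self.upper_key)
        if not keys:
            keys.append(self.nutrient_id)
        return tuple(dict.fromkeys(keys))


def _macro(nid: str, name: str) -> NutrientDefinition:
    return NutrientDefinition(
        nid, name, "g",
        has_lower_bound=True, has_upper_bound=True,
        lower_bound_kind="AMDR", upper_bound_kind="AMDR",
        kcal_per_gram=KCAL_PER_GRAM[nid],
    )


def _micro(nid: str, name: str, unit: str, *, ul: bool = True,
           har: bool = False) -> NutrientDefinition:
    return NutrientDefinition(
        nid, name, unit,
        has_lower_bound=True, has_upper_bound=ul,
        lower_bound_kind="HAR" if har else "EAR",
        upper_bound_kind="UL" if ul else "none",
    )


def default_registry() -> dict[str, NutrientDefinition]:
    """The 20-nutrient registry: 19 lower-bound rows and 17 upper-bound rows.

    Ordered; iteration order fixes the LP row order.
    """
    defs = [
        _macro("carbohydrate", "Total carbohydrate"),
        _macro("protein", "Protein"),
        _macro("fat", "Total fat"),
        _micro("calcium", "Calcium", "mg"),
        _micro("iron", "Iron", "mg", har=True),
        _micro("zinc", "Zinc", "mg", har=True),
        _micro("magnesium", "Magnesium", "mg"),
        _micro("phosphorus", "Phosphorus", "mg"),
        _micro("copper", "Copper", "mg"),
        _micro("selenium", "Selenium", "ug"),
        NutrientDefinition(
            "sodium", "Sodium", "mg",
            has_lower_bound=False, has_upper_bound=True,
            upper_bound_kind="CDRR",
        ),
        _micro("vitamin_c", "Vitamin C", "mg"),
        _micro("thiamine", "Thiamine", "mg", ul=False),
        _micro("riboflavin", "Riboflavin", "mg", ul=False),
        _micro("niacin", "Niacin", "mg"),
        _micro("vitamin_b6", "Vitamin B6", "mg"),
        _micro("folate", "Folate", "ug"),
        _micro("vitamin_b12", "Vitamin B12", "ug", ul=False),
        NutrientDefinition(
            "vitamin_a", "Vitamin A", "ug",
            has_lower_bound=True, has_upper_bound=True,
            lower_bound_kind="EAR", upper_bound_kind="UL",
            lower_key="vitamin_a_rae", upper_key="vitamin_a_retinol",
        ),
        _micro("vitamin_e", "Vitamin E", "mg"),
    ]
    return {d.nutrient_id: d for d in defs}


def composition_columns(registry: dict[str, NutrientDefinition]) -> list[str]:
    """All food-composition column names implied by a registry (no energy)."""
    cols: dict[str, None] = {}
    for d in registry.values():
        for k in d.composition_keys:
            cols[k] = None
    return list(cols)
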