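"""Synthetic food-price worlds and exact analytic fixtures.

Real internationally standardized price collections are access-restricted,
so this module generates worlds with the same *structure*: a master list of
food items in six categories, each country pricing a random subset
(defaults: 200 master items, availability 0.625 per country, matching a
mean of ~125 priced items per country), log-normal price dispersion with
country-level price and currency heterogeneity, and category-structured
nutrient densities (cheap calories in starchy staples, calcium concentrated
in dairy-like animal-source foods, vitamin B12 only in animal-source foods,
provitamin A in fruits and vegetables, and so on).

The dietary-reference tables produced here are **synthetic**: values are in
plausible reference-intake ranges and obey EAR <= RDA <= UL, but they are
generated from compact scaling rules and make no claim of reproducing any
published requirement table.

Everything is deterministic given the spec's seed; there is no hidden
global random state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    AGE_BANDS,
    Country,
    Dataset,
    DemographicGroup,
    DriTable,
    FoodItem,
)
from .errors import ValidationError
from .lp_core import assemble_lp, brute_force_solve
from .nutrients import (
    FOOD_CATEGORIES,
    NutrientDefinition,
    composition_columns,
    default_registry,
)
from .requirements import RequirementSet, enumerate_groups

STAPLES, PULSES, ANIMAL, FRUITVEG, OILS, SWEETS = FOOD_CATEGORIES

#: Share of the master item list per category (roughly mirroring a global
#: retail food list: many animal-source and fruit/vegetable items, few oils).
CATEGORY_WEIGHTS = {
    STAPLES: 0.16, PULSES: 0.13, ANIMAL: 0.28,
    FRUITVEG: 0.26, OILS: 0.07, SWEETS: 0.10,
}

#: Median price in international $ per kg as purchased, by category.
CATEGORY_PRICE_MEDIAN = {
    STAPLES: 2.7, PULSES: 4.8, ANIMAL: 7.5,
    FRUITVEG: 3.6, OILS: 5.4, SWEETS: 4.5,
}

#: Relative price of animal-source foods by national income class (dairy
#: and eggs are comparatively cheap where cold chains and feed are cheap).
ANIMAL_PRICE_BY_INCOME = {
    "high": 0.70, "upper-middle": 0.85, "lower-middle": 1.05, "low": 1.35,
}

INCOME_CLASS_PROBS = {
    "high": 0.26, "upper-middle": 0.28, "lower-middle": 0.28, "low": 0.18,
}

FOOD_EXPENDITURE_BY_INCOME = {  # USD per capita per day, class median
    "high": 6.5, "upper-middle": 4.0, "lower-middle": 2.5, "low": 1.6,
}

#: Mean nutrient density per 100 g edible portion, by category. Keys are
#: composition columns of the default registry plus energy.
CATEGORY_DENSITY: dict[str, dict[str, float]] = {
    STAPLES: dict(
        energy=350, carbohydrate=74, protein=9, fat=1.5, calcium=25,
        iron=3.5, zinc=1.6, magnesium=85, phosphorus=210, copper=0.25,
        selenium=16, sodium=6, vitamin_c=0.5, thiamine=0.32,
        riboflavin=0.12, niacin=4.0, vitamin_b6=0.22, folate=45,
        vitamin_b12=0.0, vitamin_a_rae=1, vitamin_a_retinol=0.0,
        vitamin_e=0.4,
    ),
    PULSES: dict(
        energy=380, carbohydrate=42, protein=22, fat=12, calcium=110,
        iron=7.0, zinc=3.5, magnesium=180, phosphorus=400, copper=1.0,
        selenium=10, sodium=10, vitamin_c=2, thiamine=0.5,
        riboflavin=0.22, niacin=2.5, vitamin_b6=0.4, folate=280,
        vitamin_b12=0.0, vitamin_a_rae=2, vitamin_a_retinol=0.0,
        vitamin_e=5.0,
    ),
    ANIMAL: dict(
        energy=150, carbohydrate=5, protein=15, fat=8, calcium=150,
        iron=1.5, zinc=2.5, magnesium=20, phosphorus=200, copper=0.1,
        selenium=20, sodium=90, vitamin_c=1, thiamine=0.1,
        riboflavin=0.3, niacin=3.0, vitamin_b6=0.2, folate=12,
        vitamin_b12=1.6, vitamin_a_rae=55, vitamin_a_retinol=55,
        vitamin_e=0.4,
    ),
    FRUITVEG: dict(
        energy=45, carbohydrate=9, protein=2, fat=0.3, calcium=60,
        iron=1.5, zinc=0.4, magnesium=25, phosphorus=45, copper=0.1,
        selenium=1, sodium=30, vitamin_c=40, thiamine=0.08,
        riboflavin=0.1, niacin=0.7, vitamin_b6=0.15, folate=60,
        vitamin_b12=0.0, vitamin_a_rae=160, vitamin_a_retinol=0.0,
        vitamin_e=1.5,
    ),
    OILS: dict(
        energy=850, carbohydrate=0.5, protein=0.2, fat=95, calcium=2,
        iron=0.1, zinc=0.05, magnesium=1, phosphorus=3, copper=0.01,
        selenium=0.5, sodium=3, vitamin_c=0, thiamine=0.0,
        riboflavin=0.0, niacin=0.0, vitamin_b6=0.0, folate=1,
        vitamin_b12=0.0, vitamin_a_rae=10, vitamin_a_retinol=10,
        vitamin_e=14.0,
    ),
    SWEETS: dict(
        energy=310, carbohydrate=72, protein=2, fat=2, calcium=20,
        iron=0.8, zinc=0.3, magnesium=20, phosphorus=40, copper=0.1,
        selenium=2, sodium=50, vitamin_c=3, thiamine=0.03,
        riboflavin=0.05, niacin=0.5, vitamin_b6=0.05, folate=8,
        vitamin_b12=0.0, vitamin_a_rae=3, vitamin_a_retinol=1.0,
        vitamin_e=0.5,
    ),
}

EDIBLE_FRACTION_RANGE = {
    STAPLES: (0.85, 1.0), PULSES: (0.9, 1.0), ANIMAL: (0.55, 0.95),
    FRUITVEG: (0.55, 0.95), OILS: (1.0, 1.0), SWEETS: (0.9, 1.0),
}


@dataclass(frozen=True)
class WorldSpec:
    """Parameters of a synthetic world; the seed fully determines output."""

    seed: int
    n_countries: int = 172
    n_master_items: int = 200
    availability_prob: float = 0.625
    price_sigma: float = 0.35      # within-country log price noise
    item_price_sigma: float = 0.30  # item-level global relative price
    country_level_sigma: float = 0.12  # real price-level dispersion
    currency_log_mean: float = 1.6  # log of median LCU per intl $
    currency_log_sigma: float = 1.2
    density_sigma: float = 0.30    # log-normal nutrient density dispersion
    availability_concentration: float = 20.0  # Beta concentration across countries
    income_class_probs: dict[str, float] = field(
        default_factory=lambda: dict(INCOME_CLASS_PROBS)
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.availability_prob <= 1.0):
            raise ValidationError("availability_prob must be in (0, 1]")
        if self.n_countries < 1 or self.n_master_items < 6:
            raise ValidationError("world too small")
        if abs(sum(self.income_class_probs.values()) - 1.0) > 1e-9:
            raise ValidationError("income_class_probs must sum to 1")


def _master_categories(n: int) -> list[str]:
    counts = {c: max(1, int(round(w * n))) for c, w in CATEGORY_WEIGHTS.items()}
    cats: list[str] = []
    for c in FOOD_CATEGORIES:
        cats.extend([c] * counts[c])
    # pad/trim deterministically to exactly n
    while len(cats) < n:
        cats.append(FOOD_CATEGORIES[len(cats) % len(FOOD_CATEGORIES)])
    return cats[:n]


def _make_foods(spec: WorldSpec, rng: np.random.Generator,
                registry: dict[str, NutrientDefinition]) -> dict[str, FoodItem]:
    cats = _master_categories(spec.n_master_items)
    comp_cols = composition_columns(registry)
    foods = {}
    for idx, cat in enumerate(cats):
        item_id = f"i{idx:03d}"
        means = CATEGORY_DENSITY[cat]
        comp = {}
        for col in comp_cols:
            mu = means.get(col, 0.0)
            if mu <= 0:
                comp[col] = 0.0
            else:
                comp[col] = float(
                    mu * rng.lognormal(0.0, spec.density_sigma)
                )
        # keep preformed retinol a subset of total RAE activity
        if "vitamin_a_retinol" in comp and "vitamin_a_rae" in comp:
            comp["vitamin_a_retinol"] = min(
                comp["vitamin_a_retinol"], comp["vitamin_a_rae"]
            )
        energy = float(
            means["energy"] * rng.lognormal(0.0, spec.density_sigma / 2)
        )
        lo, hi = EDIBLE_FRACTION_RANGE[cat]
        foods[item_id] = FoodItem(
            item_id=item_id,
            name=f"{cat.split(',')[0].split(' ')[0]}_{idx:03d}",
            category=cat,
            edible_fraction=float(rng.uniform(lo, hi)),
            energy_per_100g=energy,
            nutrients_per_100g=comp,
        )
    return foods


def _country_availability(spec: WorldSpec, rng: np.random.Generator) -> float:
    p = spec.availability_prob
    if p >= 1.0:
        return 1.0
    k = spec.availability_concentration
    return float(rng.beta(p * k, (1 - p) * k))


def _sample_country_items(spec: WorldSpec, rng: np.random.Generator,
                          foods: dict[str, FoodItem],
                          max_retries: int = 50) -> list[str]:
    """Priced item subset for one country; every category represented."""
    ids = sorted(foods)
    cats = {i: foods[i].category for i in ids}
    for attempt in range(max_retries):
        p = _country_availability(spec, rng)
        keep = [i for i in ids if rng.random() < p]
        if not keep:
            continue
        present = {cats[i] for i in keep}
        if len(present) == len(FOOD_CATEGORIES):
            return keep
    warnings.warn("country item sampling exhausted retries; using last draw")
    return keep if keep else ids[:6]


def generate_world(spec: WorldSpec,
                   registry: dict[str, NutrientDefinition] | None = None,
                   ) -> Dataset:
    """Generate a full synthetic dataset bundle (foods, prices, countries, DRI)."""
    registry = registry or default_registry()
    rng = np.random.default_rng(spec.seed)
    foods = _make_foods(spec, rng, registry)
    item_price_factor = {
        i: rng.lognormal(0.0, spec.item_price_sigma) for i in sorted(foods)
    }
    classes = list(spec.income_class_probs)
    probs = np.array([spec.income_class_probs[c] for c in classes])
    countries: dict[str, Country] = {}
    price_rows = []
    for ci in range(spec.n_countries):
        cid = f"c{ci:03d}"
        income = classes[rng.choice(len(classes), p=probs)]
        level = rng.lognormal(0.0, spec.country_level_sigma)
        currency = rng.lognormal(spec.currency_log_mean,
                                 spec.currency_log_sigma)
        ppp = currency * level
        expenditure = FOOD_EXPENDITURE_BY_INCOME[income] * rng.lognormal(0.0, 0.25)
        population = rng.lognormal(np.log(8e6), 1.6)
        countries[cid] = Country(
            country_id=cid, income_group=income, ppp_factor=float(ppp),
            food_expenditure_per_capita_day=float(expenditure),
            population=float(round(population)),
        )
        for item_id in _sample_country_items(spec, rng, foods):
            food = foods[item_id]
            base = CATEGORY_PRICE_MEDIAN[food.category]
            mult = (ANIMAL_PRICE_BY_INCOME[income]
                    if food.category == ANIMAL else 1.0)
            price = (base * mult * item_price_factor[item_id] * currency
                     * level * rng.lognormal(0.0, spec.price_sigma))
            price_rows.append((cid, item_id, float(price)))
    prices = pd.DataFrame(
        price_rows, columns=["country_id", "item_id", "price_lcu_per_kg"]
    )
    dri = synthetic_dri_table()
    return Dataset(foods=foods, prices=prices, countries=countries,
                   dri=dri, registry=registry)


# ---------------------------------------------------------------------------
# Synthetic dietary-reference tables
# ---------------------------------------------------------------------------

#: Adult (19-30 y) average-requirement anchors per day: (male, female),
#: ratio of RDA to EAR, and the tolerable upper level. Values sit in
#: plausible reference-intake ranges but are synthetic. The magnesium,
#: niacin and folate upper levels are deliberately generous because the
#: published figures apply to supplemental forms only and would make
#: ordinary food-based diets infeasible.
_MICRO_PARAMS: dict[str, tuple[float, float, float, float | None]] = {
    # nid: (ear_male, ear_female, rda_factor, ul)
    "calcium": (800, 800, 1.25, 2500),
    "iron": (6.0, 8.1, 1.6, 45),
    "zinc": (9.4, 6.8, 1.18, 40),
    "magnesium": (330, 255, 1.22, 1600),
    "phosphorus": (580, 580, 1.2, 4000),
    "copper": (0.7, 0.7, 1.28, 10),
    "selenium": (45, 45, 1.22, 400),
    "vitamin_c": (75, 60, 1.2, 2000),
    "thiamine": (1.0, 0.9, 1.2, None),
    "riboflavin": (1.1, 0.9, 1.18, None),
    "niacin": (12, 11, 1.33, 60),
    "vitamin_b6": (1.1, 1.0, 1.3, 100),
    "folate": (320, 320, 1.25, 2500),
    "vitamin_b12": (2.0, 2.0, 1.2, None),
    "vitamin_a": (625, 500, 1.44, 3000),
    "vitamin_e": (12, 12, 1.25, 1000),
}

#: Harmonised-average-requirement multiplier over the EAR (low
#: bioavailability of iron and zinc in plant-dominated diets).
_HAR_FACTOR = {"iron": 1.45, "zinc": 1.5}

#: Generic age multipliers for micronutrient requirements.
_AGE_MULT = {"4-8": 0.55, "9-13": 0.85, "14-18": 1.0, "19-30": 1.0,
             "31-50": 1.0, "51-70": 1.0, "71+": 1.0}
#: Per-nutrient overrides (e.g. calcium and phosphorus peak in adolescence,
#: calcium rises again after 50 for women and after 70 for everyone).
_AGE_OVERRIDES: dict[str, dict[str, float]] = {
    "calcium": {"4-8": 1.0, "9-13": 1.375, "14-18": 1.375, "71+": 1.25},
    "phosphorus": {"4-8": 0.7, "9-13": 1.82, "14-18": 1.82},
    "iron": {"4-8": 0.6, "9-13": 0.75},
    "zinc": {"4-8": 0.45, "9-13": 0.75},
}
_CALCIUM_F_51_70 = 1.25  # women 51-70 need more calcium than men

#: Pregnancy / lactation multipliers on the EAR (selected nutrients).
_PREG_MULT = {"iron": 2.0, "folate": 1.6, "zinc": 1.15, "vitamin_a": 1.1,
              "vitamin_b6": 1.4, "vitamin_b12": 1.1}
_LACT_MULT = {"vitamin_c": 1.6, "vitamin_e": 1.4, "vitamin_a": 1.6,
              "zinc": 1.3, "selenium": 1.3, "vitamin_b12": 1.2,
              "copper": 1.3}

#: Estimated energy requirements, kcal/day, active physical activity,
#: distinct for every group.
_EER = {
    ("male", "4-8"): 1642, ("male", "9-13"): 2279, ("male", "14-18"): 3152,
    ("male", "19-30"): 3067, ("male", "31-50"): 2917,
    ("male", "51-70"): 2657, ("male", "71+"): 2450,
    ("female", "4-8"): 1538, ("female", "9-13"): 2071,
    ("female", "14-18"): 2368, ("female", "19-30"): 2403,
    ("female", "31-50"): 2319, ("female", "51-70"): 2142,
    ("female", "71+"): 1978,
}
_STATUS_EER_ADD = {"pregnant": 300, "lactating": 450}

_CDRR = {"4-8": 1500, "9-13": 1800}  # mg/day; 2300 for 14+
_AMDR = {  # (carb_lo, carb_hi), (protein_lo, protein_hi), (fat_lo, fat_hi)
    "child": {"carbohydrate": (0.45, 0.65), "protein": (0.10, 0.30),
              "fat": (0.25, 0.40)},
    "adult": {"carbohydrate": (0.45, 0.65), "protein": (0.10, 0.35),
              "fat": (0.20, 0.35)},
}
_PROTEIN_EAR_PER_KG = 0.66  # g/kg/day
_REFERENCE_KG = {"4-8": 23, "9-13": 39, "14-18": 61, "19-30": 65,
                 "31-50": 67, "51-70": 66, "71+": 62}
_CARB_EAR = 100.0  # g/day, all groups


def _group_eer(group: DemographicGroup) -> float:
    eer = _EER[(group.sex, group.age_band)]
    return eer + _STATUS_EER_ADD.get(group.reproductive_status, 0)


def synthetic_dri_table(registry: dict[str, NutrientDefinition] | None = None,
                        ) -> DriTable:
    """Deterministic synthetic DRI table covering all 20 groups.

    Built from adult anchors with age/sex/reproductive-status scaling;
    guarantees EAR <= RDA <= UL everywhere and HAR values for iron and
    zinc only.
    """
    registry = registry or default_registry()
    rows = []
    for group in enumerate_groups():
        gid = group.group_id
        eer = _group_eer(group)
        kind = "child" if group.age_band in ("4-8", "9-13", "14-18") else "adult"
        sexi = 0 if group.sex == "male" else 1
        for nid, nd in registry.items():
            row = dict(group_id=gid, nutrient_id=nid, ear=np.nan, har=np.nan,
                       rda=np.nan, ul=np.nan, cdrr_upper=np.nan,
                       amdr_lower_frac=np.nan, amdr_upper_frac=np.nan,
                       eer=eer)
            if nd.upper_bound_kind == "AMDR":
                lo, hi = _AMDR[kind][nid]
                row["amdr_lower_frac"], row["amdr_upper_frac"] = lo, hi
                if nid == "carbohydrate":
                    row["ear"] = _CARB_EAR
                    row["rda"] = 130.0
                elif nid == "protein":
                    ear = _PROTEIN_EAR_PER_KG * _REFERENCE_KG[group.age_band]
                    if group.reproductive_status != "none":
                        ear *= 1.3
                    row["ear"] = round(ear, 1)
                    row["rda"] = round(ear * 1.22, 1)
            elif nd.upper_bound_kind == "CDRR":
                row["cdrr_upper"] = _CDRR.get(group.age_band, 2300)
            else:
                ear_m, ear_f, rda_f, ul = _MICRO_PARAMS[nid]
                mult = _AGE_OVERRIDES.get(nid, {}).get(
                    group.age_band, _AGE_MULT[group.age_band]
                )
                ear = (ear_m, ear_f)[sexi] * mult
                if (nid == "calcium" and group.sex == "female"
                        and group.age_band == "51-70"):
                    ear *= _CALCIUM_F_51_70
                if group.reproductive_status == "pregnant":
                    ear *= _PREG_MULT.get(nid, 1.0)
                elif group.reproductive_status == "lactating":
                    ear *= _LACT_MULT.get(nid, 1.0)
                row["ear"] = round(ear, 3)
                row["rda"] = round(ear * rda_f, 3)
                if nid in _HAR_FACTOR:
                    row["har"] = round(ear * _HAR_FACTOR[nid], 3)
                if ul is not None:
                    row["ul"] = ul
            rows.append(row)
    return DriTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Analytic fixtures with documented optima
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalyticFixture:
    """A tiny dataset with a known optimum for exact verification."""

    name: str
    dataset: Dataset
    requirements: RequirementSet
    expected: dict[str, float | dict[str, float]]


def _mini_registry_a() -> dict[str, NutrientDefinition]:
    return {
        "calcium": NutrientDefinition(
            "calcium", "Calcium", "mg",
            has_lower_bound=True, has_upper_bound=False,
            lower_bound_kind="EAR",
        ),
    }


def _mini_registry_b() -> dict[str, NutrientDefinition]:
    return {
        "calcium": NutrientDefinition(
            "calcium", "Calcium", "mg",
            has_lower_bound=True, has_upper_bound=False,
            lower_bound_kind="EAR",
        ),
        "iron": NutrientDefinition(
            "iron", "Iron", "mg",
            has_lower_bound=True, has_upper_bound=False,
            lower_bound_kind="EAR",
        ),
        "sodium": NutrientDefinition(
            "sodium", "Sodium", "mg",
            has_lower_bound=False, has_upper_bound=True,
            upper_bound_kind="CDRR",
        ),
    }


def _dri_frame(gid: str, eer: float, rows: list[dict]) -> DriTable:
    base = dict(group_id=gid, ear=np.nan, har=np.nan, rda=np.nan, ul=np.nan,
                cdrr_upper=np.nan, amdr_lower_frac=np.nan,
                amdr_upper_frac=np.nan, eer=eer)
    return DriTable(pd.DataFrame([{**base, **r} for r in rows]))


def analytic_fixture(name: str) -> AnalyticFixture:
    """Return one of the documented analytic fixtures.

    ``fixtureA``
        Two foods, energy equality (2000 kcal) plus one binding nutrient
        lower bound (100 mg). Closed-form optimum: cost 7/6 LCU/day with
        888.89 g of the nutrient-dense food and 555.56 g of the cheap-
        calorie food; duals 1/6000 LCU/kcal (energy) and 1/120 LCU/mg
        (nutrient); elasticities 2/7 and 5/7.
    ``fixtureB``
        Four foods, energy equality plus two nutrient lower bounds and a
        binding sodium-like upper bound; its optimum is computed at build
        time by exhaustive vertex enumeration and stored in ``expected``.
    """
    group = DemographicGroup(sex="male", age_band="19-30")
    gid = group.group_id
    if name == "fixtureA":
        registry = _mini_registry_a()
        foods = {
            "X": FoodItem("X", "dense", STAPLES, 1.0, 100.0,
                          {"calcium": 10.0}),
            "Y": FoodItem("Y", "cheap", ANIMAL, 1.0, 200.0,
                          {"calcium": 2.0}),
        }
        prices = pd.DataFrame(
            [("A", "X", 1.0), ("A", "Y", 0.5)],
            columns=["country_id", "item_id", "price_lcu_per_kg"],
        )
        countries = {"A": Country("A", "high", 1.0, 4.0, 1e6)}
        dri = _dri_frame(gid, 2000.0, [
            dict(nutrient_id="calcium", ear=100.0, rda=100.0),
        ])
        reqs = RequirementSet(
            group_id=gid, scenario="EAR", eer=2000.0,
            lower_bounds={"calcium": 100.0}, upper_bounds={},
        )
        expected = {
            "cona": 7.0 / 6.0,
            "quantities_g": {"X": 8000.0 / 9.0, "Y": 5000.0 / 9.0},
            "duals": {"energy": 1.0 / 6000.0, "calcium:lb": 1.0 / 120.0},
            "elasticities": {"energy": 2.0 / 7.0, "calcium:lb": 5.0 / 7.0},
            "binding": {"energy", "calcium:lb"},
        }
        ds = Dataset(foods=foods, prices=prices, countries=countries,
                     dri=dri, registry=registry)
        return AnalyticFixture(name, ds, reqs, expected)
    if name == "fixtureB":
        registry = _mini_registry_b()
        foods = {
            "bread": FoodItem("bread", "salty staple", STAPLES, 1.0, 280.0,
                              {"calcium": 30.0, "iron": 2.0, "sodium": 500.0}),
            "rice": FoodItem("rice", "plain staple", STAPLES, 1.0, 360.0,
                             {"calcium": 10.0, "iron": 1.5, "sodium": 2.0}),
            "milk": FoodItem("milk", "dairy", ANIMAL, 1.0, 64.0,
                             {"calcium": 120.0, "iron": 0.1, "sodium": 45.0}),
            "beans": FoodItem("beans", "pulse", PULSES, 1.0, 340.0,
                              {"calcium": 120.0, "iron": 7.0, "sodium": 10.0}),
        }
        prices = pd.DataFrame(
            [("B", "bread", 0.8), ("B", "rice", 1.4),
             ("B", "milk", 1.0), ("B", "beans", 2.2)],
            columns=["country_id", "item_id", "price_lcu_per_kg"],
        )
        countries = {"B": Country("B", "low", 1.0, 2.0, 1e6)}
        dri = _dri_frame(gid, 2200.0, [
            dict(nutrient_id="calcium", ear=900.0, rda=900.0),
            dict(nutrient_id="iron", ear=12.0, rda=12.0),
            dict(nutrient_id="sodium", cdrr_upper=2000.0),
        ])
        reqs = RequirementSet(
            group_id=gid, scenario="EAR", eer=2200.0,
            lower_bounds={"calcium": 900.0, "iron": 12.0},
            upper_bounds={"sodium": 2000.0},
        )
        ds = Dataset(foods=foods, prices=prices, countries=countries,
                     dri=dri, registry=registry)
        problem = assemble_lp(ds.prices_for("B"), foods, reqs,
                              registry=registry, country_id="B")
        status, obj, _ = brute_force_solve(problem)
        if status != "optimal":
            raise RuntimeError("fixtureB enumeration failed")
        expected = {"cona": obj}
        return AnalyticFixture(name, ds, reqs, expected)
    raise ValueError(f"unknown fixture {name!r}")
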