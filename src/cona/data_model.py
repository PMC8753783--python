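"""Domain types and CSV readers/writers for the diet-cost pipeline.

Unit conventions (these meet only in LP assembly, see :mod:`cona.lp_core`):

* food composition is stored **per 100 g edible portion**;
* prices are stored in **local currency units per kg as purchased**;
* the edible fraction links the two.

CSV schemas (one header row, UTF-8, ``.`` decimal separator):

``foods.csv``
    item_id, name, category, edible_fraction, energy_kcal_100g, plus one
    column per composition key of the nutrient registry (for the default
    registry: carbohydrate, protein, fat, calcium, iron, zinc, magnesium,
    phosphorus, copper, selenium, sodium, vitamin_c, thiamine, riboflavin,
    niacin, vitamin_b6, folate, vitamin_b12, vitamin_a_rae,
    vitamin_a_retinol, vitamin_e).
``prices.csv``
    country_id, item_id, price_lcu_per_kg.
``countries.csv``
    country_id, income_group, ppp_factor, food_expenditure_per_capita_day,
    population.
``dri.csv``
    group_id, nutrient_id, ear, har, rda, ul, cdrr_upper, amdr_lower_frac,
    amdr_upper_frac, eer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .nutrients import (
    FOOD_CATEGORIES,
    NutrientDefinition,
    composition_columns,
    default_registry,
)

logger = logging.getLogger(__name__)

AGE_BANDS: tuple[str, ...] = (
    "4-8", "9-13", "14-18", "19-30", "31-50", "51-70", "71+",
)
#: Age bands in which pregnancy/lactation variants exist.
REPRODUCTIVE_BANDS: tuple[str, ...] = ("14-18", "19-30", "31-50")
INCOME_GROUPS: tuple[str, ...] = ("high", "upper-middle", "lower-middle", "low")


@dataclass(frozen=True)
class FoodItem:
    """One food with composition per 100 g edible portion."""

    item_id: str
    name: str
    category: str
    edible_fraction: float
    energy_per_100g: float
    nutrients_per_100g: Mapping[str, float]

    def __post_init__(self) -> None:
        if not (0.0 < self.edible_fraction <= 1.0):
            raise ValidationError(
                f"food {self.item_id!r}: edible_fraction "
                f"{self.edible_fraction} outside (0, 1]"
            )
        if self.energy_per_100g < 0:
            raise ValidationError(f"food {self.item_id!r}: negative energy")
        if self.category not in FOOD_CATEGORIES:
            raise ValidationError(
                f"food {self.item_id!r}: unknown category {self.category!r}"
            )
        for k, v in self.nutrients_per_100g.items():
            if v < 0:
                raise ValidationError(
                    f"food {self.item_id!r}: negative {k} ({v})"
                )


@dataclass(frozen=True)
class PriceRecord:
    country_id: str
    item_id: str
    price_lcu_per_kg: float

    def __post_init__(self) -> None:
        if not self.price_lcu_per_kg > 0:
            raise ValidationError(
                f"price for ({self.country_id}, {self.item_id}) must be > 0"
            )


@dataclass(frozen=True)
class Country:
    country_id: str
    income_group: str
    ppp_factor: float
    food_expenditure_per_capita_day: float
    population: float

    def __post_init__(self) -> None:
        if self.income_group not in INCOME_GROUPS:
            raise ValidationError(
                f"country {self.country_id!r}: income_group "
                f"{self.income_group!r} not in {INCOME_GROUPS}"
            )
        if not self.ppp_factor > 0:
            raise ValidationError(
                f"country {self.country_id!r}: ppp_factor must be > 0"
            )


@dataclass(frozen=True)
class DemographicGroup:
    """One age/sex/reproductive-status cell of the reference population."""

    sex: str
    age_band: str
    reproductive_status: str = "none"

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.age_band not in AGE_BANDS:
            raise ValidationError(f"unknown age band {self.age_band!r}")
        if self.reproductive_status not in ("none", "pregnant", "lactating"):
            raise ValidationError(
                f"unknown reproductive status {self.reproductive_status!r}"
            )
        if self.reproductive_status != "none":
            if self.sex != "female" or self.age_band not in REPRODUCTIVE_BANDS:
                raise ValidationError(
                    "pregnant/lactating groups exist only for females aged "
                    f"{REPRODUCTIVE_BANDS}, got {self.sex} {self.age_band}"
                )

    @property
    def group_id(self) -> str:
        gid = f"{self.sex}_{self.age_band}"
        if self.reproductive_status != "none":
            gid += f"_{self.reproductive_status}"
        return gid


class DriTable:
    """Dietary-reference-intake inputs per (group, nutrient).

    Wraps the ``dri.csv`` long table. ``eer`` (the energy requirement) is
    carried on every row of a group and validated for consistency.
    """

    COLUMNS = (
        "group_id", "nutrient_id", "ear", "har", "rda", "ul",
        "cdrr_upper", "amdr_lower_frac", "amdr_upper_frac", "eer",
    )

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"dri table missing column(s): {missing}")
        df = df.copy()
        dup = df.duplicated(["group_id", "nutrient_id"])
        if dup.any():
            row = df[dup].iloc[0]
            raise ValidationError(
                f"duplicate dri row for ({row.group_id}, {row.nutrient_id})"
            )
        eers = df.groupby("group_id")["eer"].nunique()
        if (eers > 1).any():
            bad = eers[eers > 1].index[0]
            raise ValidationError(f"group {bad!r} has inconsistent eer values")
        if not (df.groupby("group_id")["eer"].first() > 0).all():
            raise ValidationError("eer must be > 0 for every group")
        both = df.dropna(subset=["ear", "rda"])
        bad = both[both["ear"] > both["rda"]]
        if len(bad):
            r = bad.iloc[0]
            raise ValidationError(
                f"ear > rda for ({r.group_id}, {r.nutrient_id})"
            )
        amdr = df.dropna(subset=["amdr_lower_frac", "amdr_upper_frac"])
        if (amdr["amdr_lower_frac"] >= amdr["amdr_upper_frac"]).any():
            raise ValidationError("amdr_lower_frac must be < amdr_upper_frac")
        self._df = df.set_index(["group_id", "nutrient_id"]).sort_index()

    @property
    def frame(self) -> pd.DataFrame:
        return self._df.reset_index()

    @property
    def group_ids(self) -> list[str]:
        return sorted(self._df.index.get_level_values(0).unique())

    def eer(self, group_id: str) -> float:
        try:
            return float(self._df.loc[group_id, "eer"].iloc[0])
        except KeyError:
            raise ValidationError(f"no dri rows for group {group_id!r}")

    def cell(self, group_id: str, nutrient_id: str) -> pd.Series:
        try:
            return self._df.loc[(group_id, nutrient_id)]
        except KeyError:
            raise ValidationError(
                f"missing dri cell for ({group_id!r}, {nutrient_id!r})"
            )

    def value(self, group_id: str, nutrient_id: str, column: str) -> float | None:
        v = self.cell(group_id, nutrient_id)[column]
        return None if pd.isna(v) else float(v)


@dataclass
class Dataset:
    """A validated bundle of foods, prices, countries and DRI inputs."""

    foods: dict[str, FoodItem]
    prices: pd.DataFrame  # columns country_id, item_id, price_lcu_per_kg
    countries: dict[str, Country]
    dri: DriTable
    registry: dict[str, NutrientDefinition] = field(default_factory=default_registry)

    def prices_for(self, country_id: str) -> dict[str, float]:
        """Mapping item_id -> LCU/kg for one country, sorted by item."""
        sub = self.prices[self.prices["country_id"] == country_id]
        return dict(
            sorted(zip(sub["item_id"], sub["price_lcu_per_kg"]))
        )

    @property
    def country_ids(self) -> list[str]:
        return sorted(self.countries)

    def to_csv(self, outdir: str | Path) -> dict[str, Path]:
        """Write the bundle back out as the four schema CSVs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "foods": outdir / "foods.csv",
            "prices": outdir / "prices.csv",
            "countries": outdir / "countries.csv",
            "dri": outdir / "dri.csv",
        }
        comp_cols = composition_columns(self.registry)
        rows = []
        for it in self.foods.values():
            row = {
                "item_id": it.item_id, "name": it.name,
                "category": it.category,
                "edible_fraction": it.edible_fraction,
                "energy_kcal_100g": it.energy_per_100g,
            }
            for c in comp_cols:
                row[c] = it.nutrients_per_100g.get(c, 0.0)
            rows.append(row)
        pd.DataFrame(rows).sort_values("item_id").to_csv(
            paths["foods"], index=False
        )
        self.prices.sort_values(["country_id", "item_id"]).to_csv(
            paths["prices"], index=False
        )
        pd.DataFrame(
            [vars(c) for c in self.countries.values()]
        ).sort_values("country_id").to_csv(paths["countries"], index=False)
        self.dri.frame.to_csv(paths["dri"], index=False)
        return paths


def _require_columns(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing column(s) {missing}")


def load_foods(path: str | Path,
               registry: dict[str, NutrientDefinition] | None = None,
               ) -> dict[str, FoodItem]:
    registry = registry or default_registry()
    df = pd.read_csv(path)
    comp_cols = composition_columns(registry)
    _require_columns(
        df,
        ["item_id", "name", "category", "edible_fraction", "energy_kcal_100g"]
        + comp_cols,
        "foods.csv",
    )
    if df["item_id"].duplicated().any():
        dup = df.loc[df["item_id"].duplicated(), "item_id"].iloc[0]
        raise ValidationError(f"foods.csv: duplicate item_id {dup!r}")
    n_missing = int(df[comp_cols + ["energy_kcal_100g"]].isna().sum().sum())
    if n_missing:
        logger.warning(
            "foods.csv: %d missing composition values treated as 0", n_missing
        )
        df[comp_cols] = df[comp_cols].fillna(0.0)
        df["energy_kcal_100g"] = df["energy_kcal_100g"].fillna(0.0)
    foods = {}
    for _, r in df.iterrows():
        foods[str(r.item_id)] = FoodItem(
            item_id=str(r.item_id),
            name=str(r["name"]),
            category=str(r.category),
            edible_fraction=float(r.edible_fraction),
            energy_per_100g=float(r.energy_kcal_100g),
            nutrients_per_100g={c: float(r[c]) for c in comp_cols},
        )
    return foods


def load_prices(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df, ["country_id", "item_id", "price_lcu_per_kg"], "prices.csv"
    )
    df["country_id"] = df["country_id"].astype(str)
    df["item_id"] = df["item_id"].astype(str)
    dup = df.duplicated(["country_id", "item_id"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ValidationError(
            f"prices.csv: duplicate (country, item) row "
            f"({r.country_id}, {r.item_id})"
        )
    if not (df["price_lcu_per_kg"] > 0).all():
        r = df[~(df["price_lcu_per_kg"] > 0)].iloc[0]
        raise ValidationError(
            f"prices.csv: non-positive price for ({r.country_id}, {r.item_id})"
        )
    return df[["country_id", "item_id", "price_lcu_per_kg"]].copy()


def load_countries(path: str | Path) -> dict[str, Country]:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["country_id", "income_group", "ppp_factor",
         "food_expenditure_per_capita_day", "population"],
        "countries.csv",
    )
    if df["country_id"].duplicated().any():
        dup = df.loc[df["country_id"].duplicated(), "country_id"].iloc[0]
        raise ValidationError(f"countries.csv: duplicate country_id {dup!r}")
    return {
        str(r.country_id): Country(
            country_id=str(r.country_id),
            income_group=str(r.income_group),
            ppp_factor=float(r.ppp_factor),
            food_expenditure_per_capita_day=float(
                r.food_expenditure_per_capita_day
            ),
            population=float(r.population),
        )
        for _, r in df.iterrows()
    }


def load_dri(path: str | Path) -> DriTable:
    return DriTable(pd.read_csv(path))


def load_dataset(foods_path: str | Path,
                 prices_path: str | Path,
                 countries_path: str | Path,
                 dri_path: str | Path,
                 registry: dict[str, NutrientDefinition] | None = None,
                 ) -> Dataset:
    """Load and cross-validate the four input tables.

    Raises :class:`SchemaError` for missing columns and
    :class:`ValidationError` for invariant violations, naming the offending
    row or key.
    """
    registry = registry or default_registry()
    foods = load_foods(foods_path, registry)
    prices = load_prices(prices_path)
    countries = load_countries(countries_path)
    dri = load_dri(dri_path)
    unknown_items = set(prices["item_id"]) - set(foods)
    if unknown_items:
        raise ValidationError(
            f"prices.csv references unknown item(s): {sorted(unknown_items)[:5]}"
        )
    unknown_countries = set(prices["country_id"]) - set(countries)
    if unknown_countries:
        raise ValidationError(
            "prices.csv references unknown country(ies): "
            f"{sorted(unknown_countries)[:5]}"
        )
    ds = Dataset(foods=foods, prices=prices, countries=countries, dri=dri,
                 registry=registry)
    logger.info(
        "loaded dataset: %d foods, %d prices, %d countries, %d dri rows",
        len(foods), len(prices), len(countries), len(dri.frame),
    )
    return ds


@dataclass
class CoverageReport:
    """Per-country presence of the six reporting food categories."""

    missing: dict[str, list[str]]  # country -> categories absent (non-fatal)
    fatal: list[str]  # countries with zero priced items

    def flags_for(self, country_id: str) -> list[str]:
        return self.missing.get(country_id, [])


def validate_category_coverage(dataset: Dataset) -> CoverageReport:
    """Flag countries lacking a food category (informational, not fatal).

    The LP itself is constrained on nutrients only, so a missing category
    never blocks construction; a country with *no* priced items at all is
    flagged fatal.
    """
    missing: dict[str, list[str]] = {}
    fatal: list[str] = []
    by_country = dict(tuple(dataset.prices.groupby("country_id")))
    for cid in dataset.country_ids:
        sub = by_country.get(cid)
        if sub is None or not len(sub):
            fatal.append(cid)
            continue
        cats = {dataset.foods[i].category for i in sub["item_id"]}
        absent = [c for c in FOOD_CATEGORIES if c not in cats]
        if absent:
            missing[cid] = absent
    return CoverageReport(missing=missing, fatal=fatal)


RESULT_COLUMNS = (
    "country_id", "group_id", "scenario", "status", "cona_lcu_day",
    "cona_usd_day", "cona_usd_per_1000kcal", "affordability_ratio",
    "n_items", "binding",
)


def write_results(results: pd.DataFrame, path: str | Path) -> Path:
    """Write one row per (country, group[, scenario]) of solved diets.

    ``binding`` is a ``;``-joined list of binding-constraint ids.
    Raises :class:`ValidationError` on an empty frame rather than writing
    an empty file.
    """
    if results is None or not len(results):
        raise ValidationError("refusing to write empty results")
    _require_columns(results, RESULT_COLUMNS, "results")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results.loc[:, list(RESULT_COLUMNS)].to_csv(path, index=False)
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    _require_columns(df, RESULT_COLUMNS, "results")
    return df
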