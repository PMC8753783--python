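"""Synthetic world generation: determinism, structure, and realism."""

import numpy as np
import pandas as pd
import pytest

import cona
from cona.lp_core import solve_cona
from cona.requirements import build_requirement_set
from cona.synthetic import ANIMAL, FRUITVEG, PULSES, synthetic_dri_table


def _bundle_signature(ds, tmp_path):
    paths = ds.to_csv(tmp_path)
    return {k: p.read_bytes() for k, p in paths.items()}


def test_same_seed_byte_identical(tmp_path):
    spec = cona.WorldSpec(seed=7, n_countries=10, n_master_items=200,
                          availability_prob=0.6)
    a = _bundle_signature(cona.generate_world(spec), tmp_path / "a")
    b = _bundle_signature(cona.generate_world(spec), tmp_path / "b")
    assert a == b


def test_different_seed_changes_prices_keeps_schema():
    s1 = cona.generate_world(cona.WorldSpec(seed=1, n_countries=4,
                                            n_master_items=80))
    s2 = cona.generate_world(cona.WorldSpec(seed=2, n_countries=4,
                                            n_master_items=80))
    assert not s1.prices["price_lcu_per_kg"].equals(
        s2.prices["price_lcu_per_kg"]
    )
    for ds in (s1, s2):
        assert cona.validate_category_coverage(ds).fatal == []
        assert (ds.prices["price_lcu_per_kg"] > 0).all()


def test_full_availability_prices_every_item():
    ds = cona.generate_world(cona.WorldSpec(seed=3, n_countries=3,
                                            n_master_items=60,
                                            availability_prob=1.0))
    counts = ds.prices.groupby("country_id").size()
    assert (counts == 60).all()


def test_mean_items_per_country_matches_binomial_expectation():
    """availability 0.625 x 200 items -> ~125 priced items per country."""
    ds = cona.generate_world(cona.WorldSpec(seed=9, n_countries=100))
    counts = ds.prices.groupby("country_id").size()
    assert counts.mean() == pytest.approx(125, abs=8)


def test_dri_table_is_complete_and_ordered():
    dri = synthetic_dri_table()
    groups = [g.group_id for g in cona.enumerate_groups()]
    assert sorted(dri.group_ids) == sorted(groups)
    frame = dri.frame
    both = frame.dropna(subset=["ear", "rda"])
    assert (both["ear"] <= both["rda"]).all()
    with_ul = frame.dropna(subset=["rda", "ul"])
    assert (with_ul["rda"] <= with_ul["ul"]).all()
    har = frame.dropna(subset=["har"])
    assert set(har["nutrient_id"]) == {"iron", "zinc"}


def test_b12_only_in_animal_source_foods():
    ds = cona.generate_world(cona.WorldSpec(seed=21, n_countries=2,
                                            n_master_items=120))
    for f in ds.foods.values():
        b12 = f.nutrients_per_100g["vitamin_b12"]
        if f.category == ANIMAL:
            assert b12 > 0
        else:
            assert b12 == 0.0


def test_retinol_never_exceeds_rae():
    ds = cona.generate_world(cona.WorldSpec(seed=22, n_countries=2,
                                            n_master_items=120))
    for f in ds.foods.values():
        assert (f.nutrients_per_100g["vitamin_a_retinol"]
                <= f.nutrients_per_100g["vitamin_a_rae"] + 1e-12)


def test_default_world_mostly_feasible(small_world, small_world_solutions):
    share = np.mean([s.is_optimal
                     for _, s, _ in small_world_solutions.values()])
    assert share >= 0.95


def test_fixture_a_values(fixture_a):
    assert fixture_a.expected["cona"] == pytest.approx(7 / 6)


def test_fixture_b_solver_matches_stored_enumeration(fixture_b):
    ds = fixture_b.dataset
    p = cona.assemble_lp(ds.prices_for("B"), ds.foods,
                         fixture_b.requirements, registry=ds.registry)
    sol = solve_cona(p)
    assert sol.status == "optimal"
    assert sol.cona_lcu == pytest.approx(fixture_b.expected["cona"],
                                         rel=1e-10)
    assert "sodium:ub" in sol.binding


def test_unknown_fixture_rejected():
    with pytest.raises(ValueError):
        cona.analytic_fixture("fixtureC")


def test_animal_price_inflation_shifts_diets_to_plants():
    """Pricier animal-source foods push diets toward pulses and produce."""
    ds = cona.generate_world(cona.WorldSpec(seed=33, n_countries=3,
                                            n_master_items=120))
    animal_items = {i for i, f in ds.foods.items() if f.category == ANIMAL}
    inflated = ds.prices.copy()
    mask = inflated["item_id"].isin(animal_items)
    inflated.loc[mask, "price_lcu_per_kg"] *= 4.0
    groups = cona.enumerate_groups()[:4]
    deltas_animal, deltas_plant = [], []
    for cid in ds.country_ids:
        base_prices = ds.prices_for(cid)
        ds_inf = cona.Dataset(foods=ds.foods, prices=inflated,
                              countries=ds.countries, dri=ds.dri,
                              registry=ds.registry)
        inf_prices = ds_inf.prices_for(cid)
        for g in groups:
            reqs = build_requirement_set(g, ds.dri, "EAR")
            s0 = solve_cona(cona.assemble_lp(base_prices, ds.foods, reqs,
                                             country_id=cid))
            s1 = solve_cona(cona.assemble_lp(inf_prices, ds.foods, reqs,
                                             country_id=cid))
            if not (s0.is_optimal and s1.is_optimal):
                continue
            c0 = cona.summarize_composition(s0, ds.foods)
            c1 = cona.summarize_composition(s1, ds.foods)
            deltas_animal.append(c1.grams_day[ANIMAL] - c0.grams_day[ANIMAL])
            deltas_plant.append(
                (c1.grams_day[PULSES] + c1.grams_day[FRUITVEG])
                - (c0.grams_day[PULSES] + c0.grams_day[FRUITVEG])
            )
    assert len(deltas_animal) >= 8
    assert np.mean(deltas_animal) < 0
    assert np.mean(deltas_plant) > 0
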