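"""Loading, validation, round-trips, and category coverage."""

import numpy as np
import pandas as pd
import pytest

import cona
from cona.data_model import RESULT_COLUMNS, load_dataset, read_results
from cona.errors import SchemaError, ValidationError
from cona.nutrients import composition_columns, default_registry


@pytest.fixture(scope="module")
def world_csvs(tmp_path_factory):
    ds = cona.generate_world(cona.WorldSpec(seed=5, n_countries=4,
                                            n_master_items=60))
    outdir = tmp_path_factory.mktemp("world")
    return ds, ds.to_csv(outdir)


def test_registry_structure():
    reg = default_registry()
    assert len(reg) == 20
    lbs = [n for n, d in reg.items() if d.has_lower_bound]
    ubs = [n for n, d in reg.items() if d.has_upper_bound]
    assert len(lbs) == 19 and len(ubs) == 17
    assert "sodium" not in lbs
    assert reg["sodium"].upper_bound_kind == "CDRR"
    for nid in ("vitamin_b12", "riboflavin", "thiamine"):
        assert not reg[nid].has_upper_bound
    amdr = [n for n, d in reg.items() if d.lower_bound_kind == "AMDR"]
    assert sorted(amdr) == ["carbohydrate", "fat", "protein"]
    assert reg["vitamin_a"].lower_key == "vitamin_a_rae"
    assert reg["vitamin_a"].upper_key == "vitamin_a_retinol"


def test_load_round_trip_identity(world_csvs, tmp_path):
    """Load -> write -> load preserves all numeric fields."""
    ds, paths = world_csvs
    loaded = load_dataset(paths["foods"], paths["prices"],
                          paths["countries"], paths["dri"])
    assert set(loaded.foods) == set(ds.foods)
    paths2 = loaded.to_csv(tmp_path / "again")
    reloaded = load_dataset(paths2["foods"], paths2["prices"],
                            paths2["countries"], paths2["dri"])
    for iid, f in ds.foods.items():
        g = reloaded.foods[iid]
        assert g.edible_fraction == pytest.approx(f.edible_fraction, rel=1e-10)
        assert g.energy_per_100g == pytest.approx(f.energy_per_100g, rel=1e-10)
        for k, v in f.nutrients_per_100g.items():
            assert g.nutrients_per_100g[k] == pytest.approx(v, rel=1e-10, abs=1e-12)
    pd.testing.assert_frame_equal(
        reloaded.prices.reset_index(drop=True),
        ds.prices.sort_values(["country_id", "item_id"]).reset_index(drop=True),
    )


def test_duplicate_price_row_rejected(world_csvs, tmp_path):
    _, paths = world_csvs
    df = pd.read_csv(paths["prices"])
    df = pd.concat([df, df.iloc[[0]]])
    bad = tmp_path / "prices.csv"
    df.to_csv(bad, index=False)
    with pytest.raises(ValidationError, match="duplicate"):
        load_dataset(paths["foods"], bad, paths["countries"], paths["dri"])


def test_edible_fraction_out_of_range_rejected(world_csvs, tmp_path):
    _, paths = world_csvs
    df = pd.read_csv(paths["foods"])
    df.loc[0, "edible_fraction"] = 1.2
    bad = tmp_path / "foods.csv"
    df.to_csv(bad, index=False)
    with pytest.raises(ValidationError, match="edible_fraction"):
        load_dataset(bad, paths["prices"], paths["countries"], paths["dri"])


def test_missing_column_is_schema_error(world_csvs, tmp_path):
    _, paths = world_csvs
    df = pd.read_csv(paths["foods"]).drop(columns=["calcium"])
    bad = tmp_path / "foods.csv"
    df.to_csv(bad, index=False)
    with pytest.raises(SchemaError, match="calcium"):
        load_dataset(bad, paths["prices"], paths["countries"], paths["dri"])


def test_missing_values_become_zero_with_warning(world_csvs, tmp_path, caplog):
    _, paths = world_csvs
    df = pd.read_csv(paths["foods"])
    df.loc[0, "calcium"] = np.nan
    bad = tmp_path / "foods.csv"
    df.to_csv(bad, index=False)
    with caplog.at_level("WARNING"):
        ds = load_dataset(bad, paths["prices"], paths["countries"],
                          paths["dri"])
    item = str(df.loc[0, "item_id"])
    assert ds.foods[item].nutrients_per_100g["calcium"] == 0.0
    assert any("missing composition" in r.message for r in caplog.records)


def test_every_composition_column_has_a_registry_nutrient(world_csvs):
    ds, _ = world_csvs
    cols = set(composition_columns(ds.registry))
    keys = {k for f in ds.foods.values() for k in f.nutrients_per_100g}
    assert keys <= cols


def test_category_coverage_flags():
    ds = cona.generate_world(cona.WorldSpec(seed=5, n_countries=3,
                                            n_master_items=60))
    report = cona.validate_category_coverage(ds)
    assert report.fatal == [] and report.missing == {}
    # drop every pulses/nuts/seeds price in one country
    pulse_items = {i for i, f in ds.foods.items()
                   if f.category == "pulses, nuts, and seeds"}
    cid = ds.country_ids[0]
    mask = ~((ds.prices["country_id"] == cid)
             & (ds.prices["item_id"].isin(pulse_items)))
    ds.prices = ds.prices[mask]
    report = cona.validate_category_coverage(ds)
    assert report.flags_for(cid) == ["pulses, nuts, and seeds"]
    # remove the country's prices entirely -> fatal
    ds.prices = ds.prices[ds.prices["country_id"] != cid]
    report = cona.validate_category_coverage(ds)
    assert cid in report.fatal


def test_write_results_round_trip(tmp_path):
    rows = []
    for c in ("c0", "c1"):
        for g in [g.group_id for g in cona.enumerate_groups()]:
            rows.append(dict(
                country_id=c, group_id=g, scenario="EAR", status="optimal",
                cona_lcu_day=1.23456789, cona_usd_day=0.987654321,
                cona_usd_per_1000kcal=0.5, affordability_ratio=0.4,
                n_items=7, binding="energy;calcium:lb",
            ))
    df = pd.DataFrame(rows)
    path = cona.write_results(df, tmp_path / "r.csv")
    back = read_results(path)
    assert len(back) == 40
    assert list(back.columns) == list(RESULT_COLUMNS)
    pd.testing.assert_frame_equal(back, df[list(RESULT_COLUMNS)],
                                  check_dtype=False)


def test_write_results_empty_is_error(tmp_path):
    with pytest.raises(ValidationError):
        cona.write_results(pd.DataFrame(), tmp_path / "r.csv")
    assert not (tmp_path / "r.csv").exists()
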