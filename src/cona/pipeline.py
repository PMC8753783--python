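"""End-to-end pipeline: load -> requirements -> solve -> sensitivity ->
metrics -> stats -> write.

One LP is solved per (country, group, scenario) cell. Infeasible cells —
which occur in practice when a country's priced food list is short — are
recorded with their status rather than dropped, so downstream summaries
can account for them instead of being silently biased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .data_model import Dataset, load_dataset, write_results
from .errors import ValidationError
from .lp_core import assemble_lp, solve_cona
from .requirements import build_requirement_set, enumerate_groups
from .sensitivity import sensitivity_table
from .stats import fe_group_means

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    foods: str | Path
    prices: str | Path
    countries: str | Path
    dri: str | Path
    out_dir: str | Path
    scenario: str = "EAR"  # EAR | RDA | both
    poverty_line_usd_day: float = _metrics.DEFAULT_POVERTY_LINE_USD
    food_share: float = _metrics.DEFAULT_FOOD_SHARE
    binding_rel_tol: float = 1e-6
    verbose: bool = False

    @property
    def scenarios(self) -> tuple[str, ...]:
        if self.scenario == "both":
            return ("EAR", "RDA")
        if self.scenario in ("EAR", "RDA"):
            return (self.scenario,)
        raise ValidationError(f"unknown scenario {self.scenario!r}")


def enumerate_jobs(country_ids, groups, scenarios) -> list[tuple[str, str, str]]:
    """The (country, group, scenario) work list the pipeline will solve."""
    return [
        (c, g.group_id, s)
        for s in scenarios
        for c in sorted(country_ids)
        for g in groups
    ]


@dataclass
class RunSummary:
    n_jobs: int
    n_optimal: int
    n_infeasible: int
    results: pd.DataFrame
    sensitivity: pd.DataFrame
    composition: pd.DataFrame
    group_effects: pd.DataFrame
    files: dict[str, Path] = field(default_factory=dict)


def run_on_dataset(dataset: Dataset, config: RunConfig) -> RunSummary:
    """Solve every cell of a loaded dataset and assemble all outputs."""
    groups = enumerate_groups()
    jobs = enumerate_jobs(dataset.country_ids, groups, config.scenarios)
    reqs_cache = {
        (g.group_id, s): build_requirement_set(
            g, dataset.dri, s, registry=dataset.registry
        )
        for g in groups for s in config.scenarios
    }
    res_rows, sens_frames, comp_rows = [], [], []
    n_opt = n_inf = 0
    prices_cache = {c: dataset.prices_for(c) for c in dataset.country_ids}
    for cid, gid, scen in jobs:
        reqs = reqs_cache[(gid, scen)]
        prices = prices_cache[cid]
        if not prices:
            n_inf += 1
            res_rows.append(dict(
                country_id=cid, group_id=gid, scenario=scen,
                status="no_items", cona_lcu_day=np.nan, cona_usd_day=np.nan,
                cona_usd_per_1000kcal=np.nan, affordability_ratio=np.nan,
                n_items=0, binding="",
            ))
            continue
        problem = assemble_lp(prices, dataset.foods, reqs,
                              registry=dataset.registry, country_id=cid)
        sol = solve_cona(problem, binding_rel_tol=config.binding_rel_tol)
        if not sol.is_optimal:
            n_inf += 1
            res_rows.append(dict(
                country_id=cid, group_id=gid, scenario=scen,
                status=sol.status, cona_lcu_day=np.nan, cona_usd_day=np.nan,
                cona_usd_per_1000kcal=np.nan, affordability_ratio=np.nan,
                n_items=0, binding="",
            ))
            if config.verbose:
                logger.info("%s/%s/%s: %s", cid, gid, scen, sol.status)
            continue
        n_opt += 1
        country = dataset.countries[cid]
        cr = _metrics.cost_record(sol, country, reqs)
        res_rows.append(dict(
            country_id=cid, group_id=gid, scenario=scen, status="optimal",
            cona_lcu_day=cr.cona_lcu_day, cona_usd_day=cr.cona_usd_day,
            cona_usd_per_1000kcal=cr.cona_usd_per_1000kcal,
            affordability_ratio=cr.affordability_ratio,
            n_items=sol.n_selected(),
            binding=";".join(sorted(sol.binding)),
        ))
        st = sensitivity_table(sol)
        st.insert(0, "scenario", scen)
        st.insert(0, "group_id", gid)
        st.insert(0, "country_id", cid)
        sens_frames.append(st)
        comp = _metrics.summarize_composition(sol, dataset.foods)
        cf = comp.to_frame()
        cf.insert(0, "scenario", scen)
        cf.insert(0, "group_id", gid)
        cf.insert(0, "country_id", cid)
        comp_rows.append(cf)
    results = pd.DataFrame(res_rows)
    sensitivity = (pd.concat(sens_frames, ignore_index=True)
                   if sens_frames else pd.DataFrame())
    composition = (pd.concat(comp_rows, ignore_index=True)
                   if comp_rows else pd.DataFrame())
    group_effects = _group_effect_frame(results)
    return RunSummary(
        n_jobs=len(jobs), n_optimal=n_opt, n_infeasible=n_inf,
        results=results, sensitivity=sensitivity, composition=composition,
        group_effects=group_effects,
    )


def _group_effect_frame(results: pd.DataFrame) -> pd.DataFrame:
    """Country-fixed-effects adjusted group means for both cost outcomes."""
    rows = []
    ok = results[results["status"] == "optimal"]
    for scen in ok["scenario"].unique():
        sub = ok[ok["scenario"] == scen]
        for outcome in ("cona_usd_day", "cona_usd_per_1000kcal"):
            panel = sub.rename(columns={outcome: "value"})[
                ["country_id", "group_id", "value"]
            ]
            if panel["country_id"].nunique() < 2 or panel["group_id"].nunique() < 2:
                continue
            try:
                ests = fe_group_means(panel)
            except ValidationError:
                continue
            for e in ests:
                rows.append(dict(
                    outcome=outcome, scenario=scen, group=e.group_id,
                    adjusted_mean=e.adjusted_mean, ci_lower=e.ci_lower,
                    ci_upper=e.ci_upper, n_countries=e.n_countries,
                ))
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunSummary:
    """Load the input CSVs, run every LP, and write all result files."""
    dataset = load_dataset(config.foods, config.prices, config.countries,
                           config.dri)
    summary = run_on_dataset(dataset, config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "results": write_results(summary.results, out / "cona_results.csv"),
    }
    summary.sensitivity.to_csv(out / "sensitivity.csv", index=False)
    files["sensitivity"] = out / "sensitivity.csv"
    summary.composition.to_csv(out / "composition.csv", index=False)
    files["composition"] = out / "composition.csv"
    summary.group_effects.to_csv(out / "group_effects.csv", index=False)
    files["group_effects"] = out / "group_effects.csv"
    log_path = out / "run_log.txt"
    status_counts = summary.results["status"].value_counts().to_dict()
    with open(log_path, "w") as fh:
        fh.write(f"jobs: {summary.n_jobs}\n")
        fh.write(f"optimal: {summary.n_optimal}\n")
        fh.write(f"infeasible_or_failed: {summary.n_infeasible}\n")
        for k, v in sorted(status_counts.items()):
            fh.write(f"status[{k}]: {v}\n")
        bad = summary.results[summary.results["status"] != "optimal"]
        for _, r in bad.iterrows():
            fh.write(
                f"cell {r.country_id}/{r.group_id}/{r.scenario}: {r.status}\n"
            )
    files["log"] = log_path
    summary.files = files
    logger.info("pipeline: %d jobs, %d optimal, %d infeasible",
                summary.n_jobs, summary.n_optimal, summary.n_infeasible)
    return summary
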