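"""Per-group constraint bounds from dietary reference intakes.

A :class:`RequirementSet` holds, for one demographic group and scenario,
the energy equality target (EER, kcal/day), the nutrient lower bounds and
the nutrient upper bounds that the least-cost diet must satisfy.

Scenario rules
--------------
* ``EAR`` (main specification): lower bounds are estimated average
  requirements, meeting the median need of a healthy population.
* ``RDA`` (restrictive): lower bounds are recommended dietary allowances,
  meeting the needs of 97.5% of the population.
* Iron and zinc use the harmonised average requirement (HAR) in place of
  the EAR; under either scenario the bound is ``max(HAR, scenario value)``
  so the bioavailability adjustment survives tightening.
* Macronutrient bounds come from the AMDR energy fractions converted to
  grams/day at 4 kcal/g (carbohydrate, protein) or 9 kcal/g (fat); where a
  gram-denominated average requirement also exists (carbohydrate, protein),
  the lower bound is the max of the two, i.e. both constraints hold.
* Sodium has no lower bound and its upper bound is the CDRR.
* The vitamin A lower bound is accounted in RAE and its upper bound in
  preformed retinol; the split is carried by the nutrient registry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .data_model import AGE_BANDS, REPRODUCTIVE_BANDS, DemographicGroup, DriTable
from .errors import ValidationError
from .nutrients import NutrientDefinition, default_registry

SCENARIOS = ("EAR", "RDA")


def enumerate_groups() -> list[DemographicGroup]:
    """The 20 demographic groups, in stable order.

    Males then females over the seven age bands, then pregnant and
    lactating variants for females aged 14-18, 19-30 and 31-50.
    """
    groups = [
        DemographicGroup(sex=sex, age_band=band)
        for sex in ("male", "female")
        for band in AGE_BANDS
    ]
    groups += [
        DemographicGroup(sex="female", age_band=band, reproductive_status=st)
        for st in ("pregnant", "lactating")
        for band in REPRODUCTIVE_BANDS
    ]
    return groups


def amdr_to_grams(energy_fraction: float, eer: float,
                  kcal_per_gram: float) -> float:
    """Convert an AMDR energy fraction into grams/day at a given EER."""
    if not 0.0 <= energy_fraction <= 1.0:
        raise ValueError(f"energy_fraction {energy_fraction} outside [0, 1]")
    if eer <= 0:
        raise ValueError("eer must be > 0")
    if kcal_per_gram <= 0:
        raise ValueError("kcal_per_gram must be > 0")
    return energy_fraction * eer / kcal_per_gram


@dataclass(frozen=True)
class RequirementSet:
    """Assembled constraint bounds for one group under one scenario."""

    group_id: str
    scenario: str
    eer: float
    lower_bounds: Mapping[str, float]
    upper_bounds: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        if self.eer <= 0:
            raise ValidationError("eer must be > 0")
        for nid, lb in self.lower_bounds.items():
            ub = self.upper_bounds.get(nid)
            if ub is not None and lb > ub:
                raise ValidationError(
                    f"group {self.group_id}, nutrient {nid}: "
                    f"lower bound {lb} exceeds upper bound {ub}"
                )


def validate_requirement_set(reqs: RequirementSet,
                             registry: Mapping[str, NutrientDefinition]) -> None:
    """Check bound counts and routing against a registry.

    For the default registry this enforces 19 lower bounds, 17 upper
    bounds, and no sodium lower bound.
    """
    want_lb = {n for n, d in registry.items() if d.has_lower_bound}
    want_ub = {n for n, d in registry.items() if d.has_upper_bound}
    if set(reqs.lower_bounds) != want_lb:
        raise ValidationError(
            f"lower bounds {sorted(set(reqs.lower_bounds) ^ want_lb)} "
            "do not match registry"
        )
    if set(reqs.upper_bounds) != want_ub:
        raise ValidationError(
            f"upper bounds {sorted(set(reqs.upper_bounds) ^ want_ub)} "
            "do not match registry"
        )


def build_requirement_set(group: DemographicGroup, dri: DriTable,
                          scenario: str = "EAR",
                          registry: Mapping[str, NutrientDefinition] | None = None,
                          ) -> RequirementSet:
    """Construct the bounds for one group from a DRI table.

    Raises :class:`ValidationError` on a missing DRI cell (naming the
    group and nutrient) or on infeasible bounds (lower above upper).
    """
    if scenario not in SCENARIOS:
        raise ValidationError(f"unknown scenario {scenario!r}")
    registry = registry or default_registry()
    gid = group.group_id
    eer = dri.eer(gid)
    scen_col = "ear" if scenario == "EAR" else "rda"
    lower: dict[str, float] = {}
    upper: dict[str, float] = {}
    for nid, nd in registry.items():
        if not (nd.has_lower_bound or nd.has_upper_bound):
            continue
        cell = dri.cell(gid, nid)
        if nd.has_lower_bound:
            base = dri.value(gid, nid, scen_col)
            if nd.lower_bound_kind == "HAR":
                har = dri.value(gid, nid, "har")
                if har is None:
                    raise ValidationError(
                        f"missing har for ({gid}, {nid})"
                    )
                base = max(har, base if base is not None else 0.0)
            if nd.lower_bound_kind == "AMDR" or nd.upper_bound_kind == "AMDR":
                lo_frac = dri.value(gid, nid, "amdr_lower_frac")
                if lo_frac is None:
                    raise ValidationError(
                        f"missing amdr_lower_frac for ({gid}, {nid})"
                    )
                amdr_lo = amdr_to_grams(lo_frac, eer, nd.kcal_per_gram)
                base = max(amdr_lo, base if base is not None else 0.0)
            if base is None:
                raise ValidationError(
                    f"missing {scen_col} for ({gid}, {nid})"
                )
            lower[nid] = base
        if nd.has_upper_bound:
            if nd.upper_bound_kind == "AMDR":
                hi_frac = dri.value(gid, nid, "amdr_upper_frac")
                if hi_frac is None:
                    raise ValidationError(
                        f"missing amdr_upper_frac for ({gid}, {nid})"
                    )
                upper[nid] = amdr_to_grams(hi_frac, eer, nd.kcal_per_gram)
            elif nd.upper_bound_kind == "CDRR":
                cdrr = dri.value(gid, nid, "cdrr_upper")
                if cdrr is None:
                    raise ValidationError(
                        f"missing cdrr_upper for ({gid}, {nid})"
                    )
                upper[nid] = cdrr
            else:
                ul = dri.value(gid, nid, "ul")
                if ul is None:
                    raise ValidationError(f"missing ul for ({gid}, {nid})")
                upper[nid] = ul
    reqs = RequirementSet(
        group_id=gid, scenario=scenario, eer=eer,
        lower_bounds=lower, upper_bounds=upper,
    )
    validate_requirement_set(reqs, registry)
    return reqs
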