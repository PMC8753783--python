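"""Shadow prices and shadow-price elasticities of diet cost.

The shadow price of a constraint is its dual value: the marginal change in
the minimized diet cost per unit change in that requirement, in the
currency of the objective. Non-binding constraints have a shadow price of
zero. The shadow-price elasticity of constraint ``j`` is the percentage
change in the least-cost solution per 1% change in that requirement,

    e_sp(j) = sp_j * rhs_j / CoNA,

which is dimensionless and comparable across currencies and constraints.
Raising a binding upper bound relaxes the problem, so raw upper-bound
elasticities are negative; headline reporting uses their magnitude with
the sign retained alongside.

Elasticities are computed from duals (exact and local). A literal
finite-difference re-solve at rhs*(1 +/- delta) is provided as an
independent verification oracle; the two agree whenever the optimal basis
does not change inside the perturbation interval.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import SolverStateError
from .lp_core import DietSolution, LpProblem, solve_cona


@dataclass(frozen=True)
class ConstraintSensitivity:
    constraint_id: str
    shadow_price: float
    elasticity: float      # signed; NaN when rhs = 0 (undefined)
    magnitude: float       # |elasticity| for upper bounds, else elasticity
    binding: bool
    method: str = "dual"


def shadow_prices(solution: DietSolution) -> dict[str, float]:
    """Dual value per constraint, exactly zero for non-binding rows."""
    if not solution.is_optimal:
        raise SolverStateError(
            f"shadow prices require an optimal solution, got {solution.status!r}"
        )
    return {
        rid: (solution.duals[rid] if rid in solution.binding else 0.0)
        for rid in solution.duals
    }


def shadow_price_elasticity(solution: DietSolution,
                            constraint_id: str) -> float:
    """Signed elasticity ``sp_j * rhs_j / CoNA`` for one constraint.

    Returns NaN (a flagged non-value) when the constraint's bound is zero,
    where a percentage change is undefined.
    """
    sp = shadow_prices(solution)[constraint_id]
    rhs = solution.rhs[constraint_id]
    if rhs == 0:
        return math.nan
    if not solution.cona_lcu or solution.cona_lcu <= 0:
        raise SolverStateError("elasticity undefined for zero-cost solution")
    return sp * rhs / solution.cona_lcu


def finite_difference_elasticity(problem: LpProblem, constraint_id: str,
                                 delta_frac: float = 0.01) -> float:
    """Re-solve oracle: central-difference %dCoNA / %d rhs.

    Perturbs the bound to ``rhs*(1 +/- delta_frac)`` and re-solves. Falls
    back to a one-sided difference with a warning if one side is
    infeasible. Exact (to solver tolerance) whenever no basis change
    occurs in the interval, because the LP value is piecewise linear in
    any single bound.
    """
    if delta_frac <= 0:
        raise ValueError("delta_frac must be > 0")
    base = solve_cona(problem)
    if not base.is_optimal:
        raise SolverStateError("base problem is not optimal")
    rhs0 = problem.rhs[problem.row_index(constraint_id)]
    if rhs0 == 0:
        return math.nan
    c0 = base.cona_lcu
    up = solve_cona(problem.with_rhs(constraint_id, rhs0 * (1 + delta_frac)))
    dn = solve_cona(problem.with_rhs(constraint_id, rhs0 * (1 - delta_frac)))
    if up.is_optimal and dn.is_optimal:
        return (up.cona_lcu - dn.cona_lcu) / c0 / (2 * delta_frac)
    if up.is_optimal:
        warnings.warn(
            f"{constraint_id}: downward perturbation infeasible; "
            "using one-sided difference"
        )
        return (up.cona_lcu - c0) / c0 / delta_frac
    if dn.is_optimal:
        warnings.warn(
            f"{constraint_id}: upward perturbation infeasible; "
            "using one-sided difference"
        )
        return (c0 - dn.cona_lcu) / c0 / delta_frac
    raise SolverStateError(
        f"{constraint_id}: both perturbed problems infeasible"
    )


def sensitivity_table(solution: DietSolution) -> pd.DataFrame:
    """Per-constraint shadow prices and elasticities for one solved diet."""
    if not solution.is_optimal:
        raise SolverStateError("sensitivity requires an optimal solution")
    sp = shadow_prices(solution)
    rows = []
    for rid in solution.rhs:
        e = shadow_price_elasticity(solution, rid)
        is_ub = solution.senses[rid] == "le"
        rows.append(ConstraintSensitivity(
            constraint_id=rid,
            shadow_price=sp[rid],
            elasticity=e,
            magnitude=abs(e) if is_ub else e,
            binding=rid in solution.binding,
        ))
    return pd.DataFrame([vars(r) for r in rows])
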