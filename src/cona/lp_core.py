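"""Least-cost diet linear program: assembly, solution, and duals.

The diet problem for one country ``c`` and demographic group ``g`` is

.. code-block:: text

    min   sum_i  cost_i * x_i                     (cost of the diet)
    s.t.  sum_i  energy_i * x_i  = EER_g          (energy balance, equality)
          sum_i  a_in * x_i     >= LB_ng          (nutrient adequacy)
          sum_i  a_in * x_i     <= UB_ng          (toxicity / AMDR / CDRR)
          x_i >= 0

Decision variables ``x_i`` are in units of 100 g edible portion (matching
how composition tables are expressed); reported quantities are grams/day
(``x * 100``). Prices arrive in local currency units per kg *as purchased*,
so the cost coefficient for item ``i`` is::

    cost_i = price_lcu_per_kg / (10 * edible_fraction)

i.e. LCU per 100 g edible portion.

The solver is HiGHS dual simplex (via :func:`scipy.optimize.linprog`),
chosen because it returns a vertex (basic) optimal solution and exact dual
values; both are needed downstream: shadow prices are constraint duals, and
at a non-degenerate vertex the number of foods selected equals the number
of binding constraints.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .errors import SolverStateError, ValidationError
from .nutrients import NutrientDefinition, default_registry
from .requirements import RequirementSet

#: Feasibility tolerance passed to the solver.
FEASIBILITY_TOL = 1e-9
#: Default relative tolerance for classifying a constraint as binding.
BINDING_REL_TOL = 1e-6

ENERGY_ROW = "energy"


@dataclass(frozen=True)
class LpProblem:
    """An assembled diet LP in natural (>=, <=, =) row orientation."""

    country_id: str
    group_id: str
    item_ids: tuple[str, ...]
    cost: np.ndarray          # LCU per 100 g edible unit, per item
    row_ids: tuple[str, ...]  # "energy", "<nid>:lb", "<nid>:ub"
    senses: tuple[str, ...]   # "eq" | "ge" | "le"
    matrix: np.ndarray        # rows x items, per 100 g edible unit
    rhs: np.ndarray

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def row_index(self, constraint_id: str) -> int:
        try:
            return self.row_ids.index(constraint_id)
        except ValueError:
            raise KeyError(f"unknown constraint {constraint_id!r}")

    def with_rhs(self, constraint_id: str, value: float) -> "LpProblem":
        rhs = self.rhs.copy()
        rhs[self.row_index(constraint_id)] = value
        return replace(self, rhs=rhs)


@dataclass
class DietSolution:
    """Solved diet: quantities in grams/day, objective in LCU/day, duals."""

    country_id: str
    group_id: str
    status: str  # optimal | infeasible | unbounded
    cona_lcu: float | None = None
    quantities: dict[str, float] = field(default_factory=dict)  # grams/day
    duals: dict[str, float] = field(default_factory=dict)  # LCU per rhs unit
    achieved: dict[str, float] = field(default_factory=dict)
    rhs: dict[str, float] = field(default_factory=dict)
    senses: dict[str, str] = field(default_factory=dict)
    binding: set[str] = field(default_factory=set)

    @property
    def is_optimal(self) -> bool:
        return self.status == "optimal"

    def n_selected(self, tol: float = 1e-6) -> int:
        """Number of foods with positive quantity (grams above ``tol``)."""
        return sum(1 for q in self.quantities.values() if q > tol)


def assemble_lp(prices: Mapping[str, float],
                foods: Mapping[str, "FoodItem"],
                reqs: RequirementSet,
                registry: Mapping[str, NutrientDefinition] | None = None,
                country_id: str = "",
                ) -> LpProblem:
    """Build the LP for one country x group.

    ``prices`` maps item_id -> LCU/kg as purchased for the items priced in
    this country; only priced items become variables. Constraint rows are
    the energy equality, then lower bounds, then upper bounds, in registry
    order; the vitamin A lower row reads the RAE composition column and its
    upper row the preformed-retinol column.
    """
    registry = registry or default_registry()
    item_ids = tuple(sorted(set(prices) & set(foods)))
    if not item_ids:
        raise ValidationError(
            f"country {country_id!r}: no priced items to assemble an LP from"
        )
    cost = np.array([
        prices[i] / (10.0 * foods[i].edible_fraction) for i in item_ids
    ])
    rows: list[np.ndarray] = []
    row_ids: list[str] = [ENERGY_ROW]
    senses: list[str] = ["eq"]
    rhs: list[float] = [reqs.eer]
    rows.append(np.array([foods[i].energy_per_100g for i in item_ids]))

    def comp_row(key: str) -> np.ndarray:
        return np.array([
            foods[i].nutrients_per_100g.get(key, 0.0) for i in item_ids
        ])

    for nid, lb in reqs.lower_bounds.items():
        nd = registry[nid]
        rows.append(comp_row(nd.lower_key))
        row_ids.append(f"{nid}:lb")
        senses.append("ge")
        rhs.append(lb)
    for nid, ub in reqs.upper_bounds.items():
        nd = registry[nid]
        rows.append(comp_row(nd.upper_key))
        row_ids.append(f"{nid}:ub")
        senses.append("le")
        rhs.append(ub)
    return LpProblem(
        country_id=country_id, group_id=reqs.group_id,
        item_ids=item_ids, cost=cost,
        row_ids=tuple(row_ids), senses=tuple(senses),
        matrix=np.vstack(rows), rhs=np.array(rhs, dtype=float),
    )


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def solve_cona(problem: LpProblem,
               binding_rel_tol: float = BINDING_REL_TOL) -> DietSolution:
    """Solve the assembled LP and return quantities, duals and binding set.

    Duals are reported as shadow prices in the natural orientation of each
    row: the marginal change of the minimized cost per unit increase of
    that row's bound (so lower-bound duals are >= 0 and upper-bound duals
    are <= 0 at an optimum).
    """
    eq = [s == "eq" for s in problem.senses]
    A_eq = problem.matrix[eq]
    b_eq = problem.rhs[np.array(eq)]
    ub_rows, ub_rhs, ineq_kind = [], [], []
    for sense, row, b in zip(problem.senses, problem.matrix, problem.rhs):
        if sense == "ge":
            ub_rows.append(-row)
            ub_rhs.append(-b)
            ineq_kind.append("ge")
        elif sense == "le":
            ub_rows.append(row)
            ub_rhs.append(b)
            ineq_kind.append("le")
    res = linprog(
        problem.cost,
        A_ub=np.vstack(ub_rows) if ub_rows else None,
        b_ub=np.array(ub_rhs) if ub_rows else None,
        A_eq=A_eq if len(A_eq) else None,
        b_eq=b_eq if len(b_eq) else None,
        bounds=(0, None),
        method="highs-ds",
        options={"primal_feasibility_tolerance": FEASIBILITY_TOL,
                 "dual_feasibility_tolerance": FEASIBILITY_TOL},
    )
    status = _STATUS.get(res.status, "infeasible")
    sol = DietSolution(
        country_id=problem.country_id, group_id=problem.group_id,
        status=status,
    )
    if status != "optimal":
        return sol
    x = np.asarray(res.x)
    sol.cona_lcu = float(res.fun)
    sol.quantities = {
        i: float(q * 100.0) for i, q in zip(problem.item_ids, x)
    }
    achieved = problem.matrix @ x
    sol.achieved = dict(zip(problem.row_ids, map(float, achieved)))
    sol.rhs = dict(zip(problem.row_ids, map(float, problem.rhs)))
    sol.senses = dict(zip(problem.row_ids, problem.senses))
    duals: dict[str, float] = {}
    eq_marg = iter(np.atleast_1d(res.eqlin.marginals) if len(A_eq) else [])
    ineq_marg = iter(
        np.atleast_1d(res.ineqlin.marginals) if ub_rows else []
    )
    kind = iter(ineq_kind)
    for rid, sense in zip(problem.row_ids, problem.senses):
        if sense == "eq":
            duals[rid] = float(next(eq_marg))
        else:
            m = float(next(ineq_marg))
            k = next(kind)
            # marginal is d(obj)/d(b_ub); for a ge-row b_ub = -LB, so flip.
            duals[rid] = -m if k == "ge" else m
    sol.duals = duals
    sol.binding = binding_constraints(sol, rel_tol=binding_rel_tol)
    return sol


def binding_constraints(solution: DietSolution,
                        rel_tol: float = BINDING_REL_TOL) -> set[str]:
    """Constraints satisfied with equality at the optimum.

    A row ``j`` is binding iff ``|achieved_j - rhs_j| <= rel_tol *
    max(1, |rhs_j|)``; equality rows are always included.
    """
    if not solution.is_optimal:
        raise SolverStateError(
            "binding_constraints requires an optimal solution, got "
            f"{solution.status!r}"
        )
    out = set()
    for rid, sense in solution.senses.items():
        if sense == "eq":
            out.add(rid)
            continue
        b = solution.rhs[rid]
        if abs(solution.achieved[rid] - b) <= rel_tol * max(1.0, abs(b)):
            out.add(rid)
    return out


def brute_force_solve(problem: LpProblem, tol: float = 1e-7,
                      ) -> tuple[str, float | None, np.ndarray | None]:
    """Independent vertex-enumeration oracle for small instances.

    Enumerates every basic solution (each choice of ``n`` active
    constraints among the LP rows and the ``x_i >= 0`` bounds, with
    equality rows always active), keeps the feasible ones, and returns the
    minimum-cost vertex. Exponential in problem size: intended for
    verification on instances with a handful of foods, never as the
    production solve path.
    """
    n = problem.n_items
    rows = [problem.matrix[i] for i in range(len(problem.row_ids))]
    rows += [np.eye(n)[i] for i in range(n)]  # x_i = 0 planes
    rhs_all = list(problem.rhs) + [0.0] * n
    eq_idx = [i for i, s in enumerate(problem.senses) if s == "eq"]
    other_idx = [i for i in range(len(rows)) if i not in eq_idx]
    if len(eq_idx) > n:
        return "infeasible", None, None
    best: tuple[float, np.ndarray] | None = None
    found_feasible = False
    for combo in itertools.combinations(other_idx, n - len(eq_idx)):
        active = eq_idx + list(combo)
        A = np.array([rows[i] for i in active])
        b = np.array([rhs_all[i] for i in active])
        try:
            x = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        if not np.all(np.isfinite(x)):
            continue
        if np.any(x < -tol):
            continue
        lhs = problem.matrix @ x
        ok = True
        for sense, v, b_j in zip(problem.senses, lhs, problem.rhs):
            scale = max(1.0, abs(b_j))
            if sense == "eq" and abs(v - b_j) > tol * scale:
                ok = False
            elif sense == "ge" and v < b_j - tol * scale:
                ok = False
            elif sense == "le" and v > b_j + tol * scale:
                ok = False
            if not ok:
                break
        if not ok:
            continue
        found_feasible = True
        obj = float(problem.cost @ np.maximum(x, 0.0))
        if best is None or obj < best[0]:
            best = (obj, np.maximum(x, 0.0))
    if not found_feasible:
        return "infeasible", None, None
    return "optimal", best[0], best[1]
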