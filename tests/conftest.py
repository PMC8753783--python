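import numpy as np
import pytest

import cona
from cona.requirements import build_requirement_set


@pytest.fixture(scope="session")
def fixture_a():
    return cona.analytic_fixture("fixtureA")


@pytest.fixture(scope="session")
def fixture_a_problem(fixture_a):
    ds = fixture_a.dataset
    return cona.assemble_lp(
        ds.prices_for("A"), ds.foods, fixture_a.requirements,
        registry=ds.registry, country_id="A",
    )


@pytest.fixture(scope="session")
def fixture_a_solution(fixture_a_problem):
    return cona.solve_cona(fixture_a_problem)


@pytest.fixture(scope="session")
def fixture_b():
    return cona.analytic_fixture("fixtureB")


@pytest.fixture(scope="session")
def small_world():
    """A 6-country synthetic world for unit-level pipeline tests."""
    return cona.generate_world(cona.WorldSpec(seed=11, n_countries=6))


@pytest.fixture(scope="session")
def small_world_solutions(small_world):
    """Solved EAR-scenario cells of the small world."""
    ds = small_world
    groups = cona.enumerate_groups()
    reqs = {g.group_id: build_requirement_set(g, ds.dri, "EAR")
            for g in groups}
    out = {}
    for c in ds.country_ids:
        prices = ds.prices_for(c)
        for g in groups:
            p = cona.assemble_lp(prices, ds.foods, reqs[g.group_id],
                                 country_id=c)
            out[(c, g.group_id)] = (p, cona.solve_cona(p), reqs[g.group_id])
    return out


def random_small_problem(rng: np.random.Generator) -> cona.LpProblem:
    """Random diet-like LP with <= 4 foods and <= 3 nutrient rows."""
    from cona.lp_core import LpProblem

    n = int(rng.integers(2, 5))
    m = int(rng.integers(1, 4))
    cost = rng.uniform(0.02, 0.5, n)
    energy = rng.uniform(40, 400, n)
    A = rng.uniform(0, 12, (m, n))
    # rhs drawn near an achievable point so many instances are feasible
    x0 = rng.uniform(0, 12, n)
    eer = float(energy @ x0)
    row_ids, senses, rows, rhs = ["energy"], ["eq"], [energy], [eer]
    for j in range(m):
        ach = float(A[j] @ x0)
        if rng.random() < 0.6:
            senses.append("ge")
            rhs.append(ach * rng.uniform(0.3, 1.4))
        else:
            senses.append("le")
            rhs.append(ach * rng.uniform(0.6, 1.7))
        row_ids.append(f"n{j}:{'lb' if senses[-1] == 'ge' else 'ub'}")
        rows.append(A[j])
    return LpProblem(
        country_id="rnd", group_id="g", item_ids=tuple(f"f{i}" for i in range(n)),
        cost=cost, row_ids=tuple(row_ids), senses=tuple(senses),
        matrix=np.vstack(rows), rhs=np.array(rhs),
    )
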