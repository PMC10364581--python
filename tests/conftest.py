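import numpy as np
import pytest

from diabem import WorldConfig, make_world


@pytest.fixture(scope="session")
def small_config():
    """A compact world: 3 locations, 10 age groups, shorter history."""
    return WorldConfig(
        n_locations=3,
        age_group_edges=tuple(float(a) for a in range(0, 101, 10)),
        year_start=1990,
        year_end=2021,
        n_draws=20,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return make_world(small_config)


@pytest.fixture()
def age_edges_20():
    return np.arange(0.0, 101.0, 5.0)


@pytest.fixture()
def smooth_truth(age_edges_20):
    """A smooth illness-death truth representable by the fitting basis."""
    from diabem import solve_illness_death

    edges = age_edges_20
    ages = edges[:-1]
    n = len(ages)
    i = 2e-4 * np.exp(0.035 * ages)
    r = np.full(n, 0.005)
    f = 0.008 * np.exp(0.012 * ages)
    m = 5e-4 * np.exp(0.07 * ages)
    bundle = solve_illness_death(i, r, f, m, edges)
    return {"edges": edges, "ages": ages, "i": i, "r": r, "f": f, "m": m,
            "bundle": bundle}
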