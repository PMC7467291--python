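import numpy as np
import pytest

import nodulecea as nc


@pytest.fixture(scope="session")
def defs():
    return nc.load_parameter_table()


@pytest.fixture(scope="session")
def base_params(defs):
    return nc.draw_parameter_set(defs, probabilistic=False)


@pytest.fixture(scope="session")
def life_table():
    return nc.gompertz_life_table()


@pytest.fixture(scope="session")
def zero_life_table():
    """No background mortality: isolates disease-specific dynamics."""
    return nc.LifeTable(np.zeros(101), source="zero")


@pytest.fixture(scope="session")
def config_a():
    return nc.scenario_config("A")


@pytest.fixture(scope="session")
def config_b():
    return nc.scenario_config("B")


def assert_trace_matches_microsim(
    params, config, life_table, initial, seed=99, n=50_000, check_at=(12, 60, 240)
):
    """Cohort-trace occupancy must agree with an n-individual Monte-Carlo
    simulation of the same per-cycle transition rules within 3 MC standard
    errors at each checked cycle."""
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, initial)
    trace = nc.run_cohort(initial, params, config, life_table)
    for cycle in range(1, max(check_at) + 1):
        M = nc.build_transition_matrix(params, cycle, config, life_table)
        new = np.zeros(nc.STATES.n, dtype=int)
        for s in np.nonzero(counts)[0]:
            new += rng.multinomial(counts[s], np.clip(M[s], 0, None))
        counts = new
        if cycle in check_at:
            frac = counts / n
            p = trace.occupancy[cycle]
            se = np.sqrt(np.clip(p * (1 - p), 0, None) / n)
            assert np.all(np.abs(frac - p) <= 3 * se + 5.0 / n), f"cycle {cycle}"


@pytest.fixture(scope="session")
def base_results(base_params, config_a, config_b, life_table):
    """Deterministic base-case results for both strategies and scenarios."""
    surv, aabt_a = nc.evaluate_both(base_params, config_a, life_table)
    _, aabt_b = nc.evaluate_both(base_params, config_b, life_table)
    aabt_b = nc.StrategyResult("AABT+Surveillance (B)", aabt_b.cost, aabt_b.qaly)
    return {"surv": surv, "aabt_a": aabt_a, "aabt_b": aabt_b}
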