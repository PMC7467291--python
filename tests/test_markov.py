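"""Markov engine: matrix assembly, cohort propagation, discounting and
half-cycle-corrected accumulation."""

import numpy as np
import pytest

import nodulecea as nc
from nodulecea.markov import (
    STATES,
    CohortTrace,
    build_cause_matrix,
    state_utility_matrix,
)
from nodulecea.strategies import apply_initial_test_split

ZERO_CAUSE = dict(
    growth_first_month=0.0, growth_subsequent=0.0, progression_monthly=0.0,
    undiag_malignant_mortality=0.0,
    **{f"distant_mortality_y{i}": 0.0 for i in range(1, 5)},
    **{f"local_mortality_y{i}": 0.0 for i in range(1, 5)},
    **{f"regional_mortality_y{i}": 0.0 for i in range(1, 5)},
)


def surveillance_initial(params):
    v, _, _ = apply_initial_test_split(
        params["prevalence"],
        (params["stage_local"], params["stage_regional"]),
        None,
        params,
    )
    return v


class TestTransitionMatrix:
    def test_rows_sum_to_one_across_cycles(self, base_params, config_a, life_table):
        for cycle in (1, 2, 3, 13, 37, 120, 300, 456):
            M = nc.build_transition_matrix(base_params, cycle, config_a, life_table)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(M >= 0)

    def test_event_tree_composition(self, base_params, config_a, zero_life_table):
        """Progression and cause mortality compose as independent events."""
        M = nc.build_transition_matrix(base_params, 5, config_a, zero_life_table)
        s = STATES
        p = base_params["progression_monthly"]
        m = base_params["undiag_malignant_mortality"]
        assert M[s.UNDIAG_LOCAL, s.UNDIAG_REGIONAL] == pytest.approx(p * (1 - m))
        assert M[s.UNDIAG_LOCAL, s.DEAD] == pytest.approx(m)
        assert M[s.UNDIAG_LOCAL, s.UNDIAG_LOCAL] == pytest.approx((1 - p) * (1 - m))
        assert M[s.UNDIAG_REGIONAL, s.undiag_distant[0]] == pytest.approx(p * (1 - m))

    def test_zeroed_probabilities_leave_only_scheduled_moves(
        self, base_params, config_a, zero_life_table
    ):
        ps = base_params.replace(**ZERO_CAUSE)
        M = nc.build_transition_matrix(ps, 2, config_a, zero_life_table)
        s = STATES
        # static states self-loop
        for i in (s.UNDIAG_BENIGN, s.UNDIAG_LOCAL, s.UNDIAG_REGIONAL,
                  s.DIAG_BENIGN, s.DISEASE_FREE, s.DEAD):
            assert M[i, i] == 1.0
        # tunnels still advance deterministically
        assert M[s.diag_local[0], s.diag_local[1]] == 1.0
        assert M[s.diag_local[-1], s.DISEASE_FREE] == 1.0
        assert M[s.diag_distant[-1], s.diag_distant[-1]] == 1.0

    def test_tunnel_mortality_by_year(self, base_params, config_a, zero_life_table):
        M = nc.build_transition_matrix(base_params, 2, config_a, zero_life_table)
        s = STATES
        # distant tunnel months 1, 13, 25, 37 and the 49+ bucket
        expected = [0.1255, 0.0670, 0.0589, 0.0150, 0.0150]
        months = [0, 12, 24, 36, 48]
        for k, e in zip(months, expected):
            assert M[s.undiag_distant[k], s.DEAD] == pytest.approx(e)
            assert M[s.diag_distant[k], s.DEAD] == pytest.approx(e)
        assert M[s.diag_local[0], s.DEAD] == pytest.approx(0.0106)
        assert M[s.diag_regional[36], s.DEAD] == pytest.approx(0.0155)

    def test_rejects_cycle_zero(self, base_params, config_a, life_table):
        with pytest.raises(ValueError):
            nc.build_transition_matrix(base_params, 0, config_a, life_table)


class TestRunCohort:
    def test_dead_cohort_is_absorbing(self, base_params, config_a, life_table):
        v = STATES.zeros()
        v[STATES.DEAD] = 1.0
        trace = nc.run_cohort(v, base_params, config_a, life_table)
        assert np.all(trace.occupancy[:, STATES.DEAD] == 1.0)

    def test_distant_cohort_geometric_survival(
        self, base_params, config_a, zero_life_table
    ):
        v = STATES.zeros()
        v[STATES.undiag_distant[0]] = 1.0
        trace = nc.run_cohort(v, base_params, config_a, zero_life_table)
        alive = 1.0 - trace.occupancy[12, STATES.DEAD]
        assert alive == pytest.approx((1 - 0.1255) ** 12, abs=1e-12)

    def test_mass_conserved_and_death_monotone(
        self, base_params, config_a, life_table
    ):
        trace = nc.run_cohort(
            surveillance_initial(base_params), base_params, config_a, life_table
        )
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        dead = trace.occupancy[:, STATES.DEAD]
        assert np.all(np.diff(dead) >= -1e-12)

    def test_matches_explicit_matrix_products(
        self, base_params, config_a, life_table
    ):
        v = surveillance_initial(base_params)
        trace = nc.run_cohort(v, base_params, config_a, life_table)
        w = v.copy()
        for cycle in range(1, 30):
            M = nc.build_transition_matrix(base_params, cycle, config_a, life_table)
            w = w @ M
            np.testing.assert_allclose(trace.occupancy[cycle], w, atol=1e-12)

    def test_rejects_unnormalised_initial(self, base_params, config_a, life_table):
        with pytest.raises(ValueError):
            nc.run_cohort(STATES.zeros(), base_params, config_a, life_table)

    def test_agrees_with_individual_microsimulation(
        self, base_params, config_a, life_table
    ):
        """Cohort trace vs a 50,000-individual Monte-Carlo simulation of the
        same per-cycle transition rules."""
        from tests.conftest import assert_trace_matches_microsim

        assert_trace_matches_microsim(
            base_params, config_a, life_table, surveillance_initial(base_params)
        )


class TestDiscountingAndAccumulation:
    def test_discount_factor(self):
        assert nc.discount_factor(0, 0.035) == 1.0
        assert nc.discount_factor(12, 0.035) == pytest.approx(1 / 1.035)
        assert nc.discount_factor(24, 0.035) == pytest.approx(
            nc.discount_factor(12, 0.035) ** 2
        )

    def test_full_health_no_discount_gives_horizon_years(
        self, base_params, config_a, zero_life_table
    ):
        import dataclasses

        cfg = dataclasses.replace(config_a, discount_rate_annual=0.0)
        ps = base_params.replace(**ZERO_CAUSE)
        v = STATES.zeros()
        v[STATES.UNDIAG_BENIGN] = 1.0
        trace = nc.run_cohort(v, ps, cfg, zero_life_table)
        _, qaly = nc.accumulate_outcomes(trace, np.ones(STATES.n), cfg)
        assert qaly == pytest.approx(38.0, abs=1e-9)

    def test_geometric_closed_form(self, config_a):
        """Constant survival p, utility u, discount f: the half-cycle sum has
        a closed geometric form."""
        T = config_a.n_cycles
        p, u = 0.99, 0.8
        occ = np.zeros((T + 1, STATES.n))
        occ[:, STATES.DISEASE_FREE] = p ** np.arange(T + 1)
        occ[:, STATES.DEAD] = 1.0 - occ[:, STATES.DISEASE_FREE]
        trace = CohortTrace(occ, 62, np.zeros(T + 1), np.zeros(T + 1))
        utilities = np.zeros(STATES.n)
        utilities[STATES.DISEASE_FREE] = u
        _, qaly = nc.accumulate_outcomes(trace, utilities, config_a)
        f = 1.035 ** (-1 / 12)
        x = p * f
        expected = u / 12 * ((1 - x ** (T + 1)) / (1 - x) - 0.5 * (1 + x**T))
        assert qaly == pytest.approx(expected, rel=1e-12)

    def test_half_cycle_brackets_endpoint_conventions(
        self, base_params, config_a, life_table
    ):
        trace = nc.run_cohort(
            surveillance_initial(base_params), base_params, config_a, life_table
        )
        U = state_utility_matrix(base_params, config_a, trace.n_cycles)
        _, half = nc.accumulate_outcomes(trace, U, config_a)
        df = nc.discount_factor(np.arange(trace.n_cycles + 1), 0.035)
        per_cycle = (trace.occupancy * U).sum(axis=1) / 12 * df
        start = per_cycle[:-1].sum()
        end = per_cycle[1:].sum()
        assert min(start, end) <= half <= max(start, end)

    def test_life_expectancy_matches_life_table_closed_form(
        self, base_params, config_a, life_table
    ):
        """With all disease off, engine life-years equal the life-table-only
        monthly closed form."""
        import dataclasses

        cfg = dataclasses.replace(config_a, discount_rate_annual=0.0)
        ps = base_params.replace(prevalence=0.0, **ZERO_CAUSE)
        v = STATES.zeros()
        v[STATES.UNDIAG_BENIGN] = 1.0
        trace = nc.run_cohort(v, ps, cfg, life_table)
        utilities = np.ones(STATES.n)
        utilities[STATES.DEAD] = 0.0
        _, ly = nc.accumulate_outcomes(trace, utilities, cfg)

        T = cfg.n_cycles
        surv = np.ones(T + 1)
        for t in range(1, T + 1):
            qm = life_table.monthly_qx(62 + (t - 1) // 12)
            surv[t] = surv[t - 1] * (1 - qm)
        w = np.ones(T + 1)
        w[0] = w[-1] = 0.5
        expected = (w * surv).sum() / 12
        assert ly == pytest.approx(expected, abs=1e-6)


class TestUtilities:
    def test_age_bands_switch_at_65_and_75(self, base_params, config_a):
        U = state_utility_matrix(base_params, config_a, config_a.n_cycles)
        s = STATES
        assert U[35, s.UNDIAG_BENIGN] == pytest.approx(0.810)  # age 64.9
        assert U[36, s.UNDIAG_BENIGN] == pytest.approx(0.773)  # age exactly 65
        assert U[156, s.UNDIAG_BENIGN] == pytest.approx(0.703)  # age exactly 75
        assert np.all(U[:, s.DEAD] == 0.0)

    def test_cancer_utilities_capped_by_age_norm(self, base_params, config_a):
        U = state_utility_matrix(base_params, config_a, config_a.n_cycles)
        s = STATES
        # local utility 0.71 < norms before 75; capped to 0.703 after 75
        assert U[0, s.diag_local[0]] == pytest.approx(0.71)
        assert U[200, s.diag_local[0]] == pytest.approx(0.703)
        assert U[0, s.diag_distant[0]] == pytest.approx(0.62)

    def test_undiagnosed_utility_toggle(self, base_params, config_a):
        import dataclasses

        cfg = dataclasses.replace(config_a, undiag_cancer_utility=False)
        U = state_utility_matrix(base_params, cfg, cfg.n_cycles)
        assert U[0, STATES.UNDIAG_LOCAL] == pytest.approx(0.810)
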