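"""Monthly-cycle Markov cohort engine for the nodule-management model.

Health states follow the natural history of an indeterminate pulmonary
nodule: undiagnosed benign (with a latent "growth observed" flag),
undiagnosed malignant at local/regional/distant stage, diagnosed
(post-treatment) states carrying a months-since-diagnosis tunnel index,
a post-surgical-biopsy diagnosed-benign state, disease-free, and death.

Diagnosed local/regional patients face time-dependent excess mortality for
60 tunnel months and then exit to disease-free (the 5-year disease-free
assumption).  Distant-stage patients (diagnosed or not) face tunnel
mortality that continues at the final (37–48 month) level for life.
Undiagnosed local/regional patients face a constant excess mortality and a
monthly probability of stage progression.  Background all-cause mortality
is composed with all cause-specific risks competing-risk style each cycle.

Within a cycle the event order is: scheduled detection events (applied by
the strategy layer through an event hook), disease progression, cause-
specific mortality, background mortality.  Progression and cause-specific
mortality compose as independent within-cycle events, so e.g. from
undiagnosed local the probability of reaching undiagnosed regional is
p_prog·(1 − p_mort).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .parameters import ParameterSet, ScenarioConfig
from .simdata import LifeTable

DISTANT_TUNNEL = 49  # months 1..48 explicitly, then a "49+" bucket
DIAG_TUNNEL = 60  # 5 years of excess risk, then disease-free


class StateSpace:
    """Enumerates the engine's states and index ranges."""

    def __init__(self) -> None:
        names = ["UndiagBenign", "UndiagBenignGrown", "UndiagLocal", "UndiagRegional"]
        self.UNDIAG_BENIGN = 0
        self.UNDIAG_BENIGN_GROWN = 1
        self.UNDIAG_LOCAL = 2
        self.UNDIAG_REGIONAL = 3
        self.undiag_distant = np.arange(len(names), len(names) + DISTANT_TUNNEL)
        names += [f"UndiagDistant_m{k + 1}" for k in range(DISTANT_TUNNEL)]
        self.diag_local = np.arange(len(names), len(names) + DIAG_TUNNEL)
        names += [f"DiagLocal_m{k + 1}" for k in range(DIAG_TUNNEL)]
        self.diag_regional = np.arange(len(names), len(names) + DIAG_TUNNEL)
        names += [f"DiagRegional_m{k + 1}" for k in range(DIAG_TUNNEL)]
        self.diag_distant = np.arange(len(names), len(names) + DISTANT_TUNNEL)
        names += [f"DiagDistant_m{k + 1}" for k in range(DISTANT_TUNNEL)]
        self.DIAG_BENIGN = len(names)
        names.append("DiagBenign")
        self.DISEASE_FREE = len(names)
        names.append("DiseaseFree")
        self.DEAD = len(names)
        names.append("Dead")
        self.names = names
        self.n = len(names)
        self.index = {name: i for i, name in enumerate(names)}
        self.alive = np.array([i != self.DEAD for i in range(self.n)])
        # states still on the CT surveillance schedule
        self.surveillance = np.concatenate(
            [
                [self.UNDIAG_BENIGN, self.UNDIAG_BENIGN_GROWN,
                 self.UNDIAG_LOCAL, self.UNDIAG_REGIONAL],
                self.undiag_distant,
            ]
        )

    def zeros(self) -> np.ndarray:
        return np.zeros(self.n)


STATES = StateSpace()


def _tunnel_rates(y1: float, y2: float, y3: float, y4: float, length: int) -> np.ndarray:
    """Monthly mortality by tunnel month: yearly bands, year-4 value carried
    forward for any months beyond 48."""
    per_year = [y1, y2, y3, y4]
    rates = np.empty(length)
    for k in range(length):
        rates[k] = per_year[min(k // 12, 3)]
    return rates


def distant_tunnel_rates(params: ParameterSet) -> np.ndarray:
    return _tunnel_rates(
        params["distant_mortality_y1"], params["distant_mortality_y2"],
        params["distant_mortality_y3"], params["distant_mortality_y4"],
        DISTANT_TUNNEL,
    )


def build_cause_matrix(params: ParameterSet, first_cycle: bool = False) -> np.ndarray:
    """Cause-specific (no background mortality) transition matrix."""
    s = STATES
    M = np.zeros((s.n, s.n))

    g = params["growth_first_month"] if first_cycle else params["growth_subsequent"]
    M[s.UNDIAG_BENIGN, s.UNDIAG_BENIGN_GROWN] = g
    M[s.UNDIAG_BENIGN, s.UNDIAG_BENIGN] = 1.0 - g
    M[s.UNDIAG_BENIGN_GROWN, s.UNDIAG_BENIGN_GROWN] = 1.0

    m = params["undiag_malignant_mortality"]
    p = params["progression_monthly"]
    M[s.UNDIAG_LOCAL, s.DEAD] = m
    M[s.UNDIAG_LOCAL, s.UNDIAG_REGIONAL] = p * (1.0 - m)
    M[s.UNDIAG_LOCAL, s.UNDIAG_LOCAL] = (1.0 - p) * (1.0 - m)
    M[s.UNDIAG_REGIONAL, s.DEAD] = m
    M[s.UNDIAG_REGIONAL, s.undiag_distant[0]] = p * (1.0 - m)
    M[s.UNDIAG_REGIONAL, s.UNDIAG_REGIONAL] = (1.0 - p) * (1.0 - m)

    dist = distant_tunnel_rates(params)
    for block in (s.undiag_distant, s.diag_distant):
        nxt = np.minimum(np.arange(1, DISTANT_TUNNEL + 1), DISTANT_TUNNEL - 1)
        M[block, s.DEAD] = dist
        M[block, block[nxt]] += 1.0 - dist

    loc = _tunnel_rates(
        params["local_mortality_y1"], params["local_mortality_y2"],
        params["local_mortality_y3"], params["local_mortality_y4"], DIAG_TUNNEL,
    )
    reg = _tunnel_rates(
        params["regional_mortality_y1"], params["regional_mortality_y2"],
        params["regional_mortality_y3"], params["regional_mortality_y4"], DIAG_TUNNEL,
    )
    for block, rates in ((s.diag_local, loc), (s.diag_regional, reg)):
        M[block, s.DEAD] = rates
        M[block[:-1], block[1:]] = 1.0 - rates[:-1]
        M[block[-1], s.DISEASE_FREE] = 1.0 - rates[-1]

    M[s.DIAG_BENIGN, s.DIAG_BENIGN] = 1.0
    M[s.DISEASE_FREE, s.DISEASE_FREE] = 1.0
    M[s.DEAD, s.DEAD] = 1.0
    return M


def _apply_background(M: np.ndarray, qm: float) -> np.ndarray:
    """Compose background mortality with a cause-specific matrix."""
    s = STATES
    out = M.copy()
    out[s.alive, :] *= 1.0 - qm
    out[s.alive, s.DEAD] += qm
    return out


def build_transition_matrix(
    params: ParameterSet,
    cycle: int,
    config: ScenarioConfig,
    life_table: LifeTable,
    strategy_context=None,
) -> np.ndarray:
    """Full row-stochastic transition matrix for a given cycle.

    Scheduled detection events are not part of the matrix; the strategy
    layer applies them as an event hook before the cycle's transition
    (``strategy_context`` is accepted for interface completeness).
    """
    if cycle < 1:
        raise ValueError("cycle must be >= 1")
    age = config.start_age + (cycle - 1) // 12
    qm = life_table.monthly_qx(age)
    M = _apply_background(build_cause_matrix(params, first_cycle=(cycle == 1)), qm)
    rowsum = M.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > 1e-9):
        bad = int(np.argmax(np.abs(rowsum - 1.0)))
        raise RuntimeError(
            f"transition row {STATES.names[bad]} sums to {rowsum[bad]!r}"
        )
    return M


@dataclass
class CohortTrace:
    """Cycle-by-state occupancy of the cohort plus per-cycle event flows."""

    occupancy: np.ndarray  # (n_cycles + 1, n_states)
    start_age: float
    event_costs: np.ndarray  # undiscounted GBP per cycle (per cohort member)
    event_qalys: np.ndarray  # undiscounted QALY adjustments per cycle

    def __post_init__(self) -> None:
        rowsum = self.occupancy.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-9):
            raise ValueError("occupancy rows must each sum to 1")
        if np.any(self.occupancy < -1e-12):
            raise ValueError("occupancy must be non-negative")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def ages(self) -> np.ndarray:
        return self.start_age + np.arange(self.occupancy.shape[0]) / 12.0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=STATES.names)
        df.insert(0, "cycle", np.arange(self.occupancy.shape[0]))
        df.insert(1, "age", self.ages())
        df["event_cost"] = self.event_costs
        df["event_qaly"] = self.event_qalys
        return df


EventHook = Callable[[int, np.ndarray], tuple[np.ndarray, float, float]]


def run_cohort(
    initial: np.ndarray,
    params: ParameterSet,
    config: ScenarioConfig,
    life_table: LifeTable,
    event_hook: EventHook | None = None,
    event_cycles: Iterable[int] = (),
) -> CohortTrace:
    """Propagate the cohort from cycle 0 to the lifetime horizon.

    ``event_hook(cycle, state_vector)`` is called at the start of each
    cycle in ``event_cycles`` (scheduled scans) and must return the
    redistributed state vector plus the event's undiscounted cost and QALY
    adjustment per initial cohort member.
    """
    initial = np.asarray(initial, dtype=float)
    if initial.shape != (STATES.n,):
        raise ValueError(f"initial must have shape ({STATES.n},)")
    if abs(initial.sum() - 1.0) > 1e-9 or np.any(initial < -1e-12):
        raise ValueError("initial state distribution must be a probability vector")

    T = config.n_cycles
    event_set = set(event_cycles)
    trace = np.zeros((T + 1, STATES.n))
    event_costs = np.zeros(T + 1)
    event_qalys = np.zeros(T + 1)
    trace[0] = initial

    Mc_first = build_cause_matrix(params, first_cycle=True)
    Mc = build_cause_matrix(params, first_cycle=False)
    alive = STATES.alive
    dead = STATES.DEAD

    v = initial.copy()
    for t in range(1, T + 1):
        if event_hook is not None and t in event_set:
            v, c, q = event_hook(t, v)
            event_costs[t] += c
            event_qalys[t] += q
        age = config.start_age + (t - 1) // 12
        qm = life_table.monthly_qx(age)
        w = v @ (Mc_first if t == 1 else Mc)
        alive_mass = w[alive].sum()
        w[alive] *= 1.0 - qm
        w[dead] += alive_mass * qm
        v = w
        trace[t] = v

    return CohortTrace(
        occupancy=trace,
        start_age=config.start_age,
        event_costs=event_costs,
        event_qalys=event_qalys,
    )


def discount_factor(cycle, annual_rate: float):
    """Per-cycle discount factor (1 + r)^(−cycle/12)."""
    return (1.0 + annual_rate) ** (-np.asarray(cycle, dtype=float) / 12.0)


def state_utility_matrix(
    params: ParameterSet, config: ScenarioConfig, n_cycles: int
) -> np.ndarray:
    """Per-cycle per-state utilities.

    Age-band population norms switch exactly at ages 65 and 75; cancer
    states take the stage-specific utility capped by the age norm.  The
    undiagnosed-malignant toggle selects cancer vs age-norm utility for
    undetected disease.
    """
    s = STATES
    ages = config.start_age + np.arange(n_cycles + 1) / 12.0
    norm = np.where(
        ages < 65.0,
        params["util_age_55_64"],
        np.where(ages < 75.0, params["util_age_65_74"], params["util_age_75plus"]),
    )
    U = np.tile(norm[:, None], (1, s.n))
    local = np.minimum(params["util_local"], norm)
    regional = np.minimum(params["util_regional"], norm)
    distant = np.minimum(params["util_distant"], norm)
    U[:, s.diag_local] = local[:, None]
    U[:, s.diag_regional] = regional[:, None]
    U[:, s.diag_distant] = distant[:, None]
    if config.undiag_cancer_utility:
        U[:, s.UNDIAG_LOCAL] = local
        U[:, s.UNDIAG_REGIONAL] = regional
        U[:, s.undiag_distant] = distant[:, None]
    U[:, s.DEAD] = 0.0
    return U


def accumulate_outcomes(
    trace: CohortTrace,
    state_utilities: np.ndarray,
    config: ScenarioConfig,
    state_costs: np.ndarray | None = None,
) -> tuple[float, float]:
    """Lifetime discounted (cost, QALY) totals with half-cycle correction.

    State-occupancy rewards (utility/12 per monthly cycle, plus any
    per-cycle state costs) receive half weight at the first and terminal
    cycles; event-triggered costs and QALY adjustments recorded on the
    trace are added in full at their cycle of occurrence.
    """
    T = trace.n_cycles
    t = np.arange(T + 1)
    df = discount_factor(t, config.discount_rate_annual)
    w = np.ones(T + 1)
    w[0] = w[-1] = 0.5

    if state_utilities.ndim == 1:
        state_utilities = np.tile(state_utilities, (T + 1, 1))
    per_cycle_qaly = (trace.occupancy * state_utilities).sum(axis=1) / 12.0
    qaly = float((w * df * per_cycle_qaly).sum() + (df * trace.event_qalys).sum())

    cost = float((df * trace.event_costs).sum())
    if state_costs is not None:
        if state_costs.ndim == 1:
            state_costs = np.tile(state_costs, (T + 1, 1))
        cost += float((w * df * (trace.occupancy * state_costs).sum(axis=1)).sum())
    return cost, qaly
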