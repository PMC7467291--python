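"""Testing pathways: the upfront blood-test decision tree and the CT
surveillance schedule, wired into the Markov cohort engine.

Two strategies are compared for a cohort presenting with an indeterminate
pulmonary nodule:

* **Surveillance** — CT scans at 3, 12 and 24 months.  Observed growth in
  a benign nodule triggers surgical biopsy; a detected malignant nodule is
  confirmed by guided needle biopsy and treated with surgery.  After the
  24-month scan with no growth the patient is discharged.
* **AABT+Surveillance** — an upfront autoantibody blood test.  Positives
  are referred to a multidisciplinary team and receive a guided needle
  biopsy (assumed perfectly accurate): confirmed malignancies go straight
  to surgery, benign results return to the surveillance schedule.
  Negatives follow the surveillance schedule.

Every positive finding is charged a multidisciplinary-team review.  Each
guided needle biopsy carries a small mortality risk and a probability of a
serious adverse event costing 0.2 utility for one month.  Surgery carries
stage-independent mortality and complication risks; complications,
radiotherapy and chemotherapy enter as expected costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import AccuracyPair
from .markov import (
    STATES,
    CohortTrace,
    accumulate_outcomes,
    run_cohort,
    state_utility_matrix,
)
from .parameters import ParameterSet, ScenarioConfig
from .simdata import LifeTable


@dataclass(frozen=True)
class StrategyDefinition:
    """A named testing pathway."""

    name: str
    scan_months: tuple[int, ...] = (3, 12, 24)
    test: AccuracyPair | None = None
    test_price: float = 0.0

    def __post_init__(self) -> None:
        if tuple(sorted(self.scan_months)) != tuple(self.scan_months):
            raise ValueError("scan months must be strictly increasing")


@dataclass
class EventOutcome:
    """Expected consequences of a testing event for one person."""

    expected_cost: float
    expected_qaly_decrement: float
    mortality_probability: float
    state_split: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.state_split.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state split sums to {total}, not 1")


@dataclass
class StrategyResult:
    """Lifetime discounted cost and QALYs for one strategy."""

    name: str
    cost: float
    qaly: float
    trace: CohortTrace | None = None


def surveillance_strategy(config: ScenarioConfig) -> StrategyDefinition:
    return StrategyDefinition("Surveillance", config.scan_months)

def aabt_strategy(config: ScenarioConfig) -> StrategyDefinition:
    return StrategyDefinition(
        "AABT+Surveillance",
        config.scan_months,
        test=config.aabt_accuracy,
        test_price=config.test_price,
    )


def expected_surgery_outcome(malignant: bool, params: ParameterSet) -> EventOutcome:
    """Expected cost, mortality and destination of a surgical episode.

    Malignant surgery costs are complication-weighted plus expected
    adjuvant radiotherapy/chemotherapy; survivors go to the diagnosed
    state of their pre-surgical stage (resolved by the caller).  A benign
    episode is the surgical biopsy performed after observed growth;
    survivors are diagnosed benign.
    """
    if malignant:
        comp = params["surgery_complication_malignant"]
        cost = (
            (1.0 - comp) * params["cost_surgery_no_comp"]
            + comp * params["cost_surgery_comp"]
            + params["prop_radiotherapy"] * params["cost_radiotherapy"]
            + params["prop_chemotherapy"] * params["cost_chemotherapy"]
        )
        mort = params["surgery_mortality_malignant"]
        split = {"ByStage": 1.0 - mort, "Dead": mort}
    else:
        comp = params["surgery_complication_benign"]
        cost = (
            (1.0 - comp) * params["cost_surgical_biopsy_no_comp"]
            + comp * params["cost_surgical_biopsy_comp"]
        )
        mort = params["surgery_mortality_benign"]
        split = {"DiagBenign": 1.0 - mort, "Dead": mort}
    return EventOutcome(
        expected_cost=cost,
        expected_qaly_decrement=0.0,
        mortality_probability=mort,
        state_split=split,
    )


def apply_initial_test_split(
    prevalence: float,
    stage_split: tuple[float, float],
    test: AccuracyPair | None,
    params: ParameterSet,
    test_price: float | None = None,
) -> tuple[np.ndarray, float, float]:
    """Initial state distribution plus upfront cost and QALY adjustment.

    With ``test=None`` (surveillance alone) the whole cohort enters the
    scan schedule at no upfront cost.  With an accuracy pair, positives
    (true: prevalence×sens, false: (1−prevalence)×(1−spec)) receive MDT
    review and guided needle biopsy; biopsy-confirmed malignancies go to
    surgery, biopsy-benign results and all negatives enter surveillance.
    """
    if not 0.0 <= prevalence < 1.0:
        raise ValueError("prevalence must be in [0, 1)")
    local_share, regional_share = stage_split
    if abs(local_share + regional_share - 1.0) > 1e-9:
        raise ValueError("stage split must sum to 1")

    s = STATES
    v = s.zeros()
    prev_local = prevalence * local_share
    prev_regional = prevalence * regional_share
    benign = 1.0 - prevalence

    if test is None:
        v[s.UNDIAG_LOCAL] = prev_local
        v[s.UNDIAG_REGIONAL] = prev_regional
        v[s.UNDIAG_BENIGN] = benign
        return v, 0.0, 0.0

    if test_price is None:
        test_price = params["cost_aabt"]
    sens, spec = test.sensitivity, test.specificity
    bm = params["biopsy_mortality"]
    sae = params["biopsy_complication"]
    dec = params["util_decrement_biopsy_sae"]

    tp_local = prev_local * sens
    tp_regional = prev_regional * sens
    fp = benign * (1.0 - spec)
    positives = tp_local + tp_regional + fp

    cost = test_price + positives * (params["cost_mdt"] + params["cost_needle_biopsy"])
    qaly_adj = -positives * sae * dec / 12.0
    dead = positives * bm

    surgery = expected_surgery_outcome(True, params)
    for tp, diag_block in ((tp_local, s.diag_local), (tp_regional, s.diag_regional)):
        survivors = tp * (1.0 - bm)
        cost += survivors * surgery.expected_cost
        dead += survivors * surgery.mortality_probability
        v[diag_block[0]] += survivors * (1.0 - surgery.mortality_probability)

    v[s.UNDIAG_BENIGN] = benign - fp + fp * (1.0 - bm)  # false positives return
    v[s.UNDIAG_LOCAL] = prev_local - tp_local
    v[s.UNDIAG_REGIONAL] = prev_regional - tp_regional
    v[s.DEAD] = dead

    total = v.sum()
    if abs(total - 1.0) > 1e-9:
        raise RuntimeError(f"initial split sums to {total!r}")
    return v, cost, qaly_adj


def _scan_outcomes(params: ParameterSet) -> dict[str, EventOutcome]:
    """Expected per-person consequences of one scheduled CT scan, by the
    state occupied when the scan happens."""
    c_ct = params["cost_ct_scan"]
    c_mdt = params["cost_mdt"]
    c_nb = params["cost_needle_biopsy"]
    sens = params["ct_sensitivity"]
    spec = params["ct_specificity"]
    bm = params["biopsy_mortality"]
    sae = params["biopsy_complication"]
    dec = params["util_decrement_biopsy_sae"]

    fp = 1.0 - spec
    benign_surgery = expected_surgery_outcome(False, params)
    malignant_surgery = expected_surgery_outcome(True, params)

    out: dict[str, EventOutcome] = {}
    mort = fp * bm
    out["benign_not_grown"] = EventOutcome(
        expected_cost=c_ct + fp * (c_mdt + c_nb),
        expected_qaly_decrement=fp * sae * dec / 12.0,
        mortality_probability=mort,
        state_split={"UndiagBenign": 1.0 - mort, "Dead": mort},
    )
    mort = benign_surgery.mortality_probability
    out["benign_grown"] = EventOutcome(
        expected_cost=c_ct + c_mdt + benign_surgery.expected_cost,
        expected_qaly_decrement=0.0,
        mortality_probability=mort,
        state_split={"DiagBenign": 1.0 - mort, "Dead": mort},
    )
    for stage in ("local", "regional"):
        mort = sens * (bm + (1.0 - bm) * malignant_surgery.mortality_probability)
        treated = sens * (1.0 - bm) * (1.0 - malignant_surgery.mortality_probability)
        out[f"undiag_{stage}"] = EventOutcome(
            expected_cost=c_ct
            + sens * (c_mdt + c_nb + (1.0 - bm) * malignant_surgery.expected_cost),
            expected_qaly_decrement=sens * sae * dec / 12.0,
            mortality_probability=mort,
            state_split={
                f"Undiag{stage.capitalize()}": 1.0 - sens,
                f"Diag{stage.capitalize()}_m1": treated,
                "Dead": mort,
            },
        )
    # surgery always follows a biopsy-confirmed malignancy, distant included;
    # survivors continue the distant tunnel as diagnosed
    mort = sens * (bm + (1.0 - bm) * malignant_surgery.mortality_probability)
    out["undiag_distant"] = EventOutcome(
        expected_cost=c_ct
        + sens * (c_mdt + c_nb + (1.0 - bm) * malignant_surgery.expected_cost),
        expected_qaly_decrement=sens * sae * dec / 12.0,
        mortality_probability=mort,
        state_split={
            "UndiagDistant_m*": 1.0 - sens,
            "DiagDistant_m*": sens
            * (1.0 - bm)
            * (1.0 - malignant_surgery.mortality_probability),
            "Dead": mort,
        },
    )
    return out


def surveillance_scan_event(
    cycle: int, params: ParameterSet, scan_months: tuple[int, ...] = (3, 12, 24)
) -> dict[str, EventOutcome]:
    """Per-state expected outcomes of the scheduled scan at ``cycle``."""
    if cycle not in scan_months:
        raise ValueError(f"cycle {cycle} is not a scheduled scan month")
    return _scan_outcomes(params)


def apply_scan(
    v: np.ndarray, params: ParameterSet
) -> tuple[np.ndarray, float, float]:
    """Apply one scheduled CT scan to the cohort state vector.

    Returns the redistributed vector, the expected undiscounted cost and
    the expected QALY adjustment (negative) per initial cohort member.
    """
    s = STATES
    o = _scan_outcomes(params)
    w = v.copy()
    cost = 0.0
    qaly = 0.0
    dead = 0.0

    nb = v[s.UNDIAG_BENIGN]
    oc = o["benign_not_grown"]
    cost += nb * oc.expected_cost
    qaly -= nb * oc.expected_qaly_decrement
    dead += nb * oc.mortality_probability
    w[s.UNDIAG_BENIGN] = nb * oc.state_split["UndiagBenign"]

    g = v[s.UNDIAG_BENIGN_GROWN]
    oc = o["benign_grown"]
    cost += g * oc.expected_cost
    dead += g * oc.mortality_probability
    w[s.UNDIAG_BENIGN_GROWN] = 0.0
    w[s.DIAG_BENIGN] += g * oc.state_split["DiagBenign"]

    for stage, idx, block in (
        ("local", s.UNDIAG_LOCAL, s.diag_local),
        ("regional", s.UNDIAG_REGIONAL, s.diag_regional),
    ):
        m = v[idx]
        oc = o[f"undiag_{stage}"]
        cost += m * oc.expected_cost
        qaly -= m * oc.expected_qaly_decrement
        dead += m * oc.mortality_probability
        w[idx] = m * oc.state_split[f"Undiag{stage.capitalize()}"]
        w[block[0]] += m * oc.state_split[f"Diag{stage.capitalize()}_m1"]

    d = v[s.undiag_distant]
    oc = o["undiag_distant"]
    cost += d.sum() * oc.expected_cost
    qaly -= d.sum() * oc.expected_qaly_decrement
    dead += d.sum() * oc.mortality_probability
    w[s.undiag_distant] = d * oc.state_split["UndiagDistant_m*"]
    w[s.diag_distant] += d * oc.state_split["DiagDistant_m*"]

    w[s.DEAD] += dead
    return w, cost, qaly


def evaluate_strategy(
    defn: StrategyDefinition,
    params: ParameterSet,
    config: ScenarioConfig,
    life_table: LifeTable,
    keep_trace: bool = False,
) -> StrategyResult:
    """Lifetime discounted cost and QALYs for one strategy."""
    v0, upfront_cost, upfront_qaly = apply_initial_test_split(
        params["prevalence"],
        (params["stage_local"], params["stage_regional"]),
        defn.test,
        params,
        test_price=defn.test_price if defn.test is not None else None,
    )

    def hook(cycle: int, v: np.ndarray):
        return apply_scan(v, params)

    trace = run_cohort(
        v0, params, config, life_table,
        event_hook=hook, event_cycles=defn.scan_months,
    )
    trace.event_costs[0] += upfront_cost
    trace.event_qalys[0] += upfront_qaly

    utilities = state_utility_matrix(params, config, trace.n_cycles)
    cost, qaly = accumulate_outcomes(trace, utilities, config)
    return StrategyResult(
        name=defn.name, cost=cost, qaly=qaly, trace=trace if keep_trace else None
    )


def evaluate_both(
    params: ParameterSet,
    config: ScenarioConfig,
    life_table: LifeTable,
) -> tuple[StrategyResult, StrategyResult]:
    """Evaluate surveillance-alone and test-plus-surveillance under one
    parameter set (common inputs across strategies)."""
    surv = evaluate_strategy(surveillance_strategy(config), params, config, life_table)
    aabt = evaluate_strategy(aabt_strategy(config), params, config, life_table)
    return surv, aabt
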