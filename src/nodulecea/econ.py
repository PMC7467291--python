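"""Deterministic economic comparison: ICER, net monetary benefit,
dominance classification, efficiency frontier and threshold pricing."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .strategies import StrategyResult


@dataclass
class CEResult:
    """Pairwise comparison of a comparator against a reference strategy."""

    ref_name: str
    comp_name: str
    ref_cost: float
    ref_qaly: float
    comp_cost: float
    comp_qaly: float
    delta_cost: float
    delta_qaly: float
    icer: float  # GBP/QALY; +/-inf when delta_qaly == 0; nan when dominated
    label: str  # "icer", "dominates", "dominated"

    def nmb(self, wtp: float) -> tuple[float, float]:
        return (
            compute_nmb(StrategyResult(self.ref_name, self.ref_cost, self.ref_qaly), wtp),
            compute_nmb(StrategyResult(self.comp_name, self.comp_cost, self.comp_qaly), wtp),
        )


def compute_nmb(result: StrategyResult, wtp: float) -> float:
    """Net monetary benefit: QALYs × willingness-to-pay − cost."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return result.qaly * wtp - result.cost


def compute_icer(ref: StrategyResult, comp: StrategyResult) -> CEResult:
    """Incremental cost-effectiveness of ``comp`` relative to ``ref``.

    The ICER ΔC/ΔQ is reported when both increments share a sign
    (more costly & more effective, or cheaper & less effective); otherwise
    the comparator strictly dominates or is dominated.  ΔQ = 0 with
    ΔC ≠ 0 yields a signed infinite ICER rather than an error.
    """
    dc = comp.cost - ref.cost
    dq = comp.qaly - ref.qaly
    if dq == 0.0:
        icer = float(np.inf) * np.sign(dc) if dc != 0 else 0.0
        label = "icer"
    elif (dc > 0 and dq > 0) or (dc < 0 and dq < 0):
        icer = dc / dq
        label = "icer"
    elif dq > 0:  # no more costly, more effective
        icer = float("nan")
        label = "dominates"
    else:  # no cheaper, less effective
        icer = float("nan")
        label = "dominated"
    return CEResult(
        ref_name=ref.name, comp_name=comp.name,
        ref_cost=ref.cost, ref_qaly=ref.qaly,
        comp_cost=comp.cost, comp_qaly=comp.qaly,
        delta_cost=dc, delta_qaly=dq, icer=icer, label=label,
    )


def efficiency_frontier(results: Sequence[StrategyResult]) -> pd.DataFrame:
    """Multi-strategy incremental table with dominance screening.

    Strategies are ordered by QALYs; strictly dominated options (more
    costly, fewer QALYs than another) and extendedly dominated options
    (higher pairwise ICER than the next more effective option) are
    flagged; ICERs are computed along the surviving frontier.
    """
    ordered = sorted(results, key=lambda r: (r.qaly, -r.cost))
    rows = []
    status = {r.name: "on frontier" for r in ordered}
    for r in ordered:
        for other in ordered:
            if other.name != r.name and other.qaly >= r.qaly and other.cost < r.cost:
                status[r.name] = "dominated"
    frontier = [r for r in ordered if status[r.name] == "on frontier"]
    # extended dominance: rising ICER sequence required along the frontier
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        icers = [
            (frontier[i + 1].cost - frontier[i].cost)
            / (frontier[i + 1].qaly - frontier[i].qaly)
            for i in range(len(frontier) - 1)
        ]
        for i in range(len(icers) - 1):
            if icers[i] > icers[i + 1]:
                status[frontier[i + 1].name] = "extendedly dominated"
                frontier.pop(i + 1)
                changed = True
                break
    prev = None
    for r in ordered:
        icer = np.nan
        if status[r.name] == "on frontier":
            if prev is not None:
                icer = (r.cost - prev.cost) / (r.qaly - prev.qaly)
            prev = r
        rows.append(
            {
                "strategy": r.name,
                "cost": r.cost,
                "qaly": r.qaly,
                "icer_vs_next_on_frontier": icer,
                "status": status[r.name],
            }
        )
    return pd.DataFrame(rows)


def threshold_price(
    evaluator: Callable[[float], tuple[StrategyResult, StrategyResult]],
    wtp: float,
    p0: float = 70.0,
    bracket: tuple[float, float] | None = None,
) -> float:
    """Test price at which the two strategies' net benefits are equal.

    ``evaluator(price)`` must return (reference, comparator) results with
    the comparator's cost linear in price with slope 1 (every tested
    person pays the price once, undiscounted).  The closed form
    p* = p0 + (ΔQ·wtp − ΔC(p0)) is cross-checked against a bisection
    solve of the incremental-NMB root; the two must agree to £0.01.
    """
    ref0, comp0 = evaluator(p0)
    dq = comp0.qaly - ref0.qaly
    dc0 = comp0.cost - ref0.cost
    closed = p0 + (dq * wtp - dc0)

    def inmb(price: float) -> float:
        ref, comp = evaluator(price)
        return compute_nmb(comp, wtp) - compute_nmb(ref, wtp)

    if bracket is None:
        span = max(abs(closed - p0), 1.0)
        bracket = (closed - max(2.0, 0.1 * span), closed + max(2.0, 0.1 * span))
    solved = float(brentq(inmb, *bracket, xtol=1e-4))
    if abs(solved - closed) > 0.01:
        raise RuntimeError(
            f"threshold price mismatch: closed form {closed:.4f} vs "
            f"bisection {solved:.4f}"
        )
    return closed
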