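"""Probabilistic sensitivity analysis: joint parameter sampling, paired
strategy evaluation, cost-effectiveness plane and acceptability curves.

Each draw realizes one parameter set (Beta/normal/HSROC as specified in
the registry) and evaluates every strategy under that same set — common
random parameters across strategies within a draw, so cost and QALY
increments are coherent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .parameters import ParameterDef, ParameterSet, ScenarioConfig, draw_parameter_set
from .simdata import LifeTable, gompertz_life_table
from .strategies import aabt_strategy, evaluate_strategy, surveillance_strategy

logger = logging.getLogger(__name__)


@dataclass
class PsaResults:
    """Per-draw (cost, QALY) pairs per strategy plus the sampled parameters."""

    strategies: list[str]
    costs: np.ndarray  # (n_draws, n_strategies)
    qalys: np.ndarray  # (n_draws, n_strategies)
    params: pd.DataFrame  # (n_draws, n_parameters) sampled values
    seed: int
    n_resampled: int = 0

    @property
    def n_draws(self) -> int:
        return self.costs.shape[0]

    def nmb(self, wtp: float) -> np.ndarray:
        """Net monetary benefit per draw per strategy."""
        return self.qalys * wtp - self.costs

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for j, name in enumerate(self.strategies):
            frames.append(
                pd.DataFrame(
                    {
                        "draw": np.arange(self.n_draws),
                        "strategy": name,
                        "cost": self.costs[:, j],
                        "qaly": self.qalys[:, j],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _is_valid(ps: ParameterSet) -> bool:
    for name in ("ct_sensitivity", "ct_specificity"):
        if not 0.0 < ps[name] < 1.0:
            return False
    return True


def run_psa(
    defs: Sequence[ParameterDef],
    config: ScenarioConfig,
    n_draws: int,
    seed: int = 0,
    life_table: LifeTable | None = None,
    extra_configs: Mapping[str, ScenarioConfig] | None = None,
    probabilistic: bool = True,
) -> PsaResults:
    """Run the probabilistic sensitivity analysis.

    Evaluates surveillance-alone and test-plus-surveillance under
    ``config`` for every draw; ``extra_configs`` adds further
    test-plus-surveillance variants (e.g. the second accuracy scenario)
    evaluated under the same draws.  Invalid sampled sets (degenerate CT
    accuracy) are resampled with a logged count, never silently.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if life_table is None:
        life_table = gompertz_life_table(max_age=config.max_age)

    strategies = [surveillance_strategy(config), aabt_strategy(config)]
    strat_configs = [config, config]
    names = [s.name for s in strategies]
    for name, cfg in (extra_configs or {}).items():
        strategies.append(aabt_strategy(cfg))
        strat_configs.append(cfg)
        names.append(name)

    rng = np.random.default_rng(seed)
    costs = np.zeros((n_draws, len(strategies)))
    qalys = np.zeros((n_draws, len(strategies)))
    rows = []
    n_resampled = 0
    for i in range(n_draws):
        ps = draw_parameter_set(
            defs, seed=seed, probabilistic=probabilistic, draw_id=i, rng=rng
        )
        while not _is_valid(ps):
            n_resampled += 1
            ps = draw_parameter_set(
                defs, seed=seed, probabilistic=probabilistic, draw_id=i, rng=rng
            )
        rows.append(ps.values)
        for j, (defn, cfg) in enumerate(zip(strategies, strat_configs)):
            # strategy definitions embed the accuracy pair, so rebuild with
            # the drawn CT values already inside ps; AABT accuracy is fixed
            res = evaluate_strategy(defn, ps, cfg, life_table)
            costs[i, j] = res.cost
            qalys[i, j] = res.qaly
    if n_resampled:
        logger.warning("resampled %d invalid parameter draws", n_resampled)
    return PsaResults(
        strategies=names,
        costs=costs,
        qalys=qalys,
        params=pd.DataFrame(rows),
        seed=seed,
        n_resampled=n_resampled,
    )


def ceac(results: PsaResults, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    For each willingness-to-pay value, the probability that each strategy
    has the maximum net monetary benefit; ties are split evenly, so the
    probabilities sum to 1 across strategies at every point.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp grid must be non-empty")
    out = np.zeros((wtp_grid.size, len(results.strategies)))
    for i, wtp in enumerate(wtp_grid):
        nmb = results.nmb(wtp)
        best = nmb.max(axis=1, keepdims=True)
        is_best = np.isclose(nmb, best, rtol=0.0, atol=1e-9)
        out[i] = (is_best / is_best.sum(axis=1, keepdims=True)).mean(axis=0)
    df = pd.DataFrame(out, columns=results.strategies)
    df.insert(0, "wtp", wtp_grid)
    return df
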