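"""Value-of-information analysis: EVPI and regression-based EVPPI.

Per-person EVPI is the expected opportunity loss of deciding under
uncertainty: mean over draws of the best strategy's net monetary benefit,
minus the net benefit of the strategy that is best on average.  Partial
EVPI (EVPPI) for a parameter group is estimated by the nonparametric
regression approach: each strategy's net benefit is regressed on the
group's sampled values with an additive spline smoother, and the EVPI
formula is applied to the fitted (conditional-expectation) values.
Population values scale the per-person quantity by discounted incidence
over the technology's relevant horizon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .psa import PsaResults


@dataclass
class VoiConfig:
    """Population scaling assumptions for value-of-information results."""

    annual_incidence: float = 50_000.0
    horizon_years: int = 10
    discount_rate: float = 0.035

    def __post_init__(self) -> None:
        if self.annual_incidence <= 0 or self.horizon_years <= 0:
            raise ValueError("incidence and horizon must be positive")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be >= 0")


@dataclass
class ParameterGroup:
    """A named set of registry parameters for partial-information analysis."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("group must have at least one member")


def default_parameter_groups() -> list[ParameterGroup]:
    """Standard groupings: disease mortality, cohort composition, utilities,
    CT accuracy."""
    return [
        ParameterGroup(
            "mortality rates",
            (
                "undiag_malignant_mortality",
                "distant_mortality_y1", "distant_mortality_y2",
                "distant_mortality_y3", "distant_mortality_y4",
                "local_mortality_y1", "local_mortality_y2",
                "local_mortality_y3", "local_mortality_y4",
                "regional_mortality_y1", "regional_mortality_y2",
                "regional_mortality_y3", "regional_mortality_y4",
            ),
        ),
        ParameterGroup(
            "initial patient characteristics", ("prevalence", "stage_regional")
        ),
        ParameterGroup(
            "utility values",
            (
                "util_age_55_64", "util_age_65_74", "util_age_75plus",
                "util_local", "util_regional", "util_distant",
            ),
        ),
        ParameterGroup("test accuracy", ("ct_specificity", "hsroc_lambda")),
    ]


def evpi_per_person(results: PsaResults, wtp: float) -> float:
    """Per-person expected value of perfect information (GBP)."""
    if len(results.strategies) < 2:
        raise ValueError("EVPI needs at least two strategies")
    nmb = results.nmb(wtp)
    # mathematically >= 0; clip the ~1e-13 float residue
    return float(max(nmb.max(axis=1).mean() - nmb.mean(axis=0).max(), 0.0))


def population_multiplier(config: VoiConfig) -> float:
    """Discounted number of people affected over the decision horizon.

    annual incidence × Σ_{t=0}^{horizon−1} (1 + d)^(−t); the first yearly
    cohort is undiscounted.
    """
    t = np.arange(config.horizon_years)
    return float(config.annual_incidence * ((1.0 + config.discount_rate) ** (-t)).sum())


def _fit_conditional_nmb(nmb: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Fitted E[NMB | group values] per strategy via additive B-splines.

    The spline bases are assembled per parameter and fit jointly by least
    squares with a pseudo-inverse, which tolerates the collinearity that
    B-spline bases of several parameters inevitably share.
    """
    import statsmodels.api as sm
    from statsmodels.gam.api import BSplines

    n, p = X.shape
    # degrees of freedom kept modest so ~1,000 draws support many smoothers
    df = [min(5, max(4, n // 200))] * p
    smoother = BSplines(X, df=df, degree=[3] * p)
    design = sm.add_constant(smoother.basis, has_constant="add")
    fitted = np.empty_like(nmb)
    for j in range(nmb.shape[1]):
        res = sm.OLS(nmb[:, j], design).fit()
        fitted[:, j] = res.fittedvalues
    return fitted


def evppi_regression(results: PsaResults, group: ParameterGroup, wtp: float) -> float:
    """Partial EVPI for a parameter group (GBP per person).

    Nonparametric-regression estimator: the fitted values of each
    strategy's net benefit given the group's draws stand in for the
    conditional expectations; the EVPI formula applied to them gives the
    value of learning the group exactly.  Clipped at zero; bounded above
    by EVPI up to Monte-Carlo/smoothing error.
    """
    cols = [m for m in group.members if m in results.params.columns]
    X = results.params[cols].to_numpy(dtype=float) if cols else np.empty((0, 0))
    keep = [i for i in range(X.shape[1]) if np.std(X[:, i]) > 0]
    if not keep:
        warnings.warn(
            f"group {group.name!r} has no varying sampled members; EVPPI = 0"
        )
        return 0.0
    X = X[:, keep]
    nmb = results.nmb(wtp)
    if np.allclose(nmb.std(axis=0), 0.0):
        return 0.0
    fitted = _fit_conditional_nmb(nmb, X)
    value = fitted.max(axis=1).mean() - fitted.mean(axis=0).max()
    return float(max(value, 0.0))


def voi_table(
    results: PsaResults,
    wtp_grid,
    groups: Sequence[ParameterGroup] = (),
    population: VoiConfig | None = None,
) -> pd.DataFrame:
    """EVPI (and optional group EVPPIs) across a willingness-to-pay grid."""
    population = population or VoiConfig()
    mult = population_multiplier(population)
    rows = []
    for wtp in np.asarray(wtp_grid, dtype=float):
        row = {"wtp": wtp, "evpi_per_person": evpi_per_person(results, wtp)}
        row["population_evpi"] = row["evpi_per_person"] * mult
        for g in groups:
            row[f"evppi[{g.name}]"] = evppi_regression(results, g, wtp)
        rows.append(row)
    return pd.DataFrame(rows)
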