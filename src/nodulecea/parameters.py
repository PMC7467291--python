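"""Model parameter registry, uncertainty distributions and coherent draws.

Every model input (prevalence, stage split, transition probabilities,
procedure risks, unit costs, utilities, test accuracy) is a
:class:`ParameterDef` with a base value and an uncertainty family:

* ``fixed`` — no uncertainty (unit costs, the autoantibody-test accuracy
  scenarios, the HSROC shape parameter);
* ``beta`` — probabilities/utilities; parameterised from printed counts
  (conjugate Beta(events, n−events)), a standard error, or a range
  converted via ``se = (U − L)/(2×1.96)`` and the method of moments;
* ``normal`` — the HSROC accuracy parameter Λ;
* ``derived`` — computed from other parameters after sampling (the local
  stage share as the complement of the regional share; CT sensitivity from
  the HSROC curve).

:func:`draw_parameter_set` realizes one complete assignment, either the
base case or a probabilistic draw in which CT sensitivity/specificity are
sampled jointly through the HSROC curve, never independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .calibration import AccuracyPair, HsrocParams, hsroc_sensitivity

VALID_FAMILIES = ("fixed", "beta", "normal", "derived")
VALID_UNITS = (
    "probability/month",
    "probability/event",
    "GBP",
    "utility",
    "proportion",
    "logit",
)
_BOUNDED_UNITS = ("probability/month", "probability/event", "utility", "proportion")

SCENARIO_A = AccuracyPair(sensitivity=0.41, specificity=0.93)
SCENARIO_B = AccuracyPair(sensitivity=0.28, specificity=0.98)


def se_from_range(upper: float, lower: float) -> float:
    """Standard error implied by a 95% range: (U − L)/(2×1.96)."""
    if upper < lower:
        raise ValueError("upper must be >= lower")
    return (upper - lower) / (2.0 * 1.96)


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta(α, β) with the given mean and standard error (method of moments).

    α = mean·k, β = (1−mean)·k with k = mean(1−mean)/se² − 1.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError("mean must be strictly inside (0, 1)")
    var = se * se
    if var <= 0:
        raise ValueError("se must be > 0")
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible moments: se^2={var:.6g} >= mean(1-mean)={mean * (1 - mean):.6g}"
        )
    k = mean * (1.0 - mean) / var - 1.0
    return mean * k, (1.0 - mean) * k


@dataclass
class ParameterDef:
    """One model input: base value plus uncertainty specification."""

    name: str
    base: float
    family: str = "fixed"
    se: float | None = None
    low: float | None = None
    high: float | None = None
    events: float | None = None
    denom: float | None = None
    units: str = "proportion"
    source: str = ""

    def validate(self) -> None:
        if self.family not in VALID_FAMILIES:
            raise ValueError(f"{self.name}: unknown family {self.family!r}")
        if self.units not in VALID_UNITS:
            raise ValueError(f"{self.name}: unknown units {self.units!r}")
        if self.units in _BOUNDED_UNITS and not 0.0 <= self.base <= 1.0:
            raise ValueError(f"{self.name}: {self.units} base {self.base} outside [0, 1]")
        if self.units == "GBP" and self.base < 0:
            raise ValueError(f"{self.name}: negative cost {self.base}")
        if self.se is not None and self.se < 0:
            raise ValueError(f"{self.name}: negative se")
        if self.low is not None and self.high is not None:
            if not self.low <= self.base <= self.high:
                raise ValueError(
                    f"{self.name}: base {self.base} outside range "
                    f"[{self.low}, {self.high}]"
                )
        if (self.events is None) != (self.denom is None):
            raise ValueError(f"{self.name}: events and denom must come together")
        if self.events is not None and not 0 < self.events < self.denom:
            raise ValueError(f"{self.name}: need 0 < events < denom")
        if self.family == "beta" and (
            self.se is None and self.low is None and self.events is None
        ):
            raise ValueError(f"{self.name}: beta family needs se, range or counts")
        if self.family == "normal" and self.se is None:
            raise ValueError(f"{self.name}: normal family needs se")

    def effective_se(self) -> float | None:
        """Standard error used for sampling (direct, or from the range)."""
        if self.se is not None:
            return self.se
        if self.low is not None and self.high is not None:
            return se_from_range(self.high, self.low)
        return None


@dataclass
class ParameterSet:
    """A complete realized assignment of every model parameter."""

    values: dict[str, float]
    draw_id: int = 0
    seed: int = 0

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def get(self, name: str, default: float | None = None):
        return self.values.get(name, default)

    def replace(self, **overrides: float) -> "ParameterSet":
        vals = dict(self.values)
        vals.update(overrides)
        return ParameterSet(vals, draw_id=self.draw_id, seed=self.seed)


@dataclass
class ScenarioConfig:
    """Run configuration: test scenario, price, discounting and horizon."""

    aabt_accuracy: AccuracyPair = SCENARIO_A
    test_price: float = 70.0
    wtp: float = 20_000.0
    discount_rate_annual: float = 0.035
    start_age: int = 62
    cycle_length_months: int = 1
    max_age: int = 100
    scan_months: tuple[int, ...] = (3, 12, 24)
    # utility used in undiagnosed malignant states: cancer-state utilities
    # (capped by the age norm) when True, the age norm alone when False
    undiag_cancer_utility: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.discount_rate_annual < 1.0:
            raise ValueError("discount rate must be in [0, 1)")
        for v in self.aabt_accuracy:
            if not 0.0 < v < 1.0:
                raise ValueError("accuracy values must be in (0, 1)")
        if self.max_age <= self.start_age:
            raise ValueError("max_age must exceed start_age")
        if tuple(sorted(self.scan_months)) != tuple(self.scan_months):
            raise ValueError("scan months must be strictly increasing")

    @property
    def n_cycles(self) -> int:
        return (self.max_age - self.start_age) * 12 // self.cycle_length_months


def scenario_config(scenario: str = "A", **overrides) -> ScenarioConfig:
    """Convenience constructor for the two published accuracy scenarios."""
    acc = {"A": SCENARIO_A, "B": SCENARIO_B}[scenario.upper()]
    return ScenarioConfig(aabt_accuracy=acc, **overrides)


def load_parameter_table(path=None) -> list[ParameterDef]:
    """Load the parameter registry (bundled defaults when path is None)."""
    if path is None:
        text = (resources.files("nodulecea") / "data/parameters.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "parameters" not in raw:
        raise ValueError("parameter file must contain a top-level 'parameters' list")
    allowed = {
        "name", "base", "family", "se", "low", "high",
        "events", "denom", "units", "source",
    }
    defs: list[ParameterDef] = []
    seen: set[str] = set()
    for row in raw["parameters"]:
        unknown = set(row) - allowed
        if unknown:
            raise ValueError(
                f"{row.get('name', '<unnamed>')}: unknown field(s) {sorted(unknown)}"
            )
        d = ParameterDef(**row)
        d.validate()
        if d.name in seen:
            raise ValueError(f"duplicate parameter {d.name}")
        seen.add(d.name)
        defs.append(d)
    return defs


def save_parameter_table(defs: Iterable[ParameterDef], path) -> None:
    """Serialize a registry back to YAML (lossless round-trip)."""
    rows = []
    for d in defs:
        row = {"name": d.name, "base": d.base, "family": d.family}
        for key in ("se", "low", "high", "events", "denom"):
            v = getattr(d, key)
            if v is not None:
                row[key] = v
        row["units"] = d.units
        row["source"] = d.source
        rows.append(row)
    with open(path, "w") as fh:
        yaml.safe_dump({"parameters": rows}, fh, sort_keys=False)


def _hsroc_from_defs(by_name: Mapping[str, ParameterDef]) -> HsrocParams:
    return HsrocParams(
        lambda_mean=by_name["hsroc_lambda"].base,
        lambda_se=by_name["hsroc_lambda"].se or 0.0,
        beta_shape=by_name["hsroc_beta"].base,
        spec_mean=by_name["ct_specificity"].base,
        spec_se=by_name["ct_specificity"].se or 0.0,
    )


def draw_parameter_set(
    defs: Sequence[ParameterDef],
    seed: int = 0,
    probabilistic: bool = False,
    draw_id: int = 0,
    rng: np.random.Generator | None = None,
) -> ParameterSet:
    """Realize one coherent parameter set.

    With ``probabilistic=False`` every parameter takes its base value.
    Otherwise each uncertain parameter is drawn independently from its
    distribution, except CT sensitivity/specificity which are sampled
    jointly through the HSROC curve, and the local stage share which is
    the complement of the sampled regional share.
    """
    by_name = {d.name: d for d in defs}
    required = {"stage_regional", "ct_specificity", "hsroc_lambda", "hsroc_beta"}
    missing = required - set(by_name)
    if missing:
        raise ValueError(f"parameter registry incomplete: missing {sorted(missing)}")

    values: dict[str, float] = {}
    if not probabilistic:
        for d in defs:
            values[d.name] = d.base
        return ParameterSet(values, draw_id=draw_id, seed=seed)

    if rng is None:
        rng = np.random.default_rng(seed)
    for d in defs:
        if d.name in ("ct_specificity", "ct_sensitivity"):
            continue  # drawn jointly below
        if d.family == "fixed" or d.family == "derived":
            values[d.name] = d.base
        elif d.family == "normal":
            values[d.name] = float(rng.normal(d.base, d.se))
        elif d.family == "beta":
            if d.events is not None:
                alpha, beta = d.events, d.denom - d.events
            else:
                se = d.effective_se()
                if se is None or se == 0:
                    raise ValueError(f"{d.name}: no usable uncertainty for PSA")
                alpha, beta = beta_from_moments(d.base, se)
            values[d.name] = float(rng.beta(alpha, beta))
        else:  # pragma: no cover - guarded by validate()
            raise ValueError(f"{d.name}: cannot sample family {d.family!r}")

    # joint CT accuracy draw: Beta specificity, normal Λ, fixed β
    hs = _hsroc_from_defs(by_name)
    # Λ was already drawn above under its own def; reuse it for coherence
    lam = values["hsroc_lambda"]
    if hs.spec_se == 0:
        spec = hs.spec_mean
    else:
        alpha, beta = beta_from_moments(hs.spec_mean, hs.spec_se)
        spec = float(rng.beta(alpha, beta))
    values["ct_specificity"] = spec
    values["ct_sensitivity"] = hsroc_sensitivity(spec, lam, hs.beta_shape)

    # derived complements
    values["stage_local"] = 1.0 - values["stage_regional"]

    return ParameterSet(values, draw_id=draw_id, seed=seed)
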