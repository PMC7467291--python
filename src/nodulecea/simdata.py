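"""Synthetic model inputs: parametric life tables and nodule doubling times.

The cohort model needs an age-indexed all-cause mortality table.  National
statistics tables cannot be bundled, so the default background-mortality
input is a Gompertz life table calibrated to a UK-like remaining life
expectancy at age 62 of about 23 years.  A real life table can be supplied
as a two-column CSV (age, qx) and is validated, gap-filled and, if it stops
short of the model's maximum age, extended by Gompertz extrapolation.

Doubling-time samples (log-normal) emulate the shape of observed pulmonary
nodule volume-doubling-time data and feed the exponential-rate calibration
utilities in :mod:`nodulecea.calibration`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import brentq


@dataclass
class LifeTable:
    """Annual death probabilities qx indexed by integer age 0..max_age."""

    qx: np.ndarray
    source: str = "synthetic"
    start_age: int = 0

    def __post_init__(self) -> None:
        self.qx = np.asarray(self.qx, dtype=float)
        if self.qx.ndim != 1 or len(self.qx) == 0:
            raise ValueError("qx must be a non-empty 1-d array")
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ValueError("qx values must lie in [0, 1]")

    @property
    def max_age(self) -> int:
        return self.start_age + len(self.qx) - 1

    def annual_qx(self, age: int) -> float:
        """Annual death probability at integer age (clamped to table ends)."""
        i = int(np.clip(age - self.start_age, 0, len(self.qx) - 1))
        return float(self.qx[i])

    def monthly_qx(self, age: int) -> float:
        """Monthly death probability via 1 − (1 − qx)^(1/12)."""
        return 1.0 - (1.0 - self.annual_qx(age)) ** (1.0 / 12.0)

    def life_expectancy(self, age: int) -> float:
        """Remaining (complete) life expectancy at `age` in years.

        Curtate expectation from annual survival plus the standard half-year
        continuity correction.
        """
        i = age - self.start_age
        if i < 0 or i >= len(self.qx):
            raise ValueError(f"age {age} outside table range")
        surv = np.cumprod(1.0 - self.qx[i:])
        return float(surv.sum() + 0.5)

    def to_frame(self) -> pd.DataFrame:
        ages = np.arange(self.start_age, self.start_age + len(self.qx))
        return pd.DataFrame({"age": ages, "qx": self.qx})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@lru_cache(maxsize=8)
def _calibrated_baseline(b: float, target_e62: float, max_age: int) -> float:
    """Solve the Gompertz baseline hazard so that e(62) hits the target."""

    def e62(a: float) -> float:
        ages = np.arange(0, max_age + 1)
        qx = 1.0 - np.exp(-a * np.exp(b * ages))
        qx[-1] = 1.0
        return LifeTable(qx).life_expectancy(62) - target_e62

    return brentq(e62, 1e-8, 1e-2, xtol=1e-14)


def gompertz_life_table(
    a: float | None = None,
    b: float = 0.095,
    max_age: int = 100,
    target_e62: float = 23.0,
) -> LifeTable:
    """Gompertz life table qx = 1 − exp(−a·e^(b·age)).

    With ``a`` omitted, the baseline hazard is calibrated so remaining life
    expectancy at 62 equals ``target_e62`` (default 23 years, UK-like).
    The final age's qx is forced to 1 so the table is closed.
    """
    if b < 0:
        raise ValueError("log-slope b must be >= 0")
    if a is None:
        a = _calibrated_baseline(b, target_e62, max_age)
    if a <= 0:
        raise ValueError("baseline hazard a must be > 0")
    ages = np.arange(0, max_age + 1)
    qx = 1.0 - np.exp(-a * np.exp(b * ages))
    qx[-1] = 1.0
    return LifeTable(qx, source=f"gompertz(a={a:.3g}, b={b:g})")


def load_life_table(path, max_age: int = 100) -> LifeTable:
    """Load a life table from a CSV with columns (age, qx).

    Missing interior ages are filled by linear interpolation (warned); a
    table ending before ``max_age`` is extended by a Gompertz fit to its
    upper ages (warned).  qx outside [0, 1] is a validation error.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "age" not in cols or "qx" not in cols:
        raise ValueError("life table CSV needs columns 'age' and 'qx'")
    df = df[[cols["age"], cols["qx"]]].rename(
        columns={cols["age"]: "age", cols["qx"]: "qx"}
    )
    df = df.dropna().sort_values("age")
    ages = df["age"].to_numpy(dtype=int)
    qx = df["qx"].to_numpy(dtype=float)
    if np.any((qx < 0) | (qx > 1)):
        bad = ages[(qx < 0) | (qx > 1)][0]
        raise ValueError(f"qx outside [0, 1] at age {bad}")
    if len(ages) < 2:
        raise ValueError("life table needs at least two ages")

    full_ages = np.arange(ages.min(), ages.max() + 1)
    if len(full_ages) != len(ages):
        warnings.warn("life table has gaps; filling by linear interpolation")
    full_qx = np.interp(full_ages, ages, qx)

    if full_ages.max() < max_age:
        warnings.warn(
            f"life table ends at {full_ages.max()}; extending to {max_age} "
            "by Gompertz extrapolation"
        )
        # fit log-hazard ~ age on the top of the table (qx>0 ages only)
        tail = full_qx > 0
        fit_ages = full_ages[tail][-20:]
        fit_qx = full_qx[tail][-20:]
        hz = -np.log1p(-np.minimum(fit_qx, 1 - 1e-12))
        slope, intercept = np.polyfit(fit_ages, np.log(hz), 1)
        ext_ages = np.arange(full_ages.max() + 1, max_age + 1)
        ext_qx = 1.0 - np.exp(-np.exp(intercept + slope * ext_ages))
        full_ages = np.concatenate([full_ages, ext_ages])
        full_qx = np.concatenate([full_qx, ext_qx])
    full_qx = full_qx.copy()
    full_qx[-1] = 1.0
    return LifeTable(full_qx, source=str(path), start_age=int(full_ages[0]))


def generate_doubling_times(
    n: int, log_mean: float = np.log(4.8), log_sd: float = 0.8, seed: int = 0
) -> np.ndarray:
    """Log-normal nodule volume-doubling times in months.

    Defaults give a right-skewed distribution with median ~4.8 months,
    emulating the shape of observed doubling-time data for malignant
    pulmonary nodules.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if log_sd < 0:
        raise ValueError("log_sd must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=log_mean, sigma=log_sd, size=n)
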