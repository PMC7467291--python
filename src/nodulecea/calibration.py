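"""Diagnostic-accuracy sampling and rate/probability calibration utilities.

CT accuracy enters the model through a hierarchical summary ROC (HSROC)
summary: an accuracy parameter Λ and a fixed shape parameter β link the
logit of sensitivity to the logit of specificity,

    logit(sens) = Λ·exp(−β/2) − exp(−β)·logit(spec).

Probabilistic draws sample specificity (Beta, method of moments) and Λ
(normal) and derive sensitivity through the curve, preserving the joint
structure of the two accuracy values.

The remaining functions convert between rates, mean survival times,
interval survival fractions and per-cycle probabilities under constant
(exponential) hazards — the conversions used to build the model's monthly
transition probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.special import expit, logit


class AccuracyPair(NamedTuple):
    """A (sensitivity, specificity) pair for a diagnostic test."""

    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class HsrocParams:
    """HSROC summary parameters for CT nodule assessment.

    Defaults are the meta-analytic (metandi) summary: specificity 0.7234
    (se 0.0276), accuracy Λ = 3.156 (se 0.2296) and shape β = −0.5362433
    held fixed.
    """

    lambda_mean: float = 3.156
    lambda_se: float = 0.2296
    beta_shape: float = -0.5362433
    spec_mean: float = 0.7234
    spec_se: float = 0.0276

    def __post_init__(self) -> None:
        if not 0.0 < self.spec_mean < 1.0:
            raise ValueError("spec_mean must be in (0, 1)")
        if self.lambda_se < 0 or self.spec_se < 0:
            raise ValueError("standard errors must be >= 0")


def hsroc_sensitivity(specificity: float, lam: float, beta_shape: float) -> float:
    """Sensitivity implied by the HSROC curve at a given specificity.

    Returns expit(Λ·e^(−β/2) − e^(−β)·logit(spec)); always in (0, 1).
    """
    specificity = float(specificity)
    if not 0.0 < specificity < 1.0:
        raise ValueError("specificity must be strictly inside (0, 1)")
    lin = lam * np.exp(-beta_shape / 2.0) - np.exp(-beta_shape) * logit(specificity)
    return float(expit(lin))


def sample_ct_accuracy(
    params: HsrocParams, seed: int | np.random.Generator = 0
) -> AccuracyPair:
    """Draw a joint (sensitivity, specificity) pair for the CT scan.

    Specificity ~ Beta (method of moments from spec_mean/spec_se), Λ ~
    Normal(lambda_mean, lambda_se), β fixed; sensitivity follows from the
    HSROC curve.  Zero standard errors degenerate to the point summary.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if params.spec_se == 0:
        spec = params.spec_mean
    else:
        from .parameters import beta_from_moments

        alpha, beta = beta_from_moments(params.spec_mean, params.spec_se)
        spec = float(rng.beta(alpha, beta))
        # Beta draws can underflow to exactly 0/1 only pathologically; guard
        spec = min(max(spec, 1e-12), 1 - 1e-12)
    lam = float(rng.normal(params.lambda_mean, params.lambda_se))
    sens = hsroc_sensitivity(spec, lam, params.beta_shape)
    return AccuracyPair(sensitivity=sens, specificity=spec)


def prob_from_rate(rate: float, t: float) -> float:
    """Probability of an event within time t under a constant rate.

    1 − exp(−rate·t); monotone in both arguments.
    """
    if rate < 0 or t < 0:
        raise ValueError("rate and t must be >= 0")
    return float(-np.expm1(-rate * t))


def monthly_prob_from_mean_survival(mean_survival: float) -> float:
    """Monthly death probability for exponential survival with given mean.

    1 − exp(−1/mean_survival) with mean survival in months; e.g. a mean of
    36.7 months gives 0.02688/month.
    """
    if mean_survival <= 0:
        raise ValueError("mean_survival must be > 0")
    return prob_from_rate(1.0 / mean_survival, 1.0)


def interval_monthly_prob(surv_start: float, surv_end: float) -> float:
    """Constant monthly death probability over a 12-month interval.

    Given survival fractions at the start and end of a year, returns
    1 − (surv_end/surv_start)^(1/12).
    """
    if not 0.0 < surv_end <= surv_start <= 1.0:
        raise ValueError("need 0 < surv_end <= surv_start <= 1")
    return float(1.0 - (surv_end / surv_start) ** (1.0 / 12.0))


def fit_exponential_rate_ml(event_times) -> float:
    """Maximum-likelihood exponential rate from fully observed event times.

    For uncensored exponential data the MLE is 1/mean.  Used to calibrate
    monthly progression probabilities from doubling-time samples.
    """
    times = np.asarray(event_times, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 event times")
    if np.any(times <= 0):
        raise ValueError("event times must be positive")
    return float(1.0 / times.mean())
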