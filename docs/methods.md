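# Methods

## The decision problem

Patients with an indeterminate pulmonary nodule (IPN, 4–20 mm) have a
malignancy risk that is too low to justify immediate biopsy but too high
to discharge.  Standard management is CT surveillance: repeat scans at 3,
12 and 24 months watching for volume doubling.  The model compares that
pathway against adding an upfront autoantibody blood test (AABT) whose
positives are referred for multidisciplinary-team (MDT) review, guided
needle biopsy and, if malignancy is confirmed, surgery.  The evaluation
is from the health-care payer perspective, outcomes in quality-adjusted
life years (QALYs), costs in GBP (2016/17 tariffs), both discounted at
3.5% per year, for a cohort aged 62 at presentation followed to age 100
(a lifetime horizon; residual survivorship at 100 is below 1% and is
truncated with the terminal half-cycle weight).

## Model structure

A decision tree resolves the upfront test at cycle 0 (undiscounted) and
hands the resulting cohort distribution to a monthly-cycle Markov cohort
model.  States: undiagnosed benign (with a latent "growth observed"
flag), undiagnosed malignant at local/regional/distant stage, diagnosed
local/regional/distant carrying a months-since-treatment tunnel index,
diagnosed benign (after surgical biopsy of a grown benign nodule),
disease-free, and dead.

* Undiagnosed local and regional disease progress one stage at
  0.19224/month and carry an excess mortality of 0.02688/month (the
  monthly probability implied by a 36.7-month mean survival of an
  untreated 2 cm nodule under an exponential survival model).
* Distant-stage disease — diagnosed or not — faces tunnel mortality of
  0.1255 / 0.0670 / 0.0589 / 0.0150 per month in years 1–4, with the
  year-4 value continued for life ("constant risk of cancer-related
  mortality for the rest of their lives").  The tunnel clock starts on
  entering the distant stage and continues across diagnosis.
* Diagnosed local and regional states carry year-banded tunnel mortality
  (local: 0.0106/0.0100/0.0090/0.0114; regional:
  0.0340/0.0296/0.0225/0.0155 per month, years 1–4) for 60 tunnel
  months, after which patients exit to disease-free (the 5-year
  disease-free assumption).  No value is published for year 5, so the
  year-4 value is carried through months 49–60 — the same continuation
  rule used for the distant state.
* Benign nodules trigger the growth flag at 0.28 in the first month of
  observation and 0.005/month thereafter; growth is acted on at the next
  scheduled scan (nodules are diagnosed only following a CT scan), where
  detection of growth is assumed perfect.
* Background all-cause mortality (annual qx converted to monthly via
  1 − (1 − qx)^(1/12)) applies in every alive state, composed
  competing-risk style with the cause-specific probabilities.

Within a cycle, events are ordered: scheduled detection (scans, applied
by the strategy layer as an event hook before the transition), disease
progression, cause-specific mortality, background mortality.
Progression and cause-specific mortality compose as independent
within-cycle events (from undiagnosed local, P(reach regional) =
0.19224 × (1 − 0.02688)); this ordering is a modelling choice — the
pathway description does not fix one — and it is enumerable, which is
how the unit tests check the assembled matrices against a brute-force
event tree.

## Testing pathways

At each scheduled scan every patient still under surveillance is charged
a CT tariff (£85.56).  Undiagnosed malignant nodules are detected with
the CT sensitivity (0.923); detection leads to MDT (£111.99) + guided
needle biopsy (£948.92) and then surgery.  Biopsy-confirmed malignancy
always proceeds to surgery regardless of stage.  CT specificity (0.723)
applies to non-grown benign nodules, so each scan sends a fraction
1 − spec of them to an MDT + needle biopsy whose benign result returns
them to surveillance; grown benign nodules get a surgical biopsy and are
then diagnosed benign with no further follow-up.  After the 24-month
scan surveillance stops: undetected benign patients are discharged and
undetected malignant patients continue untreated natural history.

Every guided needle biopsy carries a mortality of 29/31,960 and a
serious-adverse-event probability of 230/31,960 costing 0.2 utility for
one month (0.2/12 QALYs).  Surgery on a malignant nodule costs the
complication-weighted tariff plus expected adjuvant radiotherapy (5/35
of operated patients) and chemotherapy (11/35), with mortality 0.042;
the benign surgical biopsy analogue uses its own tariffs and mortality
0.005.  MDT review is charged at every positive finding that triggers a
biopsy, following the assumption that a positive test leads to MDT
referral.

Two detection-timing choices were genuinely open and are implemented as
documented defaults: CT test accuracy applies to undiagnosed malignant
nodules at every scheduled scan (not only after a doubling event), and
the upfront-test arm's events occur at cycle 0 undiscounted with the
3-month scan as the first discounted event.

## Outcomes

QALYs accrue as occupancy × utility/12 per monthly cycle, discounted at
(1.035)^(−t/12) and half-cycle corrected (half weight on the first and
terminal cycles; event costs and decrements enter in full at their cycle
of occurrence).  Utilities are age-banded population norms (0.810 under
65, 0.773 at 65–74, 0.703 at 75+) switching exactly at the band ages;
cancer states use 0.71/0.65/0.62 (local/regional/distant) capped by the
age norm, in diagnosed and — by default, toggleable — undiagnosed
malignant states.  There are no ongoing state costs: all costs are
event-triggered (test, scans, MDT, biopsies, surgery, adjuvant
therapy).

The economic layer reports ICERs from unrounded internals, net monetary
benefit NMB = QALYs × WTP − cost at a willingness-to-pay of
£20,000/QALY, an efficiency frontier with strict and extended dominance
screening, and the threshold test price.  Because every tested patient
pays the price exactly once at cycle 0, the comparator's cost is linear
in price with slope 1 and the threshold has the closed form
p* = p₀ + (ΔQ·WTP − ΔC(p₀)); a bisection solve of the incremental-NMB
root must agree to £0.01 or the function raises.

## Uncertainty analysis

Probabilistic draws sample each uncertain parameter independently except
where structure requires otherwise:

* probabilities and utilities: Beta.  Printed counts use the conjugate
  form Beta(events, n − events); printed ranges are converted to a
  standard error via SE = (U − L)/(2 × 1.96) and then method-of-moments;
  "±50%" ranges are read as multiplicative bounds on the monthly
  probability (0.5×, 1.5× the base).
* CT accuracy: specificity ~ Beta (mean 0.7234, SE 0.0276), the HSROC
  accuracy parameter Λ ~ Normal(3.156, 0.2296), shape β = −0.5362433
  fixed, and sensitivity derived through
  logit(sens) = Λ·e^(−β/2) − e^(−β)·logit(spec).  This reading of the
  curve reproduces the published operating point (0.923, 0.723) exactly,
  which is how it was validated.  Sensitivity and specificity are never
  drawn independently.
* the local stage share is the complement of the sampled regional share.
* the autoantibody test's accuracy is fixed per scenario (A: 0.41/0.93;
  B: 0.28/0.98) — no sampling distribution is published for it.
* no uncertainty is published for the utility values; the package
  assumes a 5% relative standard error so the utility group participates
  in the value-of-information analysis.  The −0.2 biopsy decrement is
  fixed.

All strategies within a draw share one parameter set (common random
parameters), which is what makes per-draw increments coherent.  The
default is 1,000 draws.  Acceptability curves give each strategy the
probability of maximal NMB per willingness-to-pay point, splitting ties
evenly.

A consequence worth knowing: with common parameters and fixed
per-scenario test accuracy, the scenario-A-vs-scenario-B net-benefit
difference at £20,000/QALY is positive in essentially every draw, so the
three-way acceptability curve concentrates on scenario A (~100%) rather
than spreading ~10% of probability onto scenario B.  Spreading would
require independent draws per scenario or a sampling distribution for
the blood test's accuracy; both are outside the model as specified.

## Value of information

Per-person EVPI is mean(max-strategy NMB) − max(mean NMB).  EVPPI for a
parameter group uses the nonparametric-regression estimator: each
strategy's NMB is regressed on the group's sampled values with additive
cubic B-splines (4–5 degrees of freedom per parameter, fit by least
squares with a pseudo-inverse so collinear bases are tolerated), and the
EVPI formula is applied to the fitted values, clipped at zero.
Population scaling multiplies by annual incidence (50,000) summed over a
10-year horizon discounted at 3.5%, first cohort undiscounted
(≈ 430,384 people).

## Synthetic background mortality

The only input not published is the age-indexed all-cause mortality
table.  The default stand-in is a Gompertz life table
qx = 1 − exp(−a·e^(b·age)) with b = 0.095/year and a calibrated so
remaining life expectancy at 62 is 23 years (UK-like); the final age's
qx is forced to 1.  A real life table can be supplied as a CSV
(age, qx): gaps are interpolated and short tables are extended by a
Gompertz fit to their own upper ages, both with warnings.  The synthetic
table reproduces the overall level and age-slope of UK mortality but not
cohort effects, sex structure or the exact 2018 national values, so
absolute costs and QALYs shift by a few percent relative to results
computed with the real table; incremental comparisons between strategies
are much less sensitive because both arms share the same background
mortality.  The doubling-time generator produces log-normal samples
(median ≈ 4.8 months, log-SD 0.8) emulating the right-skewed shape of
observed volume-doubling-time data; it feeds the exponential
maximum-likelihood calibration utilities and their recovery tests, not
the base-case transition probabilities, which are used as printed.

## Numerical choices and problem sizes

The state space has 225 states (two benign substates, two undiagnosed
malignant stages, 49-month distant tunnels, 60-month diagnosed
local/regional tunnels, diagnosed benign, disease-free, dead).  The
cohort runs 456 monthly cycles (age 62→100).  Transition rows are
validated to sum to 1 within 1e-9 and the trace conserves mass to the
same tolerance.  One strategy evaluation takes ~15 ms, so the 1,000-draw
three-strategy PSA completes in well under a minute; tests use a
50,000-individual micro-simulation oracle and 5,000–100,000-sample
recovery checks sized to keep the whole suite under a few minutes.

## Limitations

No palliative/terminal-care costs; compliance with surveillance is
assumed complete; biopsy is assumed perfectly accurate; recurrence risk
is folded into the diagnosed-state tunnel mortality rather than modelled
as a separate state; costs are 2016/17 GBP without inflation machinery;
and the PSA inherits the published parameter uncertainty only — inputs
printed without uncertainty (costs, test accuracy scenarios) are fixed,
which tends to understate decision uncertainty and hence the value of
further research.
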