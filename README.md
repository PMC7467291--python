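# nodulecea

Cost-effectiveness modelling of an autoantibody blood test (AABT) added
to CT surveillance, versus CT surveillance alone, for patients with
indeterminate pulmonary nodules (IPNs).

Who it is for: health economists and methodologists who want a tested,
scriptable implementation of a decision-tree + Markov cohort evaluation
of a rule-in diagnostic added to a watchful-waiting pathway — including
probabilistic sensitivity analysis, acceptability curves, threshold
pricing and value-of-information analysis.

## The model in brief

A cohort of 62-year-olds presents with an IPN (malignancy prevalence
9.5%, split 0.875 local / 0.125 regional).  A decision tree resolves the
upfront blood test: positives get multidisciplinary-team review and
guided needle biopsy; confirmed malignancies get surgery; everyone else
enters CT surveillance at 3, 12 and 24 months.  A monthly Markov model
then follows undiagnosed benign/malignant, diagnosed (with
months-since-treatment tunnels), disease-free and dead states to age
100.  Lifetime discounted (3.5%/yr, half-cycle corrected) costs and
QALYs feed:

* **ICER** = ΔC/ΔE between strategies, and **NMB** = E·λ − C at a
  willingness-to-pay λ = £20,000/QALY;
* **threshold price** p\* = p₀ + (ΔQ·λ − ΔC(p₀)), exact because every
  tested patient pays the price once, cross-checked by bisection;
* **PSA**: Beta (method-of-moments / conjugate-count) and normal draws,
  with CT sensitivity–specificity sampled jointly through an HSROC
  curve, logit(sens) = Λ·e^(−β/2) − e^(−β)·logit(spec);
* **EVPI / EVPPI** (nonparametric-regression estimator with additive
  B-splines), scaled to a 50,000/year incident population over 10
  discounted years.

Every model input (Tables of transition probabilities, tariffs,
utilities, test accuracy) ships as a validated YAML registry in
`src/nodulecea/data/parameters.yaml`.  The one external input — an
age-indexed all-cause mortality table — defaults to a Gompertz life
table calibrated to a UK-like life expectancy at 62 of 23 years; pass a
real table as a CSV of (age, qx) with `--life-table`.

## Worked example

```python
import nodulecea as nc

defs = nc.load_parameter_table()
params = nc.draw_parameter_set(defs)          # base-case values
lt = nc.gompertz_life_table()                 # synthetic UK-like table
cfg = nc.scenario_config("A")                 # AABT sens 0.41, spec 0.93, £70

surv, aabt = nc.evaluate_both(params, cfg, lt)
ce = nc.compute_icer(surv, aabt)
print(f"Surveillance       £{surv.cost:7.0f}  {surv.qaly:.4f} QALYs")
print(f"AABT+Surveillance  £{aabt.cost:7.0f}  {aabt.qaly:.4f} QALYs")
print(f"dC £{ce.delta_cost:.0f}  dQ {ce.delta_qaly:.4f}  ICER £{ce.icer:,.0f}/QALY")
```

prints

```
Surveillance       £   2709  10.7013 QALYs
AABT+Surveillance  £   2884  10.7620 QALYs
dC £175  dQ 0.0607  ICER £2,882/QALY
```

i.e. at £70 per test, adding the blood test costs £175 more per patient,
gains 0.061 QALYs, and at under £3,000 per QALY is comfortably
cost-effective against the usual £20,000 threshold.  The same analyses
are available from the shell:

```bash
nodule-cea basecase --scenario both --out results/
nodule-cea psa --scenario A --n-draws 1000 --seed 1 --plots --out results/
nodule-cea threshold --scenario B --out results/
nodule-cea voi --scenario A --n-draws 1000 --out results/
```

Every output CSV records the package version, seed and a configuration
hash; identical invocations are byte-identical.

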