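# doublehit

Synergy of dual early-life exposures in small survival cohorts.

`doublehit` is a Python package for epidemiologists studying the **double-hit
hypothesis**: that two early-life adversities — here prenatal exposure to a
major disaster ("SS") and perinatal maternal cannabis use ("CB") — jointly
confer a risk of child psychopathology that exceeds the *sum* of their
individual excess risks. It provides

- a **synthetic-cohort generator** for four-group dual-exposure designs
  (neither / CB-only / SS-only / both) with eleven confounders,
  retrospectively dated disorder onsets over ages 0–5 years under
  exponential or piecewise-constant hazards, right-censoring at the
  interview age, and a correlated longitudinal panel of parenting-stress
  and social-support scales at ages 2–5 with wave-level missingness;
- the **survival core**: product-limit (Kaplan–Meier) cumulative lifetime
  risk, K-sample log-rank tests, Cox proportional-hazards fits with the
  four-level exposure factor, and Schoenfeld-residual diagnostics;
- **staged (hierarchical) Cox modelling** with block likelihood-ratio
  tests: confounders first, postnatal environment second, the 3-df
  exposure factor last;
- the core statistic, **Rothman's synergy index** with a delta-method
  standard error and Z test;
- a **GEE module** for the longitudinal panel (exchangeable working
  correlation, robust SEs, a-priori pairwise contrasts); and
- a **Monte-Carlo harness** for the type-I error and power of the synergy
  test.

## The statistic

For hazard ratios HR_A, HR_B and HR_AB of the two singly-exposed groups and
the doubly-exposed group against the unexposed reference, the synergy index
is

    SI = (HR_AB − 1) / (HR_A + HR_B − 2)

SI = 1 means the excess risks add exactly; SI > 1 means superadditive
("synergistic") risk; SI > 2 is conventionally read as appreciable
synergistic acceleration. Inference is on the log scale: with
β = (ln HR_A, ln HR_B, ln HR_AB) and covariance Σ (from the adjusted Cox
fit, or rebuilt from the 4×2 case/control table), the delta method gives

    se(ln SI) = sqrt(hᵀ Σ h),   h = (−e^{β₁}/D, −e^{β₂}/D, e^{β₃}/(e^{β₃}−1)),
    D = e^{β₁} + e^{β₂} − 2,

and Z = ln SI / se(ln SI) is referred to the standard normal.

## Worked example

```python
from doublehit import DoubleHitModel, default_scenario, generate_cohort, generate_panel

scenario = default_scenario(seed=11)          # N=163 split 70/27/53/13
cohort = generate_cohort(scenario)
panel = generate_panel(cohort, scenario)
results = DoubleHitModel(cohort, panel=panel).fit()
print(results.summary())
```

prints

```
Double-hit analysis summary
=============================

N = 163; storm-exposed 40.5%, cannabis-exposed 24.5%, both 8.0%

[any_dbd] log-rank chi2(3) = 27.37, p = 4.922e-06
  SI = 8.01, z = 2.47, p = 0.01355 (synergistic)
[any_anxiety] log-rank chi2(3) = 52.73, p = 2.09e-11
  SI = 3.11, z = 1.94, p = 0.05296
```

The exposure percentages are exact bookkeeping from the group sizes. The
log-rank lines test equality of the four onset-age distributions per
disorder. The SI lines estimate additive interaction from the
covariate-adjusted Cox fit. Note how volatile the index is at N=163: the
generative SI for disruptive disorders is 2.19 but this draw estimates
8.01, while the anxiety draw (generative SI 2.60) lands at 3.11 with
p ≈ 0.05 — small dual-exposure groups inflate interaction estimates, and
the simulation harness quantifies exactly this instability.

The same analysis is available from the shell:

```bash
doublehit analyze --out results_run      # simulate + full report bundle
doublehit simulate-study --reps 1000 --si 2.6 --out study_out
```

`analyze` writes `cohort.csv`, `km_curves.csv`, `logrank.csv`,
`staged_cox.csv`, `risk_table.csv`, `gee_table.csv` and `summary.json`.

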