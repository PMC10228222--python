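# Methods

This note documents the statistical model behind `doublehit`, the
generative assumptions of its simulator, the numerical choices made where
the design was genuinely open, and what the test suite does and does not
establish about real data.

## The dual-exposure design

Subjects are children classified by two binary early-life exposures —
prenatal disaster-related stress (SS) and perinatal maternal cannabis use
(CB) — into four groups: `neither` (reference), `cb_only`, `ss_only`,
`both`. The default cohort mirrors a small observational study: N = 163
split 70/27/53/13, eleven subject-level confounders (child sex, race,
ethnicity; maternal age; marital status; parity; SES class; normative
prenatal-stress class; prenatal substance use; objective storm severity;
subjective post-traumatic stress), lifetime disorder onsets dated
retrospectively in months, and an annual caregiver-report panel at ages
2–5.

## Onset-time model

Onset age for disorder *d* of subject *i* in group *g* follows a
proportional-hazards law

    λ_di(t) = λ_d0(t) · HR_dg · exp(xᵢᵀ β_d),

with `λ_d0` constant by default (exponential onsets) or piecewise-constant
over configurable age bands. A semi-parametric analysis model does not pin
down a generative law; the constant-hazard default is the simplest member
of the family the Cox model assumes and is exact for the closed-form
oracles used in tests. Censoring is administrative at a simulated
interview age drawn uniformly on a configurable window, 24–60 months by
default (the instrument covers ages 2–5; the true interview-age
distribution is unknown, so the uniform window is a documented guess).
Times are continuous months; `round_to_month` (off by default) rounds up
to whole months for grouped-time realism, with events conventionally
preceding censorings at tied times.

Confounders are drawn independently (binary/categorical with plausible
prevalences, continuous scores standardised); `covariate_effects` are
log-hazard coefficients, zero by default so group contrasts are
unconfounded. An optional `exposure_covariate_assoc` knob shifts the two
storm-severity scores in storm-exposed groups to induce confounding; it is
off by default so that every estimator is exercised first under its own
assumptions.

### Default disorder parameters

Two composite outcomes are configured. Disruptive behavioural disorders:
group hazard ratios (SS 6.4, CB 9.4, both 31.2) with the reference
cumulative risk 2.9% by 60 months. Anxiety disorders: (SS 3.3, CB 2.35,
both 7.89) with reference cumulative risk 20%. The CB-only anxiety ratio
is not reported in the motivating study; 2.35 is back-derived from the
reported synergy index 2.60 together with the other two ratios
(HR_B = (HR_AB − 1)/SI − HR_A + 2), so the default scenario is internally
consistent with a generative SI of 2.60 for anxiety and 2.19 for
disruptive disorders.

## Panel model

Each scale score is

    y_isw = μ_s[g(i), w] + b_is + e_isw,   b_is ~ N(0, ρσ_s²),  e_isw ~ N(0, (1−ρ)σ_s²),

an exchangeable within-subject correlation ρ (default 0.5) around a
group-by-wave mean surface, clipped to the instrument's printed range
(parenting-stress total 36–138, its subscales 12–56/12–57/12–50,
social-support scales 1–5). Whole waves go missing completely at random
with probability 0.15 by default — a missed annual visit drops all scales
at once. MCAR is the simplest regime under which GEE is valid; informative
missingness is deliberately out of scope. Default group means encode the
qualitative pattern of interest: dual-exposure families highest on
parenting stress and lowest on social support, cannabis-only intermediate,
storm-only close to the reference.

## Estimation

- **Cumulative lifetime risk** is the product-limit (Kaplan–Meier)
  estimator on retrospectively reported onset ages with censoring at the
  interview age; equality of the four strata is tested with the K-sample
  log-rank statistic (χ² on 3 df). Both delegate to `lifelines`.
- **Cox fits** use `lifelines`' partial-likelihood solver (Efron tie
  handling; immaterial for the continuous default times), Newton precision
  1e-8. The four-level group enters as three indicators against
  `neither`. Zero-event groups are flagged as monotone-likelihood
  (divergent estimate) rather than silently accepted; non-convergence
  triggers one flagged ridge-penalised (0.1) refit so diagnostics remain
  available. Wald confidence intervals on the log-hazard scale, two-sided,
  95% by default.
- **Proportional hazards** are checked with Grambsch–Therneau score tests
  on Schoenfeld residuals against a transform of event time (identity
  default; rank, Kaplan–Meier and log transforms available). Per-term
  statistics reproduce `lifelines`' exactly; the global p-df statistic
  `d·uᵀVu / Σ(g−ḡ)²` is computed in-package.
- **Staged modelling** enters blocks cumulatively — 11 confounders, then
  the two postnatal-environment scores (subject-level panel means), then
  the 3-df exposure factor — and tests each transition by likelihood ratio
  (Wald optional). Each confounder enters as a single column, so the first
  block carries 11 df. Stage p-values are unadjusted, matching a
  single-predictor design.
- **Synergy.** SI = (HR_AB − 1)/(HR_A + HR_B − 2), with the delta-method
  standard error of ln SI computed from either (a) the exposure-block
  covariance of the adjusted Cox fit (primary path) or (b) a 4×2
  case/control table, using var(β_k) = 1/a_k + 1/b_k + 1/a_0 + 1/b_0 and
  cov(β_j, β_k) = 1/a_0 + 1/b_0 for log odds ratios sharing the reference
  cells — a reconstruction of the classical count-based recipe, validated
  against a parametric bootstrap. Results record which path produced them.
  The index is undefined when HR_AB ≤ 1 or HR_A + HR_B ≤ 2; such inputs
  raise a named error and, in the simulation harness, are counted as
  failures rather than imputed. Zero table cells raise an error suggesting
  the (off-by-default) 0.5 continuity correction. RERI and the
  attributable proportion are provided as conveniences. No
  multiple-testing adjustment is applied across disorders by default.
- **GEE** uses `statsmodels` with identity link, Gaussian family and
  exchangeable working correlation (AR(1) and independence available),
  robust sandwich covariance, a 3-df Wald test for the overall group
  effect, and the six a-priori pairwise contrasts unadjusted.

## Simulation studies and problem sizes

The harness derives one sub-seed per replicate from the master seed
(`default_rng(seed).integers(0, 2³¹−1, n_reps)`), so every report is
reproducible bit-for-bit. Replicates with undefined SI or failed fits are
counted and reported; above 5% the scenario is marked unstable — at the
study's own size (163 split 70/27/53/13) with rare outcomes this flag
fires, which is the package's quantitative statement of the small-sample
caveat on inflated risk estimates.

Operating characteristics are measured where the asymptotic regime holds:
the type-I study uses n = 2000 per cohort with equal group allocation and
a reference cumulative risk of ~30% by 60 months (baseline hazard
0.006/month), giving several hundred events per replicate. Under the
skewed 70/27/53/13 allocation the dual-exposure arm is small and the Z
test runs conservative (rejection ≈ 0.03–0.04 at the same n); both
behaviours are real and the harness exposes either, but the calibration
claim is made under the information-rich design. Parameter-recovery
checks run at n = 20 000; the chi-square calibration of the staged block
test uses 1000 replicates of n = 200 cohorts; bootstrap validation of the
delta-method SE uses 10 000 resamples of a table with all cells ≥ 20.
These sizes make each check's Monte-Carlo error small relative to its
tolerance.

## What the synthetic data do not show

The generator emits SES and normative-stress class labels directly rather
than deriving them from latent-class models of indicator batteries; it
draws confounders independently of exposure by default; panel missingness
is MCAR; and onsets are exactly proportional-hazards. Passing tests
therefore establish the correctness and calibration of the estimators
under their stated assumptions — not robustness to informative
missingness, confounded exposure, measurement error in diagnoses, or
non-proportional hazards (beyond the Schoenfeld diagnostic's own power,
which is tested explicitly).

## Known limitations

- The "both" group in study-sized cohorts is tiny (n = 13); SI estimates
  there are heavy-tailed and the package deliberately reports instability
  instead of point estimates alone.
- No frailty terms, time-varying covariates, competing risks, mediation
  or growth-curve modelling.
- The count-table SE path uses odds ratios as the risk-ratio inputs; with
  common outcomes it overstates the hazard-ratio-based index's SE. The
  Cox-covariance path is primary for exactly this reason.
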