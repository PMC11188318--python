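# Methods

## Study design implemented

The package reconstructs a retrospective inception-cohort, per-protocol
comparative-effectiveness analysis from raw dispensing records. The exposure
is the monotherapy class of the first-ever antihypertensive dispensing
(reference: beta-blockers). Follow-up runs on a 180-day grid from the index
date to the earliest of: the acute-CDT outcome (two qualifying outcome-drug
dispensings within 180 days of each other; the event day is the first of the
pair), discontinuation (> 180-day gap in same-class supply, measured from the
end of covered supply), an add-on (a second antihypertensive class started
before discontinuation), 3,780 days, or the administrative end of data. A
switch (new class within 180 days *after* discontinuation) is recorded but
never censors. Ties at the follow-up end resolve event > add-on >
discontinuation, favoring outcome capture.

Two adherence measures are proportions of days covered by same-class supply:
over the whole follow-up (cohort-1 eligibility uses ≥ 0.80) and within each
180-day interval (a time-varying covariate). Supply intervals are half-open
`[dispense_day, dispense_day + days_covered)`; overlapping supply counts once
(no stockpiling credit). All dates are integer day offsets internally so
interval arithmetic is exact.

## Decisions where the design was open

- **`days_covered`** is a required input column (synthetic default: 90 days,
  the typical Dutch chronic-refill length). Adherence is undefined without a
  supply duration.
- **Registration history**: "2 years of records before index" is implemented
  as *earliest dispensing of any kind ≥ 730 days before index*; "1 year
  after" as *any dispensing after index + 365* (both parameterized).
- **Multiple-monotherapy exclusion**: a patient is excluded when *more than
  two* classes each reach ≥ 3 dispensings in the first post-index year
  (threshold `multi_class_limit=2`, configurable, since "more than two" could
  also be read as "two or more"). Exposure is always the index-date class.
- **Lipid co-therapy window**: the year *starting at* the index date
  (`lipid_window=(0, 365)`), parallel to the other first-year rules; a
  symmetric window is available by configuration.
- **Terminal interval denominator** for interval adherence: the actual
  interval length (a 100-day final interval fully covered scores 1.0), with
  the fixed-180-day reading selectable.
- **Outcome window**: rolling (two outcome dispensings within 180 days of
  each other), with a fixed-grid alternative selectable.
- **Discontinuation gap** is measured from the end of covered supply, not the
  dispense date (selectable), so long refills are not penalized.
- **Calendar time** enters the weight models as a three-level period factor
  (1996–2000, 2000–2010, 2010–2020; boundary years to the later period); age
  is continuous in the weight models and banded (18–39, 40–69, ≥ 70) in
  subgroup analyses.
- **Chronic-exclusion and comorbidity ATC sets** default to the standard ATC
  chapters for each indication (heart failure C01AA, migraine N02C, adrenal
  disease H02AA, hyperparathyroidism H05B, thyroid H03A/H03B; diabetes A10,
  RA M01C + L04A, asthma/COPD R03) and are fully configurable.

## Stabilized weights for a baseline-assigned exposure

The numerator model is a 5-class multinomial logit of the observed class on
sex, age and calendar period; the denominator adds the interval's
comorbidity-drug flags (model 1) or additionally the interval adherence
(model 2). Both are fitted by maximum likelihood on the pooled person-period
rows. The stabilized weight is the cumulative product over a patient's
intervals of the per-interval ratios of numerator-to-denominator treatment
probabilities.

Because the exposure is assigned once at baseline, the per-interval
probability of treatment *conditioned on treatment history* is 1 after the
first interval: the product reduces to the first-interval ratio carried
forward (`WeightModelSpec.weighting="treatment_history"`, the default). The
naive alternative — multiplying unconditional per-interval ratios
(`"pooled_product"`) — is retained for diagnostics but is inconsistent for a
baseline exposure with persistent confounders: each patient's ratio is
roughly constant across intervals, so weights grow or shrink geometrically
(in a 40,000-patient run over 10 intervals, weights reached ~5,000 and all
hazard-ratio estimates collapsed far below their planted values). With the
default semantics, weights stay bounded (max ≈ 4 under the default
confounding), per-interval mean weights sit at 1, and planted hazard ratios
are recovered.

Weighted Cox fits use a patient-clustered Lin–Wei sandwich variance computed
with exact delayed-entry risk sets (a row is at risk at event time *t* iff
`start < t ≤ stop`) and Breslow handling of tied events in the residuals;
point estimates use the Efron approximation. The implementation was checked
against R `survival::coxph(..., weights, cluster(id), robust=TRUE)`:
coefficients agree to 6 decimals, robust SEs to 4–5. Crude fits report the
model-based variance. Weight truncation is off by default; symmetric
percentile truncation is available. The probability floor for positivity
checking is 1e−12. The weighted Kaplan–Meier estimator is the product-limit
over counting-process rows with weighted risk sets, which with integer
weights equals the classical estimator on row-replicated data exactly.

Subgroup analyses reuse the overall weights (never refitted per subgroup);
interaction tests add exposure-by-subgroup product terms to the weighted Cox
model and report robust Wald p-values.

## What the synthetic generator emulates

Per patient: sex (45% male), age at index ~ N(58, 13.7²) clipped to [18, 90],
an index date inside 1996–2020, baseline comorbidity-drug flags (diabetes
8%, RA 1.2%, asthma/COPD 8%), class assignment by multinomial logit with
class shares matching a large inception cohort (BB 34%, ACEI 25%, thiazide
22%, ARB 9%, CCB 9%) and confounding by indication: diabetics shift toward
ACEI (+1.2 log-odds) and ARB (+1.0), and away from beta-blockers in
asthma/COPD (+0.55 toward each alternative) — magnitudes chosen to emulate
the strong ACEI/ARB-diabetes prescribing channel observed in real baseline
tables (diabetic share ~15% among ACEI vs ~2% among BB initiators).

Events follow a discrete-time complementary log-log hazard per 180-day
interval: baseline probability 0.009 (≈ 6% cumulative over a typical
follow-up), planted log hazard ratios vs BB of 0 (ACEI), log 0.79 (ARB),
log 1.10 (CCB), log 0.80 (thiazide), and comorbidity-flag effects (diabetes
HR 2.5, RA 1.3, asthma/COPD 1.5). Comorbidity onset is absorbing (0.1–0.5%
per interval). **By default sex, age and calendar time affect prescribing but
not the hazard**, so the planted class effects are exactly the marginal
hazard ratios the weighted analysis targets; hazard coefficients for these
covariates exist as knobs (default 0), as does a sex-by-class interaction
for effect-modification studies.

The full rendering emits ≥ 2 years of pre-index background dispensings,
90-day class refills with short gaps (5%/interval, 30–150 days), permanent
discontinuation (2%/interval, 30% followed by a switch), add-ons
(0.5%/interval), comorbidity-drug streams following the flag trajectories,
two outcome dispensings within 180 days of each event (proxy sensitivity 1
unless a misclassification rate is configured), and low rates of
exclusion-triggering co-medication. A fast rendering emits the person-period
table directly (full adherence, no protocol censoring) for estimator studies.

What it does **not** emulate: dose changes, stockpiling behavior, seasonal or
pharmacy-level structure, mortality or other competing risks, and any
dependence of adherence or discontinuation on prognosis (censoring is
non-informative by construction). Passing recovery tests therefore shows the
estimator chain is correct under its stated assumptions, not that those
assumptions hold in real claims data.

## Validation design and problem sizes

- **Replicate recovery bench** (`replication_config`): 200 replicates of
  4,000 patients, 6 intervals, baseline interval hazard 0.02 (~500 events per
  replicate). The elevated event rate keeps the weighted fit's small-sample
  bias an order of magnitude below the planted confounding signal at this
  reduced n; at the population event rate (~230 events) the bias-ordering
  comparison would be noise-dominated. Checks: robust 95% CIs cover each
  planted HR in ≥ 90% of replicates, and the mean log-HR bias after weighting
  is smaller in magnitude than the crude bias for every non-null class.
- **Large-sample coverage run** (`coverage_config`): one 20,000-patient
  simulation over 9 intervals (~4.4 years, matching a typical cohort's mean
  follow-up) at the population event rate.
- **Null calibration** (`calibration_config`): 2,000 patients, 5 intervals,
  hazard 0.03, comorbidity prevalences lifted (diabetes/asthma 10%, RA 5%)
  so every exposure-by-flag cell stays populated; used for the
  interaction-p-value uniformity check (200 replicates).
- The end-to-end pipeline (raw records → cohorts → episodes → estimates) is
  validated on a planted-null configuration and on a 23-patient hand-built
  fixture with one patient per eligibility rule, whose decisions, follow-up
  ends, censoring reasons and event counts are enumerated by hand.

## Numerical choices and degenerate inputs

- Multinomial fits: Newton–Raphson, max 200 iterations; a pre-fit check
  rejects binary covariates with an empty exposure-class cell (quasi-
  separation) naming the covariate; the pipeline falls back to crude-only
  estimates with a logged warning when weighting is unavailable.
- Constant covariate columns are dropped from design matrices (they make the
  MLE singular); period dummies absent from the data are omitted.
- Zero-length person-period rows and event-free datasets are rejected with
  explicit errors; non-positive follow-up drops the patient with a warning.
- Eligibility attrition attributes each excluded patient to their first
  failing rule in the fixed ledger order; all rules are evaluated for every
  indexed patient (no short-circuiting), so complete reason lists are
  reported.
- Follow-up years use 365.25 days/year; percentages are reported to one
  decimal.

## Known limitations

- The acute-CDT outcome is a drug proxy; in simulation its sensitivity is 1
  by default, which is optimistic for real data.
- Comorbidity flags are drug-use proxies, not diagnoses.
- No competing-risk or mortality modelling; censoring by the 10-year horizon
  and administrative end is assumed non-informative.
- The weighted analysis adjusts only for measured prescribing channels; the
  numerator covariates (sex, age, period) are balanced by stabilization, not
  adjustment, so they must not be outcome-relevant — true in the generator's
  default scaffold, unverifiable in real data.
- Hazard ratios are non-collapsible; planted conditional effects and
  estimated marginal effects coincide here only because the generator keeps
  frailty variation small and censoring independent.
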