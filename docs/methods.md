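# Methods

## The index

The DDCI treats chronic drug exposure as a proxy for chronic disease.
Exposure is assessed over the half-open baseline year `[index − 365 d,
index)`: a package dispensed exactly 365 days before the index date counts,
one dispensed on the index date does not.  "Packages" sums per-dispensation
package quantities, not prescription rows, matching how Italian pharmacy
claims record dispensations.  Nineteen drug classes are defined by ATC
prefix sets with per-class package thresholds (3 for most classes, 2 for
antihyperglycemics, 1 for the neuro/psychiatric classes) and two special
constructions:

* **Opioids** exclude codeine and tramadol.  The source names substances,
  not codes; the default exclusion list is N02AA59, N02AA79, N02AX02,
  N02AX52 and is configurable.
* **Hypertensive heart disease** uses a 45-day combination rule: the flag
  is raised when, within any sliding 45-day span of the baseline year,
  prescriptions matching at least two *distinct* members of
  {C01AA05, C03CA01, C03DA01, C07AG02, C07AB07, C07AB03, C09} occur, or at
  least two prescription rows of digoxin (C01AA05) occur.  The published
  wording ("any combination of drugs … within 45 days") does not fix
  whether two agents must be co-prescribed on one day or merely fall in the
  same window; we chose the window reading, with "within" meaning a date
  difference of at most 45 days.  A whole C09 subgroup counts as a single
  member: two different ACE-inhibitor products are one agent, not a
  combination.

The published class table maps anti-dementia drugs to N06A and
antidepressants to N06D — the reverse of standard ATC semantics.  The
default rule table follows the published source verbatim;
`default_rule_table(standard_neuro_atc=True)` restores the standard
assignment.  Rule tables round-trip through YAML so users can re-define
classes.

Scoring is the algebraic sum of integer weights over positive flags.  No
exclusivity between classes is imposed: the positive weights sum to 36,
although the source states a maximum of 33; the discrepancy is immaterial
downstream because scores of 11 or more share the top risk class.  Class
folding maps ≤0 → 0, 1–10 → identity, ≥11 → 11, giving exactly 12 classes.

The Charlson comparator uses a Deyo-style ICD-9-CM prefix mapping with the
original Charlson weights, shipped as an editable YAML file
(`ddci/data/charlson_icd9.yaml`).  Three severity hierarchies are applied
(complicated diabetes over diabetes, metastatic over primary malignancy,
moderate/severe over mild liver disease).  The CCI baseline window equals
the prescription window (admission date in the year before index); persons
without a baseline admission score 0.

## Weight derivation

`DdciWeightModel.fit()` maximises the Cox partial likelihood (lifelines,
Efron tie handling — event dates in claims tie heavily at day resolution)
for the 19 exposure flags, converts each coefficient to
`round(β/0.3)` with halves away from zero, drops classes whose two-sided
Wald p ≥ 0.05 ("not significantly associated"), and keeps zero-weight
classes in the table.  Dropped classes also remain in the table with weight
0 so that downstream scoring always sees a complete table; they are listed
separately as excluded.  None of the 19 published coefficients sits on a
rounding tie, so the tie-break is observationally free but fixed.

By default the fit includes **age (centred at 60) as an adjustment
covariate** that is never converted to a weight.  The synthetic cohort has
a real age effect on mortality; omitting it from the regression acts as a
lognormal frailty (σ ≈ 1.1 at the default age spread) and attenuates the
flag coefficients well beyond their standard errors, which is a property of
the marginal Cox estimand, not an estimation error.  Adjusting for age
restores unbiased recovery of the generative conditional coefficients
(verified at n = 400,000: spot z-scores within ±1.9).  A flags-only fit
remains available by passing `adjustment=None`.

## Survival and evaluation

Follow-up runs from the index date to the earliest of death, migration and
the 7-year horizon; the event indicator is a death occurring no later than
the other two.  Date arithmetic is in days with years = days/365.25.

* **Kaplan–Meier** curves per risk class (lifelines product-limit).
* **Class-wise hazard ratios**: Cox with indicator covariates for classes
  1–11 plus age and sex, class 0 as reference.  A sparse class whose
  indicator makes the information matrix singular (complete separation) is
  dropped with a warning, smallest class first.
* **Harrell's C**: among usable pairs — the shorter time is an event and
  times differ, or times are equal and exactly one is an event — the
  fraction where the higher risk score fails first, 0.5 credit for score
  ties.  The 95% CI uses a delete-one jackknife linearisation of the
  pair-ratio statistic (asymptotically equivalent to the classical
  large-sample variance of the concordance U-statistic); a seeded
  person-level bootstrap (200 resamples) is available for small cohorts.
  The pair scan is blockwise O(n²), practical to ~10⁵ persons.
* **NRI** is the category-free (continuous) variant: the published
  component values (e.g. 0.656 for non-events) are not compatible with any
  small set of published risk categories, and no categories are stated.
  Predicted horizon risk is `1 − S₀(t)^exp(lp)` with the Breslow baseline
  from the fitted Cox model.  Persons censored before the horizon have
  unknown event status and are excluded from the NRI denominators — a
  documented limitation; an inverse-probability-of-censoring-weighted
  variant (`ipcw=True`, KM of the censoring distribution) is provided but
  off by default.  Variance is the standard asymptotic sum of the two net
  proportion variances.
* **Readmissions**: exposure time starts at the first unplanned discharge
  after index and ends at death/migration/study end; all later admissions
  count.  Rates per class and IRRs vs class 0 come from a log-linear
  Poisson model with log person-years offset, adjusted for age (continuous)
  and sex.  With a single binary class and no covariates the model IRR
  equals the crude rate ratio exactly, which the tests assert.
* **Model comparison** (`ModelComparison`) fits a reference Cox model (age
  + sex; optionally + CCI) and an augmented one (+DDCI and/or +CCI) on the
  same persons, truncates follow-up at the chosen horizon (1 y and 7 y
  mirror the published analyses), and reports both C-indices and the NRI
  between the predicted horizon risks.

## Synthetic cohort

The generator emulates the development-cohort conditions; every value is a
`SimulationConfig` field:

| parameter | default | origin |
|---|---|---|
| exposure prevalences | published per-class values (0.05%–29.45%) | training-cohort table |
| class log-HRs | published coefficients | weight table |
| age | normal(60.17, 13.57) truncated at 40 | cohort demographics |
| male fraction | 0.4629 | cohort demographics |
| horizon | 7 y | study design |
| baseline hazard | 0.0059 /y | solved so expected 7-y cumulative mortality equals the published 10.67% given prevalences, coefficients and the age effect |
| β_age | 0.08 per year | small plausible effect so age-adjusted paths are exercised; the real cohort's value is unpublished |
| migration rate | 0.005 /y | consistent with the published mean follow-up of 6.62 y |
| admission rate, class 0 | 0.10 /y | makes P(≥1 unplanned admission in 7 y) ≈ the published 48.6% any-hospitalization fraction |
| admission rate step | 1.17 per class | ≈ 5.62^(1/11), the published top-class readmission IRR gradient |
| baseline admission probability | 0.125 | published 12.5% with ≥1 prior hospitalization |

Flags are drawn independently per class (a Gaussian-copula correlation
option exists for stress tests, off by default); death times are
exponential given the per-person hazard; prescription rows are constructed
to satisfy true flags (codes drawn from a per-class list chosen so that one
class's codes never satisfy another class's rule) and to fail false flags
(sub-threshold noise at 5% per class, single combination agents, tramadol
rows).  Dates are emitted at day resolution; a re-derived survival time
differs from the generative one by at most half a day.  ICD-9 codes in
baseline admissions mix Charlson-mappable and filler codes so the CCI has
signal.  Randomness uses one `numpy` sub-stream per output table, derived
deterministically from the seed; identical seeds give byte-identical files.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: correlated multimorbidity (statin use co-occurs
with hypertension treatment in life, not here), non-exponential and
age-varying baseline hazards, seasonal or adherence-driven dispensing
patterns, regional care variation, in-hospital drug dispensing (the known
under-capture of cancer therapy), and any dependence of admission intensity
on time since discharge.

## Problem sizes and known limitations

Default test problem sizes were chosen to keep the full suite fast while
leaving each statistical check well-powered: n = 4,000 for shared unit
fixtures, 20,000–50,000 for calibration checks, 100,000 for the
weight-recovery run, 30,000 for the qualitative risk-gradient checks.

At n = 100,000 the integer weight column is *not* reliably recoverable even
by an unbiased fit: several published coefficients sit within one standard
error of a rounding boundary (bronchodilators 0.739 vs the 0.75 cut,
parenteral anticoagulants 0.435 and corticosteroids 0.464 vs 0.45,
opioids 1.672 vs 1.65 with only ~50 exposed), and the rarest class
(immunosuppressants, 0.19%) passes the significance filter with only
~25–30% power, so typical agreement is 15–17 of 19 classes.  The original
derivation cohort was an order of magnitude larger, which shrinks the
standard errors ~3-fold.  The 3-SE coefficient-recovery check, by
contrast, passes consistently.

Other limitations: transfers between admissions are not merged (each
discharge row is a record); ICD-9 validation is syntactic only; the NRI
under heavy censoring before the horizon relies on the exclusion (or IPCW)
convention above; person identifiers are opaque strings with no
record-linkage semantics.
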