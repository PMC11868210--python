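# Methods

This note documents the statistical model behind `icecohort`, the design
choices made where several defensible options existed, the synthetic
cohort's assumptions, and what the tests do and do not establish.

## Register phenotyping

Diagnosis codes are normalized to uppercase, dot-free form before any
matching; the Danish SKS "D"-prefix dialect can be stripped with an
explicit flag (default off — the synthetic data uses plain ICD-10, and a
"D" is only stripped when the remainder looks like an ICD-10 code, so
D-chapter codes are safe). Code lists live in a versioned YAML file
(`src/icecohort/data/attempt_algorithm_codes.yaml`) as inclusive three-character
ranges and prefixes plus exclusion prefixes; matching is prefix-closed
(X631 ∈ X60–X84) and an exclusion always wins (T40.1 never matches the
accidental-intoxication list even though T40 does).

Decisions worth recording:

- **Definition scope.** The X-code criterion (a) checks the main *and*
  supplementary diagnoses and is also triggered by a reason-of-contact
  recording of "suicide attempt", modelled as a boolean flag rather than
  a parsed national contact-reason taxonomy (it acts only as a binary
  trigger). Criteria (b)–(d) check the *main* diagnosis only, combined
  with sub-diagnoses for (c)/(d). Y87.0 counts only toward suicide
  deaths, never attempts.
- **Episode definition.** The registers record contacts, not attempts; a
  transfer between departments on the same day is one event. Default:
  one episode per person per calendar day (union of triggered
  definitions), with a configurable `merge_window_days` that chains
  contacts whose gap is ≤ k days for sensitivity analyses. Admission
  chains longer than the window remain separate episodes.
- **Age filter and censoring.** Episodes before the 10th birthday are
  dropped (register-recorded "attempts" at younger ages are almost all
  accidental ingestions); age is completed years at the contact date
  (floor, registry convention). For respondents, episodes on or after the
  questionnaire completion date are censored; non-respondents are not
  censored. A contact dated before birth raises an error (corrupt input).
- **Suicide rule.** Cause in X60–X84 or Y87.0, *or* manner of death
  registered as suicide — a missing cause with manner "suicide" still
  counts.

## Survey processing

Three lifetime items (ideation, plans, attempt) with answers
yes/no/do-not-know; an affirmative lifetime answer triggers a last-year
follow-up item. The skip pattern maps "follow-up not asked" to *false*
for last-year indicators: someone denying lifetime suicidality has no
last-year suicidality. "Do not know" is recoded to "no" in the main
analysis (`dk_as_no`, nobody dropped) and treated as missing in the
sensitivity analysis (`dk_excluded`, the person is dropped for that
item); the same rule applies to last-year answers. The plans items exist
only for respondents completing after the rollout date (default
2019-05-31); earlier respondents carry `not_asked` and are excluded from
plans analyses but not from anything else. A missing lifetime answer on a
non-plans item marks the record ineligible — the study population is
defined by complete suicidality items.

## Iceberg linkage

One mutually exclusive category per respondent at the highest level:
none(0) < ideation(1) < plans(2) < self-reported attempt(3) <
hospital-recorded attempt(4) < suicide(5). The plans level is assignable
only in analyses of the plans sub-population. Suicide is quantified
separately on the full background population by sex (unweighted — the
denominator is every birth in the recruitment window) because death
precludes survey participation; a respondent is never re-assigned to the
suicide level.

## Participation weighting

Participation in the survey is modelled per analysis stratum by a
maximum-likelihood logistic regression of the participation indicator on
categorical background covariates (income quartile, parental education,
parental job status, maternal age band, parity band, co-living parents,
out-of-home placement, adolescent psychiatric diagnosis, parental
psychiatric diagnosis; sex and income enter only when not stratified
upon). Missing covariate values form their own explicit level. Weights
are w = 1/π̂ for participants, truncated at τ = median(w) + 5·IQR(w)
computed on the *untruncated* within-stratum weights (so τ is independent
of any later normalization), then rescaled so Σw equals the stratum's
participant count — percentages and CI formulas then use familiar
denominators. Inverse predicted probability was chosen over
post-stratification ratios: it is the standard correction for
participation selection and matches the intended direction (lower
participation probability ⇒ larger weight).

Numerical safeguards: complete separation is detected before fitting and
reported with the offending covariate and level; within sparse strata the
stratified driver drops the separated covariate (logged) and, in the
degenerate limit, falls back to a constant participation rate, which
yields unit weights. Fitted probabilities are clipped to (1e-10,
1 − 1e-10) against floating-point underflow.

## Prevalence estimation

Weighted prevalence p̂ = Σwᵢ1[catᵢ = c]/Σwᵢ with a Wald 95% CI
p̂ ± z₀.₉₇₅·√(p̂(1−p̂)/n_eff), clipped to [0, 1]. For weighted analyses
n_eff is the Kish effective sample size (Σw)²/Σw² — the minimal honest
variance adjustment for unequal weights; unweighted analyses use the raw
n (this reproduces textbook Wald intervals, e.g. the worked suicide
example). Degenerate strata (single category) yield p̂ = 1 with a [1, 1]
interval; empty or all-zero-weight strata are errors. Category estimates
within a stratum sum to 1 exactly before rounding; reported percentages
round to one decimal, ratios to the nearest integer ("1:2" style). The
hidden-number ratio divides the self-reported-only attempt prevalence by
the hospital-recorded prevalence; a zero denominator is reported as
undefined rather than raising. Income quartiles are cut from the
*background* income distribution (quartiles describe the population, not
the respondent sample). Joint sex-by-income stratification is refused by
default — hospital-recorded attempts are too sparse for it — but can be
forced.

Design-based variance (accounting for weight estimation) is not
implemented; the Kish adjustment treats weights as fixed.

## Algorithm validation

Among respondents with ≥1 eligible episode, the proportion answering
"yes" to the attempt (or ideation) item, with normal-approximation CIs,
overall, by sex, and by definition subgroup. A person with any
definition-(a) episode belongs to `def_a` (explicitly recorded intent);
only-(b)–(d) persons to `def_bcd`. Proportions are unweighted: they
condition on register positivity, which is itself a register quantity.
The overall proportion is exactly the positive-count-weighted mixture of
the subgroup proportions (tested as an identity). The last-year variant
restricts both the episodes (within 365 days before completion) and the
self-report window.

## Synthetic cohort generator

The generator is a pure function of (config, seed) emitting
persons/contacts/deaths/survey CSVs plus a latent truth table. Defaults
describe a birth cohort of 100,000 (configurable) born 1996–2003,
questionnaire at age 18 years 3 months plus up to 90 days of jitter.

- **Covariates** are drawn independently from marginals matching the
  background population of the study setting (49% girls, near-uniform
  income quartiles with 1.5% missing, etc.). Joint covariate structure is
  *not* emulated — the weighting model is main-effects and the
  participation mechanism is generated from the same family, so the
  model is correctly specified by construction. Passing tests therefore
  show the estimators work when their assumptions hold, not that a
  main-effects model suffices for real registry data.
- **Latent suicidality** is nested by default (attempt ⇒ plans ⇒
  ideation), parameterised as P(ideation), P(plans|ideation),
  P(attempt|plans) per sex, with an income-quartile odds multiplier on
  the attempt stage producing the social gradient (Q1 odds ×1.9 … Q4
  ×0.55). A non-nested switch draws the three states independently at
  the implied marginals. Defaults are calibrated so the *measured*
  landscape reproduces the published one: girls ≈ 4.1% self-reported-only
  and 1.8% hospital-recorded attempts (ratio 1:2), boys ≈ 2.4%/0.4%
  (1:6), plans ≈ 8%/7%.
- **Hospital presentation** given a lifetime attempt is sex-specific
  (girls 0.25, boys 0.094 — solved from the published prevalence pairs
  and reporting probabilities). Presenters get 1 + Poisson(0.5 girls /
  0.2 boys) episodes at ages 12–18, each coded to a configurable
  definition mix (a 55%, b 18%, c 17%, d 10%; one in five (a)-episodes is
  flag-only with a non-specific main diagnosis). 10% of episodes gain a
  same-day transfer contact (exercises merging). Decoy contacts (5% of
  persons: T40.1, forearm injuries without psychiatric main diagnosis,
  alcohol intoxications, accidents) must never classify; rare
  under-age (0.4%) and post-completion (0.3%) attempt-coded contacts
  exercise the age and censoring filters.
- **Participation** follows a main-effects logit on the covariates
  (intercept 0.15; girls +0.78; Q1 −1.0 vs Q4 +0.35; …) giving ≈61%
  participation among girls and ≈44% among boys, with the low-income,
  low-education groups under-represented — the selection the weights must
  undo.
- **Reporting.** Given a true state, the "yes" probabilities are
  ideation 0.92, plans 0.80, attempt 0.78 (girls)/0.62 (boys) — boys
  under-report more, as the validity analysis expects. A reported attempt
  or plan forces the ideation answer to "yes" (no one reports an attempt
  while denying ideation). There are no false-positive reports.
  Do-not-know rates among non-"yes" answers: ideation 5%, plans 2%,
  attempt 1%. Last-year "yes" given lifetime "yes": 60/50/25%.
- **Deaths.** Suicide before 18 with probability 0.011% (girls) /
  0.016% (boys), independent of the latent states (the analysis treats
  suicide as a separate background quantity); 0.05% other deaths. The
  dead never respond and carry no hospital contacts.
- `expected_category_proportions()` returns the exact closed-form
  category distribution implied by a configuration (mixing over the
  income marginals), which is the estimand a correctly weighted analysis
  targets; the recovery tests compare pipeline output against it.
- `fixture_small()` is a deterministic 12-person cohort covering every
  level in each sex plus every tricky edge (T40.1, same-day transfer,
  under-age and post-completion contacts, do-not-know, pre-rollout,
  manner-only and Y87.0 suicides); it backs the unit tests.

## Problem sizes

The shipped test suite uses a 30,000-person shared cohort for module
tests, 100,000 for the end-to-end parameter-recovery checks, and
`scripts/acceptance.py` runs an 80,000-person cohort; these sizes give
respondent strata of ~15–25k, where CI half-widths (≈0.2–0.3 percentage
points on the attempt categories) are informative against the configured
truth. All simulations are seeded and deterministic.

## Known limitations

- The "last-year ≤ lifetime" relation holds for *cumulative*
  (at-level-or-above) prevalences and is tested as such; it is not a
  theorem for the exclusive middle categories (a lifetime-hospital person
  can be ideation-only within the last year).
- Weight-estimation variability is ignored in the CIs (no design-based or
  replicate-weight variance).
- The generator draws covariates independently and uses a
  correctly-specified participation model; it does not reproduce real
  joint covariate distributions, regional coding practice, or repeated
  attempts spanning the age-10 boundary.
- Validation measures concordance with self-report only; it cannot
  separate register misclassification from under-reporting (the generator
  makes both mechanisms explicit parameters instead).
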