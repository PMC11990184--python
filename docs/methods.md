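# Methods

## Scope and data model

The package implements a cross-sectional association analysis between
ultra-processed food (UPF) consumption and plant-based diet quality on
single-day 24 h recall data with complex-survey weights. All inputs are
plain delimited tables: a food-composition table (8-digit food codes,
energy density in kJ/100 g, a recipe flag), a recipe/ingredient table
(parent code, ingredient code, weight fraction), a NOVA assignment table
(food code → processing group 1–4), a plant-group apportionment table
(food code → servings per 100 g across 23 source food groups), per-item
recall records (participant, food code, grams, energy in kJ), participant
covariates/anthropometry, and person + replicate weights.

Energy is canonically kJ internally (1 kcal = 4.184 kJ); outputs report
kcal where tables conventionally do.

## Cohort filter

Participants are excluded sequentially: age < 19 y, pregnant,
breastfeeding, missing UPF intake. The exclusion ledger records the count
removed at each step, in that order. Energy misreporters are never
excluded (see below).

## Recipe disaggregation and the UPF energy share

Handmade mixed dishes are split one level deep into ingredients by recipe
weight fractions (the reference loader rejects nested recipes, so one pass
suffices). Ingredient energies are first computed as grams × ingredient
energy density and then rescaled proportionally so they sum to the recall's
reported energy for the dish; the reported energy is treated as
authoritative because it keeps every participant's total energy identical
before and after disaggregation. Whether the original survey analysis
rescaled this way is unknowable from the outside; the rule is this
package's own declared convention. If all ingredient densities are zero the
reported energy is split by weight fraction.

Every post-disaggregation item must carry exactly one NOVA group; a missing
assignment is a hard error rather than a silent default, because
misclassification propagates directly into the outcome. The UPF share is
100 × (energy in NOVA 4)/(total energy) per participant; participants with
zero total energy are excluded with a logged warning. NOVA-group energy
shares sum to 100% per participant by construction.

## Servings, quintiles, and index scoring

Apportionment is collapsed from 23 source groups to the 18 analysis groups
before scoring. The exact source scheme is configurable YAML; the shipped
default collapses three dairy fat strata into one dairy group and four
red-meat/poultry strata into one meat group, with every other source group
mapping to itself. This default is an explicit assumption: only the dairy
and meat collapses are standard, and any alternative 23-group layout can be
supplied without code changes.

Daily servings per group are Σ grams/100 × servings_per_100g over a
participant's items, zero-filled for unconsumed groups. Quintile cutpoints
are the weighted 20/40/60/80th percentiles of each group's distribution,
where the weighted quantile is the left-continuous inverse of the weighted
empirical CDF — chosen because it is exactly reproducible and directly
checkable against a brute-force weighted-rank oracle. Cutpoints use the
survey person weights by default (all analyses are weighted; a flag
disables this for sensitivity).

Quintile membership uses half-open intervals (−∞,c1], (c1,c2], …, (c4,∞):
boundary ties fall in the lower quintile. Under heavy zero-inflation
(legumes, fish) several cutpoints collapse; all tied values then share the
lowest applicable quintile, so a non-consumer of a healthy group scores 1
under forward scoring. This deterministic tie rule matches the
"lowest-consumption" semantics of reverse scoring and avoids random
tie-breaking.

Component scores are forward (score = quintile) or reverse (6 − quintile)
per the index: PDI scores all plant groups forward and animal groups in
reverse; hPDI scores healthy plant groups forward and everything else in
reverse; uPDI scores unhealthy plant groups forward and everything else in
reverse. Indices are the sums of the 18 components, so each lies in
[18, 90]. Useful identities (all property-tested): for healthy plant
groups hPDI + uPDI components = 6 and PDI = hPDI; for unhealthy plant
groups PDI = uPDI and hPDI = 6 − uPDI; animal components are identical
under all three indices. Servings are not energy-adjusted before scoring.

## Energy misreporting

The misreporting covariate is the ratio of reported energy intake to
predicted basal metabolic rate (EI:BMR), both in MJ/day. BMR comes from
Schofield-type sex- and age-band linear functions of body weight (bands
19–30, 31–60, 61+; e.g., male 19–30: 0.063·kg + 2.896 MJ/d), shipped as a
YAML-swappable coefficient table since equation families differ between
surveys. Participants missing body weight receive the weighted-mean ratio
(logged) so the adjusted model loses no one; no Goldberg cut-off exclusion
is applied anywhere.

## Survey-weighted inference

`SurveyWLS` computes weighted least-squares point estimates with the person
weights (statsmodels WLS under the hood) and estimates the covariance by
refitting under each of the R replicate-weight columns:

Var(β̂) = c · Σ_r (β̂_r − β̂)(β̂_r − β̂)ᵀ,  c = (R−1)/R by default.

The generic delete-a-group jackknife form is used because replication
schemes differ between surveys; c is configurable. CIs and p-values use
the standard normal reference — the usual large-sample survey convention,
since jackknife degrees of freedom are ambiguous. A rank-deficient
weighted design matrix is an error naming the suspect columns;
zero-variance covariate columns (a constant covariate, or an unobserved
category level in a subgroup) are absorbed into the intercept rather than
treated as rank deficiency.

Analysis outputs:

* **Descriptives by index quintile** — weighted means (replicate SE) for
  continuous rows and weighted percentages for categorical rows, across
  weighted quintiles of each index. Trend p-values come from a weighted
  regression of the row variable on the quintile number 1–5 (the simplest
  reading of a linear trend across ordered groups); categorical rows use a
  weighted Pearson χ² on the weighted contingency table (with unit weights
  this is the classic count statistic). A first-order Rao–Scott
  design-effect correction, estimated from replicate variances of the cell
  proportions, is available by flag and off by default.
* **Index models** — for each index: crude, model 1 (age, sex, education,
  country of birth, rurality, area-level disadvantage), model 2 (+
  EI:BMR). The UPF energy share is the dependent variable and the index
  the exposure; a flag transposes the two as a sensitivity analysis.
* **Component associations** — one model-2-adjusted fit per component
  score per index; the six animal groups enter as one combined score (sum
  of the six animal components), identical under all indices.
* **Moderation** — model 2 plus index × moderator product terms for age
  (continuous), sex, and education (dummy products); subgroup fits by
  moderator level (weighted median split for age) are emitted alongside.

No multiple-testing adjustment is applied anywhere (α = 0.05 throughout).

## Synthetic-data generator

The generator emulates the survey features the analysis consumes, with
marginals fixed at the study conditions: mean daily energy 2001 kcal
(SD 600, truncated at 600), mean UPF energy share 39.1%, mean age 49.4 y
(SD 17.3, truncated 19–95), 49.4% female, R = 30 delete-a-group jackknife
replicate weights, and group-specific zero-inflation probabilities (e.g.,
legumes 0.75, vegetables 0.05) with log-normal servings given consumption.

A latent unhealthful-diet axis z ~ N(0,1) tilts log servings (healthy
groups load −0.35, unhealthy +0.40, animal +0.15), creating realistic
correlation structure among groups and hence among the indices. Items
realise the servings (one food per consumed group; ~15% of participants
additionally eat a handmade recipe dish with all-non-UPF ingredients), the
recalls are scored with the package's own pipeline, and only then is the
UPF share assigned:

UPF_i = 39.1 + Σ_k slope_k (index_ki − weighted mean) [+ interaction] + ε_i,
ε ~ N(0, 4), clipped to (0.5, 99.5).

Because the indices in this formula are exactly the indices the analysis
recomputes from the same grams, each configured slope is the exact
conditional expectation of the corresponding single-index regression
coefficient — which makes effect-size recovery testable without
derivations about rank statistics. Item energies then realise both the
daily total and the UPF share by proportional scaling within the NOVA-4
and non-NOVA-4 item pools; two always-consumed zero-serving beverage
"filler" foods (one NOVA 1, one NOVA 4) guarantee both pools are
non-empty, and all-non-UPF recipe ingredients keep the share invariant
under disaggregation.

What the generator does **not** emulate: day-to-day intake variation
(single recall by design), correlated measurement error between energy and
servings, realistic per-item energy bookkeeping (item energies are scaled
to meet the participant-level targets, so a single item's kJ/g can be
unrealistic even though totals and shares are exact), stratified/clustered
sampling beyond what delete-a-group jackknife weights encode, and the full
joint distribution of the real food supply. Passing recovery tests
therefore demonstrates that the pipeline's estimators are correct and
unbiased under the stated generating process, not that the published
coefficient values would be reproduced on restricted microdata.
Sociodemographic gradients (younger age, lower education at higher z) are
available but off by default so recovery tests are unconfounded.

All randomness derives from a single integer seed through separate
`SeedSequence` streams per component, making every dataset and every
downstream result hash-stable.

## Problem sizes and numerical conventions

Monte-Carlo suites use 20 replicate datasets of n = 2000 for effect-size
and interaction recovery (band: 3 Monte-Carlo SDs of the mean), 50
populations of n = 50 for quintile-oracle equivalence, and n = 400 cohorts
for the distributional unit tests. Weighted-quantile ties, quintile
boundaries, and the jackknife variance scale follow the conventions above;
exact-arithmetic oracles are asserted at 1e-8 (WLS vs normal equations)
and 1e-9 (χ², conservation identities). Sorting before aggregation is
stable (mergesort) so results are invariant to input row order.

## Known limitations

* The 23→18 collapse beyond dairy and meat is an assumption; real
  apportionment databases may differ.
* The replicate-variance form is generic delete-a-group jackknife; a
  survey with Fay-adjusted BRR weights needs a custom `variance_scale`.
* The weighted χ² without Rao–Scott correction can be anti-conservative
  under strong clustering; the correction flag is provided but first-order
  only.
* BMR equations apply to ages ≥ 19 only, matching the cohort filter.
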