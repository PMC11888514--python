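# Methods

## The problem

Randomized nutrition trials differ from drug trials in two structural ways.
First, the control arm is not unexposed: participants obtain the tested
nutrient from their habitual diet, sometimes in amounts matching the
intervention.  Second, adherence is usually tracked by pill-count
questionnaires, which overstate it.  Both errors misclassify actual exposure
relative to randomized assignment and bias the intention-to-treat (ITT)
effect estimate toward the null.  Validated urinary intake biomarkers allow
both to be measured: a spot-urine sample at baseline measures the background
diet, and one during follow-up measures achieved exposure (background +
supplement).  This package implements that re-analysis strategy — threshold
derivation, exposure classification, and contrasted survival analyses — for
the cocoa-flavanol setting, with gVLM_B (γ-valerolactone metabolites, a
general flavanol biomarker with longer half-life) and SREM_B
((−)-epicatechin metabolites, specific and shorter-lived) as the biomarker
pair and 500 mg/day as the reference dose.

## Threshold derivation (`calibration`)

A dose-escalation study supplies (dose mg, concentration µM) pairs per
biomarker.  We fit OLS of log2(concentration) on dose and define the
classification threshold at a target dose D as the *lower* end of a 95%
interval for log2-concentration at D, back-transformed by 2^(·).  Quantiles
use Student's t with n−2 df rather than the normal, since calibration
studies are small.

Two interval kinds are implemented and the choice is config-exposed:

* **prediction** (default): lower bound of the new-individual prediction
  interval, variance = s²(1 + h) with h the leverage of the target dose
  point.  A threshold is applied to *individual* urines, and the stated goal
  of a conservative threshold is to keep false negatives rare despite
  inter-individual variability — that is what a prediction bound controls.
* **mean_ci**: lower confidence bound for the mean response, variance = s²h.
  This reads more literally as "CI of the expected concentration" but is far
  less conservative (at n=40 it sits near the fitted mean).

The dose predictor is untransformed by default (only the concentration is
log-transformed); a log2-dose mode is available because published
calibration analyses are often ambiguous on this point.  The reference
profile `cosmos` ships the field's published thresholds, 18.2 µM (gVLM_B)
and 7.8 µM (SREM_B), which are not recomputable here because the underlying
calibration dataset is not distributed with this package.

## Classification (`classify`)

A sample is **above** iff gVLM ≥ t_g OR SREM ≥ t_s.  The OR rule exploits
the two half-lives: either biomarker being high evidences intake at or above
the reference dose.  Boundary values count as above ("at least" semantics).
Below-LOQ measurements are classified by their stored numeric value (always
below any realistic threshold); the below-LOQ *statistic* uses the assay
flags, not the values.

Participant groups: **biomarker-active** = above at baseline or at any
follow-up visit (any-visit OR; the combination operator across follow-up
years is not standardized in the field — OR is the one consistent with the
group's "either at baseline or follow-up" definition); **biomarker-control**
= below everywhere observed; **excluded** = intervention-arm participants
with no follow-up sample and a below-threshold baseline, whose adherence is
unobservable; **unclassifiable** = no baseline sample.  The exclusion is
deliberately asymmetric: a placebo participant without follow-up is a valid
control because their exposure is the background diet, which the baseline
sample measures.

Percentages in tabulated output are rounded half-up to integer percent,
matching the display convention of published cohort tables.

## Survival contrasts (`survival`)

All contrasts are Cox proportional-hazards fits (partial likelihood, Efron
tie handling) of a binary exposure indicator plus covariates:

* **ITT**: exposure = randomized arm, all participants;
* **PP**: as ITT, but follow-up is censored at the first self-report of
  missing >8 pills/month, being unsure, or outside supplement use; reports
  dated after the endpoint time change nothing and are counted in
  diagnostics;
* **biomarker**: active vs control groups, excluded/unclassifiable dropped.

Covariate ladders: model 1 = sex, age, recruitment cohort; model 2 adds BMI,
smoking (never/ever/current), aspirin; model 3 adds diet-quality score
(aHEI, consumed as a given numeric column), family history and hypertension
history; models 4 and 5 extend model 2 by randomization and aHEI
respectively.  Continuous covariates enter as restricted cubic splines with
3 knots at the 0.1/0.5/0.9 sample quantiles (the middle knot location is a
convention, configurable), truncated-power basis with linearity constraints
beyond the outer knots.  The proportional-hazards assumption is checked via
the scaled-Schoenfeld construction (cox.zph), identity time transform by
default.

Missing covariates are imputed by chained equations with the event indicator
and the Nelson–Aalen cumulative-hazard estimate (computed once, on the full
data, before imputation) among the predictors — the standard recipe for Cox
covariate imputation — with m=10 by default and Rubin's rules pooling
(Barnard–Rubin t reference; with zero between-imputation variance the pooled
result reduces exactly to a single fit).  Only numeric covariates are
imputable; categorical missingness is rejected rather than silently handled.

Adjusted cumulative-incidence curves are 1 − exp(−H(t | x_ref, group)) from
the Breslow baseline hazard at a fixed reference profile (age 75, male, BMI
25 kg/m², never-smoker, no aspirin, WHI recruitment cohort).

Cox fitting, the PH test, Nelson–Aalen estimation and the baseline hazard
are delegated to lifelines; OLS to statsmodels; chained-equation imputation
to statsmodels MICE (which draws from numpy's global RNG — the imputation
seed is set immediately before use).  The spline basis and Rubin pooling are
implemented here.  Tests check the Cox path against a brute-force grid
maximization of the explicitly written partial likelihood, the spline basis
against a symbolic evaluation of the truncated-power formula, and the
incidence curves against an independent Breslow computation.

## Sensitivity (`sensitivity`)

The threshold sweep re-applies the *entire* classification — including the
exclusion rule, since who is excludable depends on baseline status — and
refits the biomarker contrast at every point of a (t_g, t_s) grid, default
1 µM pitch over 1–50 × 1–30 µM.  Cells with fewer than 5 events in either
group are flagged not-estimable.  CIs are not adjusted for multiplicity
across cells.  The stability report grows a rectangle around the reference
cell, one full grid line at a time in each of the four directions, while
every added cell's HR upper confidence limit stays within a relative
tolerance (default ±10%) of the reference cell's and on the same side of 1.
The ±10% figure operationalizes "no material change", which has no standard
numeric definition; it is a package choice, not a field constant.

## Synthetic cohort generator (`cohort`)

The generator encodes the study conditions the analysis is designed for:
n=6,509 default, 1:1 randomization, ~3.6 years of administrative follow-up,
spot urine at baseline for everyone and at one of years 1–3 for ~31.5% of
participants (the published follow-up subset fraction, 2,051/6,509), 20%
of participants with background intake at or above 500 mg/day, 5% with
negligible intake, and 67% pill-taking adherence in both arms.

*Background intake* is a three-component mixture — none / moderate
(uniform 10–150 mg/day) / at-reference (exactly 500 mg/day) — rather than a
continuous distribution: only the classification boundary matters
downstream, and the mixture keeps every above-threshold probability
analytically computable for oracle tests.  The moderate range's upper end is
set where the measurement model's false-positive rate stays small, so the
baseline above-threshold share is driven by the high component, as in the
cohort being emulated.

*Measurement model*: log2-concentration = intercept + slope·dose + noise,
per biomarker, with bivariate normal noise (correlation 0.7, representing
shared spot-urine collection-time and dilution variability; the generator
folds time-of-collection variability into this term rather than modeling
collection times).  Default truths (gVLM: 1.254 + 0.009·dose, sd 0.8; SREM:
0.531 + 0.008·dose, sd 0.8) are chosen so the population lower 95%
prediction bound at 500 mg sits at the reference thresholds — i.e. the
generator and the reference profile are mutually consistent.  Zero intake
bypasses the regression line (whose positive intercept describes habitual
consumers) and yields below-LOQ values: no intake, no metabolites.

*Events*: four independent exponential clocks per participant — nonfatal
total-CVD (0.010/py), nonfatal major-CVD (0.0025/py), CVD death (0.002/py),
non-CVD death (0.0055/py) — each multiplied by exp(log-HR) iff the
participant's actual exposure (background, plus supplement when intervention
and adherent) is at or above the reference dose.  Composite endpoints take
the minimum of their component clocks; death censors nonfatal endpoints, so
no endpoint's event time exceeds the all-cause death time.  The per-endpoint
log-HR applies to the endpoint's own clock, and the non-CVD-death clock's
log-HR is solved so the all-cause composite hits its target in the exposed.
Composite endpoints are exactly proportional-hazards only when the component
log-HRs coincide; parameter-recovery tests use that configuration.  Default
true HRs (0.65 / 0.44 / 0.54 / 0.48 for total CVD, CVD death, all-cause
death, major CVD) give event counts at n=6,509 comparable to the cohort
being emulated.  Baseline hazards do not depend on covariates by default, so
the exposure log-HR is exactly the generator parameter and adjustment models
exercise the estimation machinery without confounding; a confounded variant
would require covariate-dependent hazards, which the generator does not
model.

*Self-reports* arrive every 182 days while alive, with persistent reporter
behaviour: a non-adherent participant either always claims adherence
(probability 0.57, chosen so that with 67% true adherence the self-reported
adherence rate lands at the published 85%) or starts reporting non-adherence
at a uniformly chosen report index 1–4, spreading per-protocol censoring
over follow-up; an adherent participant falsely reports a miss once with
probability 0.02.  Placebo-arm reports are generated identically (the
per-protocol rule censors all randomized participants).

*Randomness*: one integer seed; each output table draws from its own jumped
Philox (counter-based) stream, so sub-tables are reproducible independently.

*What the generator does not emulate*: covariate-outcome confounding (see
above), multivitamin co-randomization, dietary questionnaires, LC-MS error
structure beyond log-normal noise, staggered enrolment, or time-varying
adherence.  Passing tests therefore demonstrate that the pipeline recovers
known truth under misclassification of the kind modeled — not that any
particular real-cohort estimate is correct.

## The deterministic classification fixture

`table1_fixture()` builds a 6,509-row cohort whose classification margins at
(18.2, 7.8) µM reproduce a published cohort table exactly: arm sizes
3,257/3,252, follow-up subset 991/1,060, baseline-above 603/646 (186/228
within the subset), follow-up-above 175/706, 325 participants below LOQ, and
self-reports tabulating to 85% adherence per arm.  The one degree of freedom
the printed margins leave open — the per-arm union of baseline-above and
follow-up-above within the follow-up subset — is pinned down by the printed
group-composition percentages (62% of the active group and 10% of the
control group randomized to intervention): an integer search over the
feasible ranges (placebo union 186–361, intervention 706–934) finds 1,034
admissible pairs under half-up rounding and selects the one whose exact
percentages are closest to the printed values, (U_p, U_i) = (317, 780).
Biomarker values are placed deterministically well above or below the
thresholds; the fixture uses no RNG and regenerates byte-identically.

## Problem sizes used in tests and scripts

Stochastic checks use n=50,000 for mixture-tail and adherence oracles (3
standard errors), n=20,000 × 100 replicates for the attenuation ordering and
log-HR recovery (the recovery criterion is a 0.02 tolerance on the mean),
and n≈4,000 for structural tests.  The analysis drivers default to n=20,000
and a 4 µM sweep pitch; both are arguments, and the full 1 µM × 1–50 × 1–30
grid is available through `flavatrial sweep`.

## Known limitations

* The reference thresholds cannot be re-derived from first principles
  without the original calibration dataset; they are shipped as a named
  profile and the derivation machinery is validated on synthetic data.
* The biomarker contrast is observational (groups are self-selected through
  diet and adherence); model 3 adjusts for measured baseline differences but
  the generator plants none, so residual-confounding behaviour is untested.
* With thresholds far from the defaults the excluded set changes size
  substantially, so sweep cells are comparable as *analyses*, not as
  estimates on a fixed population.
* MICE imputation handles numeric covariates only.
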