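# flavatrial

Biomarker-based re-analysis of randomized nutrition trials, built around the
cocoa-flavanol / urinary-metabolite setting.

## The problem

In a nutrition RCT the randomized arms do not coincide with the exposed and
unexposed: control-arm participants obtain the nutrient from their habitual
diet (here, ~20% of participants eat ≥500 mg/day of flavanols anyway), and a
third of intervention-arm participants do not take their supplements —
more than the ~15% that pill-count questionnaires suggest.  Both errors
attenuate the intention-to-treat (ITT) hazard ratio toward 1.

Validated urinary biomarkers of flavanol intake — gVLM_B (γ-valerolactone
metabolites) and SREM_B ((−)-epicatechin metabolites) — let exposure be
*measured*: a spot urine at baseline reflects the background diet, and one
during follow-up reflects achieved exposure.  The package implements the
full re-analysis pipeline:

1. **calibration** — fit log₂(concentration) ~ dose to dose-escalation data
   and derive the classification threshold as the lower 95% bound of the
   concentration expected after 500 mg (t-quantile, prediction or mean-CI
   interval); the published profile (18.2 µM gVLM_B, 7.8 µM SREM_B) ships
   as the `cosmos` default;
2. **classify** — a sample is above threshold iff gVLM ≥ t_g **or**
   SREM ≥ t_s; participants are *biomarker-active* (above at baseline or any
   follow-up), *biomarker-control* (below throughout), or *excluded*
   (intervention arm, no follow-up sample, baseline below — adherence
   unobservable);
3. **survival** — Cox proportional-hazards contrasts (Efron ties, 3-knot
   restricted cubic splines for continuous covariates, cox.zph-style PH
   check, survival-aware multiple imputation, Breslow-based adjusted
   cumulative incidence) under ITT, per-protocol (censoring at first
   self-reported non-adherence) and biomarker-based exposure definitions,
   with covariate models 1–5;
4. **sensitivity** — re-classify and refit over a 2-D grid of thresholds and
   report the rectangle where the HR upper confidence limit is stable;
5. **cohort** — a synthetic trial generator encoding background-diet
   contamination and partial adherence, plus a deterministic fixture that
   reproduces the published classification margins exactly.

The expected signature, and the package's central simulated result, is the
ordering |log HR_ITT| ≤ |log HR_PP| ≤ |log HR_biomarker| when a true
protective effect is diluted by misclassification.

## Worked example

```python
from flavatrial import (CohortParams, COSMOS_THRESHOLDS, generate_cohort,
                        classify_participants, run_contrasts)

params = CohortParams(n_total=20000, seed=1)   # true total-CVD HR 0.65 in the exposed
participants, samples, reports, events, _ = generate_cohort(params)
cls = classify_participants(participants, samples, COSMOS_THRESHOLDS)
table, _ = run_contrasts(participants, events, self_reports=reports,
                         classifications=cls, model_ids=[2],
                         endpoints=["total_cvd"])
print(table[["contrast", "hr", "ci_low", "ci_high", "n", "events"]])
```

prints

```
 contrast    hr  ci_low  ci_high     n  events
      itt  0.76    0.65     0.88 20000     690
       pp  0.74    0.63     0.86 20000     626
biomarker  0.64    0.53     0.77 14611     522
```

The randomized contrast (ITT 0.76) is attenuated relative to the planted
exposure effect (0.65) because one in five placebo participants is truly
exposed through diet and one in three intervention participants is not.
Per-protocol censoring recovers a little (0.74); the biomarker-defined
groups recover nearly all of it (0.64).  The biomarker analysis uses fewer
participants because intervention-arm members without a follow-up urine
sample and with a below-threshold baseline are excluded.

The same steps are packaged as numbered drivers:

```
python analysis/01_simulate_cohort.py        --seed 1
python analysis/02_derive_thresholds.py      --seed 1
python analysis/03_classify_participants.py
python analysis/04_survival_contrasts.py     --seed 1
python analysis/05_threshold_sensitivity.py  --seed 1
```

each of which narrates what it finds and writes its tables under
`results/`.  A `flavatrial` console script exposes the stages
(`simulate | calibrate | classify | analyze | sweep | run`) for use on
external CSV cohorts; `flavatrial run --config run.yaml` executes the whole
pipeline with a provenance manifest.

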