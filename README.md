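# respscore

Individualized treatment-response scores for two-arm time-to-progression
trials, with secondary progressive multiple sclerosis (SPMS) as the model
setting.

Average treatment effects reported by randomized trials hide substantial
heterogeneity: in progressive MS, the same drug may slow disability
accumulation (EDSS), walking speed loss (T25FW), hand-dexterity loss
(9HPT) or cognitive decline (SDMT) in different patients. `respscore`
implements a predictive heterogeneity-of-treatment-effect (HTE) workflow
that turns a patient's *baseline profile* into a per-outcome **response
score (RS)** — an estimate of that patient's own treatment effect on the
log hazard-ratio scale, where more negative means more expected benefit.

## The method

For one outcome with confirmed-progression event times, fit proportional-
hazards prognostic models separately in the two arms,

```
control:    h(t | x) = h0c(t) · exp(βc' z)
treatment:  h(t | x) = h0t(t) · exp(βt' z)
```

with `z` the transformed baseline covariates (age, male indicator, prior
2-year relapses, log10 disease duration, EDSS). If treatment benefit does
not depend on the profile, βt ≈ βc; where they differ, the difference
predicts who benefits. The response score is

```
RS(x) = α + (βt − βc)' z,     predicted patient-specific HR = exp(RS)
```

with α the treatment main effect. In practice both pieces come from one
pooled Cox model with treatment × covariate interactions (a `two_fit`
literal mode is also provided). The pipeline then:

1. splits the cohort 70:30 (Cohen's d balance diagnostics, |d| > 0.10
   flagged), imputing missing baselines by chained equations (m = 10);
2. searches **all 2ⁿ−1 covariate subsets**, ranking each candidate RS by
   the ratio of treatment HRs in its predicted responders (lowest score
   quartile) versus non-responders;
3. re-classifies the held-out 30% against a threshold equal to the
   whole-group HR and declares the winner *validated* when the
   responder/non-responder HR ratio is < 0.80 and/or the treatment ×
   score interaction has p < 0.20;
4. reports discrimination (AD(q) curve and its AUC), calibration by score
   quartiles, bootstrap replicability over repeated train/validation
   resamples, and conditional-permutation variable importance.

Confirmed-progression endpoints are derived from visit-level scores:
+1.0 EDSS point (baseline ≤ 5.0) or +0.5 (≥ 5.5), ≥ 20% worsening of
T25FW/9HPT, or a ≥ 4-point SDMT drop — each sustained to a confirmation
visit at least 3 months (SDMT: 6 months) later.

Because patient-level data from the motivating SPMS trial are not public,
the package ships a **synthetic trial generator** (`respscore.synthetic_trial`)
that draws a 2:1 randomized SPMS-like cohort and simulates the four
outcomes from arm-specific proportional-hazards models, returning the
true response score alongside — so every stage of the pipeline is
testable against a known answer, including an *event-first* visit
trajectory builder whose noise-free output round-trips exactly through
the progression rules.

## Worked example

The published clinical-practice scores ship as fixtures. Three
illustrative patients (`respscore worked-examples`):

```
 patient outcome  score   hr  threshold_hr         label
       1    EDSS  -0.19 0.83          0.79 non_responder
       1   T25FW  -0.24 0.79          0.95     responder
       1    9HPT  -0.11 0.89          0.86 non_responder
       1    SDMT  -0.33 0.72          0.75     responder
       2    EDSS  -0.33 0.72          0.79     responder
       2   T25FW   0.22 1.24          0.95 non_responder
       2    9HPT  -0.16 0.85          0.86     responder
       2    SDMT   0.19 1.21          0.75 non_responder
       3    EDSS  -0.47 0.63          0.79     responder
       3   T25FW  -0.66 0.52          0.95     responder
       3    9HPT  -0.24 0.79          0.86     responder
       3    SDMT  -0.41 0.67          0.75     responder
```

Patient 1 (age 55, female, EDSS 3.0, five relapses in 2 years, 3-year
disease duration) has a predicted T25FW hazard ratio of 0.79 — below the
whole-group HR threshold of 0.95, so she counts as a potential responder
on walking speed, while her predicted EDSS effect (HR 0.83) is weaker
than the group average (0.79) and she is a non-responder there. Patient 3
(age 30, EDSS 2.0, short disease duration) is a predicted responder on
all four outcomes.

A full synthetic run, from simulation through selection and validation:

```
respscore -v run --out-dir demo --seed 7
```

writes `demo/report.json` with, per outcome: the overall HR with CI, the
selected covariate subset and its fitted RS, responder/non-responder HRs
on the validation set, interaction p-values, the AD(q) curve and AUC, and
the calibration table. Reruns with the same seed are byte-identical.

Library use mirrors the CLI:

```python
from respscore import scenario, simulate_trial, split_train_validation, CLINICAL_PRACTICE
from respscore.model_selection import select_response_score
from respscore.response_score import overall_treatment_effect

cfg = scenario("table2_like", n_patients=2000, seed=7)
trial, truth = simulate_trial(cfg)
split = split_train_validation(trial, 0.7, seed=1)
hr = overall_treatment_effect(trial, "EDSS").hr("treat")
result = select_response_score(split.train, split.validation, "EDSS",
                               CLINICAL_PRACTICE, hr)
print(result.selected.subset, result.verdict.validated)
```

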