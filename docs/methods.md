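# Methods

This note records the statistical model behind `respscore`, the design
choices made where the procedure was genuinely open, what the synthetic
generator does and does not emulate, and the numerical conventions the
implementation fixes.

## Response-score model

The estimand is the patient-specific treatment effect on the log
hazard-ratio scale. Under proportional hazards with arm-specific
coefficient vectors βt, βc on transformed covariates z, the score

RS(x) = α + (βt − βc)ᵀ z

is the log HR a patient with profile x is expected to experience; α is
the treatment main effect at z = 0. Transforms are fixed per variable:
identity for age (years), EDSS (0–10 ordinal, 0.5 steps) and the 2-year
relapse count; a male indicator for sex; base-10 logarithm for disease
duration (years) and for the skewed tier-2/3/4 variables (walk/peg times,
T2 lesion volume, GFAP, NfL).

Two constructions are provided:

* **pooled_interaction** (default): one Cox partial-likelihood fit on the
  pooled arms with treatment, covariates, and treatment × covariate
  products. The product coefficients estimate βt − βc and the treatment
  term supplies α, all with a single tie-handling and convergence
  behavior.
* **two_fit**: the literal two separate arm-wise fits differenced
  variable-wise; α taken from a pooled main-effects model. Asymptotically
  the slopes agree with the pooled route (checked by test).

Arm-wise Cox fits have no intercept, so α cannot come from the two
separate fits alone; the pooled model is the canonical source. Covariates
are deliberately *uncentered*: the published score formulas are written
on raw scales, and centering would only shift α. A consequence is that α
itself is an extrapolation to z = 0 and is estimated much less precisely
than the slopes; recovery checks therefore assess slopes directly plus
the score level at the cohort mean, which is the quantity the data
actually identify well.

Cox fitting is delegated to lifelines (Efron tie handling, its default
convergence criteria). Non-convergence, complete separation and unstable
fits (any coefficient SE above 50, or a constant covariate) are caught
and surfaced as a `converged=False` flag rather than an exception, so the
subset search can rank past pathological candidates.

## Published score fixtures

The four clinical-practice scores ship in
`src/respscore/data/published_scores.json` with responder thresholds
equal to the log of the whole-group HR per outcome (EDSS log 0.79, 9HPT
log 0.86, T25FW log 0.95, SDMT log 0.75). Three printed ambiguities were
resolved by recomputing the worked example patients:

* the disease-duration logarithm is **base 10** (natural log does not
  reproduce the printed T25FW score −0.24 for the 55-year-old patient);
* the EDSS relapse coefficient is stored as **+0.05**: the printed sign
  (−0.05) reproduces neither worked patient, +0.05 reproduces both;
* the SDMT disease-duration coefficient is stored as **−0.15** (the value
  in the score table); the −0.19 appearing in the accompanying text does
  not reproduce the worked scores.

One residual inconsistency is documented rather than patched: the third
patient's SDMT score evaluates to −0.405 (i.e. −0.41 at two decimals with
full-precision log10(2)), while the printed value −0.40 matches rounding
log10(2) ≈ 0.30 before multiplying. The printed HR (0.67) and the
responder label are unaffected.

Display rounding is half-up toward +∞ at two decimals
(floor(100x + 0.5)/100): the printed 9HPT score −0.115 → −0.11 fixes the
convention. The same rule applied to 0.7 × 1645 gives the 1152/493
train/validation sizes.

## Selection and validation

All 2ⁿ−1 non-empty covariate subsets are enumerated (guarded at n ≤ 20),
ordered by size then lexicographically. For each subset the RS is fit on
the training set; training patients at or below the first quartile of the
training-score distribution (type-7 linear-interpolation quantile,
inclusive at ties) are provisional responders; the candidate's ranking
statistic is HR_resp / HR_nonresp from unadjusted treatment-only Cox fits
in the two strata, ascending. Ties break toward fewer variables, then
lexicographically. The validation stage re-classifies held-out patients
against log(whole-group HR) — the two thresholds follow the procedure's
sequencing (quartile during ranking, overall HR for the final
classification); both are recorded in outputs. The validation verdict is
the OR of (ratio < 0.80) and (treatment × responder-indicator Wald
p < 0.20); the continuous treatment × RS interaction p is reported
alongside. "HR < 0.80" is read as the *ratio* of stratum HRs (the
treatment effect being ≥ 20% stronger in responders); a
`ranking="responders_hr"` option gives the alternative reading.

Even in a no-HTE world the training-set ratio sits somewhat below 1,
because the score is fit on the same data it stratifies; at n ≈ 1,645 the
median ratio is ≈ 0.87. This in-sample optimism is exactly what the
held-out validation step guards against, and it is why the null
calibration of the interaction test is assessed on the validation half.

## Performance measures

* **AD(q)**: for q over {0.1, …, 1.0}, the treatment HR re-estimated in
  the subgroup with RS at or below the empirical q-quantile; AUC is the
  trapezoidal integral over the evaluable grid divided by its q-span (a
  normalized mean height on the HR scale). At q = 1 the subgroup is the
  full set, so the curve ends exactly at the overall HR; a flat curve at
  the overall HR means no heterogeneity, and more benefit concentrated at
  low scores pushes the AUC down. The original curve's exact estimand and
  normalization are not recoverable from its description, so this
  definition is this package's own and its numeric AUCs are not
  comparable to externally printed values.
* **Calibration**: score-quartile bins; per bin the mean RS (predicted
  log HR) against the observed treatment-only log HR with a 95% Wald CI.
* **Replicability**: the dataset is bootstrap-resampled (duplicated
  patients re-keyed), split 70:30, and the full rank-select-validate
  procedure re-run; the replicability rate is the fraction of replicates
  whose selected model validates, with per-subset selection frequencies
  reported alongside. A split-only (no resampling) mode exists.
* **Variable importance**: a scikit-learn random forest (1,000 trees by
  default) grown on a random half of the data; each variable is permuted
  within strata defined by quartile bins of covariates with |Pearson
  r| > 0.2 to it, and importance is the held-out accuracy drop (mean of 5
  permutation repeats), normalized to the maximum as a percentage.
  Held-out evaluation is essential: in-sample permutation importance on
  an overfit forest reports spurious signal even for random labels.
* 95% intervals are Wald on the log-HR scale throughout.

## Missing data

Chained-equation imputation (m = 10 completed datasets, 10 cycles each)
is delegated to statsmodels `MICEData`, each covariate regressed on all
others, with predictive-mean-matching draws (k = 5 donors by default).
PMM keeps imputed values on the observed support, which handles the EDSS
half-point grid, integer relapse counts and bounded scores without
explicit rounding or clipping. Missingness is assumed at random; arm and
outcomes must be complete. Downstream, the winning subset is refit on
every completed dataset and point estimates are averaged (Rubin's rule
for means).

## Synthetic generator

The generator defines the study conditions the tests run under:

* n = 1,645 with 2:1 treatment:control allocation by default (treatment
  count = round(2N/3)); baseline marginals: age truncated-normal
  (48 ± 8 on [18, 60]), EDSS on the 3.0–6.5 half-point grid with mass
  toward 6.0, relapses Poisson(0.7), disease duration log-normal (median
  16 y, σ_log = 0.6), 60% female, log-normal walk/peg times and a
  truncated-normal SDMT; a Gaussian copula induces mild age–duration
  (ρ = 0.4) and EDSS–duration (ρ = 0.25) dependence.
* Event times by inverse-transform sampling from exponential
  (optionally Weibull) arm-specific proportional-hazards models; the
  control-arm baseline hazard is calibrated by root-finding so the
  control arm hits a target event fraction (default 30%) by the
  administrative horizon (720 days), using a fixed internal covariate
  sample so calibration is deterministic and seed-independent.
  Censoring: administrative at 720 days plus uniform dropout (10% of
  patients). Optional shared log-normal frailty correlates outcomes
  beyond their shared covariates (off by default).
* Named scenarios: `table2_like` (true RS per outcome equal to the
  published clinical-practice formulas — the coefficient-recovery ground
  truth), `null`, `main_effect` (uniform HR, no HTE), `single_modifier`
  (abstract covariates, one true modifier with interaction −0.6, for
  selection-consistency and power studies), and `recovery_t25fw`.
* Visit trajectories are built *event-first* on a 90-day grid: each
  score sits at baseline and jumps past its progression threshold at the
  event day, staying worsened through the confirmation visit (one grid
  step later; two for SDMT's 6-month window), with per-score Gaussian
  measurement noise optional. With zero noise, the confirmed-progression
  rules reproduce the simulated event table exactly — the round-trip
  identity the tests rely on. Trajectories require grid-aligned events
  (`snap_to_grid=True`); continuous event days are the default otherwise,
  because snapping all events onto an 8-point grid would degrade the Cox
  fits the recovery tests depend on.

What the generator does not emulate: the real trial's covariate
correlation structure and event rates (unpublished), relapse processes,
visit non-compliance, informative dropout, or re-baselining. Passing
tests therefore demonstrate correctness of the *procedure* under a
known proportional-hazards world, not clinical performance on real data.

The parameter-recovery experiment (`recovery_t25fw`) is designed for
identifiability rather than realism: 1:1 allocation, n = 20,000,
negligible censoring, and a log10-uniform disease-duration spread over
[0.5, 60] years, chosen a priori so the Monte-Carlo SE of the
weakest-identified slope (log10 disease duration, SE ≈ 0.02) sits well
inside the ±0.05 assessment band.

## Progression rules

Event time is always the day of the *initial* qualifying worsening, not
the confirming visit. "Three months" is 84 days minimum gap (configurable;
quarterly grids satisfy either 84- or 90-day conventions), six months is
168 days for SDMT. Confirmation is *sustained* by default: the worsening
must hold at every visit with an observed score from the initial visit
through the first scheduled visit at/after the window (a non-sustained
mode accepts any qualifying visit at/after the window). A worsening at
the final visit cannot be confirmed and yields censoring at that visit;
visits with a missing score are skipped; EDSS baselines outside
[3.0, 6.5] use the ≤ 5.0 / ≥ 5.5 dichotomy.

## Problem sizes in the test suite

Monte-Carlo tests state their own scales, chosen to keep sampling error
well inside each assertion's margin: 500 replicates at n = 2,000 for the
null calibration of the interaction test; 50 replicates at n = 4,000 for
selection consistency; n = 20,000 for coefficient recovery and
calibration recovery; n = 10,000 for AD(q) ordering and KM consistency;
smaller paired-seed designs (15–20 replicates, n = 600–3,300) for
ordering-style checks (replicability strong > null, validation power).

## Known limitations

* No multiplicity correction across the 2ⁿ−1 candidates and no shrinkage
  (penalized fitting is out of scope); the replicability rate is the
  honest summary of selection instability.
* α (the score intercept) is an extrapolation to covariate zero; scores
  should be compared between patients or against thresholds, not read as
  precise absolute HRs far from the cohort's covariate range.
* The AD(q) AUC is package-defined (above) and not comparable across
  implementations.
* Two arms only; no stratified randomization, competing risks, or
  accelerated-failure-time variants.
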