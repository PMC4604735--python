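# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `liverscore`, in the order the pipeline uses
them.

## Patient records and missing data

A record is one ICU admission described by first-available admission
values; no time series are modelled. Missingness is a single explicit
marker (`None`), never a sentinel number, and nothing is imputed at read
time. Invariants enforced on every record: age ≥ 18 (adult ICU inclusion),
concentrations and ratios strictly positive when present, GCS in [3, 15],
outcome never missing, and PaO2/FiO2 ≤ PaO2/0.21 (the room-air bound, with
0.5 % tolerance for rounding).

Units are canonical in storage — µmol/L for bilirubin and creatinine,
mmol/L for urea/lactate/sodium/potassium, kPa for PaO2 and PaO2/FiO2 — and
a read schema may declare per-column units with fixed conversion factors
(mg/dL ↔ µmol/L via 17.1 for bilirubin and 88.4 for creatinine, mmHg ↔ kPa
via 7.50062). Urea deserves a note: cohort tables in this field sometimes
label urea "µmol/L" while printing mmol/L-scale magnitudes (a median of 8.1
is only plausible in mmol/L); urea is therefore stored in mmol/L and the
schema override `units: {urea: umol/L}` divides by 1000 when a file really
is in µmol/L.

Quartiles (for "median (IQR)" summaries) use linear interpolation between
closest ranks, i.e. the quantile at `h = (n-1)q`; this convention is fixed
because published tables rarely state theirs. Percentages of categorical
levels use the full cohort size as denominator, matching tables whose
per-row n varies with missingness elsewhere.

## Scores

CTP awards 1-3 points for bilirubin, albumin, INR (PT ratio is treated as
interchangeable with INR), ascites grade and West Haven encephalopathy
grade. The printed band edges leave the boundaries ambiguous; the closures
used are: bilirubin band 2 = [34, 50] µmol/L, albumin band 2 = [28, 35]
g/L, INR band 2 = (1.70, 2.30] (so exactly 1.70 scores 1 point). These
closures make the bands exhaustive and are asserted by boundary tests.
CTP+L is the CTP total plus raw lactate in mmol/L — no banding, no
rounding, so `CTP+L == CTP + lactate` bit-exactly.

Three encephalopathy modes cover the data-collection realities:
`observed` (pre-intubation grade recorded), `presumed_2` (grade fixed at 2
when pre-intubation grades were never collected, the usual convention for
retrospective ICU cohorts), and `excluded` (four-component sum, range
4-12, for testing whether collecting the grade matters at all).

The comparator scores are declarative YAML documents: `band_sum` tables
(ordered edges partitioning the line into left-closed intervals by
default, with an explicit `right_closed` switch where the published bands
are quoted as inclusive upper bounds) or `linear_predictor` components
(optional floor/cap clamping, identity or natural-log transform, unit
conversion, coefficients). Components that no single field can express are
named derived rules in code: the SOFA cardiovascular ladder (MAP plus
noradrenaline dose; dopamine/dobutamine are not collected, so their bands
collapse onto the MAP criterion), the CLIF-style cerebral component (West
Haven grade = points, with a GCS banding fallback for cohorts without
grades), and the organ-failure count (six systems with configurable
thresholds; a criterion whose input is missing counts as not failing).

Caveats by score:

* **MELD** floors all three inputs at 1.0 before the log and caps
  creatinine at 4.0 mg/dL, per the standard definition.
* **APACHE II** is restricted to the collected variables: temperature,
  heart rate, respiratory rate, haematocrit and arterial pH are not
  collected and simply absent from the definition, and collected
  physiology missing for a given patient scores its zero-point band
  (`normal_if_missing`). Absolute APACHE II values are therefore
  systematically lower than fully instrumented implementations; the score
  remains internally consistent for ranking.
* **RFH** ships as `rfh_synthetic.yaml`: the published score's input
  structure (lactate, bilirubin, urea, organ-failure count; a continuous,
  roughly zero-centred linear predictor) with synthetic placeholder
  coefficients, flagged `provisional: true`. It exercises the pipeline's
  continuous-score path; its absolute values carry no external meaning.

## Univariate battery

Continuous variables: Welch's unequal-variance *t* (Welch-Satterthwaite
degrees of freedom) for variables summarized as mean (range); Mann-Whitney
*U* for median (IQR) variables. The Mann-Whitney implementation uses
midranks for ties; the two-sided p-value is exact (enumeration over all
C(n1+n2, n1) labelings of the pooled sample, counting |U − n1n2/2| at
least as extreme) when either group has fewer than 8 observations and the
enumeration stays under 200 000 labelings, otherwise the normal
approximation with tie correction and 0.5 continuity correction.

Categorical variables form 2×2 tables against the outcome. "Where
appropriate" is operationalized as: Yates-corrected χ² by default, Fisher's
exact test substituted whenever any expected cell count is below 5.
Fisher's two-sided p uses the probability-mass convention (sum of
hypergeometric probabilities ≤ the observed table's). Deletion is pairwise
per variable. No multiplicity correction is applied — the battery reports
unadjusted screening p-values by design.

## ROC analysis

The empirical curve is evaluated at midpoints between consecutive distinct
score values (flanked by sentinels), with the rule "predicted death when
score > threshold"; for integer-valued scores this reproduces half-integer
cut points. AUC is computed both by trapezoidal integration and by the
rank formula (ties counted ½) and the two are asserted to agree to 1e-12
on every call. The Youden cut maximizes sensitivity + specificity − 1 with
ties broken toward higher specificity, then the lower threshold — a fixed
convention, since published tables never state theirs.

Confidence intervals and curve comparisons use DeLong placement values:
the variance of the AUC is `var(V10)/m + var(V01)/n` (sample variances,
ddof 1), the CI is Wald on the AUC scale truncated to [0, 1] (degenerate
variance at AUC 0 or 1 yields a zero-width interval with a warning), and
the paired test uses the placement covariance of the two scores on the
same subjects. Identical score vectors short-circuit to z = 0, p = 1
exactly. "Clinically useful" is the conventional AUC ≥ 0.8.

## Logistic modelling

Maximum-likelihood fits via iteratively reweighted Newton steps
(statsmodels), tolerance 1e-8 on the relative log-likelihood, 100
iterations. Rank-deficient designs and (quasi-)perfect separation raise
errors naming the offending predictor (separation is flagged when the
optimizer reports it or a standardized coefficient exceeds 30). Odds
ratios are `exp(coef)` with Wald 95 % intervals `exp(coef ± 1.96·se)`.

Stepwise selection is bidirectional greedy AIC from the intercept-only
model: candidates scanned in declared order, the single best AIC
improvement taken each step, exact ties resolved toward the smaller model.
The record set is fixed to complete cases over *all* candidates before the
search, so every model in the path shares one likelihood scale and AICs
are comparable. Note the statistical character of AIC selection: a pure
noise candidate is admitted with probability P(χ²₁ > 2) ≈ 0.157, so with
nine noise candidates the expected model carries roughly 1.4 spurious
terms alongside the informative ones — the selection property worth
testing is that informative predictors are (almost) always included and
model size stays near the AIC-implied rate, not that the model is exactly
the true support.

Cross-cohort validation transports a model's Youden-optimal linear-
predictor cut point from its source cohort to the target cohort unchanged,
and scores the predicted×observed 2×2 table with the Yates χ² (Fisher for
small expected counts) and the phi coefficient
`(ad − bc)/√((a+b)(c+d)(a+c)(b+d))`; a zero margin leaves phi undefined
(reported as missing with a warning).

## Synthetic cohorts

The generator emulates the two study cohorts' printed marginal structure:

* right-skewed labs (lactate, bilirubin, creatinine, urea, PT ratio,
  PaO2, platelets where printed as median (IQR)) are lognormal with
  `mu = ln(median)` and `sigma = ln(q75/q25)/(2·z75)` — the exact
  least-squares solution for the two quartile conditions; the residual
  reports how much the printed IQR's asymmetry cannot be absorbed;
* roughly symmetric variables (age, sodium, potassium, WCC, albumin,
  MAP, GCS) are truncated normals at the printed mean with spreads chosen
  from the printed ranges; truncation is by resampling, bounds are
  physiologic;
* ordinal/categorical variables are categorical draws calibrated to the
  printed prevalences (e.g. any-ascites 41.7 %/40.9 %; any-encephalopathy
  34.5 % with grades 1-4 split uniformly, since no grade breakdown is
  published); the London-style config masks encephalopathy entirely,
  mirroring cohorts without pre-intubation grades;
* noradrenaline dose is zero-inflated lognormal (roughly half the
  patients on no vasopressor).

ICU death is Bernoulli with `logit(p) = b0 + b·x` on lactate, bilirubin,
PT ratio and PaO2/FiO2. The intercept is calibrated by bisection of the
expected mortality `mean(expit(b0 + b·x))` over a fixed 100 000-draw
covariate sample, to 0.5 % absolute (targets: 30 % Glasgow-like, 37 %
London-like). The slopes are sized so that a cohort-sized (n = 84/115)
univariate battery flags all four predictors at α = 0.05 in at least 80 %
of replicates. Because the covariates are generated independently (no
copula — no correlation structure is published), each predictor's marginal
association is attenuated by the others' contribution to the linear
predictor, and slopes large enough to survive that attenuation are
necessarily larger than per-unit odds ratios estimated on real, correlated
admission data. The default slopes (per cohort) are Glasgow: lactate 1.75
/mmol/L, bilirubin 0.035 /µmol/L, PT ratio 4.2, PaO2/FiO2 −0.21 /kPa;
London: 1.1 / 0.035 / 5.0 / −0.22. Measured flag rates are 82-99 % over
150 replicates.

What passing tests on these cohorts do and do not show: they demonstrate
that the pipeline's statistics behave correctly on data with the right
marginal shapes, missingness and outcome prevalence; they do not reproduce
the real cohorts' joint distribution, so absolute AUCs, odds ratios and
stepwise selections on simulated data are internally consistent but not
estimates of the published ones. Two visible consequences: simulated
per-unit odds ratios are larger than published ones, and scores built
mostly from variables outside the outcome model (notably APACHE II)
discriminate near chance in simulation while they would not on real data.
Small per-variable missingness rates (≈1 % Glasgow, ≈0.2 % London on the
model variables) produce a handful of complete-case exclusions per cohort,
of the order of the published 5/84 and 1/115.

Reproducibility: one `numpy` generator seeded per cohort, variables drawn
in declared order, so a (config, seed) pair yields a bit-identical cohort;
the pipeline derives per-cohort seeds from the run seed via
`SeedSequence`.

## Pipeline and problem sizes

`analyze` runs: simulate/read → complete-case exclusion over the stepwise
candidate set (lactate, bilirubin, PaO2/FiO2, PT ratio, urea, creatinine,
sodium, albumin) → univariate tables → eight-score ROC tables per cohort →
stepwise models with odds ratios → cut-point transport in both directions
→ combined-cohort CTP+L vs RFH paired DeLong comparison → encephalopathy-
mode comparison (observed vs presumed vs excluded CTP/CTP+L, with paired
DeLong tests). Reports are CSV/JSON plus a text summary; every number is
produced by a module operation, outputs are a pure function of (inputs,
config, seed), and a failed stage removes its partial outputs.

Test and acceptance problem sizes are chosen to keep the whole suite in
tens of seconds while leaving Monte-Carlo error well inside the asserted
tolerances: 10 000-replicate null calibrations for the univariate tests,
2000-replicate bootstrap against the DeLong variance at n = 200, 100
replicates for selection/AUC-ordering frequencies, n = 50 000-100 000 for
law-of-large-numbers calibration checks, n = 5000 for logistic parameter
recovery.

## Known limitations

* No inter-variable correlation in the generator (the main realism gap);
  an optional copula hook is deliberately left out until a correlation
  target exists.
* RFH coefficients are synthetic placeholders (see above).
* APACHE II omits never-collected physiology; absolute values are not
  comparable to bedside APACHE II.
* Banded-lactate CTP variants are out of scope (no published band edges),
  as are hospital (post-ICU) mortality models, deprivation indices and
  any EHR integration.
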