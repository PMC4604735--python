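# liverscore

Severity-score computation and outcome-validation tooling for patients with
liver cirrhosis admitted to a general intensive care unit.

Patients with cirrhosis arriving in a general ICU have high short-term
mortality, and the classic severity scores were designed for other settings
(transplant listing, variceal surgery, general ICU case mix). A simple
bedside modification of the Child-Turcotte-Pugh score — adding the raw
admission arterial lactate to it — turns a coarse categorical score into a
continuous one that carries the strong prognostic signal of lactate.
`liverscore` implements that score, the panel of comparators, and the full
statistical workflow used to validate prognostic scores against ICU
mortality across two cohorts.

## The score panel

* **CTP** — bilirubin, albumin, INR (or PT ratio), ascites grade and West
  Haven encephalopathy grade, each scored 1-3 points; total 5-15.
  Band closures: bilirubin band 2 is [34, 50] µmol/L, albumin band 2 is
  [28, 35] g/L, INR band 2 is (1.70, 2.30].
* **CTP+L** — `CTP + lactate` with lactate in mmol/L, unbanded and
  unrounded. Encephalopathy handling is switchable: `observed`,
  `presumed_2` (for cohorts without pre-intubation grades) or `excluded`.
* **MELD, UKELD, SOFA, CLIF-SOFA, APACHE II, RFH** — declarative YAML
  definitions (band tables or log-linear predictors with unit conversion
  and clamping) under `src/liverscore/definitions/`. The RFH definition is
  a synthetic stand-in: correct input structure (lactate, bilirubin, urea,
  organ-failure count) but placeholder coefficients; see the file header.

## The validation machinery

* univariate battery: Welch *t*, Mann-Whitney *U* (midrank ties, exact
  enumeration for small samples), χ² with Yates' correction / Fisher exact;
* ROC analysis: empirical curves, AUC computed simultaneously by the
  trapezoidal rule and the Mann-Whitney rank formula (asserted equal to
  1e-12), DeLong 95 % confidence intervals, Youden-index cut points
  (midpoint thresholds, hence the familiar half-integer cut points for
  integer scores), DeLong's test for paired curves, and the AUC ≥ 0.8
  clinical-usefulness convention;
* binary logistic regression with Wald odds ratios, bidirectional stepwise
  AIC selection on a fixed complete-case set, likelihood-ratio (ANOVA)
  model comparison, and cross-cohort cut-point transport scored by χ² and
  the phi coefficient;
* a synthetic-cohort generator calibrated to the published Glasgow (n=84,
  30 % ICU mortality) and London (n=115, 37 %) cohort summaries, so the
  whole pipeline runs reproducibly without patient data.

## Worked example

```sh
liverscore analyze --seed 1 --out reports
```

simulates both cohorts and writes the report bundle (univariate tables,
per-cohort ROC tables, stepwise model summaries, cross-cohort validation,
combined-cohort score comparison). `reports/summary.txt` from that exact
command:

```
glasgow: n=84, ICU mortality 29.8 %, 6 excluded for missing values
london: n=115, ICU mortality 34.8 %, 3 excluded for missing values

ROC (glasgow):
  RFH        AUC 0.81 (0.71-0.91) cut 0.8184 sens 0.72 spec 0.81 *
  CTP+L      AUC 0.79 (0.69-0.90) cut 13.0662 sens 0.56 spec 0.93
  CTP        AUC 0.77 (0.68-0.87) cut 9.5 sens 0.72 spec 0.72
  ...

combined cohort (n=199): CTP+L AUC 0.78 vs RFH AUC 0.80, DeLong p 0.786
encephalopathy handling (first cohort): CTP observed-vs-excluded p 0.205,
CTP+L observed-vs-excluded p 0.208
```

Reading it: each ROC row is a score's discrimination for ICU death (AUC
with DeLong 95 % CI), the Youden-optimal cut point and its sensitivity /
specificity; `*` marks scores reaching the AUC ≥ 0.8 usefulness bar. The
continuous, lactate-carrying scores (RFH, CTP+L) outrank the categorical
CTP, the paired DeLong test finds no significant difference between the two
best scores on the pooled cohort, and dropping the encephalopathy component
does not significantly change CTP or CTP+L discrimination.

The same operations are available from Python:

```python
import liverscore as ls

cohort = ls.simulate_cohort(ls.default_configs()["glasgow"], seed=1)
panel = ls.compute_panel(cohort)              # 8 scores per patient
roc = ls.roc_curve(panel["CTP+L"].tolist(),
                   [r.icu_outcome == "died" for r in cohort])
print(round(roc.auc, 2), ls.youden_cut_point(roc).cut_point)
```

## Layout

| path | contents |
| --- | --- |
| `src/liverscore/cohort.py` | patient records, CSV I/O, exclusion, summaries |
| `src/liverscore/scores.py` | CTP, CTP+L, declarative score engine |
| `src/liverscore/definitions/` | YAML definitions for the comparator scores |
| `src/liverscore/stats_univariate.py` | Welch / Mann-Whitney / χ² / Fisher battery |
| `src/liverscore/roc_analysis.py` | ROC, AUC, DeLong, Youden cut points |
| `src/liverscore/logistic_models.py` | logistic fits, stepwise AIC, transport |
| `src/liverscore/synthetic_data.py` | calibrated cohort simulator |
| `src/liverscore/pipeline.py`, `cli.py` | end-to-end workflow and CLI |
| `docs/methods.md` | modelling and numerical choices in detail |
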