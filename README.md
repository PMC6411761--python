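# bhsii

Scoring and psychometric validation of the **Bologna Healing Stifle Injury
Index (BHSII)** — a 34-item outcome instrument for dogs surgically treated
for cranial cruciate ligament (CCL) rupture.  The package is aimed at
veterinary clinical researchers and biostatisticians who need to score
BHSII response sheets, audit the instrument's measurement properties, or
prototype validation analyses when raw clinical data are unavailable.

## The instrument

The BHSII combines an owner questionnaire (**BHSII-OQ**: Pain P1–P12,
Stiffness S1–S5, Function F1–F7; 24 items) with a clinician's record
(**BHSII-CR**: Visual examination V1–V3, Manual examination M1–M7; 10
items).  Every item is a five-level Likert response, 0 (never) … 4
(always), higher meaning more severe signs.  Raw domain sums are mapped to
a 0–100 well-being scale:

```
normalized = 100 − raw × 100 / max_raw
```

with domain maxima 48/20/28/12/28, section maxima 96 (OQ) and 40 (CR),
and total maximum 136, so 100 means absence of any problem and 0 severe
stifle disease.

## The validation pipeline

* **Test–retest reliability** — ICC(2,1) (two-way random effects, absolute
  agreement, single measurement) from its ANOVA mean squares,
  `(MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E))`,
  on a healthy control group administered the instrument twice; a
  consistency-form ICC(3,1) is available behind a flag.
* **Internal consistency** — Cronbach's
  `α = k/(k−1) · (1 − Σσ²ᵢ/σ²_total)` over the 24 owner items at baseline.
* **Construct validity** — empirical ROC of healthy vs CCL-rupture dogs
  (AUC as the Mann–Whitney pairwise estimator, ties ½), sensitivity and
  specificity with exact Clopper–Pearson 95% CIs, and the Spearman
  correlation matrix of all scores with BMJ qualitative banding.
* **Responsiveness** — pairwise Wilcoxon signed-rank tests over the
  postoperative timepoints T0/T1/T3/T6 (exact ≤ 15 informative pairs,
  tie-corrected normal approximation above), Kruskal–Wallis across age
  groups, median (IQR) trajectory tables, and chi-squared demographics.

Because the original cohort data are not public, the package ships a
first-class synthetic cohort generator (`bhsii.cohort`) that reproduces
the study design — 20 control dogs tested twice, 158 surgical dogs
followed at T0/T1/T3/T6 with 77 dropouts at T6 — from a latent healing
trajectory with a calibrated ordinal response model (see
`docs/methods.md`).

## Worked example

```python
from bhsii import RunConfig, SimulationConfig, run_validation

report = run_validation(RunConfig(simulation=SimulationConfig(), seed=1)).report
rel = report["reliability"]
print(rel["cronbach_alpha"]["alpha"])       # 0.8762
print(rel["icc"]["total"]["icc"])           # 0.9828
roc = report["validity"]["roc"]
print(roc["auc"], roc["separating_interval"])  # 1.0 [16.912, 79.412]
print(roc["sensitivity_ci95"])              # [0.977, 1.0]
print(roc["specificity_ci95"])              # [0.832, 1.0]
```

Reading: the 24 owner items are internally consistent (α = 0.88 > 0.7);
total-score test–retest stability is excellent (ICC = 0.98 ≥ 0.7); the
total score separates the healthy from the diseased group perfectly in
this cohort (AUC = 1.0), with diseased dogs characterized by scores in
(16.9, 79.4] and 95% CI lower bounds of 97.7% (sensitivity, n = 158) and
83.2% (specificity, n = 20).

The same pipeline runs from the shell:

```
bhsii simulate --seed 1 --out cohort/        # metadata + responses + truth CSVs
bhsii score --responses cohort/responses.csv # normalized 0–100 scores
bhsii validate --seed 1 --out report.json    # full validation report
bhsii report --seed 1 --format md            # median (IQR) trajectory table
```

Recorded data can be scored and validated the same way by passing
`--responses`/`--metadata` CSVs instead of a simulation seed (long format:
`subject_id,timepoint,item_id,value`).

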