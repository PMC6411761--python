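# Methods

## Scoring model

The BHSII is scored by unweighted summation.  Each of the 34 items takes
an integer 0–4 (five-level Likert; 0 best).  For a domain with maximum
raw score `max_raw`, the normalized score is `100 − raw·100/max_raw`, so
every domain, section and total score lives on the same 0–100 well-being
scale.  Section scores (BHSII-OQ over Pain+Stiffness+Function, maximum
96; BHSII-CR over Visual+Manual, maximum 40) use the identical formula on
the pooled raw sums — the only definition consistent with the published
total-score formula (100 − total·100/136).  The alternative of averaging
normalized domain scores would weight domains equally rather than by item
count; we deliberately use the pooled-raw form and record it here because
summary tables of this instrument are compatible with either convention.

Scores are kept at full floating precision internally; rendered reports
round to 2 decimals, CIs to 3.

### Missing data

Two policies:

* `strict` (default): any missing item in a domain aborts scoring with an
  error naming the item.
* `prorate` (the KOOS-family convention the instrument descends from): a
  domain with ≥ 50% of its items answered imputes the mean of the
  answered items for each missing one; below that the domain — and every
  aggregate containing it — is undefined (NaN).  Undefinedness
  propagates; it is never silently dropped.

## Statistical methods

**ICC.** Test–retest stability uses ICC(2,1) in the Shrout–Fleiss
taxonomy: two-way random effects, absolute agreement, single measurement,
computed from explicit ANOVA mean squares which are retained in the
result object for audit.  Absolute agreement is the appropriate choice
for test–retest data because a systematic shift between administrations
is a real disagreement.  A consistency-form ICC(3,1) is available via
`form="consistency"` for sensitivity analyses.  ICCs are computed on the
normalized 0–100 scores (for the consistency form this is equivalent to
using raw sums; for the agreement form it fixes a common scale across
domains).  Fewer than 3 subjects or zero total variance raise a
degenerate-input error rather than returning a number.

**Cronbach's α** uses the defining variance formula with unbiased
(ddof = 1) variances, over the 24 owner-questionnaire items at baseline
only — the clinician's record comprises two short exam blocks whose
internal consistency is not a meaningful target.  The conventional 0.7
threshold is attached as a flag, never enforced.

**ROC.** The AUC is the pairwise Mann–Whitney estimator (healthy beating
diseased counts 1, ties ½), which is identical to the trapezoidal area
under the empirical ROC curve (property-tested).  Orientation is fixed by
the instrument's semantics — low score = diseased — and is *not*
auto-detected; reversed inputs produce AUC < 0.5 plus a warning so a
silent sign flip can never manufacture discrimination.  With perfectly
separated groups the reported threshold is the maximal diseased score and
the result carries the (min, max] interval of observed diseased scores;
with overlap the Youden-optimal threshold (maximizing sensitivity +
specificity, first maximizer in ascending score order) is reported
instead.  Sensitivity/specificity CIs are exact Clopper–Pearson intervals
from Beta quantiles; the boundary cases reduce to the closed forms
(α/2)^(1/n).

**Spearman matrix.** r_s is the Pearson correlation of midranks (average
ranks on ties) with a two-sided t-approximation p-value — appropriate at
the n ≈ 158 scale of a baseline correlation matrix; an exact permutation
p-value is available for n ≤ 10.  Qualitative bands follow the BMJ cuts
on |r_s| (0–0.19 very weak, 0.2–0.39 weak, 0.40–0.59 moderate, 0.6–0.79
strong, 0.8–1 very strong).  No multiple-testing correction is applied
across the matrix; the report labels this explicitly.

**Wilcoxon signed-rank.** Zero differences are discarded (Wilcoxon's
original rule, matching common clinical software); absolute differences
receive midranks.  For ≤ 15 informative pairs the two-sided p-value is
exact, by enumerating all 2ⁿ sign assignments of the observed ranks
(correct under ties, which standard exact tables are not); above that a
normal approximation with the standard tie correction and a 0.5
continuity correction is used (agrees with the exact p to within 0.01 at
the crossover).  Timepoint comparisons are complete-case: a pair enters
only if the subject was scored at both timepoints, so T6 contrasts use
exactly the non-dropout subjects.  All tests are two-sided; the family of
pairwise timepoint tests is reported uncorrected, with an optional Holm
adjustment (off by default) for sensitivity analyses.

**Kruskal–Wallis and chi-squared** delegate to scipy (tie-corrected H
with a χ² p-value; Pearson χ² without continuity correction), with
degenerate inputs (all observations identical; zero marginals) handled
explicitly.

## Synthetic cohort generator

The generator reproduces the study design the validation assumes: a
control group (n = 20) administered the instrument twice two weeks apart,
and a surgical group (n = 158) scored at diagnosis and 1, 3, 6 months
after surgery, with 77 subjects missing at T6 (40 + 555 sheets).  Age
groups A–D (< 3, 4–6, 7–9, > 9 years) are balanced 39/40/40/39; weights
are truncated normal (surgical 29.2 ± 14.4 kg, control 23.4 ± 11.3 kg,
floor 2 kg); sex and limb frequencies echo a typical caseload.
Covariates exert no effect on responses except a baseline health bonus
for the youngest group (below).

### Response model

Subject i at timepoint t has latent health h_it ∈ [0,1] drawn from the
healing trajectory (defaults: T0 0.50 ± 0.12, T1 0.78 ± 0.08, T3
0.92 ± 0.05, T6 0.96 ± 0.04; control 0.97 ± 0.02).  Item j of domain d
scores

    x_ijt = round(clamp(4(1 − h_it) + λ_j (u_i + v_id) + e_ij + ε_ijt, 0, 4))

with a global subject factor u_i ~ N(0, σ_g²), a domain factor
v_id ~ N(0, σ_d²), a **stable subject-by-item interaction**
e_ij ~ N(0, s_d²) drawn once per subject and reused in every
administration, and transient noise ε_ijt redrawn per sheet (scaled by
`retest_noise_scale` on the control retest).  Rounding is half-to-even
after clamping.

The stable interaction is the load-bearing design choice.  A model with
only shared factors plus per-sheet noise cannot simultaneously show
internal consistency below ~0.95 (which needs large item-level noise
across 24 items) and per-domain test-retest ICC above 0.7 on a 3-item
domain in a 20-dog control group (which needs small test-retest noise):
the two requirements bound the same variance component from opposite
sides.  Real respondents resolve this by being *consistently*
idiosyncratic — each owner reads each question their own way, which
dilutes inter-item correlation (capping α) but reproduces exactly two
weeks later (preserving ICC).  e_ij models exactly that.

### Calibration

Group sizes, timepoints, dropout and the healing trajectory are the
emulated design; the variance components are free parameters calibrated
once so the generated data sit in the qualitative regime expected of the
real instrument — α of the owner items in the high-0.8s, every domain
ICC ≥ 0.7 with most ≥ 0.9, near-perfect baseline discrimination, strictly
improving median trajectories, a significant baseline age effect that
vanishes postoperatively — and then frozen as defaults:

| parameter | default | role |
|---|---|---|
| σ_g (`subject_factor_sd`) | 0.12 | cross-domain subject correlation |
| σ_d (`domain_factor_sd`) | 0.15 | within-domain subject correlation |
| s_d (`item_interaction_sd_by_domain`) | P 1.10, S 0.50, F 0.65, V 0.30, M 0.30 | stable idiosyncrasy per domain |
| `transient_noise_sd` | 0.02 | administration-to-administration noise |
| `retest_noise_scale` | 1.0 | retest multiplier on transient noise |
| `age_group_t0_shift` | 0.12 | baseline health bonus, group A |
| λ_j (`item_loadings`) | 1.0 | per-item factor loading |

Owner domains carry larger interaction sds than the clinician's exam
(owner reports are noisier), and each domain's level is additionally
positioned so that its median score still separates the small T3→T6
health step on the domain's discrete score grid (a 3-item domain moves in
steps of 8.33 points; too much item-level spread parks the population
median on the same grid point at both timepoints).

With these defaults, over 40 seeds: α ∈ [0.85, 0.91], AUC ≥ 0.99,
per-domain control ICC seed-minima 0.70–0.97 (the 3-item visual domain
with n = 20 is the floor), T0→T1 Wilcoxon p < 10⁻²⁴, and exactly 81
subjects at T6.

### What the generator does and does not emulate

It reproduces the design, score ranges, trajectory shape, reliability and
discrimination regime.  It does **not** reproduce: the published
correlation structure between owner and clinician sections (both sections
load on the same latent health here, so their baseline correlation is
strong, where real owner-vs-clinician agreement was weak — passing tests
say nothing about owner-clinician agreement in real data); exact
published medians or coefficients; any informative dropout (dropout is
uniformly random); or chronic-vs-acute baseline case mix.  The
thresholded-Gaussian mechanism is a calibrated stand-in, not an estimate
of the real response process.

## Test strategy and problem sizes

Every statistic is verified against an independent oracle: explicit-sum
ANOVA for the ICC, a spreadsheet-style variance computation for α,
trapezoidal ROC integration and scikit-learn for the AUC, brute-force 2ⁿ
sign enumeration for the exact Wilcoxon p, midrank-then-Pearson for
Spearman, a hand-computed H = 7.2 for Kruskal–Wallis, and pingouin for
ICC/α cross-checks.  Stochastic properties of the generator are asserted
on a 20-seed ensemble (sheet counts, α band, AUC, Wilcoxon significance
and T6 sample size per seed; ICC thresholds and strict median increase on
the ensemble median, since single-seed medians of an 81-subject timepoint
on a discrete score grid can tie by sampling noise alone).  The full
suite runs in well under a minute.

## Known limitations

* Item prompts are placeholders; scoring never depends on prompt text,
  but the package cannot render the questionnaire for administration.
* ICC confidence intervals are not computed (point estimate + mean
  squares only).
* No smooth/binormal ROC fit and no AUC confidence interval.
* No mixed-effects longitudinal modelling; responsiveness is summarized
  by nonparametric tests and median (IQR) tables only.
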