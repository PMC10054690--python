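# Methods

This note records the statistical model, the estimators, the numerical
choices and the known limitations of the `readerstudy` package.

## Study design and data model

The unit of analysis is the 2D sagittal slice. A study consists of

- annotation records: one bounding box per finding, placed by one observer
  on one slice, with an ordinal confidence in {1,…,5} and a reading-session
  index (1 or 2);
- an observer table: years of general experience (including residency),
  cine-MRI cases reviewed, adhesion-specific cine-MRI cases reviewed, a
  clinical-significance threshold (a multiple of 20%), and a consensus
  flag;
- a slice-level reference standard; a patient is positive iff at least one
  of its slices is positive.

The slice-level score of an observer is the **maximum** box confidence on
that slice in that session, and 0 when the observer placed no box. The max
is the conventional free-response → case-level reduction; readers submit
every slice, so 0 cells are explicit negatives, not missing data.
Bounding-box geometry is carried through I/O but never analyzed: the
package deliberately stops at slice-level agreement and accuracy
(localization agreement would need a different study design).

**Binarization.** Confidence c maps to certainty 20·c %. An observer with
clinical threshold t calls a slice positive iff c > 0 and 20·c ≥ t ("at
least t% certain"); t = 0 means any annotation is a positive call. As the
threshold rises, an observer's positive calls are non-increasing (a tested
invariant).

**Experience grouping.** Observers are split into low/high groups per
dimension with cutoffs: ≥ 5 years general experience, ≥ 30 cine-MRI cases,
≥ 2 adhesion cine-MRI cases. The boundary is taken as "high" (an observer
with exactly 5 years is high-year); these conventions reproduce the
reference grouping of the bundled observer experience table exactly, which is
asserted in the tests. Consensus readers form their own group and belong
to no experience group; they are excluded from every ROC computation
because they define the reference standard.

## Agreement estimators

- **Fleiss' κ** (inter-observer, per group): per-item agreement
  P_i = (Σ_j n_ij² − m)/(m(m−1)) with chance agreement from pooled
  category proportions; κ = (P̄ − P̄e)/(1 − P̄e). For two raters this equals
  Scott's π, not Cohen's κ (pooled vs per-rater marginals) — tested on an
  asymmetric-marginal example.
- **Cohen's κ** (intra-observer, session 1 vs session 2): chance from the
  product of the two readings' marginals.
- **Percentage agreement**: the percentage of slices on which *all*
  observers in a group give the same binary diagnosis. Note this is a
  unanimity measure: it decreases (weakly) as the group grows, so values
  are only comparable between groups of similar size.
- κ is **undefined** when chance agreement is 1 (every rating in one
  category). This is raised as an error, never returned as NaN: the
  estimand is conditional on the statistic existing.

Interpretation bands (boundary in the lower band): κ ≤ 0 poor, ≤ 0.2
slight, ≤ 0.4 fair, ≤ 0.6 moderate, then the conventional Landis–Koch
extension (substantial, almost perfect).

## Resampling inference

- **Bootstrap CIs** resample *slices* (cases) with replacement, holding
  the observer panel fixed — the panels are a fixed design feature, cases
  are the sample. Percentile intervals at the requested level (default
  0.95, n_boot = 2000). Resamples where κ is undefined are dropped and
  counted, with a warning if more than 1% drop.
- **Permutation tests** for group differences re-partition the pooled
  observers into groups of the original sizes and recompute the metric
  difference; slices are never permuted (that would destroy the
  within-slice correlation that makes observers comparable). Two-sided
  p = (1 + #{|Δ*| ≥ |Δ|})/(1 + n_perm) (default n_perm = 10,000), so p is
  never 0 and the smallest attainable value is 1/(n_perm+1).
- All resampling is reproducible bit-for-bit from the seed. The pipeline
  derives independent sub-seeds per task by hashing the task label with
  the run seed, so adding or removing one table does not shift the
  randomness of the others.

Calibration of both procedures is verified by simulation in the test
suite: the permutation test's type-I error at α = 0.05 over 1000 null
studies (exchangeable readers, study-sized 15 × 61 design) and the
bootstrap CI's coverage of the true generating κ — computed independently
by numerical integration over the latent case effect — over 500 studies.

## ROC analysis

Per-reader curves sweep "positive iff score ≥ t" over the distinct scores
that reader used (so the number of operating points is reader-dependent),
plus the degenerate all-negative rule at (0,0); the lowest threshold always
reaches (1,1). AUC is the trapezoidal area and equals the Mann–Whitney
statistic with ties counted ½ (tested to 1e−12 against pairwise
enumeration).

**Diagonal averaging.** The group curve averages member curves along lines
tpr = b − fpr, perpendicular to the chance diagonal. Along a monotone ROC
curve the offset b = fpr + tpr increases strictly from 0 to 2, so each
line cuts each curve exactly once and the intersection is solved exactly
by linear interpolation on the vertex parameterization. The offset grid is
the union of 201 uniform points on [0, 2] and every input curve's own
vertex offsets; consequently averaging G copies of one curve reproduces it
exactly and the endpoints are preserved. (A uniform-only grid would
introduce secant error at vertices between grid points.)

**Group AUC inference.** The group point estimate is the AUC of the
diagonally averaged curve. Uncertainty uses a two-way bootstrap,
resampling readers (with replacement within the group) and slices
(stratified by reference label, so every resample retains both classes)
jointly; group differences use a z statistic Δ/SE(Δ) with the bootstrap SE
of the difference (slices resampled once per replicate and shared between
groups, readers independently) and a two-sided normal p-value. This
targets the same reader-and-case variability as U-statistic MRMC variance
estimators but is not that estimator; simulation shows it is
**conservative** under the null for small panels (0 rejections in 100
null studies at α = 0.05 with 5-reader groups) while still detecting a
0.60 vs 0.80 generating-AUC difference with power 1.00 at 10 readers and
500 slices. p-values from this test should be read as conservative bounds.

Operating points are extracted per target sensitivity either at the
smallest curve vertex with sensitivity ≥ target (ties toward smaller FPR)
or by linear interpolation along the curve.

## Synthetic study generator

The generator exists because annotation data from real observer studies
are typically private. It draws, per slice i, reader r and session s,

    x_ris = d_r · D_i + η_i + s_r · ε_ris,
    ε_ris = (ε0_ri + τ ζ_ris)/√(1+τ²),

with D_i the Bernoulli slice truth grouped into patients, η_i ~ N(0, σ_c²)
a case-difficulty effect shared by all readers, d_r the reader's
discrimination, s_r ≥ 1 a reader-reliability scale and τ the
test–retest mixing (sessions coincide exactly at τ = 0; the marginal stays
N(0,1) for any τ). The signal is binned into scores 0–5 by five cutpoints,
by default the 1/6…5/6 quantiles of the reader's marginal mixture at
d = 1, which makes the six score levels roughly equiprobable; any score
≥ 1 emits one fixed-size box at a seeded random location (geometry is
cosmetic). The continuous-score AUC is Φ(d/√(2(s² + σ_c²))) in closed
form, used both for parameter-recovery tests and to invert accuracy
targets into discriminations.

### Defaults (the emulated study design)

10 patients contributing 61 sagittal slices (nine patients with 6, one
with 7), 19 positive slices spread over 7 positive patients (3 patients
fully negative), slice prevalence 19/61; 15 observers with the emulated
study's experience triples and clinical thresholds, 3 of them consensus
readers; 5 observers (2 consensus) read a second session.

Latent parameters, fixed once by calibration against the emulated study's
group-level ranges reported for adhesion cine-MRI reader panels and
then frozen:

- σ_c = 1.0 (shared case effect — the main driver of between-reader
  agreement beyond the truth);
- experience → (d, s): readers high in general **or** cine experience are
  "experienced" (s = 1) with continuous AUC target 0.70; readers low in
  both are "novice" (s = 3) with target 0.66; high adhesion-specific
  experience adds +0.02. Targets are inverted to d via the closed form.
  The reliability contrast, not the accuracy contrast, carries the
  agreement gap: erratic reading collapses κ while costing little AUC,
  which is the only way to reproduce the reported pattern (κ roughly
  0.05–0.1 vs 0.25–0.35 between experience groups, AUC only ~0.66 vs
  ~0.72) — discrimination differences alone push group AUCs far apart
  before κ separates;
- τ = 0.8, giving intra-observer Cohen's κ mostly in 0.3–0.6 across
  seeds, matching the intra-observer range reported for this kind of panel.

Across 20 generator seeds these defaults give group κ means 0.07–0.28,
every group's diagonally averaged AUC inside (0.55, 0.85), and strictly
higher κ for the high-year and high-cine groups than their low
counterparts in every seed — the qualitative structure the analysis is
meant to detect. The adhesion grouping is deliberately *not* constrained:
in the emulated study that dimension showed no significant (and a
nominally reversed) agreement difference, and its high group is dominated
by otherwise-inexperienced readers.

### What the generator does not emulate

Real image content, transverse slices, the consensus meeting process,
reader drift within a session, and any spatial structure of the boxes.
The marginal-quantile score default also means simulated readers annotate
about 5/6 of slices with some box, more than real readers typically do, so
simulated unanimity percentages sit well below real-panel values (which the
tests therefore do not target); κ, being chance-corrected, is comparable.
Passing tests on synthetic data show the estimators and their inference
are correct and calibrated under the stated model — not that the model is
a faithful portrait of any particular reader population.

## Numerical choices

- Cohort percentage rounding: half away from zero to integer percent.
- Stratified patient sampling: per-stratum counts rounded by ceiling
  (configurable to floor/round); with a 20% fraction a typical
  15/49 split yields 3 + 10 patients. No uniform rounding rule reproduces
  a 3 + 7 = 10 split from 15/49, so the rounding is exposed as
  configuration rather than hard-coded.
- Diagonal averaging grid: 201 uniform offsets plus input vertex offsets;
  interpolation is exact on segments (no root-finding tolerance needed);
  repeated offsets from zero-length segments are collapsed (tolerance
  1e−15).
- Tie comparisons in permutation tests use a 1e−12 slack so exact ties
  count as at-least-as-extreme (guaranteeing p = 1 for identical groups).
- CSV float formatting uses `repr` round-tripping; annotation tables
  re-serialize byte-identically after a read (tested property).
- Default problem sizes in the validation suite (1000 null studies for
  type-I, 500 for coverage, 100 for power, 61-slice study size) were
  chosen as the smallest sizes at which the Monte-Carlo error is clearly
  inside the asserted bands.

## Known limitations

- The AUC group test is a bootstrap z approximation, not the U-statistic
  MRMC estimator; its p-values are conservative for small reader panels.
- Percentile bootstrap CIs for κ slightly undercover at 61 slices
  (measured coverage ≈ 0.93 at nominal 0.95); BCa intervals could narrow
  this but are not implemented.
- Unanimity percentage agreement depends strongly on group size and on
  how often readers annotate at all; compare it only within a design.
- The generator's equal-variance binormal latent model cannot represent
  asymmetric ROC shapes (variance ratios ≠ 1), and its
  experience-to-parameter map is a two-level simplification, not a fitted
  curve.
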