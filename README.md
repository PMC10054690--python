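# readerstudy

Observer variability and diagnostic accuracy analysis for multi-reader,
multi-case (MRMC) imaging studies — built around the design of cine-MRI
reader studies for abdominal adhesion detection, where a panel of
radiologists annotates suspicious findings on 2D sagittal slices with
bounding boxes and 5-point confidence scores, and a consensus panel sets
the slice-level reference standard.

The package is for biostatisticians and imaging researchers who need to
quantify, on slice-level ordinal confidence data:

- **inter-observer agreement** — Fleiss' κ and unanimity percentage
  agreement per reader group, with case-bootstrap confidence intervals and
  observer-permutation tests for group differences;
- **intra-observer agreement** — Cohen's κ and percentage agreement for
  readers who completed a repeat reading session;
- **diagnostic accuracy** — per-reader ROC curves and AUC from the ordinal
  confidence ratings, diagonally averaged group ROC curves, and group AUC
  comparisons with a two-way (reader × case) bootstrap z-test;
- **synthetic studies** — a seeded generator producing full annotation
  datasets from a binormal latent model with a shared case effect, so every
  pipeline stage is testable when the real annotations are private.

## Statistical core

Scores are the maximum box confidence per slice (0 = no annotation,
1–5 = confidence). For agreement metrics, each observer's scores are
binarized with their own clinical-significance threshold *t* (a multiple of
20%): a slice is called positive iff the score *c* satisfies *c* > 0 and
20·*c* ≥ *t*.

**Fleiss' κ** for *m* raters and per-slice positive counts *k*ᵢ:

    P̄  = mean over slices of (kᵢ² + (m−kᵢ)² − m) / (m(m−1))
    P̄ₑ = p² + (1−p)²,   p = pooled positive proportion
    κ  = (P̄ − P̄ₑ) / (1 − P̄ₑ)

**Cohen's κ** uses the same chance-correction with *p*ₑ from the two
readings' marginal products. **Percentage agreement** is the percentage of
slices on which *every* rater in a group gives the same diagnosis.
κ bands: ≤0 poor, (0, 0.2] slight, (0.2, 0.4] fair, (0.4, 0.6] moderate.

**ROC curves** sweep the rule "positive iff score ≥ *t*" over the distinct
scores each reader used; AUC is the trapezoidal area, equal to the
tie-corrected Mann–Whitney statistic. Group curves are **diagonally
averaged**: each member curve is intersected with the lines
tpr = *b* − fpr (perpendicular to the chance diagonal) and the intersection
points are averaged across readers at each offset *b* ∈ [0, 2].

Inference is resampling-based throughout: percentile bootstrap over slices
(readers fixed) for CIs, re-partitioning of pooled observers for group
permutation p-values, and a joint reader-and-case bootstrap for AUC
differences.

The **generator** draws a latent signal per reader, slice and session,

    x = d·D + η + s·ε,    η ~ N(0, σ_c²) shared across readers,

bins it into scores 0–5 by five cutpoints, and emits box annotations. Its
continuous-score AUC is Φ(d / √(2(s² + σ_c²))) in closed form, so accuracy
targets can be inverted exactly (`discrimination_for_auc`).

## Worked example

Generate a synthetic study with the default design — 10 patients, 61
sagittal slices (19 positive), 15 observers of varying experience with 3
forming a consensus group, 5 dual-session readers — then run the full
analysis:

```bash
readerstudy simulate --seed 1 --out demo
readerstudy analyze --data-dir demo --seed 1 --n-boot 500 --n-perm 999 --out demo_out
readerstudy report --out demo_out
```

```
Inter-observer agreement and group AUC
group         Fleiss k              % agreement               mean AUC
consensus     0.07 [-0.10, 0.24]    31.15 [21.31, 42.62]      -
low-year      0.08 [0.00, 0.14]     6.56 [1.64, 13.11]        0.62 [0.51, 0.74]
high-year     0.25 [0.14, 0.36]     26.23 [16.39, 37.70]      0.74 [0.63, 0.84]
low-cine      0.06 [-0.01, 0.14]    11.48 [4.92, 19.67]       0.61 [0.50, 0.71]
high-cine     0.28 [0.14, 0.40]     29.51 [19.67, 40.98]      0.75 [0.65, 0.84]
low-adhesion  0.14 [0.06, 0.22]     19.67 [9.84, 31.15]       0.65 [0.53, 0.77]
high-adhesion 0.16 [0.06, 0.27]     16.39 [8.20, 26.23]       0.72 [0.63, 0.82]

Intra-observer agreement (dual-session readers)
obs02         Cohen k 0.40 [0.17, 0.62]     % agreement 75.41 [65.57, 86.89]
obs04         Cohen k 0.51 [0.27, 0.73]     % agreement 78.69 [68.85, 88.52]
...
Group comparisons
fleiss_kappa        high-cine vs low-cine      delta +0.217  p 0.0580
mean_auc            high-cine vs low-cine      delta +0.143  p 0.0079 *
...
```

Reading the output: readers with high general (`high-year`) or high
cine-MRI (`high-cine`) experience agree with each other far better
(κ ≈ 0.25–0.28, "fair") than inexperienced readers (κ ≈ 0.06–0.08,
"slight"), while their diagonally averaged AUC is only moderately higher
(0.74–0.75 vs 0.61–0.62) — the structural signature of experience effects
in this kind of study. Brackets are 95% bootstrap CIs over slices; `*`
flags permutation/z-test p-values below 0.05. The bundle directory also
holds per-reader ROC curve CSVs (consensus readers are excluded from all
ROC output, since in a real study they define the reference standard) and
a `manifest.json` with seeds and a config hash; two runs with the same
inputs and seed are byte-identical.

The same pipeline runs on real annotation tables: `annotations.csv`
(observer_id, patient_id, slice_id, box coordinates, confidence, session),
`observers.csv` (experience fields, clinical threshold, consensus flag)
and `reference.csv` (slice_id, patient_id, label).

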