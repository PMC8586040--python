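# Methods

This note documents the models and procedures `metaboqc` implements, the
parameters that matter and their defaults, what the synthetic-data generator
does and does not emulate, and the numerical choices made where the design
was genuinely open. Every number quoted here is computed by the test suite
or `scripts/acceptance.py`; nothing is asserted that the code does not
reproduce.

## The data model

A peak table is a features × samples matrix of integrated peak areas with
per-sample metadata (injection order, processing batch, cell passage,
treatment, class ∈ {sample, qc, blank}) and per-feature metadata (m/z,
retention time in seconds, ionization mode, optional annotation). Injection
order is the single time axis; acquisition timestamps are not modelled,
since drift is regressed on run order. Columns are canonically sorted by
injection order. Missing measurements are NaN in memory and empty cells on
disk — never zero, which would denote a genuine absence of signal. Positive-
and negative-mode tables come from separate injection sequences; when they
are merged (feature union, sample intersection, ids prefixed `pos_`/`neg_`)
the positive run's sample metadata is kept, so any injection-order-dependent
step — drift correction in particular — must run per mode *before* merging.

## Quality metrics and filters

**Blank ratio.** `median(QC areas) / P80(blank areas)` per feature, with the
80th percentile computed by linear interpolation between order statistics
(no convention is standard; this is numpy's default). A feature is
uninformative iff the ratio is *strictly* below 3; a feature absent from all
blanks has ratio +∞ (no background to compare against). The filter is
idempotent.

**RSD_QC.** Percent relative standard deviation across QC injections
(n−1 denominator); pooled QCs are aliquots of one mixture, so their spread
is purely analytical. Features with RSD_QC strictly above 20% are removed.

**D-ratio\*.** `MAD_qc / MAD_sample × 100` — analytical dispersion as a
percentage of the total (biological + analytical) dispersion in study
samples. Both MADs are unscaled (no 1.4826 consistency factor; the constant
cancels in the ratio — stated explicitly because many MAD implementations
scale by default). Removal is strict (`> 20%` removed), so a feature at
exactly 20% is retained; the equality side is not fixed by common usage and
had to be chosen once. `MAD_sample = 0` with `MAD_qc > 0` yields +∞
(flagged); both zero yields 0 with a warning.

**Outlier samples.** Study samples whose total (non-missing) intensity falls
below `median − 3 × MAD` of the study totals are flagged, one-sided — only
low totals indicate failed extraction or injection. This formalisation of
"low total signal" is the package's own; the reports say so, and `k` is
configurable (`k = ∞` disables).

Missing intensities are ignored (never zero-imputed) in all medians, MADs
and totals.

## QC-SVRC drift correction

Per feature, an ε-insensitive support vector regression with RBF kernel of
QC intensity on injection order, refit on all QCs after hyperparameter
selection, then

```
corrected(i, j) = raw(i, j) × reference_i / predicted_i(order_j)
```

with `reference_i` the QC median. Hyperparameters per feature:

| parameter | value | rationale |
| --- | --- | --- |
| C | median of QC areas | the signal's own scale |
| ε | grid of 5 values, 2.5–8% of the QC median (endpoints included) | expected instrumental precision band |
| γ | 13 log-spaced values in [1, 10⁴] | from near-linear to highly local curves |

Selection minimises the leave-one-out RMSECV over QC points; ties break
toward larger ε, then smaller γ — the smoother model. Two numerical choices
matter:

* **Order rescaling.** Injection order is mapped to [0, 1] per run before
  fitting, so the γ range has the same meaning for a 40-injection and a
  400-injection run.
* **Intensity rescaling.** Intensities are divided by C before the solver is
  called (`C′ = 1`, ε as a fraction). The SVR problem is scale-equivariant,
  so this is mathematically identical, but it conditions the solver and is
  several-fold faster. Consequently the whole correction is exactly scale
  equivariant: multiplying a feature's row by c scales C, ε and predictions
  by c and leaves corrected/raw ratios unchanged (tested).

Features with fewer than 5 non-missing QC values are skipped and passed
through unchanged (flagged `skipped_insufficient_qc`); all-identical QCs
give a degenerate constant model (correction is the identity). Predictions
are clamped below at 0.1 × reference so a curve wandering toward zero cannot
explode the correction; clamping flags the feature `unstable_correction`.
Predictions outside the QC injection span are clamped to the span — the RBF
model has no support there and would relax to its intercept. QC injections
can be excluded from fitting by an explicit list (e.g. a visually flagged
outlier QC); none are removed automatically.

A correction is *not* exactly idempotent: the first pass leaves residual
structure inside the selected ε tube (≥ 2.5% of the QC median by
construction), which a second pass may partially remove. The test suite
bounds the second-pass change at 3% on noiseless runs and checks exact
identity for the degenerate flat case; a sub-0.1% idempotence claim is not
achievable with an ε-insensitive loss and is not made.

## ASCA

The study-sample matrix is natural-log transformed (peak areas are positive
and effects multiplicative) and autoscaled per feature (mean 0, sd 1, n−1
denominator; zero-variance features dropped with a warning) before
decomposition — whether the original analysis scaled its ASCA input is not
knowable from the outside, so both transforms are switchable flags. The
model is

```
X = Mean + X_Treatment + X_Batch + X_Passage
         + X_Treatment×Batch + X_Treatment×Passage + X_Batch×Passage + E
```

estimated sequentially by cell/level means of the mean-centred data: main
effects are level means; two-way interactions are cell means minus the two
contributing mains; the residual is the remainder. On balanced designs the
effect matrices are mutually orthogonal, sums of squares are additive, and
the percent contributions sum to 100 (tested to 1e-6 and against a
brute-force per-cell-averaging oracle to 1e-10). On unbalanced designs
(e.g. after outlier-sample removal) the same estimators are applied and the
percentages may not sum exactly to 100; the result carries a `balanced`
flag. Factors left with one level are dropped from the model with a
warning.

**Permutation test.** For each term the tested labels are shuffled and the
term's sum of squares recomputed: main effects shuffle that factor's column
across samples; an interaction A×B shuffles A's labels within each level of
B, which preserves both factors' main-effect structure while destroying
their joint structure. p = (#{SSQ_perm ≥ SSQ_obs} + 1)/(n_perm + 1), so the
smallest attainable p at the default 500 permutations is 1/501 ≈ 0.002.
Calibration under the global null was verified by simulation: per-term
rejection at nominal 0.05 lies in 0.03–0.07 over 300 null experiments.

**SCA.** Each effect matrix gets an SVD; scores/loadings are reported for
the components covering 95% of the effect's sum of squares, minimum two.

## Univariate reproducibility

Two-sided Student's t tests (pooled variance — the classical equal-variance
two-sample test; Welch is a flag) per feature within each stratum (per
batch, or per batch × passage), on corrected, unscaled intensities. Fold
change is the ratio of arithmetic means, treatment over control; a log-scale
variant is a flag. No multiple-testing correction is applied — significance
is raw p < 0.05, and the output metadata records that FDR is uncontrolled,
because the cross-batch *intersection* of significant sets is itself the
reproducibility statistic of interest here, not any single test. Strata with
fewer than two samples per group are skipped and reported. Intersection
summaries count features significant in exactly/at least k batches and in
all batches; when annotations are present, features annotated to the same
metabolite can be collapsed ("unique metabolites"). Fold-change consistency
reports, per feature, whether all stratum fold changes fall on the same side
of 1.

## Mantel meta-analysis of pathway results

Each comparison's pathway table (pathway id, enrichment p value, topology
impact) is embedded at coordinates (−log₁₀ p, impact) — unstandardised,
exactly as named; a z-scoring switch exists but is off by default. p values
of zero are floored at 1e-300 before the logarithm. Pairwise Euclidean
distances over the shared pathways (inner join on id, ≥ 3 required) give two
distance matrices; the statistic is the Pearson correlation of their upper
triangles. Significance is a one-sided permutation test (joint row/column
shuffles of one matrix, r_perm ≥ r_obs), p = (count + 1)/(n_perm + 1) with
999 permutations by default; with ≤ 5 shared pathways all n! permutations
are enumerated and the p value is exact. The implementation agrees with
scikit-bio's Mantel test (cross-checked in the suite) and with exhaustive
enumeration at n = 4 and 5. A matrix with zero variance in its distances
(all pathways at one coordinate) is degenerate: the pairwise driver reports
such pairs as failed rather than aborting the batch.

## Synthetic experiments

The generator emulates the structure the workflow assumes:

```
intensity(i, j) = exp(baseline_i + batch + passage + treatment)
                  × drift_i(order_j) × noise
```

* **Baselines** log-normal (default mean log 1e4, sd 1).
* **Effects** additive on the natural-log scale, drawn per feature per level
  from centred normals. Defaults: batch sd 0.25, passage sd 0.10, treatment
  sd 0.15 with 30% of features treatment-responsive. The ordering batch ≫
  passage reflects what processing-day/storage effects do to cell extracts
  relative to passage number, and the resulting biological spread dominates
  the 5%-CV analytical noise, so most features pass the 20% D-ratio cutoff
  after correction — the regime a competent real study sits in. Treatment
  effects are drawn for all levels and centred; signed effect sizes versus
  the control (first treatment level) are recorded in the truth object.
* **Design** defaults mirror a five-batch × four-passage × three-treatment
  study with four replicates per cell, a pooled QC every 8 study samples
  (plus one at start and end), and four blanks at the head of the run; study
  injection order is randomised.
* **Drift** is a shared decreasing shape (linear, exponential or sigmoid) of
  normalised injection order spanning the whole run, with per-feature
  magnitude `drift_magnitude × (1 + jitter)` (jitter sd 0.2, reflecting
  feature-dependent drift severity); default magnitude 0.4 — a 40% intensity
  loss across the run.
* **QCs** are synthesised as the per-feature mean of all study samples'
  drift-free expected intensities, then exposed to the same drift and noise:
  exactly the pooled-aliquot assumption behind RSD_QC and the D-ratio.
* **Blanks** carry only a contamination subset of features (default 10%) at
  1/20 of the pooled level; other features are missing in blanks.
* **Noise** is multiplicative log-normal with coefficient of variation
  `noise_cv` (default 5%, a typical well-behaved LC–MS precision).

The truth object stores realised per-level effects, responsive features with
signed effect sizes, drift magnitudes, and realised variance shares —
computed by decomposing the generated log-intensity matrix itself, so they
include what drift and noise actually did. `config_for_variance_shares`
inverts the share arithmetic: requested shares of per-feature log variance
are converted to effect sds given the noise CV (all features responsive,
drift off), which is how the recovery experiments are parameterised.

What the generator does **not** emulate: m/z or RT drift, peak-shape or
integration artefacts, missingness mechanisms (censoring at the detection
limit), correlated features (adducts/isotopes of one metabolite),
between-run batch effects in the instrumental sense, or carry-over beyond
the blank-contamination rule. Passing tests therefore demonstrate that each
algorithm does what it claims under its own assumptions — not that those
assumptions hold for any particular instrument.

## Problem sizes and verification design

Multi-seed statistical tests run on compact designs so the full suite stays
interactive: drift-correction efficacy uses 30 features, a 2×2×3×2 design
and a QC every 4 injections (≈ 31 injections, 7 QCs) over 20 seeds, keeping
the stated drift magnitude 0.4 and noise CV 0.05; ASCA recovery uses 100
features at the full 240-sample design over 20 (median error) and 100
(ranking) seeds; null calibration uses 50 seeds for the t tests (3 200
tests) and ASCA, and 100 seeds for the Mantel test. `scripts/acceptance.py`
re-runs the same computations from scratch (≈ half a minute) and writes
every number it computes; all randomness derives from its `--seed`.

## Known limitations

* QC-SVRC corrects within one injection sequence; between-run harmonisation
  and alternative correctors (LOESS, random forest) are out of scope.
* The sequential cell-mean ASCA estimators are not a GLM; severely
  unbalanced designs would need an ASCA+-style reformulation.
* The low-total-signal outlier rule is a pragmatic stand-in for visual
  inspection and is labelled as such in reports.
* The leave-one-out grid search is exact but O(n_ε × n_γ × n_QC) SVR fits
  per feature; very large feature sets benefit from the coarser grid the
  hyperparameter object exposes.
* Pathway enrichment itself (and hence the meaning of "impact") is consumed,
  not computed; the Mantel analysis inherits whatever the upstream tool did.
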