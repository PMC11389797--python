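# Methods notes

This note documents the statistical procedures mucoseq implements, the
assumptions behind them, the knobs that matter, and what the synthetic-data
generator does and does not emulate.

## Preprocessing

**Sparse-gene filter.** A gene is removed when its zero fraction across
samples is *strictly* greater than `max_zero_fraction` (default 0.5): a
gene at exactly 50% zeros is retained. The filter is idempotent and
precedes normalization throughout the pipeline.

**Library-size normalization.** Each sample's values are rescaled so the
column total equals `scale` (default 10⁶, i.e. counts-per-million). This
compensates for library-size differences but is *compositional*: a strong,
direction-imbalanced expression signature changes the library total and
therefore shifts every other gene's normalized value in the opposite
direction. This matters for interpretation (see the overlap null below)
and is preserved deliberately — it is what per-million scaling does.

**PCA.** Samples are observations, genes are mean-centered; no log
transform and no unit-variance gene scaling by default. Both alternatives
are exposed (`pca.log1p`, `pca.scale_genes`) because the choice can move
the variance fractions appreciably and conventions differ between tools.
Zero-variance genes are dropped (logged), and a component count above the
data rank is reduced with a warning rather than raised.

**Row z-scoring** (display normalization before heatmaps) uses the
population convention (ddof = 0); constant rows map to zeros with a
warning.

## Differential expression

Per gene, a two-sided Mann-Whitney test between two groups of ≥ 3 samples.
When both groups have ≤ 8 samples and the gene has no tied values, the
p-value is exact, computed from the full null distribution of U (a
dynamic-programming count over all C(n1+n2, n1) rank arrangements, doubled
smaller tail capped at 1). Otherwise the tie-corrected normal
approximation with continuity correction is used. At the study scale of
5–7 mice per group, the exact branch covers every tie-free gene; ties
arise almost solely from zeros.

Fold change is `log2((mean_treated + c) / (mean_control + c))` with
pseudocount c = 1; only its *sign* feeds the overlap statistic, and the
sign equals that of the mean difference. The significant set is
`p < alpha` (strict, default 0.05) with a nonzero direction — deliberately
uncorrected for multiple testing, mirroring the displayed DEG rule of the
analysis this package operationalizes; a Benjamini-Hochberg toggle
(`deg.correction: bh`) is available for users who prefer FDR control.

**Attainable level.** A rank test on 5 + 5 samples is discrete: the
smallest two-sided exact p is 2/252 ≈ 0.0079 and the largest attainable
level below 0.05 is 2·4/252 ≈ 0.032. The realized type-I rate of the test
is therefore *below* the nominal alpha at these sample sizes. The test
suite checks calibration against this attainable level (computed by
exhaustive label-permutation), not against the nominal 0.05, which no
correct discrete test can realize exactly.

## Direction-consistent overlap and its bootstrap null

Given signed significant sets A and B over a shared tested universe of G
genes, the statistic is the number of common members whose directions
agree. The null fixes both set *sizes* and draws uniform random subsets of
the universe without replacement, independently for A and B, B = 10,000
times; every sampled gene keeps the sign observed in the corresponding
cohort's full DEG table (genes with direction 0 never agree). The
empirical p is the raw proportion of replicates ≥ the observed value — no
+1 smoothing — with the resolution floor 1/B reported alongside
(`p < 1/B` when no replicate reaches the observed overlap).

Design choices, recorded also in every run's JSON report:

* the sampling universe is the post-filter tested gene set ("the original
  data"), not the genome;
* signs are the observed per-cohort signs, not re-randomized coins — the
  statistic is about observed fold-change directions;
* the null mean has the closed form (|A|·|B|/G)·a with a the
  universe-wide sign-agreement rate, used by the test suite at 10
  parameter settings and against exhaustive subset-pair enumeration on
  universes small enough to enumerate.

Note that under CPM normalization the sign-agreement rate a between two
cohorts is *not* 0.5 even for null genes when a strong imbalanced
signature is present (the compositional shift pushes null genes the same
way in both cohorts). The bootstrap null absorbs this automatically
because it uses the observed signs; the closed form holds with the
realized a.

A hypergeometric tail probability for the unsigned intersection is
provided purely as a cross-check utility; it is not the headline method.

## Classification harness

Four classes (cohort × treatment). Per iteration: a fresh stratified
random split — 5 training and 2 test mice per group (20/8 at the protocol
scale) — and a fresh 200-tree random forest (scikit-learn, impurity-based
importances, defaults otherwise; the ensemble is a pluggable component and
the tree count is the only protocol-fixed hyperparameter). Test
predictions accumulate into a per-true-class percentage matrix; feature
importances are averaged over iterations; the top-k ranking breaks ties by
gene ID so results are reproducible. Iteration seeds derive from the
master seed by counter, so a run at fewer iterations is a prefix of a
longer one. The protocol scale is 10,000 iterations; the package's test
and default configurations use 200, which already stabilizes the
aggregate matrix to within a few percentage points.

On uninformative features the expected diagonal is 25% for four balanced
classes, but individual mice have fixed (noise) expression profiles that
are reused across iterations, so aggregated per-class accuracies are
substantially more variable than a binomial count over
iterations × test-samples would suggest. Calibration checks therefore
bound the *overall* accuracy within ±10 percentage points of chance rather
than applying a per-entry binomial interval.

Heatmap ordering: average-linkage agglomerative clustering with
correlation distance on the row-standardized matrix, rows and columns
independently; deterministic leaf orders for a fixed input.

## Barrier metrics

* Per-mouse distance summary: mean (median via config) of ≥ 25
  measurements per mouse and probe; fewer raise a validation error listing
  the offenders (overridable with a warning).
* Taxa distance ratio: ratio of per-mouse mean distances of two probes,
  computed per mouse and then compared across groups (each animal is one
  observation; reciprocal ratios multiply to 1 by construction).
* Mucus growth rate: least-squares slope of thickness vs time over the
  recording window (default 45 min). Equivalent to the endpoint difference
  on noiseless data, more robust on noisy series; invariant to thickness
  offsets and linear in time rescaling.
* Paired secretion comparison: per-animal control/treated tissue pairs;
  differences, control/treated ratios, and a two-sided paired t test
  (p = 1 when all differences vanish; ≥ 3 complete pairs required).
* Disease activity index: weight-loss, stool and bleeding subscores, each
  0–4, summed (0–12). Subscore maps (standard DSS scheme, shipped as
  editable tables): weight loss < 1% → 0, 1–5 → 1, 5–10 → 2, 10–20 → 3,
  ≥ 20 → 4; stool normal/solid 0, loose 2, diarrhea 4; bleeding none 0,
  occult 2, gross 4. `weight_change_pct` is signed (−12 = 12% lost).
* Ulceration percent: 100·u/(u+h); undefined (error) when both areas are
  zero.
* Group comparisons in reports follow the conventions of the figures this
  mirrors: Student's t for two groups, one-way ANOVA for more, paired t
  for paired designs. These are reporting conveniences, not contributions.

## Synthetic data

The generator reproduces the *statistical structure* the analysis assumes,
with ground truth attached.

**Counts.** Negative binomial with variance μ + αμ² (default dispersion
α = 0.3, a typical bulk RNA-seq value). Baseline means are log-normal
across genes: log10 mean ~ Normal(1.5, 0.8). The location gives a median
of ~30 counts; the scale keeps the top gene below ~8% of the library. A
wider scale (e.g. 1.5 on log10) makes single genes dominate the library
total, which destabilizes per-million normalization across seeds and is
not representative of real bulk libraries — this is why 0.8 is the
default. Effect genes multiply the treated-group mean by
2^(±log2_effect_size), sign fixed per gene at generation (seeded coin
flip) and identical in both cohorts for shared genes; truth labels
partition genes into shared / cohortA-only / cohortB-only / null.

**Sparsity.** With `sparse_fraction` set, exactly
round(sparse_fraction·n_genes) designated (null-class) genes are given
near-zero means and then pinned strictly above 50% zeros, while all other
genes are topped up to at most 50% zeros — the >50%-zeros filter outcome
is then exact by construction, which is what a deterministic filter-count
fixture requires. Without it, counts are untouched negative binomial
(used for the marginal-moment property test).

**Distances.** Gamma(shape, scale) per probe and mouse (≥ 25 draws per
mouse); treatment multiplies the scale (values < 1 move bacteria toward
the epithelium). Gamma is a modeling choice for a nonnegative,
right-skewed distance distribution — the underlying imaging study reports
no distributional form.

**Mucus.** Paired control/treated series per animal:
thickness = baseline + rate·t + Gaussian noise, sampled every 5 minutes
over 45 minutes (10 points). Default rates 2 vs 1 μm/min encode the
twofold secretion-rate reduction the treated condition shows.

**What this does not emulate:** gene-gene correlation, batch effects,
library-preparation biases, probe cross-hybridization, spatial
autocorrelation of distance measurements within a section, or non-linear
mucus growth. Passing tests demonstrate correctness of the statistical
machinery under the declared generative model, not robustness to these
real-data features.

## Determinism and numerics

One master seed expands into named substreams (counts, distances, time
series, bootstrap, classifier) via `numpy` seed sequences, so stages can
be regenerated independently and any report is byte-reproducible given its
embedded config. Exact Mann-Whitney CDFs are cached per group-size pair.
Empirical p-values are raw exceedance proportions; 0 is reported with its
floor 1/B. Degenerate inputs (constant rows, zero-total samples,
undersized groups, < 25 distance measurements, unpaired tissues) raise
typed errors early rather than propagating NaNs.

## Problem sizes in the shipped tests

The test and acceptance configurations run the full pipeline at 10⁴ genes
with 5–7 mice per group, B = 10,000 bootstrap replicates for headline
p-values (1,000 within the 200-dataset null-calibration sweep), and 200
classifier iterations — sizes at which every aggregate this package
reports is stable while the whole suite completes in minutes on one core.
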