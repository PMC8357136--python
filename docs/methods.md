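# Methods

`crossclock` implements a cross-species transcriptome aging-clock
workflow: starting from per-species gene-count matrices pooled across
several public sequencing studies, it identifies genes whose expression
is correlated with chronological age in *both* of two species (the
motivating application is human prefrontal cortex versus fly head), and
validates the resulting conserved gene set by resampled age regression
and age-group classification. Because the workflow is meant to run and
be verified without multi-hundred-gigabyte downloads, a synthetic-data
module generates two-species, multi-study count data with a planted,
known ground truth.

## The discovery procedure

1. **Ingest & filter.** Counts are genes × samples non-negative
   integers with per-sample metadata (study, age, age unit, species).
   A gene is kept iff its count exceeds 10 in at least 50% of samples
   (`count > min_count` strictly; `ceil(min_fraction · n)` samples).
   Filtering precedes normalization.
2. **Normalization.** Per-sample scaling factors by TMM (trimmed mean
   of M-values) or RLE (median-of-ratios), then
   `log2((count + 0.5) / (N_k · f_k) · 1e6)` (log2-CPM). Both methods
   are reported on a common convention — `f_k` multiplies the library
   size `N_k`, `geomean(f) = 1` — so they are interchangeable
   downstream. TMM details: reference sample = upper-quartile CPM
   closest to the mean upper quartile; genes zero in either sample are
   excluded; two-tailed trims of 30% on M and 5% on A with
   `floor(frac · n)` removed per tail after a stable sort tie-broken by
   gene id (deterministic across platforms); gene weights are inverse
   asymptotic variances `1/w_g` with
   `w_g = (N_k−y_k)/(N_k y_k) + (N_r−y_r)/(N_r y_r)`.
   A scalar **study-effect score** — the variance across studies of the
   per-study mean log expression — quantifies how much between-study
   separation remains; it is compared against unnormalized `log2(count
   + 0.5)`, which carries the full sequencing-depth effect.
3. **Age-correlation ranking.** Pearson correlation (Spearman optional)
   of each gene's log-CPM with chronological age; zero-variance genes
   get r = 0. Genes are ranked by |r| by default (signed optional) with
   ties broken by gene id, and the top k = 1000 form each species' list.
   |r| is the default so that genes falling with age can enter the list.
4. **Ortholog best-match & intersection.** A scored many-to-many
   ortholog table (DIOPT-style; the score is treated as an opaque
   non-negative number) is resolved greedily: rows sorted by score
   descending (ties lexicographic by the two ids) are accepted iff
   neither gene is matched yet. Greedy-by-score is used rather than
   maximum-weight bipartite matching because it reproduces the
   keep-the-highest-ranked-homolog convention; matching would silently
   change the gene set. The conserved set is the best-match pairs whose
   members both lie in their species' top-k list, ordered by
   `min(rank_a, rank_b)`.
5. **Evaluation.** For a given gene list, 1000 (configurable)
   iterations each draw an independent disjoint 75/25 train/test
   partition, fit the model on training log2-CPM features, and score
   held-out samples (R², MSE, mean/median absolute error for
   regression; accuracy and macro F1/precision/recall plus a mean 3×3
   confusion matrix for Young/Middle/Old classification). Summaries are
   arithmetic means over iterations; the 95% CI for R² is the
   2.5th/97.5th percentile of the per-iteration values. Feature sets
   compared against each other share the identical split sequence and
   per-iteration model seeds, so rows are paired.

Age groups: years — Young < 30, Middle 30–60 (inclusive), Old > 60;
days — Young ≤ 10, Middle (10, 29], Old > 29. The day-scale source
convention leaves day 30 uncovered ("10–29" versus "above 30"); we
assign day 30 to Old so the three groups partition the positive reals.
Both boundary pairs are configurable.

## Design choices where the design was open

* **Partitions, not bootstrap.** "Random sampling with replacement"
  protocols conflict with disjoint train/test splitting; duplicated
  samples would leak between train and test. Each iteration is an
  independent disjoint partition with `|train| = round(0.75 · n)`; a
  bootstrap mode (with-replacement training set, out-of-bag test) is
  available behind a flag.
* **Stratification as class presence.** Classification splits are
  redrawn (up to 100 times, then an error) until every age group occurs
  in the training set. This preserves the exact train size while
  preventing empty-class training folds under the class imbalance
  typical of pooled public cohorts.
* **Default learner.** A gradient-boosted decision-tree ensemble
  (XGBoost) with library defaults, pinned to one thread so that runs
  are bit-reproducible; twelve further learners are reachable by name
  through the model registry for both tasks where they apply. The
  discrete-label models (logistic, LDA, naive Bayes) treat training
  ages as class labels when used for regression.
* **Global normalization.** Scaling factors and log-CPM are computed
  once on all samples, not refit inside each training fold. This is a
  mild information leak (test samples influence the reference and the
  trims) accepted for comparability across feature sets; tree ensembles
  are insensitive to the per-sample monotone shifts involved.
* **Log transform.** The feature scale is log2-CPM with pseudocount
  0.5. Correlation ranking runs on the TMM-normalized matrix.
* **TMM scaling invariance.** Multiplying *all* samples by a constant
  leaves TMM factors unchanged to numerical precision. Multiplying a
  single sample's counts by a constant changes its precision weights
  (they depend on the library size non-uniformly across genes), so
  factors are only approximately invariant (observed drift well under
  1%); this is a property of the published weighting, not an
  implementation artifact.

## The synthetic-data generator

Counts for gene *g* in sample *k* are negative binomial,
mean `mu = 2^(baseline_g + slope_g · z_k + batch_gs) · L_k` and variance
`mu + φ·mu²` (Poisson at φ = 0, sampled gamma–Poisson otherwise), where

* `z_k` is age standardized by the pooled within-species mean/SD, so a
  slope of `effect_size` log2 units per SD of age means the same thing
  for ages in years (species A) and integer days (species B);
* `batch_gs ~ N(0, gene_study_sd)` is gene × study batch noise;
* `L_k = exp(study offset + sample noise)` with
  `study offset ~ N(0, study_logsize_sd)` reproduces the order-of-
  magnitude library-size differences between pooled studies.

Planted signal: `n_conserved_pairs` ortholog pairs age in both species
(pair *i* keeps one sign in both; signs alternate half up / half down),
plus `n_private_aging_*` genes aging in one species only. Planted genes
draw their baseline expression from the upper half of
`baseline_logmean_range` so the ground truth survives the expression
filter — a truth gene the filter removes could never be recovered and
would make recall ill-defined. The ortholog table holds one true row
per conserved pair with scores in [10, 15] and decoy many-to-many rows
(fraction `ortholog_noise` of the table) scored strictly below 10, so
best-match resolution is exercised with a known answer. Within-study
ages are uniform over the study's window; real archives do not document
their within-study age distributions, so uniform is an assumption.

Two standard configurations:

* **Recovery benchmark** (`default_config`): 2000 genes/species, 3
  studies × 20 samples, uneven per-study age windows (years 20–50,
  25–75, 40–90; days 3–15, 5–40, 20–60), 40 conserved pairs, 30
  private agers per species, effect 0.5, dispersion 0.2,
  `study_logsize_sd` 0.8. The effect size was calibrated once so that
  ≥ 90% of planted genes enter each species' top-1000 with margin
  across 20 simulation replicates (median planted |r| ≈ 0.55–0.6
  against a top-1000 entry threshold near 0.1).
* **Demo cohort** (`demo_config`): per-study sample counts follow the
  pooled archive cohorts the package emulates (116 samples over 7
  studies; 108 over 6), every study spans the full age range, and 200
  genes per species age privately in addition to the 40 conserved
  pairs (~12% age-associated genes — the pervasive weak aging signal
  real brain transcriptomes show, rather than a sparse-needle regime).
  Equal age spans per study are deliberate: with uneven windows, study
  identity itself predicts age, so gene × study batch noise would make
  *any* feature set "predictive" and a noise-only negative control
  uninterpretable.

What the generator does **not** emulate: read-level artifacts (quality,
adapters, mapping), gene–gene correlation beyond shared batch factors,
sex or other covariates, nonlinear age trajectories, and annotation
drift between species. Passing tests therefore demonstrate that the
pipeline recovers monotone planted signal under realistic depth/batch
heterogeneity — not that any particular biological gene list is
correct.

## Numerical conventions and degenerate inputs

Sorting that feeds trimming, ranking, top-k lists and greedy matching is
always a stable sort with gene-id tie-breaks, so outputs are identical
across platforms and reruns; pipeline artifacts are written with fixed
float formatting and are byte-reproducible under a fixed seed (the run
manifest is excluded — it records wall-clock times). All randomness in
a run derives from one configured seed via a single generator; model
seeds are drawn per iteration interleaved with the splits.

Degenerate cases: constant genes get r = 0; constant ages are an error;
samples sharing no positive gene with the TMM reference, or RLE with no
gene positive everywhere, raise errors naming the sample; an expression
filter that removes every gene is a warning, not an error; top-k with
k exceeding the gene count truncates with a warning; test splits with
fewer than two samples or constant test ages are skipped and counted.

## Problem sizes used in the shipped experiments

The recovery benchmark runs at 2000 genes × 60 samples per species and
the demo cohort at 2000 genes × 116/108 samples — scaled down from the
~17k/9.7k-gene matrices of the motivating data so the full workflow,
including the resampled XGBoost evaluations, runs on a single CPU in
minutes. The demo evaluates 10 resampling iterations by default and
the acceptance script 40; the protocol's canonical 1000 iterations are
a configuration change (`eval_iterations`), not a code change.

## Known limitations

* Correlation ranking ignores within-study confounding; no partial
  correlation adjusting for study is offered.
* No p-values/FDR accompany the correlation ranking, mirroring the
  rank-based selection it implements.
* Global (not per-fold) normalization, as discussed above.
* DIOPT score semantics (number of agreeing prediction tools) are not
  modelled; any non-negative score column works.
* The day-30 age-group boundary is a convention choice; see above.
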