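# crossclock

Cross-species transcriptome aging clocks from pooled multi-study RNA-seq
count data.

Aging reshapes gene expression in the brain, and changes that are
*conserved* between distant species — human prefrontal cortex and fly
head being the motivating pair — point at core aging biology that can be
dissected in a short-lived model organism. `crossclock` implements the
full discovery-and-validation workflow for such conserved aging
signatures from gene-level count matrices pooled across public
sequencing studies:

1. **ingest & filter** — validate counts + sample metadata; keep genes
   with counts > 10 in ≥ 50% of samples;
2. **normalize** — TMM or RLE scaling factors and log2-CPM, with a
   scalar *study-effect score* measuring how much between-study
   separation remains;
3. **rank** — per-gene Pearson correlation of expression with
   chronological age; top-1000 lists per species;
4. **conserve** — greedy best-match resolution of a scored DIOPT-style
   ortholog table, then intersection of the two top lists into the
   conserved gene set;
5. **evaluate** — resampled validation: repeated independent 75/25
   train/test partitions, gradient-boosted (XGBoost) age regression and
   Young/Middle/Old classification, means and percentile 95% CIs over
   iterations, averaged confusion matrices, paired comparisons between
   feature sets.

A synthetic-data module (`crossclock.simulate`) generates two-species,
multi-study negative-binomial count data with planted age-associated
ortholog pairs and known ground truth, so the entire workflow runs and
is verified without downloading anything.

The key quantities are the per-gene age correlation
r_g = corr(x_g, age) over samples, the conserved set
{(a, b) ∈ best-match : a ∈ top-k_A(|r|), b ∈ top-k_B(|r|)}, and the
held-out coefficient of determination R² = 1 − SS_res/SS_tot per
resampling iteration (negative when a model is worse than predicting
the test mean).

## Worked example

The one-command demo simulates a pooled two-species cohort (116 human-
like samples over 7 studies, 108 fly-like over 6; 2000 genes per
species; 40 planted conserved ortholog pairs plus 200 private aging
genes per species), runs every stage, and validates four feature sets
with 10 resampled 75/25 XGBoost evaluations:

```bash
crossclock demo --seed 0 --out demo_out
```

prints (`a` = year-scale species, `b` = day-scale species; values are
means over iterations — accuracy for classification, R² for regression):

```
genes after filter: A=1463 B=1690
conserved pairs found: 41 (recall 1.00 of 40 planted)
classification_a: all=0.690, topk=0.686, conserved=0.741, noise=0.366
classification_b: all=0.744, topk=0.733, conserved=0.719, noise=0.463
regression_a: all=0.672, topk=0.711, conserved=0.698, noise=-0.370
regression_b: all=0.733, topk=0.754, conserved=0.698, noise=-0.282
```

Reading the output: the expression filter keeps roughly three quarters
of the 2000 simulated genes; the pipeline recovers all 40 planted
conserved pairs (one decoy pair sneaks in, hence 41); restricting the
model from all expressed genes to
the 1000 most age-correlated, or further to the ~40 conserved genes,
changes mean R² and classification accuracy only slightly — the small
penalty for drastic feature reduction that motivates conserved gene
sets — while a 50-gene noise-only control set predicts age no better
than chance (negative R², near-chance accuracy).

Every stage is also scriptable (`crossclock simulate|ingest|normalize|
rank|conserve|evaluate|run`, YAML config for `run`) and usable as a
library; `CountNormalizer` and `AgeCorrelationSelector` are
scikit-learn transformers that compose with `sklearn.pipeline`.

```python
from crossclock import SimConfig, simulate_dataset, filter_expressed, \
    normalize_dataset, correlate_with_age, top_k

sim = simulate_dataset(SimConfig(seed=1))
ds = filter_expressed(sim.dataset_a)
factors, logcpm = normalize_dataset(ds, method="tmm")
ranking = correlate_with_age(logcpm, ds.ages)
print(top_k(ranking, k=10))
```

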