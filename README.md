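# bloodmirna

Analysis pipeline for two-color (sample/reference) microRNA microarray
profiles of whole blood, built around a case–control diagnostic study
design: lung adenocarcinoma patients versus clinically relevant controls
(benign-nodule and high-smoking-risk subjects).

The package covers the full path from scanner-level spot tables to
cross-validated diagnostic classifiers:

- **Pre-processing** — normexp background correction (observed intensity =
  Normal(μ, σ²) background + Exponential(α) signal; corrected value is
  E[signal | observed] + offset), within-array global loess normalization of
  M = log₂(sample/reference) on A = ½(log₂ sample + log₂ reference),
  between-array quantile normalization of the reference channel, replicate
  summarization (mean if max < 1.5×min, else median), and an expression call
  against probe-less empty spots (signal > 3× empty level on ≥ ¼ of arrays).
- **Differential expression** — empirical-Bayes moderated t-statistics: the
  prior (d₀, s₀²) of the scaled inverse-χ² variance hierarchy is estimated
  by moment-matching of log sample variances; the statistic is
  t̃ᵧ = (x̄₁−x̄₂)/(s̃ᵧ√(1/n₁+1/n₂)) with s̃ᵧ² = (d₀s₀² + d·sᵧ²)/(d₀+d) on
  d₀+d degrees of freedom, with Benjamini–Hochberg FDR control, Wilcoxon
  rank-sum alternatives, and linear-scale fold-changes.
- **Classification** — top-scoring pairs (TSP: the probe pair maximizing
  Δᵢⱼ = |P̂(Xᵢ<Xⱼ | case) − P̂(Xᵢ<Xⱼ | control)|) and linear soft-margin SVM
  with moderated-t variable filtering (≤15 probes) and nested 3-fold tuning
  of the cost over {0.1, 0.2, 0.5, 1, 2, 5, 10, 20, 50}.
- **Cross-validation** — leave-one-out and Monte-Carlo (random 36/9 splits)
  harnesses with strict train/test isolation, accuracy/sensitivity/
  specificity/PPV/NPV accounting, feature-frequency tables, and a
  training-set-size sweep.
- **Evaluation** — empirical ROC/AUC (Mann–Whitney form), DeLong comparison
  of correlated AUCs, covariate (age, blood-count) correlation profiling
  with permutation nulls, average-linkage hierarchical clustering on
  correlation distance with optimized leaf ordering, and RT-PCR/array
  concordance statistics.
- **Synthetic data** — a spot-level generator that emulates the study's
  statistical structure (22 cases / 23 controls with an age imbalance,
  1305 quadruplicate probes + 548 empty spots per array, additive
  background + exponential signal, intensity-dependent dye bias, planted
  fold-changes in 0.54–1.59, a planted perfectly separating probe pair, and
  age-driven probes) with full ground-truth records, so every stage is
  testable end to end without any external data.

## Worked example

```python
from bloodmirna.simulate import SyntheticConfig, generate_dataset
from bloodmirna.preprocess import run_preprocess
from bloodmirna.diffexp import diffexp_table
from bloodmirna.crossval import loocv

cfg = SyntheticConfig(n_probes=300, n_empty_spots=150,
                      n_de_probes=30, n_age_probes=10, seed=42)
dataset = generate_dataset(cfg)
matrix, empty = run_preprocess(dataset.spot_tables, dataset.panel)
print(f"expressed probes: {int(matrix.expressed_mask.sum())}")
print(f"empty-spot summary mean: {empty.mean():.1f}")

expr = matrix.expressed()
classes = dataset.sample_sheet.classes
table = diffexp_table(expr.values, classes)
print(f"differentially expressed at BH 5%: {(table.q < 0.05).sum()}")

report = loocv(expr.log2, classes, method="tsp")
m = report.pooled_metrics
print(f"TSP LOOCV: accuracy {m['accuracy']:.0f}%, "
      f"sensitivity {m['sensitivity']:.0f}%, specificity {m['specificity']:.0f}%")
```

Output:

```
expressed probes: 95
empty-spot summary mean: 11.3
differentially expressed at BH 5%: 2
TSP LOOCV: accuracy 100%, sensitivity 100%, specificity 100%
```

The empty-spot summaries sit near 11 — background-only spots corrected with
a normexp offset of 10 carry about one unit of residual signal expectation.
The two BH-significant probes are the planted separating pair (their
class-dependent ordering is a ~64-fold swing); the moderate planted
fold-changes (0.54–1.59) at n = 45 are mostly below genome-wide
significance, which is why the rank-based TSP classifier, not the
single-probe tests, carries the diagnostic signal.

A command-line interface mirrors the library
(`bloodmirna simulate|preprocess|diffexp|classify-cv|evaluate`); every
subcommand takes TSV inputs as documented in `bloodmirna.io` plus `--seed`.

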