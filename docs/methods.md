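# Methods

This note documents the statistical models, numerical choices, and design
decisions behind `bloodmirna`, and what the synthetic-data tests do and do
not establish about real data.

## Study design being modeled

The pipeline targets a two-color microarray study of whole-blood microRNA
expression in a case–control setting: 22 lung adenocarcinoma cases versus
23 controls (10 with benign lung nodules, 13 at high risk from smoking
history). Each hybridization co-measures a study specimen (sample channel)
against a common pooled reference RNA (reference channel). Arrays carry
~1305 probes printed in quadruplicate plus 548 probe-less empty spots that
measure pure background. The cases are on average about a decade older
than the controls, which makes age a structural confounder; the evaluate
module exists largely to quantify that.

## Pre-processing

Stage order is fixed and recorded in the matrix provenance:

1. **normexp background correction** (per array, per channel). The observed
   spot intensity is modeled as X = B + S with B ~ Normal(μ, σ²) background
   and S ~ Exponential(mean α) signal. Parameters are estimated by full
   maximum likelihood (L-BFGS-B on (μ, log σ, log α) with analytic
   gradients, followed by a short Nelder–Mead polish). Two moment-based
   starts are used: a skewness start (the exponential component carries the
   third moment) and a lower-quantile background start. The second start
   matters because the likelihood has a degenerate σ→0 basin when the
   signal component dominates; multi-start plus bounds keeps the optimizer
   out of it. The corrected value is E[S | X = x] + offset with offset 10;
   the conditional expectation uses the erfcx form of the inverse Mills
   ratio, which is stable at low intensities, and is strictly positive and
   monotone in x, so corrected intensities are bounded below by the offset.
2. **Within-array loess** of M = log₂(sample/reference) on
   A = ½(log₂ sample + log₂ reference) over all spots jointly, span 1/3,
   degree-1 local fits with tricube weights and 3 robustness iterations
   (statsmodels `lowess`). The fitted trend is subtracted from M; A is
   unchanged. A `delta` interpolation parameter of 1% of the A-range is
   used — the standard dense-design shortcut, exact at the knots. Note
   that a degree-1 local fit carries smoothing bias of order
   f″(A)·(window width)²; at span 1/3 a trend with curvature on the scale
   of the full A-range is attenuated ~10-fold rather than removed exactly.
   This matches the behavior of the degree-1 lowess used by standard
   two-color pipelines; the span must be narrowed if a sharper trend is
   suspected.
3. **Between-array reference-channel quantile normalization.** The sorted
   reference intensities are averaged across arrays rank by rank; each
   array's reference channel is mapped onto that common distribution (ties
   receive the mean of their tied ranks' values via average-rank
   interpolation). Per-spot M is held fixed and the sample channel is
   recomputed from (M, new reference), so within-array log-ratios are
   exactly invariant.
4. **Replicate summarization.** Per probe per array, the summarized signal
   is the mean of the replicate spot values when max < 1.5×min, otherwise
   the median — the median branch is the outlier guard. Summarization runs
   on linear-scale normalized intensities.
5. **Expression call.** Each array's 548 summarized empty-spot signals are
   averaged into a per-array empty level; a probe is called expressed when
   its signal exceeds 3× that level on at least ⌈0.25 × n_arrays⌉ arrays
   (12 of 45 at the study size). A pooled-empty variant is available as a
   config option; the per-array reference is the default because it makes
   the fewest assumptions. "At least a quarter" is implemented with the
   ceiling convention.

## Differential expression

Tests run on log₂ signals; fold-changes are ratios of linear-scale group
means (the only combination consistent with reporting group means and
their ratios on the signal scale). The moderated t shrinks per-probe pooled
variances toward a prior via the scaled inverse-χ² hierarchy:
s̃ᵧ² = (d₀s₀² + d·sᵧ²)/(d₀ + d), t̃ᵧ on d₀ + d degrees of freedom. The prior
is fitted by matching the first two moments of log sᵧ² to the theoretical
log-F distribution through digamma/trigamma relations, with a Newton
trigamma inverse; when the observed dispersion of log-variances does not
exceed the sampling floor trigamma(d/2), the prior degenerates to d₀ = ∞
and all probes share s₀². d₀ = 0 reproduces the ordinary pooled t exactly
(a tested reduction). Benjamini–Hochberg adjustment is the plain step-up
with monotonicity enforcement. The Wilcoxon rank-sum alternative uses the
exact distribution when min(n₁, n₂) ≤ 8 with no ties and the
continuity-corrected normal approximation with tie correction otherwise;
at n = 8/8 the two agree to about 0.01 in p. Cohort summary comparisons
use pooled-variance two-sided t-tests (computable from raw values or from
published n/mean/sd summaries) for continuous variables and Fisher's exact
test (two-sided, summing tables at most as probable) for categorical ones.

## Classification

**TSP.** For every ordered probe pair, Δᵢⱼ is the difference in the
class-conditional frequencies of the within-sample ordering Xᵢ < Xⱼ, with
ties counting as "not less-than". The maximal Δ wins; ties are broken by
the rank-difference score γ (the gap between class means of within-sample
rank differences), then lexicographically by probe id, making selection
deterministic. Prediction reads the observed ordering through the
training-set orientation; an exact tie votes for the training majority
class. Because only within-sample order is used, TSP is invariant to any
per-sample monotone transformation — log₂ versus linear input provably
cannot change the fitted pair (tested).

**SVM.** Probes are ranked by |moderated t| on the training data only and
the top ≤15 kept; the soft-margin cost is tuned over the fixed 9-value grid
by stratified inner 3-fold cross-validation (ties go to the smaller cost,
i.e. the smoother model); the final linear SVM is refit on all training
data; probabilities come from Platt scaling (logistic regression) of the
inner out-of-fold decision values. Inner folds are seeded from the run
seed, so fitting is deterministic given (data, seed).

**Cross-validation.** LOOCV aggregates the n single-sample predictions
into one pooled confusion matrix — the only aggregation under which 45
one-sample tests yield a meaningful sensitivity/specificity/accuracy
triple. MCCV draws unstratified random 36/9 splits (stratification is a
config option); a training draw that misses a class is resampled and
logged. Per-iteration metrics with an absent denominator class are
recorded as missing, never as zero. No information from test samples
(values or labels) can reach filtering, tuning, or fitting; the test suite
asserts bitwise-identical serialized models under test-set permutation.

## Evaluation

AUC is computed in the Mann–Whitney form (ties counted ½), which equals
the trapezoid area under the empirical ROC; the per-sample structural
components are retained for the DeLong variance of correlated AUC
differences (z = ΔAUC/SE against the normal). Covariate profiling reports
per-probe Pearson r over pairwise-complete samples with a flag threshold
of |r| > 0.4, an analytic null rate via the t-transform of r, and a
permutation null of the flagged fraction. Hierarchical clustering uses
1 − Pearson r distance with average linkage; a constant profile has
undefined correlation and is assigned the maximal distance 2.0 with a
warning rather than being dropped. Leaf order minimizes the sum of
adjacent-leaf distances among orders consistent with the tree
(optimal leaf ordering). Platform concordance between RT-PCR Cq values and
log₂ array signals reports Pearson r with a Fisher-z 95% CI and the
range-amplification ratio; r is expected negative because Cq is inversely
log-linear in abundance.

## Synthetic-data generator

The generator emulates the study conditions so that every downstream stage
can be tested with known truth:

- **Cohort:** 22 cases / 23 controls; ages Normal(70.6, 7.7²) truncated to
  50–85 for cases and Normal(59.9, 9.1²) truncated to 36–74 for controls;
  10 nodule / 13 high-risk control subtypes; blood parameters present for
  17 of 23 controls.
- **Arrays:** 1305 probes in quadruplicate plus 548 empty spots. Each spot
  intensity is Normal(40, 0.5²) background plus an Exponential draw with
  mean equal to the latent expression level; empty spots are
  background-only. The reference channel uses the pooled mean latent level
  across samples — only ratios and reference-quantile behavior matter
  downstream, so the unknown composition of a real universal reference
  does not need modeling.
- **Expression structure:** only ~35% of probes carry real signal
  (baseline log₂ levels Normal(6.5, 1.48²), chosen so the quartiles of
  expressed signals sit near 2^5.5 and 2^7.5); the rest sit at background.
  This expressed minority matters numerically: without it the normexp
  background location is dragged ~2σ low by the weak-signal continuum and
  the empty-spot calibration point (summarized empty signals ≈ 11, range
  8.6–12.4, with offset 10) cannot be reproduced. Background parameters
  were calibrated once against that band.
- **Planted effects:** 96 differential probes with fold-changes log-uniform
  on [0.54, 1.59] applied multiplicatively to case samples; 22 age-linked
  probes with slope 0.06 log₂-units/year of age; a planted pair with a
  class-dependent ±3 log₂ ordering swing. The pair separation (6 log₂
  units between orientations) is deliberately large: each spot's
  exponential noise has CV 1, so a quadruplicate-summarized log-ratio
  carries ~1 log₂ unit of noise, and a perfectly separating *observed*
  ordering across 45 samples requires a margin of several noise SDs. With
  the default margin the per-sample flip probability is ~10⁻⁸.
- **Corruption:** a smooth intensity-dependent dye bias (amplitude 0.3 on
  the M scale) exercises the loess stage; 5% of spots are inflated 3× to
  exercise the median branch of summarization.
- **Reproducibility:** one `seed` drives everything; an optional
  `measurement_seed` re-draws only the measurement noise (sample-level
  noise and spot-level draws) while holding the planted truth fixed, which
  is what replicate parameter-recovery studies need.

**What passing synthetic tests do not show.** The generator has no spatial
artifacts, print-tip effects, cross-hybridization, probe-sequence
chemistry, or batch structure; its per-probe variance model is a single
log-normal spread plus exponential spot noise. Pipeline correctness on
this structure does not guarantee the same operating characteristics on
real arrays — in particular the empty-spot calibration and the expressed
fraction were tuned to the emulated study's printed values, not derived
from first principles.

## Numerical choices and degenerate inputs

- normexp refuses fewer than 50 intensities or a zero-spread vector
  (estimation error), and optimization is bounded to keep σ and α positive
  and finite.
- Probes with non-positive summarized signal are floored at 10⁻⁸ before
  log₂; this cannot occur with a positive offset and is a pure guard.
- The moderated-prior estimator returns s₀² = exp(mean adjusted
  log-variance); for identical input variances this differs from the
  common value by the factor e^{log(d/2)−ψ(d/2)} ≈ 1 + 1/d (~2% at
  d = 43) — the principled moment-matching convention is kept rather than
  special-casing.
- MCCV degenerate splits (single-class training draw) are resampled with
  logging, up to a bounded number of attempts.
- DeLong with zero variance (identical scores) returns z = 0, p = 1.
- Quantile-normalization ties receive the mean of tied ranks' values.
- All percentages are stored at full precision; rounding to integer
  percent is a display convention only.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full-scale study geometry
(1305 probes × 45 arrays) once for the classification properties, a
200-probe × 45-array geometry for the 50-replicate global-null
calibration, and 80–400-probe geometries for unit-level properties. These
sizes keep the whole suite in the minutes range on one CPU while leaving
every statistical conclusion at the study's own sample size (n = 45).
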