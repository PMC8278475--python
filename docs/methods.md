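# Methods

## Problem and model

The package classifies tissue samples as primary tumor (+1) or solid
tissue normal (−1) from three jointly measured omics blocks: protein-coding
expression counts, ncRNA expression counts, and CpG methylation beta
values. The design follows a filter-then-wrap hierarchy — cheap
unsupervised dimension reduction first, supervised screening second, a
redundancy-aware compact selection third — and a stacked ensemble whose
meta-learner is trained on the base classifiers' out-of-fold probability
errors.

### Stage 1: CpG-to-gene aggregation

A gene's methylation feature is the arithmetic mean of the beta values of
the probes mapped to it. The probe–gene relation is many-to-many and is
preserved: a probe in the neighbourhood of two genes contributes to both
means. Only probes present in the matrix enter a gene's mean; genes with no
present probe are omitted. No positional weighting (promoter vs body) is
applied — the feature is a plain mean. Because no labels are involved,
aggregation runs once globally before cross-validation; this cannot leak
class information. On a real 450K cohort this step reduces ~485k probe
dimensions to gene scale (tens of thousands); on synthetic cohorts the
output dimension equals the number of genes with at least one present
probe. The index set of the mean is the per-gene probe set: the mean is
taken over the probes related to the gene, not over the whole array.

### Stage 2: fold change + FDR

Fold change is the ratio of tumor to normal group means on the linear
scale. For counts a pseudocount of 1 is added to both means (guards
division by zero and tames low-count ratios); betas use no pseudocount
(they are bounded away from 0 in practice). P-values come from a two-sided
Welch (unequal-variance) two-sample t-test — computed on log2(x+1) for
count features, raw values for betas. The test is a deliberate,
configurable choice (`test="wilcoxon"` switches to Mann–Whitney): the
screening contract only requires *some* reasonable two-sample test, and
Welch is the standard default for heteroscedastic groups. Degenerate
features get p = 1 when both group means agree with zero variance, p = 0
when zero-variance group means differ.

Benjamini–Hochberg is applied per block family — expression types pooled
(protein-coding + ncRNA), beta-scale features separately — because the
|log2FC| gates differ per family; `pooling="global"` pools everything.
Selection uses strict inequalities exactly as printed: |log2FC| > 3 and
q < 0.05 for expression, |log2FC| > 0.5 and q < 0.05 for methylated genes.

In cross-validated runs stage-2 statistics are computed on the learning
partition of each outer fold only. If nothing survives the gates (possible
on null-like data), the pipeline falls back to the n smallest q-values with
a warning rather than failing; this keeps weak-signal benchmarks runnable
and is logged.

### Stage 3: discretized greedy mRMR

Features are discretized to three states by distance from the feature mean
in units of k standard deviations (k = 0.5; population sd, `ddof=1`
available). Boundaries are inclusive toward ±2 (x exactly at x̄ + kδ maps
to 2). A zero-variance feature satisfies both boundary conditions at its
mean; the tie resolves to the uninformative state 0. Discretization
statistics are recorded at fit time and reused to transform held-out
samples.

Mutual information is the plug-in contingency-table estimate in bits with
0·log 0 = 0, clamped at 0 against −1e−16-scale rounding. The labels
{−1, +1} are used directly as a two-letter alphabet.

The selection objective is a set criterion (mean relevance minus mean
pairwise redundancy); exhaustive subset search is intractable, so the
standard greedy incremental realization ("MID") is used: first pick
argmax I(x; y), later picks argmax I(x; y) − (1/|S|) Σ I(x; x_s). Ties
break toward the earlier input column, making the trace deterministic.
The base-2 logarithm is cosmetic — rankings are base-invariant.

The classifiers themselves consume the *continuous* selected features
(log2(x+1) counts, raw betas); discretization exists only to make the MI
estimates well-defined.

### The stacked ensemble

Base learners: RBF-SVM (probability mode, i.e. Platt-style calibration),
decision tree (library defaults), random forest, AdaBoost. Grids: SVM
C ∈ {0.001, 0.01, 0.1} × γ ∈ {1, 10, 100}; RF n_estimators ∈ {50, 100};
AdaBoost fixed at 50. Each grid point is scored by mean accuracy over K
inner validating subsets (K = 5 by default; the inner fold count is a free
parameter of the protocol); ties go to the first point in declared order,
and a grid point whose fit fails scores 0 with a warning instead of
aborting.

The meta dataset has one row per learning-set sample and four columns: the
positive-class probability from each tuned base learner, predicted
out-of-fold (the model that predicts a row never saw it in training). Only
positive-class probabilities are stacked — the complementary probability is
redundant in a two-class problem. The meta-learner is an XGBoost
classifier (n_estimators ∈ {100, 200, 300} by inner-CV accuracy on the
meta dataset, other hyperparameters at library defaults, single-threaded
for reproducibility); boosting on residuals is what lets it model the base
learners' systematic probability errors. For test-fold prediction the base
learners are refit on the entire learning set with their tuned parameters —
the standard stacking completion of the condensed protocol. The decision
threshold is 0.5 and exposed.

### Cross-validation protocol

Outer folds: a plain random partition into F = 10 folds with sizes
differing by at most one (a stratified option exists because normal classes
can be very small). Every outer fold retrains everything label-dependent —
stage 2, stage 3, tuning, stacking — on its learning set only. The pooled
(micro-averaged) confusion matrix over all folds is the primary summary.
The feature-count sweep runs the full nested CV for each n in 5..30 and
picks the smallest n attaining the maximum mean fold accuracy (first-peak
rule). Displayed metrics round half-up to two decimals; full precision is
kept internally.

Feature stability: per-fold selected lists are unioned with overlap
removal; the repetition rate is the mean over folds of the fraction of that
fold's features appearing in ≥ 2 folds (a mean-pairwise-Jaccard alternative
is available by flag); the epigenetic fraction is the share of the union
tagged ncRNA or methylated gene.

## Synthetic data

The generator emulates a TCGA-like two-class cohort at desk scale:

* Defaults: 60 tumor / 20 normal samples (3:1 imbalance), 2000
  protein-coding + 1000 ncRNA features, 500 methylated genes with
  ~3 probes/gene (1 + Poisson(2)) and 20% of probes shared with a second
  gene. Real cohorts are one to two orders of magnitude larger in feature
  dimension; the generator emulates the regime, not the size.
* Counts: gamma-Poisson (negative binomial) with dispersion 0.3 and
  per-feature base means drawn lognormally around 100. Planted features
  (40 pc, 20 nc — roughly 2% per block, a plausible order for strong
  tumor/normal differences) have their tumor mean multiplied by
  2^(±log2FC), signs alternating, with |log2FC| = 4 by default.
* Methylation: probe betas ~ Beta(μφ, (1−μ)φ) with precision φ = 30 around
  the generating gene's class mean. Planted genes (20) alternate
  hypermethylation events (baseline drawn in 0.15–0.45, +Δβ in tumors) and
  hypomethylation events (0.55–0.85, −Δβ), Δβ = 0.3 — the two canonical
  directions of aberrant promoter methylation, each guaranteed to stay
  inside (0, 1). Null genes draw baselines from 0.2–0.8. Probes are
  generated around their gene's mean, so the stage-1 mean is the correct
  recovery operator by construction; a probe shared with a second gene
  dilutes that gene's aggregate slightly, as in real data.
* Everything derives from one integer seed; identical specs give
  bit-identical matrices.

What the generator does **not** model: batch effects, purity/cellularity
gradients, probe-level biases (type I/II chemistry), count library-size
variation, correlated co-regulation beyond the probe–gene structure, and
survival or subtype structure. Passing tests therefore demonstrate the
pipeline's correctness and leakage safety under a clean generative model,
not its clinical performance on real cohorts.

## Numerical and I/O choices

* Quantile normalization uses the sort/mean/unsort construction with
  average ranks interpolated into the reference distribution (tied values
  receive the mean of the tied reference positions). Beta matrices are
  never normalized — they are already bounded ratios.
* Matrix TSVs are written with `%.17g` and parsed with numpy's correctly
  rounded string conversion, so write→read round trips are bit-identical.
* Duplicate patient aliquots with the same sample-type code: the
  lexicographically smallest barcode survives (deterministic; the choice
  is otherwise arbitrary). Cross-assay joining uses patient + sample-type
  code, since aliquot fields differ between assays.
* Missing features are dropped only at 100% missingness; partial
  missingness is mean-imputed (no imputation method is canonical here, and
  the mean is neutral for the downstream group-mean statistics).
* All fold partitions, learners and the meta-learner consume seeds derived
  from one pipeline seed via independent seed-sequence streams; two runs
  with the same config and seed produce identical reports.

## Problem sizes used in checks

The packaged verification runs use the desk-scale defaults above: the
synthetic study evaluates 3500 features × 80 samples with 10 outer and 5
inner folds at n = 10 selected features, which completes in well under a
minute on one core; oracle-equivalence batteries run on matrices of tens
of features. The n = 5..30 sweep is exercised on a reduced range in tests
and available at full range through the CLI.

## Known limitations

* The fallback when stage 2 selects nothing (smallest q-values) is a
  usability choice, not part of the screening contract.
* SVM probabilities come from Platt-style calibration, which is itself fit
  on internal CV; alternative calibrations are out of scope.
* The repetition-rate definition is one of several reasonable choices; the
  Jaccard alternative is provided for comparison.
* No moderated (empirical-Bayes) test statistics, DMR calling, M-value
  transformation, IDAT parsing, or multi-class diagnosis.
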