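# triostack

Tumor/normal diagnosis from integrated triple-omics data: protein-coding
gene expression, non-coding RNA expression and CpG methylation, combined
into one sample-aligned dataset, reduced by a three-stage hierarchical
feature selection, and classified by a probability-stacking ensemble of
four heterogeneous learners with a gradient-boosted meta-learner. It is
aimed at computational-biology practitioners who work with TCGA-style
cohorts (HTSeq count matrices, 450K beta-value matrices, barcoded samples)
and want a tested, reproducible, leakage-safe reference pipeline.

## The method

**Data integration.** Expression matrices (counts) and a CpG-probe beta
matrix (β = M/(M+U) ∈ [0,1]) are restricted to primary-tumor ("01", label
+1) and solid-tissue-normal ("11", label −1) samples, cleaned (duplicate
features collapsed, fully missing features dropped, partial missingness
mean-imputed, expression quantile-normalized across samples) and joined on
patient-level sample IDs.

**Stage 1 — CpG aggregation.** Each methylated-gene feature is the
arithmetic mean of the betas of all probes mapped to that gene,
MG<sub>g</sub> = (1/P<sub>g</sub>) Σ<sub>i∈probes(g)</sub> β<sub>i</sub>,
with the many-to-many probe–gene relation preserved (a shared probe
contributes to every gene it maps to). This is unsupervised and collapses
probe-scale data to gene scale before any cross-validation split.

**Stage 2 — fold change and FDR.** Per feature, FC = mean(tumor)/mean(normal)
(pseudocount 1 for counts) and a two-sided Welch t-test p-value
(on log2(x+1) for counts, raw betas otherwise), corrected by
Benjamini–Hochberg. A feature survives iff |log2FC| > 3 (expression) or
|log2FC| > 0.5 (methylated genes), and q < 0.05.

**Stage 3 — discretized mRMR.** Each surviving feature is discretized to
{−2, 0, 2} by x ≥ x̄ + kδ → 2, x ≤ x̄ − kδ → −2, else 0, with k = 0.5 and δ
the population standard deviation. Greedy mRMR then picks n features: the
first maximizes relevance I(x; y) (plug-in mutual information, bits), each
next pick maximizes I(x; y) − (1/|S|) Σ<sub>s∈S</sub> I(x; x<sub>s</sub>).

**Stacked ensemble.** An RBF-SVM (C ∈ {0.001, 0.01, 0.1},
γ ∈ {1, 10, 100}), a decision tree, a random forest (n_estimators ∈
{50, 100}) and AdaBoost (50 estimators) are grid-tuned on K = 5 inner
subsets of each learning set. Their out-of-fold positive-class
probabilities form a 4-column meta dataset joined with the true labels; an
XGBoost classifier (n_estimators ∈ {100, 200, 300} by inner CV) learns the
base learners' probability errors from it. Prediction: tuned base learners
refit on the full learning set produce four probabilities, the meta-learner
maps them to one, label = +1 iff p ≥ 0.5.

**Evaluation.** 10-fold outer CV (every sample predicted exactly once; all
selection and tuning redone inside each fold on the learning set only), a
pooled confusion matrix, accuracy/sensitivity/specificity/F1 as
percentages, an n = 5..30 sweep with first-peak selection, and per-fold
feature-stability reporting (union, category proportions, repetition rate).

A synthetic-data module generates cohorts with planted ground truth
(negative-binomial counts with planted log2 fold changes, Beta-distributed
probe methylation with planted gene-level mean shifts, many-to-many
probe–gene maps) so the whole pipeline is testable without downloads.

## Worked example

```python
from triostack import (SyntheticSpec, simulate_triple, make_probe_gene_map,
                       aggregate_cpg_to_genes, build_design, run_nested_cv)

spec = SyntheticSpec(seed=1)          # 60 tumor / 20 normal, planted effects
dataset, truth = simulate_triple(spec)
dataset = dataset.with_meth(
    aggregate_cpg_to_genes(dataset.meth, make_probe_gene_map(spec)))
design = build_design(dataset)        # 80 samples x 3500 features
result = run_nested_cv(design, n_features=10, n_outer=10, n_inner=5, seed=1)
print(result.pooled_confusion)
print(result.pooled.rounded())
print(round(result.features.repetition_rate, 1), result.features.category_counts)
```

prints

```
ConfusionMatrix(tp=57, tn=20, fp=0, fn=3)
{'accuracy': 96.25, 'sensitivity': 95.0, 'specificity': 100.0, 'f1': 97.44}
82.0 {'protein_coding': 20, 'methylated_gene': 16, 'ncRNA': 7}
```

i.e. pooled over the ten held-out folds the pipeline misses 3 of 60 tumors
and no normals (96.25% accuracy, perfect specificity), and 82% of each
fold's ten selected features recur in other folds, with all three omics
categories represented in the union.

The same flow from the shell:

```bash
triostack simulate --out fixture/ --seed 1
triostack run --config config.yaml --out reports/
triostack metrics confusion.json
```

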