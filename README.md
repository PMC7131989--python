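# cvbench

Benchmark comparisons of classification and feature-selection algorithms on
tabular biomedical data, with fully transparent, tidy outputs.

Choosing a classification algorithm — and its hyperparameters, and how many
features to keep — has a large effect on predictive accuracy in biomedical
applications (diagnosis, treatment response, survival).  Doing such
comparisons ad hoc invites subtle biases, the worst of which is *leakage*:
letting validation samples influence preprocessing statistics, feature
rankings, or model selection.  cvbench is a benchmarking engine for
researchers who want to compare many algorithms on a dataset under a single,
leakage-free evaluation protocol, and to see every decision the protocol
made.

## What it computes

**Resampling.**  Monte Carlo cross-validation (repeated stratified random
splits at a training fraction, default 2/3) or stratified k-fold
cross-validation.  For model selection, *nested* cross-validation: inner
Monte Carlo splits of each outer training set score the candidate options —
either an algorithm's hyperparameter combinations, or the number *c* of
top-ranked features from a grid (default 1, 3, 5, 10, 15, 20, 50, 200) — and
the option with the best mean inner score (default metric: AUROC) is
retrained on the full outer training set and evaluated on the outer
validation set.  Outer validation samples never enter any fitting step.

**Preprocessing** (fitted on training partitions only): median/mode
imputation, one-hot encoding, and robust scaling x ↦ (x − median)/IQR.

**Metrics.**  Fifteen per cell: AUROC (Mann–Whitney identity, ties half
credit), accuracy, balanced accuracy, Brier score, F1, FDR, FNR, FPR,
Matthews correlation coefficient, mean misclassification error, NPV, PPV,
recall, TNR, TPR.  Multiclass problems are scored one-vs-rest per class and
macro-averaged.

**Feature-rank aggregation.**  Per-fold rankings are combined by Borda
count: in a ranking of F features, position r earns F − r points; features
are ordered by total points (equivalently, ascending mean rank).

**Algorithms.**  12 classifiers and 10 rankers over scikit-learn and
xgboost, spanning linear, kernel, tree, ensemble, Bayesian, distance-based
and neural families, each with declarative hyperparameter combinations
(YAML, one file per algorithm).  New adapters plug in through
`register_classifier` / `register_ranker`.

**Inputs.**  `.tsv`, `.csv`, ARFF, the transposed dialects `.ttsv`/`.tcsv`,
any of them gzipped; multiple files are merged on shared sample
identifiers.  The tokens `?`, `NA` and the empty string are treated as
missing.

## Worked example

Simulate a dataset with 3 informative features (class mean shift of 2 SD)
among 10 numeric + 2 categorical features, then benchmark logistic
regression with nested feature selection:

```bash
cvbench simulate --out signal.tsv --samples 200 --numeric 10 --categorical 2 \
    --informative 3 --effect-size 2 --seed 11
cvbench run nested_featureselection --data signal.tsv --output-dir results \
    --iterations 3 --inner-iterations 3 \
    --classifiers sklearn/logistic_regression --rankers sklearn/anova \
    --num-features 1,3,5,10 --seed 11 --description example
```

`results/` then contains five tab-delimited files: `predictions.tsv` (per-
sample class probabilities), `metrics.tsv` (tidy, one metric per row),
`nested.tsv` (every option scored on every inner fold, with the chosen one
flagged), `feature_ranks.tsv` (Borda-aggregated ranks per outer iteration),
and `log.txt` (arguments, seed, per-cell wall times).  The outer AUROC rows
of `metrics.tsv`:

```
iteration  algorithm                    feature_count  value
0          sklearn/logistic_regression  3              0.990143
1          sklearn/logistic_regression  3              1.000000
2          sklearn/logistic_regression  10             1.000000
```

Nested selection picked 3 features in two of three outer iterations — the
true number planted — and the held-out AUROC is near 1, as expected for an
effect size of 2.  The top of `feature_ranks.tsv` for iteration 0:

```
feature  borda_points  mean_rank  final_rank
num_3    44            1.333333   1
num_2    43            1.666667   2
num_1    39            3.000000   3
num_7    36            4.000000   4
```

The three planted features (`num_1`–`num_3`) occupy the top three aggregate
ranks.  On a *null* dataset (labels independent of features) the same
pipeline scores at chance — AUROC ≈ 0.5 — in every mode; that is the
package's primary self-check.

The same runs are available from Python (`cvbench.run_basic`,
`cvbench.run_nested`, `cvbench.write_all`); the command line is a thin layer
over those functions.

## Limits

Datasets must fit in memory.  The engine wraps existing learning
implementations; it does not implement any classifier or ranker itself.
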