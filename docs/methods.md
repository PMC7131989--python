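# Methods

## Evaluation protocol

A benchmark run is defined by a dataset, a set of algorithms, and a plan
(scheme, counts, training fraction, feature-count grid, selection metric,
seed).  The outer resampling scheme is either Monte Carlo cross-validation —
`outer_count` independent stratified random splits, training fraction
`train_fraction` (default 2/3) — or stratified k-fold, where the k
validation sets partition the samples and fold sizes differ by at most one.
Stratification is exact to rounding: per-class training quotas use
largest-remainder rounding of `train_fraction · n_class`, and every class is
forced to appear on both sides of every split.  k-fold distributes each
class's shuffled members over the folds in near-equal blocks, rotating which
folds receive the extra member across classes so overall sizes stay
balanced.  Stratification is a deliberate choice: it protects small classes
and stabilizes the one-vs-rest metrics.

Nested selection re-applies the Monte Carlo scheme (`nested_count`
iterations, same training fraction) *inside* each outer training partition,
for both outer schemes — inner splitting is a selection device, not an
estimate, so a single scheme keeps the code and the seed derivation uniform.
Candidate options are scored on each inner validation set with the full
metric suite; the option with the best **mean** selection metric across
inner iterations wins.  "Best" respects metric orientation (Brier, MMCE,
FDR, FNR, FPR are minimized; everything else maximized).  Ties break toward
the earlier hyperparameter combination in registry order (so the default
wins ties) and toward the smaller feature count (parsimony).  The winning
option is retrained on the full outer training partition.

Leakage control: preprocessing parameters, feature rankings and selection
decisions are computed only from (subsets of) the training partition at
hand.  The inner sample identifiers of an iteration are, by construction,
a subset of its outer training identifiers; tests assert this on the actual
id sets.

## Preprocessing

Three independent steps, fitted on a training partition and applied
unchanged elsewhere, in the order impute → encode → scale:

* **Imputation**: missing numeric cells get the training median; missing
  categorical cells get the training mode (ties broken toward the
  earliest-seen value).
* **One-hot encoding**: a categorical feature with k training-observed
  levels becomes k indicators named `feature=level`, in order of first
  appearance; a level seen only at apply time yields all-zero indicators, so
  the feature space is fixed by the training partition.
* **Robust scaling**: x ↦ (x − median)/IQR, with the IQR computed as the
  linear-interpolation 75th minus 25th percentile (the convention matters:
  other quantile rules give different IQRs; this one matches
  `numpy.percentile`'s default and scikit-learn's `RobustScaler`).  A
  constant column (IQR = 0) is centered and divided by 1 rather than
  dropped, keeping feature counts stable across folds.

Whether to fit preprocessing per training partition or once globally is a
genuine design fork; per-partition fitting was chosen because the engine's
purpose is unbiased benchmarking, and global fitting would leak validation
statistics into the transform.

## Metrics

AUROC is computed by the rank-sum (Mann–Whitney) identity with average ranks,
so ties earn half credit; it equals the brute-force pairwise proportion to
1e−12 and is undefined (NaN, written as `NA`) when the truth is
single-class.  The thirteen confusion-derived metrics follow their textbook
formulas; any 0/0 ratio is reported as 0 so output files stay rectangular.
For binary problems the positive class is the lexicographically second
level (overridable); for ≥3 classes every metric is computed one-vs-rest
per class — using that class's probability column for AUROC and Brier — and
averaged with equal class weights (macro).  Unweighted averaging is a
choice; per-class AUROCs that are undefined are dropped from their average
rather than poisoning it.

Discrete predictions are the argmax of the probability vector; exact ties go
to the earlier class level in sorted order.  Adapters that emit only class
labels are wrapped to one-hot probability vectors, which makes their Brier
and AUROC values legitimate if coarse.

## Borda aggregation

In a ranking of F features the feature at 1-based position r earns F − r
points; totals are summed across rankings and ties in total points break by
feature name.  With full permutations this ordering provably equals
ascending mean rank (both are affine in the rank sum), which the suite
checks on random instances.  The output also reports the mean raw rank
per feature, the quantity most readers want to see.

## Determinism and seeds

Every random choice flows from the plan seed through
`numpy.random.SeedSequence` keyed by purpose (outer splits, inner splits,
per-cell training, ranking), iteration, and a CRC of the algorithm id.
Consequently (i) a whole run is reproducible from (dataset, plan, seed) —
the data files are byte-identical across re-runs — and (ii) the seed a cell's
final training uses does not depend on whether nested selection happened, so
a nested run whose search space has exactly one option reproduces the basic
run bit-for-bit.  The log file records wall-clock times and is excluded from
the byte-reproducibility guarantee.

Derived seeds are reduced modulo 2³¹ for back-end compatibility.

## Synthetic data

`generate_null` emulates a signal-free sanity-check cohort: 500 samples, 20
standard-normal numeric features, 10 categorical features (3 uniform levels
each — a convention, as is the 0.5 class balance), binary labels drawn
independently of every feature.  Any leakage-free pipeline must score at
chance on it; the suite requires every per-algorithm median AUROC over 5
Monte Carlo iterations to lie within ±0.08 of 0.5 in all three run modes,
a band reflecting the sampling noise of a median of 5 AUROCs on ~167
validation samples.  `generate_signal` additionally shifts the
class-conditional mean of the first `informative_features` numeric columns
by `effect_size` standard deviations and returns the ground-truth feature
names, supporting recovery tests (rankers must place the planted features at
the top; feature-count selection must choose a small subset).

What the simulations do **not** emulate: correlated features, non-Gaussian
or heavy-tailed measurements, label noise, class imbalance beyond the
balance parameter, and interactions detectable only multivariately.  Passing
the null and recovery suites therefore demonstrates protocol correctness —
no leakage, working selection machinery — not expected accuracy on real
biomedical data.

## Problem sizes in the test suite

The end-to-end suites use the 500-sample simulation for the chance-level and
signal-recovery checks (20 seeded repetitions for recovery), 1,000 random
instances for the metric and Borda oracles, 100 random plans for the
partition properties, and 200 random small tables for I/O round-trips.
These sizes give stable pass/fail behavior at desk scale; all were chosen as
the smallest sizes at which the statistical assertions are comfortably
separated from their thresholds.

## Known limitations

* Joint hyperparameter × feature-count search is not performed by default;
  nested feature selection runs classifiers at default hyperparameters.
* The ARFF dialect support covers numeric and nominal attributes, `?`
  missing values, quoting and comments — not date/relational attributes or
  sparse ARFF.
* Hyperparameter grids are curated functional sets, small enough to search
  at desk scale; they are not exhaustive tuning spaces.
* Inner selection uses the mean across inner folds; a median would be more
  robust to one degenerate fold but discards information at the default of
  3 inner iterations.
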