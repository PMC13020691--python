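# Methods

## Problem

Unsupervised analysis of a high-dimensional feature table (the
motivating case is radiomics: hundreds of texture/shape/intensity
features per lesion) usually chains a dimensionality-reduction step
into a clustering step. Both steps carry hyperparameters, and because
there is no ground truth there is no obvious loss to tune them
against. `stabclust` treats the whole chain as one tunable model and
scores hyperparameter combinations by how *reproducible* the resulting
partition is under resampling, balanced against how *compact* the
clusters are.

## The stability statistic

For one hyperparameter combination of a chain:

1. Draw `B` bootstrap resamples of the data (default: 90% of `n`,
   sampled with replacement).
2. Fit the full chain on each resample `b`, then assign a cluster
   label to **every** observation of the original dataset through the
   chain's out-of-sample path, giving a partition `P_b` of the full
   data.
3. The stability score is the mean adjusted Rand index over the `B-1`
   consecutive pairs, `mean_b ARI(P_b, P_{b+1})`.
4. The compactness score is the mean over bootstraps of the
   Davies–Bouldin index of `P_b`, computed on the full data in that
   bootstrap's reduced space (DBI is geometry-dependent, and the
   clustering operates in the reduced space, so that is the space in
   which compactness is meaningful).

Comparing consecutive bootstrap partitions on the full dataset — rather
than on sample intersections or out-of-bag points — keeps every pair
comparable over the same observations and exercises the same
out-of-sample machinery used for the final membership. Bootstraps whose
fit degenerates (a single nonempty cluster, a non-finite embedding, a
fit error) are excluded from both averages and recorded in a failure
flag; a combination with fewer than two valid fits gets an NA score.
Chains that are never stable surface as "not stable" rows, never as
crashes.

## Selection rule

Stability alone is a biased criterion: the coarsest partition (often
two clusters) is usually the most reproducible. The selection is
therefore two-stage: keep the top `k` combinations by mean ARI
(default 5), then choose the lowest mean DBI among them. Ties resolve
by lower DBI, then by grid order, making the selection invariant to
record order. Note a structural corner case: for chains whose only
searched hyperparameter is the cluster count (plain K-means, plain
spectral), a grid of ≤ `k` values makes the ARI stage vacuous and the
selection degenerates to pure min-DBI. This is inherent to the rule,
not an implementation artifact.

In practice, on mixtures with Iris-like geometry (one well-separated
component, two close ones) both the ARI stage and the DBI stage prefer
the 2-cluster merge of the two close components, so the selected
cluster count is 2 rather than 3; the resulting membership is a
coarsening of the truth and still scores a high Cramér's V. The DBI
stage counterbalances the ARI 2-cluster bias only when the latent
components are roughly equidistant.

## Out-of-sample assignment

* **K-means endings** assign new points to the nearest stored centroid
  (squared Euclidean; exact ties go to the smaller label).
* **Spectral endings** have no native out-of-sample map. A k-nearest-
  neighbour surrogate "records" the training partition: a new point
  takes the majority label among its `k` nearest training points in
  the final reduced space (default `k = 5`; ties to the smaller
  label). The affinity graph uses an RBF kernel with bandwidth
  `gamma = 1/n_features` by default — a plain `gamma = 1` collapses to
  an all-zero affinity graph on standardized high-dimensional data
  (pairwise squared distances concentrate near `2p`).
* **t-SNE stages** retain no transform at all, so chains containing
  t-SNE re-embed the union of training and new points jointly with the
  stored hyperparameters and then assign against cluster statistics
  recomputed from the stored training partition. Joint re-embedding is
  the only faithful treatment of a non-parametric embedding; its
  run-to-run inconsistency is a property of t-SNE and is expected to
  make these chains the least stable.
* NMF stages need nonnegative input while upstream z-scoring produces
  negatives; each NMF stage min-max rescales its input to [0, 1]
  column-wise with parameters learned on the training sample (new data
  is clipped into the box).

## Cross-validated membership

Final cluster membership comes from `k`-fold cross-validation
(default 10): each fold's observations are labelled by a chain fitted
on the complement, so no observation is labelled by a model that saw
it. Fold models carry arbitrary label identities, so each fold's
labels are aligned to a reference chain fitted once on all data via
maximum-overlap (Hungarian) matching computed on the fold's training
observations; fold clusters with no reference counterpart receive
fresh ids. Observations of a fold whose fit fails carry the sentinel
label −1 and are dropped pairwise by all metrics.

## Benchmark simulator

Synthetic datasets are mixtures of K = 3 multivariate normals with
parameters derived from Fisher's Iris table (bundled as a package
fixture; public domain). With per-class sample means `mu_k` and grand
mean `mu_bar`, component means are `mu_bar + s (mu_k - mu_bar)`;
covariances are the per-class sample covariances, unscaled; mixing
proportions are 1/3 each. The separation statistic is the mean over
the 4 features and 3 class pairs of `|mu_j - mu_k| / mu_bar`, and `s`
solves it exactly for the target level: 0.10 (small), 0.20 (medium),
0.50 (large). The statistic is linear in `s`, so the 1% calibration
tolerance is met by construction. Notably the unscaled Iris table has
separation 0.5097 under this statistic — the "large" level is
essentially raw Iris geometry, which supports this reading of the
percentage levels. Noise covariates are i.i.d. N(0, 1) and independent
of the component; they are pure distractors, emulating the bulk of
uninformative features in a radiomics table. What the simulator does
*not* emulate: correlated noise, non-Gaussian clusters, heavy tails,
batch effects — so passing benchmarks show robustness to dimensional
dilution of Gaussian structure, not to arbitrary real-data pathology.

## Preprocessing

Mean imputation (column means of observed entries), removal of
zero-variance columns, greedy correlation pruning (a column is dropped
if its absolute Pearson correlation with any earlier kept column
exceeds the threshold, default 0.95), then z-scoring. All statistics
are fitted once and reapplied, so folds and bootstraps share one
feature space. On Iris-derived simulations the filter typically drops
one informative column (petal length and width correlate above 0.95),
which is the intended behaviour of a correlation filter, faithfully
reducing the available signal.

## Evaluation metrics

* **ARI** — chance-corrected partition agreement (permutation model).
* **DBI** — mean over clusters of the worst `(S_i + S_j)/M_ij`;
  Euclidean geometry, arithmetic-mean centroids; NaN for a single
  cluster or coincident centroids; 0 when all clusters are singletons.
* **Cramér's V** — `sqrt((chi2/n)/min(r-1, c-1))`, no bias correction;
  label-permutation invariant, hence usable across clusterings with
  different cluster counts; 0 by convention for a constant side.
* **Interpretability** — 10-fold CV accuracy (%) of an impurity-based
  classification tree predicting cluster membership from the features
  (a generic CART-style learner; depth and seed configurable).
* **Outcome association** — AUROC of a logistic model with cluster
  membership as its only categorical predictor. The saturated MLE
  fitted probability of each observation is its cluster's event rate,
  so the AUROC is computed from those rates in closed form (identical
  by rank equivalence, immune to perfect-separation failures).
* The **effect-size reference bands** classify the distribution of
  off-diagonal inter-pipeline V values: majority < 0.3 "weak",
  majority in [0.3, 0.7] "moderate", majority > 0.7 "strong" — an
  indirect gauge of latent cluster strength when no ground truth
  exists.

## Seeds and determinism

Every stochastic step flows from one seed. Grid combinations get
independent seeds derived from `(search seed, combination index)`;
study conditions hash `(master seed, effect level, noise count,
pipeline)` so runs are order-independent and dropping a condition
leaves the others byte-identical. All derived seeds stay below 2^31.

## Problem sizes

Default study conditions mirror the benchmark factorial: n = 1000
observations, noise counts {0, 4, 20, 40, 60, 80, 140, 200}, three
effect levels, ten chains. The bootstrap count is configurable up to
100; the bundled acceptance script runs 20 bootstraps with 3–5 grid
values per hyperparameter, and the test suite runs n = 300–400 with
8–10 bootstraps and 2–3 grid values, sizes chosen to keep a full run
practical on a single CPU while preserving the method's behaviour.

## Known limitations

* The consecutive-pair ARI prefers coarse partitions, and on mixtures
  where two components are much closer to each other than to the third
  the DBI stage does not rescue the true cluster count (see above).
* t-SNE chains are supported but effectively unusable for stable
  clustering, by design of the underlying embedding.
* DBI values are not comparable across reduced spaces of different
  dimension; the selection rule compares them anyway once the ARI
  stage has shortlisted, which is a known coarseness of the rule.
* Spectral chains scale as O(n²) memory in the affinity matrix;
  n ≳ 10⁴ will be slow.
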