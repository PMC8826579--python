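# Methods

## Pipeline

An *observation* is one plant encounter recorded as a complete series of
feature vectors, one per photographic perspective (node N, inflorescence F,
leaf top LeT, leaf back LeB, ligule side LiS, ligule front LiF). The
pipeline is: species-stratified train/test split → one classifier per
perspective, trained only on that perspective's training vectors → per-
perspective score matrices for the test observations → sum-rule fusion over
a perspective subset → top-1 decision → accuracy statistics, repeated over
all non-empty subsets.

### Splitting

The split is stratified by species with exact per-species counts
(defaults 65 train / 15 test of 80 observations, the balanced design that
makes every per-species accuracy an integer multiple of 1/15 and macro
recall equal to plain accuracy). Ids are sorted within species before the
seeded shuffle, so the split depends only on (ids, seed), not on input
order. Absolute accuracies depend on the split seed; the seed is always
recorded in the run manifest.

### Classifiers and score production

Four families, all via scikit-learn: linear-kernel SVM, random forest,
k-nearest-neighbors and Gaussian naive Bayes. Feature standardization
(zero mean, unit variance, fitted on the training split only) is applied
for the margin/distance methods (SVM, KNN); the tree and Bayes models get
raw features.

Fusion needs probability-like scores. Families with native class
probabilities use them directly: random-forest `predict_proba` (the average
of per-tree class probabilities — scikit-learn's soft version of vote
fractions), naive-Bayes posteriors, and KNN neighbor-vote fractions. The
linear SVM's one-vs-rest multiclass decision values are mapped through a
softmax at temperature 1: deterministic, fit-free, and it satisfies the
row-sum-to-one contract. Rows are re-normalized defensively and validated
to 1e-9.

### Hyperparameter tuning

Bootstrap resampling, 25 iterations by default: for each candidate setting
the training set is resampled with replacement, the model fitted on the
resample and scored on the out-of-bag observations; resamples with an empty
out-of-bag set are redrawn; the same resamples are reused across settings
(paired comparison). The setting with the best mean out-of-bag accuracy
wins, ties going to the earlier grid position. A single-element grid
short-circuits the resampling entirely. A setting that cannot be fitted
(e.g. more neighbors than resample points) scores 0 and logs a warning.

Default grids hold ten settings per family: SVM cost `C` log-spaced over
[1e-3, 1e2]; random-forest features-per-split, ten integers spanning
[1, dim]; KNN neighbor counts 1, 3, …, 19 (uniform weights); naive-Bayes
variance smoothing log-spaced over [1e-12, 1e-3]. These are standard ranges,
not a reproduction of any particular framework's defaults. Whether tuning
should share hyperparameters across perspectives is an open design point;
here each perspective is tuned independently, with a per-perspective seed
derived as `base seed + perspective index` so results do not depend on the
order in which perspectives are processed.

### Fusion and decisions

The fused score over subset `P` is the unweighted arithmetic mean of the
member score rows (normalized sum rule); no weighted, product, max or
vote-level fusion is provided. Ties in the top-1 argmax are broken by the
smallest species index (deterministic; exact float ties essentially occur
only in hand-built fixtures) and logged at debug level. Missing
perspectives are a hard error by default; with `allow_incomplete` the mean
is taken over the perspectives available per observation, a documented
deviation for incomplete user data.

Subset ids are rendered in the member order of the subset, which for the
canonical experiment order N, F, LeT, LeB, LiS, LiF yields the familiar
underscore names (e.g. `N_F_LeB_LiF`).

### Evaluation

Confusion matrices are indexed by the dataset's species order (reference in
rows, prediction in columns). Per-species accuracy is the diagonal over the
row sum, in percent; macro recall is its unweighted mean; relative accuracy
divides by the maximum species accuracy (undefined, and an error, when all
accuracies are zero). Species with no reference observations are excluded
from the per-species map and the macro mean. Human-readable summaries round
to one decimal; machine outputs and the best-subset selection use full
precision, so rounding never changes which subset wins. Best-subset ties
break lexicographically on subset id. Accuracy is *not* assumed monotone in
subset size — the report must be able to show a smaller subset beating a
larger one, which real data does produce.

## Synthetic data generator

The simulator emulates the two structural facts the analysis rests on:
perspectives differ in how much species signal they carry, and the several
views of one plant are correlated because they show the same individual.

Model: species-perspective centroid `mu[k,p] = delta_p * z[k,p]`,
`z[k,p] ~ N(0, I_d)`; observation `i` of species `k` has a shared latent
`u_i ~ N(0, I_d)`; the feature is
`x[i,p] = mu[k,p] + sigma * (sqrt(rho) * u_i + sqrt(1-rho) * eps[i,p])`
with private noise `eps[i,p] ~ N(0, I_d)`.

Parameters (defaults in parentheses):

* `n_species` (31), `n_per_species` (80) — the study-scale design;
* `perspectives` — the six canonical codes;
* `dim` (64) — embedding dimension, dimensionless coordinates;
* `discriminability` `delta_p` — centroid-separation scale per perspective;
  defaults F:2.0, LiF:1.5, LiS:1.2, N:1.0, LeB:0.9, LeT:0.8, reproducing
  the observed informativeness ordering (inflorescence strongest, ligule
  front next, leaf surfaces weakest);
* `noise_sd` `sigma` (1.0) — within-class noise scale;
* `view_correlation` `rho` (0.3) — fraction of noise variance shared across
  an observation's views; 0.3 is a moderate same-individual dependence;
* `seed` — one seeded generator draws all centroids, then all shared
  latents, then all private noise, species-major, so identical configs give
  bit-identical data on any platform.

Centroids are drawn independently per (species, perspective): this keeps
per-perspective informativeness controlled by `delta_p` alone. A single
scalar `rho` for all view pairs is the simplest structure inducing within-
observation dependence. Observation ids are `obs_<species>_<replicate>`
with zero-padded indices — deterministic and sortable.

What the generator does *not* model: image content, CNN embedding geometry,
extractor-specific effects (different pretrained networks producing
systematically different feature quality), photographer or device effects,
class imbalance, or heavy-tailed noise. Passing tests therefore show that
the pipeline's algebra, contracts and ranking behavior are correct under a
controlled Gaussian world — not that any particular accuracy level will be
reached on real images.

## Numerical and design choices

* Score rows validated to sum to 1 within 1e-9; fusion exactness asserted to
  the same tolerance.
* KNN neighbor-vote and argmax ties resolve to the smallest species index —
  fixed so the hand-built fixtures are deterministic.
* Random-forest fits use 100 trees with a fixed `random_state`; any
  nondeterministic option in the underlying fits is pinned, so a fixed
  (dataset, spec, seed) triple reproduces chosen settings and score matrices
  exactly.
* The toy fixture (3 species × 4 observations × 2 perspectives, dim 2) is
  hard-coded: perspective P1 has three well-separated clusters (linearly
  separable), P2 repeats the same four points for every species (exactly
  zero signal). Exact-value tests across modules are built on it.
* Problem sizes in the test suite and acceptance study (10 species × 80
  observations × dim 16 for the ranking study; 5 species × 80 for the
  chance floor) were chosen as the smallest designs at which the studied
  effects are comfortably resolved over 10 seeds.

## Known limitations

* Score calibration across families is heuristic (softmax for SVM margins);
  mixing families across perspectives in one fusion is possible through the
  API but the scores are then not calibrated against each other.
* With `allow_incomplete`, per-observation subset means change the effective
  `|P|` per row; accuracies across observations then average over different
  evidence amounts.
* The simulator's equal-covariance Gaussian classes favor the linear SVM and
  naive Bayes; relative family rankings on synthetic data should not be
  read as predictions for real embeddings.
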