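# Methods

## Model and assumptions

The adjustment assumes additive, batch-constant structure on (log-scale)
expression: all samples of one measurement round share an unknown per-gene
offset, and the biologically meaningful variation of the training
population is concentrated in a low-dimensional linear subspace. The
training set is centered gene-wise and decomposed by SVD; the leading `k`
right singular vectors define that subspace. A test batch is centered with
the *training* means, projected onto the same basis, and translated so the
mean of its reference samples coincides, per dimension, with the mean of
the training reference samples. Reconstruction back to gene space discards
everything orthogonal to the basis — both the out-of-subspace part of the
batch offset and out-of-subspace noise — so classifiers are fitted on the
rank-k training reconstruction `Xᵏ` and applied to the adjusted test
reconstruction `Zᵏ`, keeping the two representations comparable.

Consequences worth knowing:

- The alignment of compressed reference means is exact by construction
  (enforced to 1e-8 in validation), regardless of how well the model fits.
- Any batch shift that lies in gene space (a constant added to every
  sample) is removed exactly when references are shared samples; shifts
  orthogonal to the retained basis are removed by truncation.
- The observed training references anchor the alignment, so their own
  measurement noise is transferred to the test set. Because the basis is
  fitted to the training rows, training-sample noise lies almost entirely
  inside the retained subspace: with very few training references and many
  more genes than samples this noise floor is the dominant adjustment
  error. This is inherent to the estimator, not a numerical artifact, and
  is why the training-side reference count is fixed by the protocol while
  test-side references may be varied freely (see the sweep below).

## Parameters

- `loss` (fraction, default 0.10): maximum training variance discarded when
  choosing `k`; `k` is the smallest value with cumulative squared singular
  value fraction ≥ 1 − loss. Variance is measured by squared singular
  values of the centered matrix; the `m` vs `m−1` normalization cancels in
  the ratio. `k` may instead be fixed explicitly.
- Rank handling: singular values below `1e-10 × s_max` are dropped before
  selection (centering always removes one rank; directions at that level
  are noise). A training matrix with all rows identical is rejected.
- Sign convention: each basis column is flipped so its largest-magnitude
  entry is positive, making fits bit-reproducible.
- Gene matching between model and test set is by label with reordering;
  a missing or extra gene is an error — silent subsetting or imputation
  would corrupt the projection.

## Evaluation protocol

Each dataset of a collection serves in turn as the fixed training set:
training references (default 3) are drawn once from a designated biological
group (default: lexicographically first group label); the `n_top_genes`
(default 500) genes with the largest |pooled-variance two-sample t| are
selected (ties broken by gene id; zero-variance genes rank last); the
training set is normalized; and the classifier is tuned by repeated
stratified cross-validation (default 3 × 10; folds reduced to the minority
class size with a warning when necessary) maximizing the MCC, with ties
going to the simplest grid point. The t statistic is a deliberate plain
replacement for moderated variants: at 500 selected genes the rankings are
near-identical in the simulated regime, and the ranking function is
pluggable. Per test set and iteration (default 10), test references are
redrawn, the test set is normalized (reference-based methods use only the
references; batchwise methods use all test samples, references included,
with each matrix as one batch), references are removed, and the MCC is
computed on the rest. Scores aggregate as median over iterations → mean
over test sets → mean over training sets. The MCC uses the convention that
a degenerate confusion table (any zero marginal) scores 0.

Determinism: every random draw descends from one seed through per-(train,
test, iteration) derived streams, so results are independent of execution
order and any pair can be reproduced in isolation.

The reference-count sweep varies the *test-side* reference count only. The
training-side references are drawn once per training set and belong to the
fixed trained pipeline; sweeping them too would conflate the question the
sweep asks (how many references must a new batch include?) with retraining,
and in the synthetic conditions a single training reference's in-basis
noise displaces every test sample by more than the class separation,
collapsing the score — an estimator property, not a protocol insight.

## Synthetic data

The generator emulates a cross-study microarray collection: shared per-gene
baselines `μ_g ~ N(7, 2²)` (log2-intensity scale), two equal groups with a
one-directional effect on a minority of informative genes, per-dataset
additive offsets `β ~ N(0, batch_shift_sd²)` and optional multiplicative
factors `exp(γ), γ ~ N(0, batch_scale_sd²)`, plus i.i.d. Gaussian noise —
the location/scale batch model. Defaults: 4 datasets, 25 samples per group,
2000 genes with 100 informative, effect 2, shift sd 2, scale sd 0, noise
sd 1. All latent draws are recorded and returned by `holdout_truth` for
oracle-based tests. Not emulated: gene–gene correlation, probe-level
artifacts, heteroscedastic noise, unequal dataset sizes, dataset-specific
class imbalance. Passing tests therefore demonstrate correct mechanics and
the qualitative batch-rescue phenomenon under the assumed model, not
performance on real arrays.

## Problem sizes and numerical choices

Validation and the acceptance computations run at the generator defaults
above (each cross-study run is 4 training sets × 3 test sets × 10
iterations) and use 200 random training/test pairs up to 50 × 200 for the
algebra checks; these sizes make the full suite complete in well under a
minute per heavy check. Tolerances: basis orthonormality and alignment
1e-8; reconstruction against the eigendecomposition oracle 1e-6 relative
Frobenius; `select_k` uses a 1e-12 slack so `loss = 0` is reachable despite
cumulative-sum rounding. Batchwise ratio scaling and standardization reject
exactly-zero means/variances rather than guessing a pseudocount.

## Known limitations

- Binary groups only in the evaluation protocol (the adjustment itself is
  label-free).
- The adjustment corrects location in the retained subspace; multiplicative
  batch distortions are only absorbed insofar as they project onto it.
- Reference samples should be biologically exchangeable between batches;
  the protocol draws them at random from one group, which is a lower bound
  on what dedicated control samples would achieve.
- ComBat, FAbatch and frozen-SVA style corrections are not reimplemented;
  the normalizer registry accepts external implementations through the
  two-phase fit/transform contract.
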