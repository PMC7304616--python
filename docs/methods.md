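# Methods

## Problem and data model

The package predicts binary odor-descriptor-group membership for chemical
mixtures from unit-resolution electron-ionisation mass spectra. An input
dataset consists of (a) one collapsed mass spectrum per essential oil —
how a chromatographic run is collapsed to one spectrum is upstream of this
package, which accepts the collapsed spectrum as given; (b) a table mapping
each oil to a set of descriptor words and to one of seven essential-oil
families; (c) optionally a word-embedding file in word2vec text format.

Spectra are windowed to integer m/z 50–250 (201 channels; fragments below 50
are dominated by odorless small molecules, high-m/z ions by non-volatile
compounds) and divided by the per-spectrum maximum of the *windowed* vector,
so every row of the model matrix has maximum exactly 1. Non-integer m/z
readings are rounded half-up to unit bins and collisions summed; channels with
no peak are zero (absence of a fragment is informative, and the fixed 201-wide
grid requires a dense matrix). An all-zero windowed spectrum is an error
naming the sample rather than a silent NaN row.

## Descriptor similarity

Binary annotation tables destroy the correlation between near-synonyms, which
rarely co-occur on the same oil. Two similarity backends are provided:

* **Count-vector correlation.** Descriptors occurring on fewer than 2 oils are
  removed (they carry no co-occurrence signal). Each surviving descriptor gets
  a 7-dim vector of raw occurrence counts per oil family, and
  `d(i, j) = 1 − Pearson(v_i, v_j)` ∈ [0, 2]. Counts are used raw, not
  normalised by family size; Pearson is invariant to affine maps of a single
  vector, so only cross-family size imbalance is affected by this choice, and
  raw counts keep the construction faithful to "number of times the descriptor
  appears in each family". A zero-variance vector has undefined correlation;
  it is treated as uninformative (distance 1 to everything, with a warning)
  rather than aborting the run.
* **Word-embedding cosine.** `d(i, j) = 1 − cos(v_i, v_j)`. Descriptors are
  lowercased and trimmed; multi-word descriptors are looked up verbatim and,
  failing that, as the mean of per-token vectors; any missing token raises an
  out-of-vocabulary error listing *all* missing words, so a run never guesses
  silently. Any file in the standard "count dim" text vector format is
  accepted.

## Clustering

UPGMA (unweighted average linkage: inter-cluster distance is the mean over all
cross leaf pairs) is implemented directly — naive O(n³), trivial at n ≈ 40
descriptors — because the package pins down behaviour scipy leaves
unspecified: ties within 1e-9 are broken by merging the pair whose sorted pair
of lexicographically-smallest members is smallest, making dendrograms
reproducible across runs and platforms. Average linkage is reducible, so merge
heights are monotone; a `max` guard absorbs floating-point jitter. Cluster
indices after cutting to k groups are assigned by order of each cluster's
lexicographically smallest member, giving stable downstream column labels.
Tests verify exact agreement with both an exhaustive brute-force
average-linkage oracle and scipy's `linkage(..., "average")` on random
(tie-free) matrices. The full merge history is retained and exported as
Newick with node heights equal to merge distances (branch length = parent
height − child height).

## Group labels

An oil is positive for a descriptor group iff its descriptor set intersects
the group. Oils whose descriptors were all filtered as rare receive an
all-zero row plus a warning — they stay in the matrix to remain aligned with
the spectra. k is a runtime parameter with the supported sweep range 4–8 and
default 5.

## Networks

The autoencoder is 201 → K_M → D_M → K_M → 201 with logistic-sigmoid units in
every layer (the decoder output is sigmoid because inputs lie in [0, 1]).
Cost: mean-over-samples summed-over-channels squared reconstruction error,
plus an L2 penalty (λ/2)ΣW² over weights (not biases), plus β·Σ_j KL(ρ‖ρ̂_j)
where ρ̂_j is the mean activation of encoder hidden unit j over the batch and
KL(ρ‖ρ̂) = ρ log(ρ/ρ̂) + (1−ρ) log((1−ρ)/(1−ρ̂)). The penalty is applied to
both encoder hidden layers (K_M and D_M); ρ̂ is clipped to [1e-10, 1−1e-10]
to keep saturated units finite. Defaults: K_M = 60, D_M = 20, λ = 1e-4,
β = 1, ρ = 0.05. ρ and the exact sparsity formula are package choices (the
standard KL formulation of sparse autoencoders); everything else follows the
tuned values.

The mapping network is D_M → 50 → 15 → k, sigmoid throughout, trained with
mean per-sample Bernoulli cross-entropy summed over groups plus the same L2
penalty. Output probabilities are binarised per group by an argmax over the
(p, 1−p) pair — identical to thresholding at 0.5, with the p = 0.5 tie
resolved to presence. The per-group reading treats groups as independent
presence targets; a joint multiclass softmax would forbid multi-group oils,
which the labeling rule explicitly produces.

**Optimisation.** Both networks train full-batch with Møller's scaled
conjugate gradient: deterministic given the seed, no line searches, and only
cost-decreasing steps are accepted, so logged costs are non-increasing. The
learning rate η parameterises the second-order probe scale (σ₀ = η/1000,
giving Møller's 1e-5 at the default η = 0.01); a plain gradient-descent
optimizer (η = step size) is selectable via config. Weights initialise
uniform ±sqrt(6/(fan_in+fan_out)) from a seeded generator, biases at zero;
the mapping network derives a distinct stream from the same seed so the
composed model is reproducible end to end. 1000 epochs each by default.
Non-finite costs raise a divergence error naming the epoch. Analytic
gradients of both costs are verified against central finite differences at
1e-5 relative tolerance.

## SMOTE

Most (oil, group) cells are negative, which drags a discriminative model
toward all-zero output. Rebalancing follows the DMwR count semantics: with
minority size n_min, `n_syn = n_min · floor(perc_over/100)` synthetic rows are
added — each is `m + u·(nn − m)` for a minority row m, one of its k nearest
minority neighbours nn (k = 5, clamped to n_min − 1 with a warning), and
u ~ U[0, 1] — and `floor(perc_under/100 · n_syn)` majority rows are kept
(seeded sample without replacement when possible, with replacement otherwise).
Both roundings floor; this is the only convention that reproduces printed
counts like ⌊1.2·144⌋ = 172 and ⌊1.2·48⌋ = 57. The minority class is the
smaller one; on ties the class labelled 0 is minority. `perc_over` below 100
is rejected: fractional-minority selection semantics would have to be
invented. Every output row carries an original/synthetic provenance flag.
This sampler is implemented in-package because the count contract (floor
semantics, percentage parameters) is the deliverable; the common Python
rebalancing libraries target balanced-output semantics and cannot express it.

## Evaluation protocols

Rates are pooled over all (sample, group) cells: TP = % of desired-1 cells
predicted 1, TN = % of desired-0 cells predicted 0 (bases sum to n·k, e.g.
96·5 = 480). Pooling matches a single headline TP/TN pair; per-group rates
are also emitted. An empty base yields NaN, never 0.

* **Cross-validation** (default 6-fold): seeded shuffle, contiguous equal
  blocks (96 → 6×16). The autoencoder is retrained inside each fold on the
  training block only — test spectra are never seen during training.
  Stratified folds (round-robin by label pattern) are available behind a
  flag; the default is unstratified. `eval_labels` optionally rescores
  predictions against a different reference (used to score against a
  generator's ground truth).
* **Group sweep**: for each k in 4–8 the dendrogram is re-cut, labels
  re-derived, and the CV repeated.
* **SMOTE experiment**: seeded 60/40 split (58/38 at n = 96); one autoencoder
  trained on the training spectra supplies bottleneck features to both arms;
  per group, the SMOTE arm rebalances training rows only. A per-arm k-fold CV
  on the training rows is recorded for assessment, and both arms are scored
  on the identical untouched test rows (the test set never contains synthetic
  points).

## Synthetic data

The generator plants recoverable structure at the study's scale: 96 oils in 7
families (round-robin), each family a template of 8 Gaussian-shaped peaks
(σ = 1.5 channels) at globally distinct random integer m/z in 55–245 with
uniform(0.2, 1) amplitudes; per-oil peak intensities are multiplied by
lognormal noise (σ = 0.1 by default) plus a uniform(0, 0.01) additive
baseline, then max-normalised. Each oil draws 2–5 descriptors, each draw from
its family's 8-word vocabulary with probability 0.8 and otherwise uniformly
from the other families' words; duplicate draws collapse as sets, keeping the
per-draw off-family probability at exactly 0.2 (a draw-until-distinct scheme
would silently inflate it). Seven oil families map onto 5 descriptor families
by f mod 5. Ground truth marks each oil positive exactly for its primary
descriptor family; descriptor sampling noise sits on top of that, so roughly
half the oils carry at least one off-family word. Consequently the pipeline's
*own* labels are only ~60–65% TP-predictable from spectra, while scoring the
same predictions against ground truth shows the recoverable structure
(≥ 90% TP and TN at default settings, seed 0 — computed by the test suite).
Word names sort by family, so a correctly recovered partition receives the
same canonical cluster numbering as the ground-truth columns.

Toy embeddings place each descriptor family on an orthonormal center
direction scaled by `separation`, plus isotropic unit noise; from separation
≈ 2–3 the within-family cosine distances fall strictly below all cross-family
ones and UPGMA recovers the planted partition exactly.

What the generator does **not** emulate: chemically realistic fragmentation
(peak positions are random, not structural), chromatographic artifacts,
inter-family spectral overlap (real oil families share many fragments), and a
real odor lexicon's semantics. Passing tests therefore demonstrate that the
pipeline recovers structure that is present and identifiable, not that real
spectra are this separable — published accuracies on the original
(undistributed) data are far from ceiling, consistent with much heavier
overlap.

## Experiment sizes and numerical choices

* Unit tests use reduced networks and epoch counts (30–300); the end-to-end
  recovery check runs the full default configuration (96 oils, 1000 + 1000
  epochs, 6 folds), which completes in well under a minute on one CPU.
* The SMOTE-benefit comparison uses a single planted group at ~1:5 imbalance
  (one family of 7 positive) with lognormal spectral noise σ = 1.0 and 300
  training epochs over 10 seeds. The noise level is chosen so class overlap
  is strong enough that minority recall actually suffers without rebalancing;
  in the near-noiseless regime both arms sit at 100% recall and the
  comparison degenerates to ties.
* UPGMA tie tolerance 1e-9; cross-entropy probability clip 1e-12; KL clip
  1e-10; SCG restart every n-parameters iterations and on non-descent
  directions.
* Deterministic seeds everywhere: one global seed derives per-stage and
  per-fold streams via `seed · 1000003 + stream (mod 2³¹)`.

## Known limitations

* The published per-table accuracies cannot be reproduced: the original GC-MS
  matrix and the 4.2 GB pretrained embedding model are not distributed, and
  training there was stochastic. The package instead pins the deterministic,
  checkable parts (count contracts, gradients, clustering) to oracles and
  validates the learning pipeline on planted-structure data.
* One published rebalancing row (a 4-sample minority processed with k = 5
  neighbours at 2000%/50%) is inconsistent with the count contract that
  reproduces every other row; the package clamps k and documents the
  discrepancy rather than emulating unknown behaviour.
* Single spectra per oil are assumed; no chromatographic alignment,
  deconvolution or vendor raw formats (mzML/netCDF).
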