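# Methods

This note records the statistical model behind `qab`, the parameter
defaults and why they were chosen, the numerical conventions, and the known
limitations. It documents design choices; every empirical statement below
is one the test suite or `scripts/acceptance.py` computes.

## Problem setting

Each molecule is a P-dimensional binary fingerprint x (P = 128 by default)
with a target-specific activity y = G(x) + ε on the pIC50 scale, where G is
the unknown structure–activity relationship and ε is experimental error.
Public IC50 collections are high-dimensional, clustered in chemical space,
and have low signal-to-noise; the question the framework answers is not
"how well does a model interpolate?" but "how well does it extrapolate into
the high-activity region it has never seen?". Multi-objective (multi-target)
regression is out of scope; each dataset is analysed independently.

## Data curation

Raw IC50 exports are filtered to measurements with unit nM, relation '=',
target type SINGLE PROTEIN and organism Homo sapiens (case-insensitive
after trimming — exports vary in casing; records with missing value or unit
are dropped and counted rather than raising, since curation is a cleaning
step). Values convert to pIC50 = −log10(IC50 in molar), i.e.
9 − log10(IC50/nM): converting to molar before the log is the universal
QSAR convention, and because it only shifts activities by a constant it
leaves every rank and every quantile split unchanged. Replicate
measurements of one molecule are averaged on the pIC50 (log) scale; the
alternative — averaging nM values then converting — differs for
heteroscedastic replicates and is not used.

## Fingerprints

Structures are standardized by keeping the largest fragment that contains
at least one carbon atom ("organic" is deliberately defined by this
simplest testable rule); counterion-only or unparseable entries are dropped
with a logged reason. Fingerprints are hashed binary Morgan/circular
fingerprints, radius 2, 128 bits, computed with RDKit. Exact bit patterns
differ across toolkit generations; nothing downstream depends on specific
bits, only on the binary matrix contract.

## Resampling schemes

* **Quantile-activity bootstrap.** After a stable ascending sort on
  activity, the first N_q = ⌊Nq⌋ positions form the training pool and the
  rest the fixed test set. Molecules tied exactly at the boundary activity
  are assigned by sorted index — the split is defined by index, not by
  value comparison — so set sizes are exact; a warning flags boundary ties.
  Each iteration draws N_q training indices with replacement from the pool.
  N_q < 2 or N − N_q < 2 is rejected as degenerate.
* **Standard bootstrap** (q = 1): N draws with replacement, testing
  out-of-bag; empty-OOB draws are redrawn (probability N!/N^N, negligible
  for N ≥ 5) rather than producing undefined losses.
* **5-fold cross-validation** for the conventional comparison; active-rank
  losses are computed within each fold's test set (ranks are only defined
  within a test set) and averaged.

Each iteration gets an independent RNG stream spawned from (seed,
iteration), so runs are reproducible per-iteration and order-independent.
Draws serialize to JSON-lines for exact reruns.

## Active sets and losses

The active set defaults to the top ⌈f·N_test⌉ test molecules by *true*
activity with f ∈ {0.10, 0.05, 0.01} — the ceiling guarantees "1% of the
test data" names at least one molecule. A whole-dataset quantile mode
(N_γ = ⌊N(1−γ)⌋ actives taken from the top of the full activity
distribution) is available as an option; the test-fraction mode is the one
used for all reported comparisons. Ties in true activity at the threshold
are resolved by stable sort order (flagged with a warning) so the active
count is exact.

Predicted ranks run from 0 (highest predicted activity) to N_test − 1.
Ties in predicted activity are broken uniformly at random under a seeded
RNG: deterministic index-based tie-breaking would leak the data ordering
and bias constant-prediction models toward loss 0 or 1, whereas random
tie-breaking makes a constant model equivalent to a random ranker in
expectation.

`loss_sum` uses the denominator N_γ(N_test − N_γ) by default. This is the
unique normalization under which the loss spans [0, 1] and degenerates to
`loss_min` when N_γ = 1 (both endpoints verified exhaustively in the test
suite). An `as_printed` variant with denominator N_γ(N_test − N_γ − 1) is
retained behind a flag; its maximum is (N_test − N_γ)/(N_test − N_γ − 1) > 1.

## Summary statistics

The A replicate losses per model are summarized by their mean; a delete-one
jackknife standard error of that mean (which reduces algebraically to
s/√A — asserted to 1e−12 in tests); and a 95% percentile interval
(2.5th–97.5th percentiles, numpy's linear interpolation rule) rather than a
normal approximation, since rank losses at small N_γ are far from Gaussian.
The probability of optimality is computed per iteration — the fraction of
paired draws on which a model attains the strictly lowest loss, ties split
equally among the argmin set — because it uses the full bootstrap
distribution and is exactly reproducible; it is invariant to any monotone
transform applied to all models' losses at an iteration. Iterations with a
failed model fit are dropped complete-case to keep the pairing valid.
Total model scores sum the per-dataset probabilities, treating datasets as
independent.

## Model zoo

Fixed hyperparameters, no tuning (tuning would introduce optimization bias
into the very comparison the framework is meant to protect): linear-kernel
SVR at library defaults; random forest with 100 trees and maximum depth 10;
ridge with α = 0.1; and a dense network — inputs standardized by training
mean/sd, hidden layers of 128 and 16 relu units, linear output — trained
with the squared-error objective by Adam at the default rate, 100 epochs,
batch size 32, fixed seed. The network's training regimen is a
conventional choice exposed in `qab.models.DEEP_NET_TRAINING` rather than a
claim of optimality. The zoo is a thin adapter over scikit-learn
(`SVR`, `RandomForestRegressor`, `Ridge`, `MLPRegressor` in a
`StandardScaler` pipeline); its tests are contract tests (closed-form ridge
solution, prediction-range bound for forests, seeded reproducibility), not
reimplementations of the learners.

A structural property used throughout: a random forest's prediction is an
average of training-leaf means, so it can never exceed the maximum training
activity. Under a quantile split its error on the potent test molecules is
therefore pure bias — one reason MSE mis-scores forests in the
extrapolation setting while rank losses do not.

## Similarity diagnostics

The Tanimoto coefficient |x₁∩x₂|/|x₁∪x₂| is a similarity; 1 − Tanimoto
(the Jaccard distance, a metric) is used wherever a distance is required.
Two all-zero fingerprints would give 0/0; they are rejected at matrix
construction since no valid molecule maps to the empty substructure set.
Two-medoids clustering is classic PAM: a greedy BUILD initialization
followed by best-improvement SWAP exchanges until the total distance to the
nearest medoid stops decreasing. Greedy swapping can stall in a local
optimum on rare instances; the acceptance suite checks agreement with
exhaustive search over all medoid pairs on ≥ 95% of 200 small random
instances. The dissimilarity summary compares mean pairwise distance
within a subset (unordered distinct pairs) to the global mean, reported as
a relative reduction — used to contrast unsupervised clusters with
supervised top-activity subsets.

## Synthetic data

The generator emulates the structure the framework targets, with the truth
recorded so tests can score against it:

* `linear` — i.i.d. Bernoulli(0.2) bits (sparse, realistic for 128-bit
  folded fingerprints); y = 6 + w·x + N(0, σ²) with ±1 weights on 10
  informative bits and σ = 1 by default, giving the low signal-to-noise
  regime of public IC50 data; the +6 offset puts activities on a pIC50-like
  scale.
* `clustered_linear` — cluster prototypes with members' bits flipped at
  probability 0.05, same linear G: chemical series around scaffolds.
* `similar_actives` — clustered, with one designated cluster both placed
  high on the linear gradient (its prototype carries the positive-weight
  informative bits) and given an additive activity bonus (+2) that is not a
  linear function of individual bits. This reproduces the empirical
  situation where high-activity molecules are mutually similar: under
  random partitioning a flexible model sees the potent family in training
  and exploits the cluster-level signal, while under a low-quantile
  activity split that family is almost entirely out-of-sample and a model
  can reach it only by extrapolating the linear gradient — forests saturate
  at the training maximum and tie-break randomly at the top of the ranking,
  linear models do not.

What the generator does **not** emulate: real fingerprint bit correlations
from shared substructures, assay noise heteroscedasticity, censored
measurements, activity cliffs between near-identical structures, or the
marginal statistics of any particular target. Passing tests therefore
demonstrate the machinery and the direction of the random-vs-activity-split
effect on data with known truth — not effect sizes on any real dataset.

## Problem sizes in the checked claims

The reversal check runs 10 replicate datasets of N = 500 molecules with
A = 50 bootstrap iterations per scheme and the three classical models
(ridge, SVR, random forest), asserting each side of the reversal in at
least 7 of 10 replicates; the deep net, whose training dominates runtime
and whose behaviour under random splits matches the forest's, is exercised
in the contract tests instead. Loss-function identities are enumerated
exhaustively for all permutations of test sets up to size 8; the PAM oracle
uses 200 instances of up to 10 points; partition invariants use 100 random
datasets across q ∈ {0.9, 0.8, 0.6, 0.4}.

## Limitations

* The quantile split removes any possibility of learning activity cliffs
  whose potent side lies above Y_q — inherent to holding out the top of the
  activity range.
* Active-rank losses are non-additive over test molecules, so they cannot
  serve as training objectives, only for validation.
* The probability-of-optimality rule and the percentile interval are
  declared conventions; other defensible estimators (normal-approximation
  intervals, mean±SE comparisons) would differ in small-A regimes.
* PAM with two medoids is a heuristic; global optimality is guaranteed only
  by the exhaustive search used as its test oracle.
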