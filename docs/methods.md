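# Methods

## Problem setting

Given a protein sequence, per-residue structural property tracks predicted
from sequence, and a set of lysine positions labelled phosphoglycerylated
(1) or not (0), the task is binary classification of lysine sites. The
defining difficulties are (i) severe class imbalance (roughly 29 unmodified
lysines per modified one in the motivating data), and (ii) the risk of
optimistic evaluation when the rebalancing step sees data that is later used
for testing.

## Feature model

Each site is the centre of a `2w + 1`-residue window (default `w = 2`,
chosen as the package default because short segments around the modified
lysine carry most of the discriminative structure signal; `w` is exposed in
1..15). Eight tracks per residue enter the vector in a fixed canonical
order — ASA, pc, pe, ph, φ, ψ, θ, τ — flattened **slot-major**: all eight
properties of slot −w, then slot −w+1, and so on. The ordering is a
documented convention, not a modelling claim; any fixed order yields the
same classifier, but file round trips and property masking depend on it
being stable.

**Mirror padding.** A window slot whose offset −i (or +i) falls outside the
sequence is filled by reflecting across the central lysine: it borrows the
residue at +i (resp. −i) and copies that residue's property values
verbatim. Sites on proteins so short that both ±i are out of range for some
i are skipped with a warning rather than zero-padded — a padding value
would be an invented property measurement.

**Property masking.** Removing a property deletes its column in every
window slot, so the vector shrinks by `2w + 1` per removed track
(40 → 35 → … at `w = 2`). Masking commutes with extraction and with itself
(tested as an invariant).

## KNN cleaning treatment

Distances are Euclidean on the **raw** feature vectors — no standardisation
before the distance computation, matching the procedure the pipeline
follows; this means high-variance tracks (ASA, angles in degrees) dominate
the metric, which users should keep in mind when interpreting cleaned sets.
A negative is removed when its k nearest neighbours (all samples, self
excluded; distance ties broken by ascending instance index for determinism)
include at least one positive. k starts at `⌊n_neg/n_pos⌋` and increases by
1, each value applied to the *original* dataset, until at most
`target_ratio` negatives per positive survive (3 for benchmark
construction, 2 for per-fold training rebalancing). Internally the scan
uses each negative's first-positive neighbour rank, which is exactly
equivalent to re-running the pass at every k (neighbour sets are nested in
k) but avoids a quadratic re-sort; the equivalence is property-tested
against an exhaustive O(n²) oracle.

Two boundary behaviours are defined explicitly:

* a dataset already at or below the target ratio is returned unchanged;
* in per-fold **training rebalancing only**, when classes are so well
  separated that every negative's nearest positive sits at nearly the same
  rank, one k increment can jump from removing nothing to removing every
  negative. The rebalancer then truncates the final step: negatives are
  removed in ascending first-positive-rank order just until the target
  holds, keeping the negatives farthest from the positives. The cleaning
  report flags this with `partial=True`. Overlapping real data does not
  reach this regime; strongly separable synthetic data does.

**Selection bias of benchmark-level cleaning.** Cleaning the *whole*
dataset before fold assignment uses positives from all folds to delete
negatives globally, which measurably inflates downstream null performance
(mean AUC ≈ 0.63 instead of 0.5 on signal-free synthetic data). The target
CV protocol below removes the leakage from the training side, but any
benchmark constructed by global cleaning retains this optimism. The
package's null-calibration check therefore runs target CV on uncleaned
data; the strong-signal check exercises the full pipeline including the 1:3
benchmark cleaning.

## Classifier

A single-hidden-layer perceptron, written here rather than delegated, so
that the update rule is exactly the classic configuration: logistic sigmoid
in hidden and output layers, hidden width `a = ⌊(n_features + 2)/2⌋`
(21 for 40 features, 13 for 25), learning rate 0.3, momentum 0.2,
per-sample stochastic gradient descent with update
`v ← μv − η∇; w ← w + v`, sample order reshuffled each epoch from the
seeded generator. Divergences chosen deliberately where the classic
description is silent or two-output:

* a single sigmoid output unit scoring the positive class (equivalent
  decision surface to a two-output layout for two classes);
* binary cross-entropy loss, so the output delta is simply `p − y`;
* 500 epochs by default;
* weight initialisation uniform on (−0.5, 0.5);
* inputs min-max scaled to [−1, 1] with bounds fitted on the training
  split only. Validation data may map outside [−1, 1]; it is not clipped.
  Constant training features map to 0.

Training is bit-deterministic for fixed data, configuration and seed. The
per-sample inner loop is JIT-compiled (numba) because the wrapper selection
scheme trains the network hundreds of times.

## Evaluation protocol

Sensitivity, specificity, G-Mean, accuracy, MCC and F-Measure follow the
standard confusion-table formulas; any metric whose denominator is zero is
defined as 0 (MCC: 0 when any factor under the root is zero). AUC is the
tie-aware normalised Mann–Whitney statistic computed from the continuous
scores, never from thresholded labels.

**Target cross-validation.** Folds are assigned stratified (the positive
class is small enough that unstratified folds can lose it entirely) with a
seeded shuffle, *before* any cleaning. Per iteration the training folds are
rebalanced to 1:2, the MLP is trained (fold index added to the seed so
folds do not share initialisations), and the untouched validation fold is
scored. Metrics are macro-averaged over folds. Each fold record keeps the
validation row indices and the cleaning report, and the result is audited:
validation folds partition the dataset, cleaning never touches a
validation instance, and training positive counts are invariant.

## Feature selection

Backward elimination over property groups: at each level every remaining
property is tentatively removed, candidates are compared by mean CV G-Mean
**on identical fold assignments** (same seed, same rows — removing split
noise from the comparison), and the best removal is committed; ties go to
the property latest in canonical order. Seven committed removals produce a
full ranking (survivor first) and the best mask over all levels, full mask
included. The window-size scan runs the whole pipeline (extract → clean to
1:3 → target CV) per half-width in 1..15, recording per-w failures without
aborting.

## Synthetic data

The generator emulates the three external inputs. Sequences are uniform
over the 20 canonical letters with lysines planted at rate 0.06 per
position; every lysine becomes a site and positives are drawn uniformly to
realise the configured negative:positive ratio (default 29, the observed
regime). Baseline tracks per residue: Dirichlet(1,1,1) secondary-structure
probabilities (these sum to 1 — stricter than real predictor output, and
the readers deliberately do not require it), Normal(0, 60°) angles clipped
to [−180, 180], Normal(60, 30) Å² ASA floored at 0. Class signal is an
additive mean shift of `delta` per-track noise SDs applied to chosen tracks
at chosen window offsets around each positive site, after which row
invariants are restored (probabilities renormalised, angles clipped, ASA
floored). The additive-shift mechanism is the simplest one that makes
cleaning, learning, elimination ranking and window-scan locality all
independently verifiable.

What the generator does **not** emulate: residue-composition structure of
real proteins, autocorrelation of structural tracks along the chain,
predictor error characteristics, or homology between proteins. Passing
tests on this generator therefore demonstrate the pipeline's mechanics and
statistical calibration, not field performance on curated PTM data.

## Problem sizes and numerical choices

The shipped checks run at desk scale as the package's own study design:
signal-recovery and null-calibration runs use 60 synthetic proteins
(≈ 40–50 positives, 400–500 negatives, 1:10 imbalance), 10-fold target CV,
3–5 seeds; elimination-recovery runs use 30 proteins with 3-fold CV and
150 epochs over 10 seeds. Dataset files round-trip feature values at 10
decimals. Sigmoid pre-activations are clamped at ±60 to avoid overflow
without affecting decisions.

## Known limitations

* Raw-scale Euclidean distances make the cleaning sensitive to track units.
* The greedy wrapper selection is a local search; it cannot revisit an
  elimination.
* Benchmark-level cleaning biases any evaluation run on the cleaned set
  (see above); only the per-fold rebalancing path is leakage-free.
* The mirror rule copies property values from the reflected residue, which
  is a modelling convention for missing context, not a physical claim.
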