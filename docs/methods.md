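# Methods

This note documents the model, the estimation machinery, the synthetic
cohorts used for validation, and the design choices that were genuinely
open, in the package's own terms.

## Model and orientation

Regions of interest (ROIs) plus one rest-of-brain (RoB) element are the
players of a coalitional game.  A coalition is the set of **intact**
elements; the characteristic function v(S) is the system's performance
with exactly S intact, so v(∅) is the all-lesioned performance and
positive Shapley values mean "damage here lowers performance".  The
behavioural outcome is coded as ability: the global limb motor score is
10 − (upper item + lower item), where each item grades one limb 0–4;
binarisation maps score 10 → 1 (intact) and anything lower → 0.  (The
severity-vs-ability orientation of the raw scale is resolved once, here,
rather than by chaining a binarisation and an inversion.)

## Surrogate characteristic function

A random-forest classifier is trained on the graded lesion-load matrix
(percent of each region's voxels lesioned, 0–100) against the binary
outcome; the RoB column is an ordinary feature.  Binary coalition
configurations are embedded as graded vectors — intact → 0% load,
lesioned → 100% (complete ablation).  Two alternative embeddings exist
behind flags: the region's maximum observed load (numerically identical
to complete ablation for tree models, whose split thresholds lie inside
the observed range) and its mean observed load (much weaker signal;
retained for sensitivity analyses only).

Hyperparameters are selected by exhaustive grid search maximising
stratified 5-fold cross-validated F1 on the deficit class (the minority,
clinically relevant class; configurable).  The default candidate values
span {50, 150} trees, depth {∞, 4}, feature subsampling {√p, p/2}, leaf
size {2, 5}, and are package choices: the selection *procedure* (grid ×
F1) is part of the method, the candidate values are not prescribed by
it.  Leaf sizes ≥ 2 keep leaf-level class probabilities smoothed; with
singleton leaves a handful of label-noise cases can dominate the
predictions at extreme configurations.

The surrogate can answer with the hard class (default) or the class-1
probability (`output_mode="proba"`).  Hard-class output makes each
bootstrap replicate's contribution a step function of the resample and
yields bimodal replicate distributions at moderate B; the probability
output gives markedly smoother and more stable Shapley estimates and is
what the validation experiments use.

Surrogate quality is reported as leave-one-out (LOO) accuracy, the
confusion counts, F1 = 2PR/(P+R) with P = TP/(TP+FP), R = TP/(TP+FN)
(algebraically tp/(tp + (fp+fn)/2)), and a shuffled-label chance level:
the mean LOO accuracy over 20 label permutations, which concentrates
near the majority-class proportion.

## Shapley estimation

* **Exact** (n ≤ 20): full enumeration of all 2ⁿ coalitions; used as the
  oracle in tests.  Efficiency Σγ = v(full) − v(∅) holds to machine
  precision.
* **Estimated**: R orderings of the elements drawn independently and
  uniformly; each element receives the marginal v(predecessors ∪ {i}) −
  v(predecessors); the per-element mean is unbiased and, for
  deterministic v, preserves efficiency exactly (the marginals of each
  ordering telescope).  Error decreases as 1/√R.  Within one estimation
  the v-values are cached by configuration, since orderings revisit
  configurations.
* **Bootstrap**: B patient resamples (with replacement, original cohort
  size; single-class resamples are redrawn and logged).  The surrogate
  is retrained inside every resample — the resampling covers the whole
  estimation pipeline, not just the permutation draw.  Reported per
  region: mean over replicates, standard deviation over replicates
  (reported as the SE), percentile interval at 1 − α, and a significance
  flag (interval excludes 0; a |mean|/sd z-rule is available).  No
  multiple-testing correction across regions by default; a Bonferroni
  flag exists.

Reference sizes are R = 1,000 and B = 1,000; the validation experiments
in this repository run R = 500, B = 100 on 30-region cohorts — desk-scale
sizes that keep a full 20-seed recovery study to minutes on a single CPU
while leaving the Monte-Carlo error well below the effect sizes probed.

## Iterative elimination with the RoB control

Each iteration: (1) re-select hyperparameters on the current dataset
(can be frozen after the first iteration), (2) bootstrap-estimate
contributions, (3) fold *weak contributors* into the RoB and repeat.

* A region is a **weak contributor** when its |contribution| is below
  `weak_share` (default 0.10) of the total absolute contribution.  Only
  weak contributors can be discarded: the weakest is always discarded,
  together with every region below `negligible_fraction` (default 0.01)
  of the total.  Restricting discards to weak contributors protects
  regions that hold a substantial share of the attribution but whose
  bootstrap interval happens to touch zero in one iteration; without
  this guard the elimination removes genuinely causal regions whenever
  their significance flickers.
* **Stopping**: the loop ends when no weak contributor remains
  (`min_set_reached`), or when a discard makes the RoB contribution
  significant — the sign that discarded regions carried real function.
  A significant RoB after a *batch* discard triggers a rollback and a
  retry with the batch halved (backoff), since a large batch can pool
  enough territory-correlated signal into the RoB to trip the control
  even though most of its members are innocent; only when a
  single-region discard trips the RoB does the run stop, returning the
  last set with a non-significant RoB (`rob_significant_next`).  The RoB
  is tested from the very first iteration; a RoB already significant
  before any discard is reported as a degenerate run.
* Ties on |contribution| break toward the smaller voxel count.  The RoB
  merge pools lesioned voxels: new load = 100 × (pooled lesioned voxels)
  / (pooled voxel count), which is associative and conserves each
  patient's lesioned-voxel total exactly — an invariant the tests check
  at every step of every run.

The trace records every estimation (including rolled-back probes,
flagged `reverted`); the committed path shrinks strictly.

## Synthetic cohorts

Real lesion cohorts cannot be shared, so validation uses generated
cohorts with planted truth.  Per patient: territory blocks are "touched"
with probability `lesion_prevalence` (default 0.45); within a touched
block, member regions are hit with conditional probability 0.6 under a
Gaussian copula with correlation ρ (default 0.5) — reproducing the
within-territory covariance of real lesion maps; hit regions draw a
Beta(2,2)-shaped severity on [0, 100].  The latent deficit is
Σ w_r · load_r / 100 against threshold θ = 0.5; default causal weights
(1.0, 0.8, 0.6) sit on three regions in different blocks, so each is
individually decisive under complete ablation while partial damage
interacts.  Labels flip with probability 0.05.  The RoB element carries
a large voxel count (60,000) and frequent but tiny diffuse loads.  The
default cohort (300 patients, 30 regions, ~25–30% deficit rate) is a
desk-scale analogue of a large clinical sample: sparse causal set among
many nulls, territory collinearity, mild label noise.

What the generator does **not** emulate: 3-D lesion geometry, bilateral
asymmetries, graded behavioural scales beyond the threshold rule, and
predictors correlated with lesion volume (age, stroke subtype).  Passing
recovery tests therefore demonstrate that the machinery identifies a
sparse causal set under territory collinearity and label noise — not
that it resolves every anatomical confound of clinical data.

## Numerical choices and degenerate inputs

* All randomness flows from one seed through named substreams
  (`numpy.random.SeedSequence`); runs are reproducible bit-for-bit.
* Correlation of a constant lesion column is reported missing (NaN) and
  flagged, never coerced to 0.
* Constant-outcome cohorts train (the forest predicts the sole class);
  F1 on the absent deficit class is 0 by convention.
* An all-zero contribution vector cannot be normalised (error), and a
  generator spec with no causal weight and no noise produces an
  all-normal cohort with a warning.
* `exact_shapley` refuses n > 20 and points to the estimator.

## Known limitations

* The surrogate extrapolates: binary configurations (many regions at
  100% simultaneously, a fully "lesioned" RoB) lie outside the observed
  data distribution, and contributions inherit whatever the forest does
  there.  This is intrinsic to surrogate-based MSA, not to this
  implementation.
* Territory collinearity lets correlated neighbours of a causal region
  carry positive, sometimes significant, proxy contributions until the
  elimination loop removes them; final-set precision is therefore below
  1 in a minority of runs.
* The RoB control dilutes: a small critical region merged into a huge
  RoB may not make it significant, so the control is a necessary rather
  than sufficient guard against discarding function.
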