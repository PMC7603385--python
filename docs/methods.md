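# Methods

## Connectivity features

A subject is a T×R matrix of ROI time series.  Pearson correlation of every
region pair gives a symmetric R×R matrix with unit diagonal; the feature
vector is its upper triangle in row-major order over 0-based indices,
(0,1), (0,2), …, (1,2), …, of length n = R(R−1)/2 (n = 4005 at R = 90).
The ordering is a convention the rest of the pipeline depends on, so it is
fixed here once and exposed through `FeatureIndexMap` with closed-form maps
in both directions.  Zero-variance regions raise an error naming the region
rather than producing NaN correlations, because a silent NaN would poison
the networks downstream.  Atlas files with 1-based region numbering are
converted at the reader boundary; everything internal is 0-based.

## Teacher network

The teacher is a funnel-shaped multilayer perceptron of 17 layers counting
the input and the 2-unit softmax output.  Layer widths interpolate
geometrically from n down to the code width (default 5) over 16 layers;
rounded widths are floored at code+1 before the code layer so the code
width occurs exactly once.  Activations are tanh (the features live in
[−1, 1], so relu would discard the negative half).  Dropout decays linearly
from 0.3 after the first hidden layer to 0 before the code layer — the
direction (gradual decrease) is the specified behaviour; the endpoints are
package defaults.  Training uses Adadelta (ρ = 0.95, ε = 1e−6) scaled by a
learning rate of 0.001, batch size 16, 500 epochs, and a 2-unit
cross-entropy head (label 1 = patient).  All stochastic elements —
Glorot-uniform initialisation, batch shuffling, dropout masks — draw from a
single seeded generator, so training is exactly reproducible on a fixed
BLAS configuration.

Codes are the post-activation outputs of the 5-unit layer (a flag switches
to pre-activation).  They are extracted for the full cohort after training
on the full cohort — the selection stage, not the code extraction, is where
generalisation is measured — and column-standardized with the population-sd
(divide-by-m) convention; the fitted means/sds are retained so held-out
data can be mapped consistently.

## Student network and feature scores

The student is n → h → d with h = 100 relu hidden units and a linear
output trained by MSE to reproduce the standardized codes (a relu output
could not produce negative standardized values).  Because a feature enters
the student only through its row of the input-to-hidden matrix W (n×h),
the squared Euclidean row norm diag(W·Wᵀ), computed row-wise without
forming the n×n product, measures the feature's contribution to code
reconstruction.  Features are ranked by decreasing score; ties break toward
the lower feature index.  The ranking is invariant to hidden-unit
permutations and column sign flips of W, which the tests verify.

The regulariser is what turns the row norm into an importance measure: a
row-wise group-L2 penalty (sum over features of the row's Euclidean norm)
shrinks rows the reconstruction does not need.  With m ≪ n the
over-parameterised student can otherwise reproduce the codes through
arbitrary feature combinations, leaving the row norms near their
initialisation values; pilot runs on the benchmark cohort showed recovery
of only ~5/10 planted features at a strength of 1e−4 versus 8–10/10 at the
default 2e−2.  Plain L1 is available as an alternative, and the strength is
a constructor parameter.  Student optimisation mirrors the teacher
(Adadelta, batch 16, 500 epochs) at a learning rate of 0.01 — the shallow
reproduction task tolerates, and converges faster with, the higher rate.
Training the student far longer is counterproductive: past the point where
the penalty balances the reconstruction gradient, the network starts
absorbing noise features to interpolate the codes and the score contrast
degrades.

## Forward selection

Features are scanned in ranking order in cumulative blocks (`step`,
default 50 at paper scale); prefix t contains the top min(t·step, n)
features.  Each prefix is scored by stratified k-fold mean accuracy
(default k = 10, unweighted mean over folds) with one of five seeded
classifiers: L2 logistic regression (C = 1), linear SVM (C = 1), linear
discriminant analysis, 100-tree random forest, unpruned decision tree.
The full curve is always recorded and the returned set is the argmax with
ties resolved toward fewer features; an optional threshold stops the scan
at the first prefix reaching a target accuracy.  On cohorts with planted
signal the curve shows the characteristic bias → peak → variance shape:
too-short prefixes underfit, the peak sits near the planted-set size, and
appending the remaining noise features erodes test accuracy.  For the
benchmark cohort (R = 20, n = 190, 10 planted pairs) the scan uses step 5
so prefixes resolve around the planted-set size; a step of 50 would put
every planted feature inside the first prefix.

## Evaluation

Metrics are accuracy, sensitivity = TP/(TP+FN) and specificity =
TN/(TN+FP) with the patient label 1 as the positive class.  Ratios with an
empty denominator are reported as NaN, never silently as 0 or 1.  The
combined cohort is evaluated by stratified 10-fold cross-validation; each
acquisition site is additionally evaluated by 5-fold cross-validation using
the feature set selected on the combined data (reuse probes the robustness
of one selection across sites; per-site reselection is available behind a
flag).  Sites lacking the minimum per-class count are skipped with a logged
reason.

## Synthetic cohorts

The generator simulates the statistical structure the pipeline must detect,
not BOLD physiology.  For each planted pair a subject-specific target
correlation is drawn in Fisher-z space, z_s = atanh(effect)·(1 + hetero·ξ),
ξ ~ N(0,1), and realised exactly through a shared latent series mixed into
both regions on top of independent Gaussian noise (sd `noise_sd`).
Patients (label 1) center at `effect`, controls at 0; because the
dispersion scales with the coupling, a zero effect collapses planted pairs
onto the background distribution exactly, which is what the null-control
tests require.  A second, class-symmetric term emulates background
connectivity heterogeneity: every region loads on `background_rank` shared
latents with per-subject N(0, `background_sd`²) weights, giving all region
pairs realistic between-subject correlation variability with no class
information.

Defaults (noise_sd 0.5, hetero 0.8, background rank 5 / sd 0.5) define the
benchmark regime: planted-pair class separation ≈ 0.45–0.55 in correlation
units, non-planted feature between-subject sd ≈ 0.19.  Both heterogeneity
terms are essential: without subject-level dispersion a planted correlation
separable at the class level is also a near-perfect single-subject
separator (the sampling sd of a correlation at T = 200 is only ~0.07), and
without background variability the non-planted features are near-constants
— in either case the accuracy-vs-prefix curve degenerates to a flat line
and the under/overfitting phenomenology the selector exploits cannot occur.
Sites are assigned round-robin (two sites by default) purely so site-wise
evaluation is exercisable.  What passing tests on these cohorts does *not*
show: robustness to autocorrelated BOLD noise, scanner drift, motion
artifacts, site batch effects, or class imbalance — none of which are
simulated.

## Benchmark problem sizes

The test suite and the acceptance script run the full pipeline on cohorts
of 40 subjects per class, R = 20 regions (190 features), T = 200 time
points and 10 disjoint planted pairs at effect 0.6, with the teacher
reduced to 100 epochs — at 190 input features the funnel converges well
within that budget, and one full ranking takes a few seconds.  The paper
-scale configuration (R = 90, 4005 features, 17-layer funnel from 4005,
500 epochs) is the library default for real data.

## Numerical choices and degenerate inputs

* Correlations are clipped to [−1, 1] and matrices symmetrised against
  float round-off; the zero-variance test uses a relative threshold
  (a constant column's sd is ~eps·|mean|, not exactly 0).
* Adadelta keeps ε = 1e−6 inside both square roots; softmax is computed
  with the max-subtraction trick; the cross-entropy adds 1e−12 inside the
  log.
* Code standardization refuses m = 1 (sd undefined) and zero-variance code
  columns.
* `feature_to_pair` inverts the triangular indexing in closed form with an
  integer correction loop guarding the float square root at block
  boundaries; the bijection is tested exhaustively for R ≤ 10.
* Ranking ties break toward lower feature indices (stable argsort on the
  negated scores); selection ties break toward fewer features (first
  argmax).
* Label-swap symmetry of the 2-unit head is exact in the loss but only
  approximate after optimisation (the initialisation is not mirrored), and
  is tested with a tolerance.

## Known limitations

* The exact per-layer widths and dropout rates of the original 17-layer
  architecture are not published; the geometric-interpolation funnel and
  linear dropout decay are this package's own documented defaults, and
  both are fully configurable through `TeacherSpec`.
* The exact form of the student weight regulariser in the original work is
  unpublished; row-group-L2 is the package default because it directly
  motivates diag(W·Wᵀ) as a score.
* The packaged AAL-90 atlas table is a synthetic stand-in: standard region
  names, this package's own lobe taxonomy, and approximate MNI centroids
  suitable for visualisation export, not for anatomical inference.  Supply
  your own atlas CSV for real analyses.
* Reproducibility is bit-exact for a fixed seed on a fixed
  numpy/BLAS configuration; across BLAS builds results may differ in the
  last float digits.
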