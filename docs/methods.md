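# Methods

## Setting

Transductive positive-unlabeled (PU) classification: a feature table of
n samples by p features, a set of known positives (KP), and an unlabeled
remainder U mixing hidden true positives (TP) and true negatives (TN).
The package does not try to improve PU classification itself; it
quantifies *confidence* in a PU model's output when no negative labels
exist to validate against, by asking whether the known-positive set
scores better than an equally sized randomly chosen "positive" set
would.

## PU bagging

Each of T bootstrap rounds draws |KP| samples from U with replacement as
temporary negatives, fits a binary classifier on KP (class 1) versus the
bag (class 0), and predicts every out-of-bag (OOB) unlabeled sample.
The bagging score of an unlabeled sample is the fraction of its OOB
rounds in which it was predicted class 1 — an aggregate of *hard* votes,
not of per-round probability estimates, so any classifier exposing
`predict` is pluggable.

* **T = 100** rounds by default.  With |U| ≥ 20 or so, the probability
  that a sample is never OOB is negligible at T = 100; if it happens the
  sample receives the neutral score 0.5 and a `RuntimeWarning`, keeping
  downstream ranking defined.
* **Classifier**: RBF-kernel support-vector classifier with scikit-learn
  default hyperparameters (C = 1, gamma = 'scale', tol = 1e-3), no
  tuning — with no negative labels there is no trustworthy objective to
  tune against, and the bagging procedure is empirically insensitive to
  the choice of classifier.  The default contract
  (`fast_svc_rbf_fit_predict`) invokes scikit-learn's libsvm bindings
  directly with those same parameters, skipping per-call input
  validation; a pipeline run makes 1e5–1e6 fits of tiny matrices, and
  validation would otherwise dominate runtime.  The test suite asserts
  exact prediction agreement with the public `sklearn.svm.SVC` API on
  randomized instances.
* **Scaling**: per-round standardization (zero mean, unit variance)
  whose parameters are computed from the in-bag training rows only (KP +
  bootstrapped pseudo-negatives) and applied to the OOB rows; features
  constant within the bag get a unit divisor.  This stabilizes the SVM
  numerically without leaking OOB information into the fit.

## K-fold spy scoring

A model must not score its own training positives, so each repeat
randomly partitions KP into K folds (sizes differing by at most one) and
hides one fold at a time inside U; the hidden "spies" are scored by a
fresh bagging run trained on the remaining KP.  Pooling the K folds
scores every KP exactly once per repeat.  R independent repeats (fresh
random partitions) quantify fold-assignment variance.  Defaults K = 5,
R = 30.  Two pooled-score summaries are computed per repeat:

* **EPR** — fraction of spies scoring *strictly* above the threshold
  (default 0.5; a score exactly at the threshold is not counted
  positive);
* **MBS** — the arithmetic mean of the pooled spy scores, requiring no
  decision boundary.  MBS typically varies less across repeats than EPR,
  which makes it the more sensitive of the two.

## Permutation null and statistics

Each of B permutations reassigns the |KP| positive labels to a uniformly
random subset of *all* samples (so permuted "positives" land on hidden
negatives too — that is the null being simulated), reruns the spy
procedure once, and records its EPR and MBS.  Running one spy repeat per
permutation (configurable) prices the null at B spy runs; because a
single-repeat draw has at least the variance of the R-repeat mean it is
compared against, the resulting test errs on the conservative side under
an exact null.

The comparison statistics are:

* an upper-tailed one-sample z-score, z = (μ − μ₀)/σ, with μ the mean
  actual-label score over the R repeats, μ₀ the null mean, σ the null
  sample SD (n − 1 dof), and p the upper standard-normal tail.  A null
  with zero spread raises an explicit `DegenerateNullError` rather than
  returning ±inf.
* Cliff's Delta between the R actual values and B null draws, with the
  asymptotic CI of Cliff's consistent variance estimate and the
  asymmetric interval transform that keeps bounds inside [−1, 1]
  (collapsing to a point interval under complete dominance, where the
  variance estimate is zero).  Magnitude labels use the conventional
  |δ| cut-offs 0.147 / 0.33 / 0.474.
* p-values for EPR and MBS are reported raw, without multiplicity
  adjustment, as two views of the same comparison.

When hidden ground truth is available, the **U-AUC** (ROC-AUC of U-set
bagging scores from a dedicated full-KP run against the hidden labels;
ties count one half) measures the prediction performance the confidence
test is meant to certify.  Spy-run scores are not reused for U-AUC
because removing a spy fold perturbs the positive set.

## Synthetic data generator

The generator (`sklearn.datasets.make_classification` underneath)
emulates wide profiling data: 30% "informative" features drawn from a
Gaussian cluster per class centred on class-specific hypercube vertices
at distance d (`class_sep`), 70% "redundant" features that are exact
random linear combinations of the informative block (introducing the
covariance structure typical of omics panels), configurable TN
proportion with deterministic rounding (remainder to TP), and one
cluster per class.  PU scenarios are produced by revealing n_KP randomly
chosen true positives.

What the generator does *not* emulate: heavy-tailed or discrete marginal
distributions, batch effects, missing values, and label noise
(`flip_y = 0`).  Passing tests therefore demonstrate correctness of the
procedure under clean Gaussian-mixture geometry, not robustness to every
real-data pathology.

Two numerical notes.  The toolkit requires strictly positive
`class_sep`, so d = 0 is realized as 1e-12 — twelve orders of magnitude
below the unit cluster noise, i.e. coincident class centroids.  And the
toolkit applies an independent random covariance transform to each
cluster, so even at d = 0 the two classes differ in *shape* though not
in location; d = 0 is a location-null rather than an exact
distributional null.  This matters for interpretation: on d = 0 data
the U-AUC sits modestly above 0.5 (≈ 0.53–0.65 depending on the TN
fraction), and how much of the residual covariance signal the
default-gamma RBF-SVC can exploit depends on dimensionality.  In the
wide p ≥ n regime the method targets, the z-test stays calibrated at
d = 0 (no rejections in a 30-replicate probe at n = 200, p = 200;
≈ 5% at n = 100, p = 200), whereas dropping to p < n (e.g. p = 50 at
n = 100) makes the covariance signal learnable and pushes the MBS
rejection rate to ≈ 6–7%, with the threshold-free MBS metric more
sensitive to that signal than EPR.  The bundled calibration experiment
therefore scales the problem down only along repeats/permutations/
bootstraps and keeps p ≥ n.

## Seeding

A single master seed drives everything.  Child streams are derived via
`numpy.random.SeedSequence` from (master seed, path keys), so data
generation, relabeling, bootstrap draws, fold splits, per-permutation
shuffles, and classifier seeds are mutually independent, reproducible,
and invariant to execution order; derived seeds stay below 2^31 for
libsvm compatibility.  Identical (data, config, seed) reruns are
bit-identical end to end, including the saved artifacts.

## Problem sizes used in the checked experiments

The bundled experiment scripts/tests use the standard operating points
(n = 200 × p = 200 with T = 100 for U-AUC sweeps; n = 100 × p = 200 for
the small-sample case) and a scaled-down calibration experiment
(n = 100, p = 50, R = 5, B = 20, T = 50, ~100 replicates), chosen to
keep a full reproduction in the minutes range on a single CPU while
preserving each experiment's qualitative regime.

## Known limitations

* The method flags *absence* of signal reliably but cannot distinguish,
  from a weak score alone, whether the cause is small class separation
  or a scarce true-negative fraction; with ~10% TN the test loses power
  even when the underlying classes separate well.
* Calibration is approximate: the z-test assumes the null scores are
  summarized adequately by mean and SD; heavy skew in the null (extreme
  imbalance, tiny B) degrades the normal approximation.  B ≥ 30 is
  recommended.
* The spy procedure assumes KP is an unbiased sample of the TP class;
  biased positive labeling shifts both μ and the interpretation.
* Transductive only: scores exist solely for the samples present at fit
  time.
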