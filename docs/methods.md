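# Methods

## Transfer entropy and its estimator

Transfer entropy from a source process A to a target process C quantifies
how much A's recent past improves prediction of C's next value beyond C's
own past:

    TE(A→C) = I( C_{n+1} ; A_n^{(l)} | C_n^{(k)} )

a conditional mutual information between the target's next sample, the
source's length-l history and the target's length-k history.  It is zero
exactly when C is Markov with respect to its own past given A, directed
(TE(A→C) ≠ TE(C→A)), and sensitive to nonlinear dependence.  We treat it
as *predictive* information transfer — a statistical statement about time
series, not a causal claim about physical pathways.

For continuous data we use the KSG (Kraskov–Stögbauer–Grassberger)
k-nearest-neighbor estimator, algorithm 1: for each embedded point the
Chebyshev distance ε to its k-th neighbor in the joint space sets a local
scale, and the estimate averages digamma terms over the counts of points
falling strictly inside ε in the (target-future, target-past),
(source-past, target-past) and (target-past) marginal subspaces.
Estimation runs in nats and is converted to bits (the unit used
throughout).

Parameter defaults, chosen once:

| parameter | default | why |
|---|---|---|
| `k_neighbors` | 4 | standard KSG choice; low bias at the series lengths used |
| `history_target`, `history_source` | 1 | matches the lag-1 structure of the VAR ground truth; history lengths for real data are a user decision |
| `jitter_sd` | 1e-8 × series sd | seeded tie-breaking noise so neighbor counts are well defined on discretized inputs; deterministic given the seed |
| `units` | bits | flows are reported in bits |

The jitter stream is keyed to the node *identity* (CRC of the node id),
not the row position, so permuting a panel's rows permutes the TE matrix
exactly.  The estimator is consistent but noisy: when the true TE is at or
near zero, estimates are frequently negative.  Since TE is theoretically
nonnegative, negative estimates are measurement error and are clipped to
zero, giving the sparse TE matrix that downstream stages consume.
Self-TE is defined as 0 and never estimated.

Validation: for a stationary Gaussian VAR(1) the lag-1 TE has the closed
form ½·log₂( var(target_t | target_{t−1}) / var(target_t | target_{t−1},
source_{t−1}) ), with conditional variances from Schur complements of the
stationary covariance (discrete Lyapunov equation).  The KSG estimate
matches this oracle with mean absolute error below 0.02 bits at
T = 10,000, k = 4 (10 seeds, both directions of a one-way-coupled pair) —
asserted in the acceptance tests.

## Information flow

The sparse TE matrix is the adjacency/capacity matrix of a directed graph;
connectivity from node i to node j is the **maximum flow** value, computed
with networkx (preflow-push).  The max-flow *value* is unique (min-cut
capacity) even though flow assignments are not, so results are
algorithm-independent; a brute-force min-cut enumeration serves as the
test oracle.  Zero-capacity edges are dropped at graph construction
(identical values, smaller graphs), and a source with no outgoing — or a
sink with no incoming — positive edge short-circuits to flow 0.

Three matrix variants:

* **full, unrestricted** — flows over the whole graph (n² cells, diagonal
  fixed at 0 and emitted explicitly);
* **full, restricted** — for source in group X and sink in group Y only
  edges with tail in X and head in Y are eligible (all within-group edges
  when X = Y).  The restriction is both an anatomical prior and a large
  computational saving;
* **reduced** — group × group sums of the restricted full matrix over
  ordered node pairs (i ≠ j); the diagonal holds within-group flow sums.
  With the reference 20-group hemisphere × lobe scheme this yields 400
  features, 20 of them within-group.

Feature vectors flatten the chosen matrix row-major, diagonal included,
with stable `"x->y"` labels.

## The predictive model

Given subjects × features flows and a behavior score per subject:

1. optional covariate exclusion: drop features Spearman-correlated with
   any nuisance covariate (e.g. motion summaries) at p ≤ α;
2. selection: keep features Spearman-correlated with behavior at two-sided
   p ≤ α (asymptotic t approximation; α = 0.05 default).  Constant
   features are never selected;
3. PCA on the selected features — centered, *not* variance-scaled, since
   all flows share units of bits (a scaling switch is deliberately not
   exposed; standardize beforehand if needed);
4. component count chosen by an inner leave-one-out loop over candidates
   1 … min(n_train − 1, n_selected), scored by the Spearman correlation of
   held-out predictions, smallest count on ties.  Within an inner fold a
   candidate larger than the fold's PCA rank contributes nothing beyond
   the rank (centered PCA rank is at most n_train − 2 inside folds, one
   less than the candidate bound — the extra candidate is evaluated at the
   fold's rank);
5. OLS of behavior on component scores;
6. z-scoring: a prediction is standardized against the mean/sd (ddof = 1)
   of the inner-LOOCV predictions of the training subjects, each made by a
   model fitted without that subject at the chosen mask and component
   count.

Internal validation is leave-one-out with the *entire* pipeline re-run per
fold; external validation fits once on the full training cohort and
applies the frozen model.  Both are evaluated by Spearman correlation, so
the per-fold z-scoring (an affine map with fold-specific parameters)
changes ranks only marginally; on a noiseless planted cohort the LOOCV
rho is ≈ 0.96 rather than exactly 1 for this reason.

Significance: permutation test that shuffles behavior and re-runs
selection, component choice and LOOCV per iteration (exchangeability is
preserved because nothing is reused from the observed labels), with the
add-one estimate p = (1 + #{null ρ ≥ observed ρ}) / (1 + N).  One-sided
"≥ observed" is the default ("as extreme as" in the trained direction);
a two-sided option compares magnitudes.

**Empty selection.**  With α = 0.05 and few features, folds can select
nothing — routinely so under permutation.  `loocv_internal_validation`
aborts with the offending fold named (default), or, with
`on_empty_selection="mean"`, lets such folds predict the fold-training
mean (z = 0).  `permutation_test` uses the "mean" policy for the observed
and every permuted run identically, which keeps the statistic defined on
null data without biasing the p-value.

**Null behavior of the LOOCV correlation.**  Fold models share all but two
subjects, so their selected features — and hence their predictions — are
strongly dependent; the null distribution of the LOOCV rho is far wider
than 1/√n (sd ≈ 0.4 at n = 20 with 16 features) and slightly negatively
centered (mean ≈ −0.09), the familiar anticorrelation of cross-validated
mean predictions.  This is why significance comes from the permutation
test, which reproduces exactly this null, and never from a textbook
rank-correlation p-value.  The test suite checks the null is centered
(leakage would shift it positive) and that the permutation type-I rate at
α = 0.05 sits inside exact binomial bounds over 100 replicate cohorts.

**Exact reformulations for speed.**  PCA scores are centered and mutually
orthogonal, so the OLS on the first c components decouples: one thin SVD
per fold yields held-out predictions for every candidate count via a
cumulative sum, and the single-feature case reduces to closed-form
leave-one-out simple regression.  The permutation loop additionally caches
per-fold feature ranks (features never change under permutation) and
replaces the per-feature p-value threshold by the equivalent critical
|ρ| threshold.  These are algebraic identities, not approximations; the
test suite asserts the fast engine equals the definition-following route
(`fit_cpm`/`predict_cpm` per fold, and sklearn PCA + LinearRegression)
to floating-point accuracy.

## Synthetic ground truth

`simulate_var_panel` draws from x_t = Cᵀ x_{t−1} + ε_t with Gaussian
innovations; construction rejects spectral radius ≥ 1 and a 200-sample
burn-in removes the transient.  This family is the ground truth because
its transfer entropy is exactly known (above).

`simulate_nonlinear_pair` provides y_t = c·(x_{t−1}² − 1) + η_t with white
Gaussian x: every product moment E[x_s y_t] vanishes by odd-moment
symmetry, so Pearson correlation is ≈ 0 at all lags while TE(x→y) is
large.  A quadratic map was preferred over coupled logistic maps because
the zero correlation holds exactly by construction rather than
approximately.

`simulate_cohort` gives each subject an independently jittered copy of a
template coupling matrix (multiplicative Gaussian jitter, sd 10% by
default — the source of inter-subject flow variance), simulates a panel,
runs the *real* pipeline (KSG TE → clip → restricted max flow → reduce),
and sets behavior = Σ planted_weights ∘ IF + noise.  The noise sd is
specified relative to the sd of the planted signal across subjects
(0.1 = strong effect), falling back to absolute units for null cohorts
(all-zero weights), whose behavior is pure noise.  Defaults chosen once:
T = 360 timepoints (one 6-minute resting run at a 1-second sampling
interval), template spectral radius 0.6, block-structured coupling with
within-group rings plus one link per adjacent group pair so every
group-pair flow is nonzero and subject-variable.

What the generator does *not* emulate: hemodynamics, scanner noise
spectra, spatial voxel structure, motion artifacts, or inter-regional
delay distributions.  Passing tests therefore demonstrate correctness of
the estimators and the modeling machinery under known ground truth — not
that any particular real dataset carries a recoverable signal.

Problem sizes used by the long-running checks (the package's own choices):
planted-effect recovery uses 20 replicate cohorts of 20 subjects,
12 nodes/4 groups at T = 360; permutation calibration uses 100 null
cohorts of 20 subjects, 8 nodes/4 groups at T = 250 with 200 iterations
per test.

## Numerical choices and degenerate inputs

* Neighbor counts use strict inequality (< ε) via the next float below ε;
  seeded jitter makes exact ties measure-zero.
* Spearman p-values use the asymptotic t approximation (two-sided), the
  appropriate regime for cohort sizes of ~20–70; ranks use average ties.
* Component-count ties break to the smallest count (parsimony,
  reproducibility).
* An undefined rank correlation (constant vector) propagates as NaN from
  `spearman_rho`; the permutation statistic maps it to 0 (no association).
* `train_pred_sd` must be positive; a degenerate (constant-prediction)
  training cohort is an error rather than a silent division by zero.
* All randomness flows through explicitly seeded generators; there is no
  global RNG state, and the pipeline runner records the seed in every
  output header and refuses to run without one.

## Limitations

* Capacities are estimated TEs — lower bounds on direct information
  transfer — so flows are lower bounds on maximal information flow, and
  flows along different paths are not guaranteed to be independent
  messages.
* Only pairwise (bivariate) TE with short histories is implemented;
  multivariate/conditional TE, spectral TE, and per-edge significance
  testing are out of scope, as are minimum-cost and multi-commodity flow
  variants.
* fMRI preprocessing (registration, motion correction, nuisance
  regression) is upstream of this package; `parcellate` only averages
  voxel rows into node time courses.
* Whether TE should be estimated on concatenated runs or per run and
  averaged is left to the caller: everything operates on the panel it is
  given.
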