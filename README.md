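# infoflow

Information-flow functional connectivity and behavior prediction.

`infoflow` measures the functional connectivity between regional brain
signals (or any multivariate time series) as **maximum flow over a
transfer-entropy network**, and predicts per-subject behavior scores from
those flow matrices with **connectome-based predictive modeling (CPM)**.

## The measure

Given one subject's node × time matrix of regional signals:

1. **Transfer entropy.** For every ordered node pair the directed transfer
   entropy TE(A→C) = I(C_{n+1}; A_n^{(l)} | C_n^{(k)}) is estimated with the
   Kraskov–Stögbauer–Grassberger (KSG) nearest-neighbor estimator
   (k = 4 neighbors, lag-1 histories, Chebyshev neighborhoods), in bits.
   TE captures linear *and* nonlinear directed dependence; the estimator's
   finite-sample variance makes near-zero TEs come out negative, and those
   are clipped to 0 ("sparse" TE matrix).
2. **Maximum flow.** The sparse TE matrix is read as a capacity graph:
   edge (i, j) can carry TE(i→j) bits.  Connectivity from node i to node j
   is the maximum flow IF_ij — the direct edge plus everything routable
   through intermediate nodes, so network structure enters the measure.
   Variants: unrestricted (all edges), anatomically restricted (only edges
   from group(i) to group(j), where groups are hemisphere × lobe), and the
   reduced group × group matrix IF_xy = Σ_{i∈x, j∈y} IF_ij (400 features
   for the reference 20-group scheme, 20 of them within-group flows).
3. **CPM.** Across training subjects, flow cells Spearman-correlated with
   the behavior score (two-sided p ≤ 0.05) are selected, aggregated by
   centered PCA whose component count is tuned by a nested leave-one-out
   loop, and fed to an ordinary least-squares regression.  A new subject's
   prediction is z-scored against the inner-LOOCV predictions of the
   training subjects.  Performance is the Spearman correlation between
   left-out predictions and observed scores; significance comes from a
   permutation test that re-runs the entire pipeline on shuffled scores.

Because real cohorts are not redistributable, the package ships a
synthetic-data module: stationary VAR(1) panels whose lag-1 transfer
entropy has an exact Gaussian closed form (the estimator's oracle), a
quadratically coupled pair whose dependence is invisible to Pearson
correlation, and cohorts whose behavior is a noisy linear function of
designated cells of their *computed* flow matrices.

## Worked example

Simulate a 20-subject cohort (12 nodes, 4 groups) whose behavior score is
the flow from group `g0` to group `g1` plus 10% noise, then validate the
full pipeline:

```python
import numpy as np
from infoflow import loocv_internal_validation, permutation_test
from infoflow.simulate import CohortSpec, cohort_template, simulate_cohort

template, scheme = cohort_template(n_nodes=12, n_groups=4, seed=0)
weights = np.zeros((4, 4)); weights[0, 1] = 1.0
spec = CohortSpec(n_subjects=20, panel_template=template,
                  planted_weights=weights, behavior_noise_sd=0.1, seed=1)
cohort = simulate_cohort(spec, scheme, n_timepoints=360)

res = loocv_internal_validation(cohort.features, cohort.behavior)
perm = permutation_test(cohort.features, cohort.behavior,
                        n_iterations=199, seed=1)
print(f"LOOCV Spearman rho = {res.rho:.3f}")
print(f"permutation p      = {perm.p_value:.4f}")
```

Output:

```
LOOCV Spearman rho = 0.989
permutation p      = 0.0050
```

The rank correlation of 0.989 means the left-out predictions order the
subjects almost exactly as their true attention-like scores do; p = 0.005
is the smallest value attainable with 199 permutations (no shuffled cohort
matched the observed correlation).  The planted cell itself correlates at
rho = 0.991 with behavior, so the pipeline recovered essentially all the
available signal.

The same estimators compose with scikit-learn:

```python
from sklearn.pipeline import Pipeline
from infoflow import CpmRegressor, InformationFlowExtractor

pipe = Pipeline([("flows", InformationFlowExtractor(scheme=scheme)),
                 ("cpm", CpmRegressor(alpha=0.05))])
pipe.fit(cohort.panels, cohort.behavior)
z = pipe["cpm"].predict_z(pipe["flows"].transform(cohort.panels))
```

And from the shell (`infoflow simulate`, `te`, `flow`, `train`, `predict`,
`validate-loocv`, `permtest`, `run`):

```bash
infoflow simulate cohort --subjects 20 --nodes 12 --groups 4 \
    --seed 1 --outdir cohort/
infoflow run --panels cohort/ --behavior cohort/behavior.tsv \
    --scheme cohort/scheme.tsv --iterations 1000 --seed 1 --outdir out/
```

All matrices travel as tab-separated text with label headers and
`#`-comment metadata (units, seed, parameters); trained models are JSON.

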