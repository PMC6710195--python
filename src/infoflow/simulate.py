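"""Synthetic ground truth: coupled stochastic processes and subject cohorts.

Two generators make every downstream stage testable without real data:

* a stationary lag-1 vector autoregression (VAR(1)),
  ``x_t = C^T x_{t-1} + eps_t``, whose lag-1 transfer entropy has an exact
  closed form for Gaussian innovations — the analytic oracle the KSG
  estimator is validated against;
* cohorts of subjects whose behavior score is a noisy linear function of
  designated cells of their *computed* reduced information-flow matrix, so
  the predictive pipeline has a planted, recoverable association.

A quadratically coupled pair is also provided as a fixture whose dependence
is invisible to Pearson correlation but carried by transfer entropy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .flow import compute_full_if_matrix, flatten_features, reduce_if_matrix
from .panel import GroupScheme, TimeSeriesPanel
from .te import KsgConfig, build_te_matrix, sparsify_te_matrix

__all__ = [
    "VarModel",
    "CohortSpec",
    "SyntheticCohort",
    "simulate_var_panel",
    "analytic_gaussian_te",
    "simulate_nonlinear_pair",
    "simulate_cohort",
    "cohort_template",
]

_LN2 = np.log(2.0)

#: Default cohort series length: one 6-min resting run at TR = 1 s.
DEFAULT_N_TIMEPOINTS = 360


@dataclass
class VarModel:
    """Stationary lag-1 VAR: ``x_t = coupling^T x_{t-1} + eps_t``.

    ``coupling[i, j]`` is the lag-1 influence of node i on node j.
    Stationarity (spectral radius of the coupling matrix < 1) is required at
    construction.
    """

    coupling: np.ndarray
    noise_sd: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.ndim != 2 or self.coupling.shape[0] != self.coupling.shape[1]:
            raise ValueError("coupling must be a square matrix")
        self.noise_sd = np.broadcast_to(
            np.asarray(self.noise_sd, dtype=float), (self.n_nodes,)
        ).copy()
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise_sd must be > 0 for every node")
        rho = self.max_abs_eigenvalue
        if not rho < 1:
            raise ValueError(
                f"non-stationary model: spectral radius {rho:.3f} >= 1; "
                "scale the coupling matrix down"
            )

    @property
    def n_nodes(self) -> int:
        return self.coupling.shape[0]

    @property
    def max_abs_eigenvalue(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.coupling))))

    def stationary_covariance(self) -> np.ndarray:
        """Stationary covariance Sigma solving Sigma = A Sigma A^T + Q, A = coupling^T."""
        a = self.coupling.T
        q = np.diag(np.asarray(self.noise_sd) ** 2)
        return solve_discrete_lyapunov(a, q)


def simulate_var_panel(
    model: VarModel,
    n_timepoints: int,
    seed: int,
    subject_id: str = "sim",
    condition: str = "other",
    node_ids=None,
    burn_in: int = 200,
) -> TimeSeriesPanel:
    """Simulate a node x time panel from a stationary VAR(1) model.

    A burn-in period (discarded) removes the transient from the zero initial
    state; reproducible given ``seed``.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    rng = np.random.default_rng(seed)
    n = model.n_nodes
    a = model.coupling.T
    total = burn_in + n_timepoints
    eps = rng.normal(0.0, 1.0, size=(total, n)) * np.asarray(model.noise_sd)
    x = np.zeros((total, n))
    x[0] = eps[0]
    for t in range(1, total):
        x[t] = a @ x[t - 1] + eps[t]
    if node_ids is None:
        node_ids = [f"n{i:03d}" for i in range(n)]
    return TimeSeriesPanel(
        subject_id=subject_id,
        data=x[burn_in:].T.copy(),
        node_ids=list(node_ids),
        condition=condition,
    )


def analytic_gaussian_te(model: VarModel, source: int, target: int) -> float:
    """Exact lag-1 transfer entropy (bits) of a stationary Gaussian VAR(1).

    For jointly Gaussian processes,

        TE(source -> target)
          = 1/2 * log2( var(x_T,t | x_T,t-1) / var(x_T,t | x_T,t-1, x_S,t-1) )

    with conditional variances obtained as Schur complements of the
    stationary joint covariance of (x_t, x_{t-1}).
    """
    if source == target:
        raise ValueError("source and target must differ")
    n = model.n_nodes
    for idx in (source, target):
        if not 0 <= idx < n:
            raise IndexError(f"node index {idx} out of range for {n} nodes")
    sigma = model.stationary_covariance()
    cross = model.coupling.T @ sigma  # Cov(x_t, x_{t-1})

    def cond_var(past: list[int]) -> float:
        s_ff = sigma[target, target]
        s_fp = cross[target, past]
        s_pp = sigma[np.ix_(past, past)]
        return float(s_ff - s_fp @ np.linalg.solve(s_pp, s_fp))

    v1 = cond_var([target])
    v2 = cond_var([target, source])
    te = 0.5 * np.log(max(v1, 1e-300) / max(v2, 1e-300)) / _LN2
    return max(te, 0.0)


def simulate_nonlinear_pair(
    n_timepoints: int,
    seed: int,
    coupling: float = 0.8,
    noise_sd: float = 0.3,
) -> TimeSeriesPanel:
    """Two series coupled through a quadratic lag-1 nonlinearity.

    ``x`` is white Gaussian noise and ``y_t = c (x_{t-1}^2 - 1) + eta_t``.
    The coupling is strong but every product moment E[x_s y_t] vanishes by
    symmetry, so Pearson correlation between the series is ~0 while transfer
    entropy x -> y is large — the canonical "nonlinear dependence that a
    linear metric misses" fixture.
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n_timepoints + 1)
    eta = rng.normal(scale=noise_sd, size=n_timepoints)
    y = coupling * (x[:-1] ** 2 - 1.0) + eta
    return TimeSeriesPanel(
        subject_id="nonlinear",
        data=np.vstack([x[1:], y]),
        node_ids=["src", "dst"],
        condition="other",
    )


@dataclass
class CohortSpec:
    """Recipe for a synthetic subject cohort with a planted flow-behavior link.

    Attributes
    ----------
    n_subjects : int
        Cohort size (>= 3; leave-one-out needs at least 3).
    panel_template : VarModel
        Shared coupling template; each subject receives an independent
        multiplicative Gaussian jitter of its entries.
    planted_weights : ndarray (n_groups x n_groups)
        Weight of each reduced flow cell in the behavior score.
    behavior_noise_sd : float
        Noise sd *relative to the sd of the planted signal* across subjects
        (absolute units when the planted signal is constant, e.g. null
        cohorts with all-zero weights).
    seed : int
        Master seed; everything downstream derives from it.
    coupling_jitter_sd : float
        Relative sd of the per-subject coupling jitter (default 10%).
    """

    n_subjects: int
    panel_template: VarModel
    planted_weights: np.ndarray
    behavior_noise_sd: float
    seed: int
    coupling_jitter_sd: float = 0.10

    def __post_init__(self) -> None:
        self.planted_weights = np.asarray(self.planted_weights, dtype=float)
        if self.n_subjects < 3:
            raise ValueError("a cohort needs at least 3 subjects (LOOCV)")
        if self.behavior_noise_sd < 0:
            raise ValueError("behavior_noise_sd must be >= 0")
        if self.coupling_jitter_sd < 0:
            raise ValueError("coupling_jitter_sd must be >= 0")


@dataclass
class SyntheticCohort:
    """Simulated cohort: panels, behavior, and the features that generated it."""

    panels: list[TimeSeriesPanel]
    behavior: np.ndarray
    features: np.ndarray  # n_subjects x n_groups^2, row-major reduced flows
    feature_labels: list[str]
    signal: np.ndarray  # noiseless planted component of behavior


def _jittered_model(
    template: VarModel, jitter_sd: float, rng: np.random.Generator
) -> VarModel:
    if jitter_sd == 0:
        return template
    coupling = template.coupling * (
        1.0 + rng.normal(0.0, jitter_sd, size=template.coupling.shape)
    )
    rho = float(np.max(np.abs(np.linalg.eigvals(coupling))))
    if rho >= 0.99:  # rare under 10% jitter; rescale rather than reject
        coupling *= 0.9 / rho
    return VarModel(coupling=coupling, noise_sd=template.noise_sd)


def simulate_cohort(
    spec: CohortSpec,
    scheme: GroupScheme,
    n_timepoints: int = DEFAULT_N_TIMEPOINTS,
    ksg_config: KsgConfig | None = None,
) -> SyntheticCohort:
    """Simulate a cohort and its planted behavior scores.

    Each subject's panel comes from an independently jittered copy of the
    template VAR; the subject's reduced information-flow matrix is computed
    by the real pipeline (KSG TE -> clip -> restricted max flow -> reduce),
    and behavior is ``sum(planted_weights * IF) + noise``.
    """
    template = spec.panel_template
    node_ids = [f"n{i:03d}" for i in range(template.n_nodes)]
    scheme.check_covers(node_ids)
    g = scheme.n_groups
    if spec.planted_weights.shape != (g, g):
        raise ValueError(
            f"planted_weights shape {spec.planted_weights.shape} does not match "
            f"{g} groups"
        )
    ksg_config = ksg_config or KsgConfig()
    master = np.random.SeedSequence(spec.seed & 0x7FFFFFFF)
    subject_seeds = master.spawn(spec.n_subjects)
    noise_rng = np.random.default_rng(master.spawn(1)[0])

    panels: list[TimeSeriesPanel] = []
    features = np.empty((spec.n_subjects, g * g))
    feature_labels: list[str] | None = None
    for s, ss in enumerate(subject_seeds):
        rng = np.random.default_rng(ss)
        model = _jittered_model(template, spec.coupling_jitter_sd, rng)
        panel_seed = int(rng.integers(2**31))
        panel = simulate_var_panel(
            model,
            n_timepoints,
            seed=panel_seed,
            subject_id=f"sub{s:03d}",
            condition="task",
            node_ids=node_ids,
        )
        panels.append(panel)
        te_sparse = sparsify_te_matrix(build_te_matrix(panel, ksg_config))
        if_red = reduce_if_matrix(
            compute_full_if_matrix(te_sparse, scheme, restricted=True), scheme
        )
        vec, feature_labels = flatten_features(if_red)
        features[s] = vec

    signal = features @ spec.planted_weights.ravel(order="C")
    scale = float(np.std(signal))
    if scale == 0.0:
        scale = 1.0  # null cohort: noise sd is absolute
    behavior = signal + noise_rng.normal(
        0.0, spec.behavior_noise_sd * scale, size=spec.n_subjects
    )
    return SyntheticCohort(
        panels=panels,
        behavior=behavior,
        features=features,
        feature_labels=feature_labels,
        signal=signal,
    )


def cohort_template(
    n_nodes: int = 12,
    n_groups: int = 4,
    seed: int = 0,
    spectral_radius: float = 0.6,
    noise_sd: float = 1.0,
) -> tuple[VarModel, GroupScheme]:
    """Default cohort template: block-structured coupling over contiguous groups.

    Within-group chain couplings plus one cross-group link per adjacent group
    pair, rescaled to the requested spectral radius.  Gives every group-pair
    flow cell a nonzero, subject-variable value once per-subject jitter is
    applied.
    """
    if n_nodes < n_groups:
        raise ValueError("need at least one node per group")
    node_ids = [f"n{i:03d}" for i in range(n_nodes)]
    scheme = GroupScheme.contiguous(node_ids, n_groups)
    rng = np.random.default_rng(seed)
    coupling = np.zeros((n_nodes, n_nodes))
    bounds = np.linspace(0, n_nodes, n_groups + 1).astype(int)
    for gidx in range(n_groups):
        lo, hi = bounds[gidx], bounds[gidx + 1]
        for i in range(lo, hi):  # within-group ring
            j = lo + (i - lo + 1) % (hi - lo)
            if i != j:
                coupling[i, j] = 0.5 + 0.1 * rng.standard_normal()
        # one directed link to the next group
        nxt_lo = bounds[(gidx + 1) % n_groups]
        coupling[lo, nxt_lo] = 0.4 + 0.1 * rng.standard_normal()
    rho = float(np.max(np.abs(np.linalg.eigvals(coupling))))
    if rho > 0:
        coupling *= spectral_radius / rho
    return VarModel(coupling=coupling, noise_sd=noise_sd), scheme
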