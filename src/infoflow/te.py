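"""Pairwise transfer entropy with the Kraskov-Stogbauer-Grassberger estimator.

Transfer entropy TE(A -> C) measures how much the recent past of a source
process A improves prediction of the next value of a target process C beyond
what C's own past already provides:

    TE(A->C) = I( C_{n+1} ; A_n^{(l)} | C_n^{(k)} )

i.e. a conditional mutual information between the target's next sample, the
source's length-l history, and the target's length-k history.  For continuous
data we estimate it with the KSG k-nearest-neighbor construction (algorithm 1,
Chebyshev neighborhoods in the joint space):

    I(X;Y|Z) ~= psi(k) + < psi(n_z + 1) - psi(n_xz + 1) - psi(n_yz + 1) >

where n_* count the points of each marginal subspace falling strictly inside
the distance to the k-th joint-space neighbor.  The estimator is consistent
but has finite-sample variance, so estimates of a true-zero TE are frequently
(and legitimately) negative; clipping those to zero yields the "sparse"
matrix used as a capacity graph downstream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma

from .panel import TimeSeriesPanel

__all__ = [
    "KsgConfig",
    "TEMatrix",
    "ksg_transfer_entropy",
    "build_te_matrix",
    "sparsify_te_matrix",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class KsgConfig:
    """Parameters of the KSG transfer-entropy estimator.

    Attributes
    ----------
    k_neighbors : int
        Nearest-neighbor count of the KSG estimator (default 4).
    history_target : int
        Target (conditioning) history length k of C_n^{(k)} (default 1).
    history_source : int
        Source history length l of A_n^{(l)} (default 1).
    jitter_sd : float
        Amplitude of seeded tie-breaking noise, *relative* to each series'
        standard deviation (default 1e-8).  Zero disables jitter.
    units : {"bits", "nats"}
        Output units; estimation runs in nats and divides by ln 2 for bits.
    seed : int
        Seed of the jitter stream; estimates are deterministic given it.
    """

    k_neighbors: int = 4
    history_target: int = 1
    history_source: int = 1
    jitter_sd: float = 1e-8
    units: str = "bits"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.history_target < 1 or self.history_source < 1:
            raise ValueError("history lengths must be >= 1")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.units not in ("bits", "nats"):
            raise ValueError("units must be 'bits' or 'nats'")


@dataclass
class TEMatrix:
    """Directed node x node transfer-entropy matrix.

    ``values[i, j]`` is the estimated TE from node i to node j.  The diagonal
    is identically zero (self-TE is not defined here).  ``sparse`` marks a
    matrix whose negative estimates have been clipped to zero.
    """

    values: np.ndarray
    node_ids: list[str]
    sparse: bool = False
    units: str = "bits"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.node_ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be square and match node_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TE matrix contains non-finite values")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("TE matrix diagonal must be exactly 0")
        if self.sparse and np.any(self.values < 0):
            raise ValueError("sparse TE matrix must be nonnegative")
        self.node_ids = [str(n) for n in self.node_ids]


def _node_jitter_rng(seed: int, node_id: str) -> np.random.Generator:
    # Jitter stream tied to node identity (not row position) so that
    # permuting panel rows permutes the TE matrix exactly.
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(node_id.encode())])
    )


def _jittered(series: np.ndarray, jitter_sd: float, rng: np.random.Generator):
    if jitter_sd == 0:
        return series
    scale = series.std()
    if scale == 0:
        scale = 1.0
    return series + rng.normal(0.0, jitter_sd * scale, size=series.shape)


def _embed(series: np.ndarray, history: int, offset: int, n_rows: int) -> np.ndarray:
    """History embedding: column d holds series[offset-1-d : offset-1-d+n_rows]."""
    return np.column_stack(
        [series[offset - 1 - d : offset - 1 - d + n_rows] for d in range(history)]
    )


def _ksg_cmi_nats(x: np.ndarray, y: np.ndarray, z: np.ndarray, k: int) -> float:
    """KSG (algorithm 1) conditional mutual information I(x;y|z) in nats."""
    x = x.reshape(len(x), -1)
    y = y.reshape(len(y), -1)
    z = z.reshape(len(z), -1)
    joint = np.column_stack([x, y, z])
    n = joint.shape[0]
    if n <= k + 1:
        raise ValueError("series too short for the requested neighbor count")
    tree = cKDTree(joint)
    # distance to the k-th neighbor excluding the point itself
    eps = tree.query(joint, k=k + 1, p=np.inf)[0][:, -1]
    # strict inequality: count points at distance < eps
    radius = np.nextafter(eps, 0.0)
    xz = np.column_stack([x, z])
    yz = np.column_stack([y, z])
    n_xz = cKDTree(xz).query_ball_point(xz, radius, p=np.inf, return_length=True) - 1
    n_yz = cKDTree(yz).query_ball_point(yz, radius, p=np.inf, return_length=True) - 1
    n_z = cKDTree(z).query_ball_point(z, radius, p=np.inf, return_length=True) - 1
    return float(
        digamma(k)
        + np.mean(digamma(n_z + 1) - digamma(n_xz + 1) - digamma(n_yz + 1))
    )


def _te_from_series(source, target, config: KsgConfig) -> float:
    m = max(config.history_target, config.history_source)
    n_rows = len(target) - m
    if n_rows <= config.k_neighbors + 1:
        raise ValueError(
            f"series of length {len(target)} too short for histories "
            f"({config.history_target},{config.history_source}) and "
            f"k={config.k_neighbors}"
        )
    x = target[m:]
    z = _embed(target, config.history_target, m, n_rows)
    y = _embed(source, config.history_source, m, n_rows)
    te = _ksg_cmi_nats(x, y, z, config.k_neighbors)
    return te / _LN2 if config.units == "bits" else te


def ksg_transfer_entropy(source, target, config: KsgConfig | None = None) -> float:
    """Estimate TE(source -> target) for two equal-length series.

    The returned value may be negative: the estimator has finite-sample
    variance around a true TE of (or near) zero.

    Parameters
    ----------
    source, target : 1-D arrays of equal length
    config : KsgConfig, optional
    """
    config = config or KsgConfig()
    source = np.asarray(source, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if source.shape != target.shape:
        raise ValueError("source and target must have equal length")
    if not (np.all(np.isfinite(source)) and np.all(np.isfinite(target))):
        raise ValueError("series contain non-finite values")
    if config.jitter_sd > 0:
        rng = np.random.default_rng(config.seed)
        source = _jittered(source, config.jitter_sd, rng)
        target = _jittered(target, config.jitter_sd, rng)
    return _te_from_series(source, target, config)


def build_te_matrix(panel: TimeSeriesPanel, config: KsgConfig | None = None) -> TEMatrix:
    """Populate the full directed TE matrix of a panel.

    Every ordered node pair (i, j), i != j, gets the KSG estimate of
    TE(node_i -> node_j); the diagonal is fixed at zero.  Jitter is applied
    once per node, seeded by node identity, so the result is independent of
    pair evaluation order and equivariant under node relabeling.
    """
    config = config or KsgConfig()
    n = panel.n_nodes
    # jitter each node series once, tied to its id
    data = np.empty_like(panel.data)
    for i, node in enumerate(panel.node_ids):
        data[i] = _jittered(
            panel.data[i], config.jitter_sd, _node_jitter_rng(config.seed, node)
        )
    no_jitter = replace(config, jitter_sd=0.0)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            try:
                values[i, j] = _te_from_series(data[i], data[j], no_jitter)
            except ValueError as exc:
                raise ValueError(
                    f"TE({panel.node_ids[i]} -> {panel.node_ids[j]}): {exc}"
                ) from exc
    return TEMatrix(values=values, node_ids=list(panel.node_ids), sparse=False,
                    units=config.units)


def sparsify_te_matrix(full: TEMatrix) -> TEMatrix:
    """Clip negative TE estimates to zero, producing the sparse matrix.

    Negative estimates are finite-sample artifacts (true TE is nonnegative),
    so they are treated as absent edges.  Idempotent.
    """
    return TEMatrix(
        values=np.maximum(full.values, 0.0),
        node_ids=list(full.node_ids),
        sparse=True,
        units=full.units,
    )
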