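"""Connectome-based predictive modeling (CPM) over information-flow features.

Pipeline (applied per training set, and re-applied inside every
cross-validation fold so no test information leaks into fitting):

1. *Selection* — keep flow cells whose Spearman rank correlation with the
   behavior score is significant at ``alpha`` (two-sided asymptotic t test);
   optionally drop, beforehand, cells correlated with any nuisance covariate
   (e.g. head-motion summaries).
2. *Aggregation* — PCA (centered, unscaled: flows share units of bits) on the
   selected cells; the component count is tuned by an inner leave-one-out
   loop, scoring candidate counts by the Spearman correlation of their
   held-out predictions, smallest count on ties.
3. *Regression* — ordinary least squares of behavior on component scores.
4. *Standardization* — a novel subject's raw prediction is z-scored against
   the population of inner-LOOCV predictions of the training subjects.

Evaluation is leave-one-out Spearman correlation between predictions and
observed behavior, with significance from a permutation test that re-runs
the entire pipeline on shuffled behavior scores.

Implementation notes.  PCA component scores are centered and mutually
orthogonal, so OLS on the first ``c`` components decouples across
components; one SVD per fold yields held-out predictions for *every*
candidate count via a cumulative sum.  The permutation loop additionally
reuses a per-fold cache of feature ranks (features never change, only the
shuffled behavior does) and replaces per-iteration p-values by the
equivalent critical rank-correlation threshold.  These are exact
reformulations, not approximations; the slow, definition-following route is
kept in ``select_features``/``fit_cpm`` and the two are asserted equal in
the test suite.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import stdtr
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TrainedCpmModel",
    "CpmRegressor",
    "LoocvResult",
    "PermutationResult",
    "select_features",
    "exclude_covariate_correlated",
    "choose_n_components",
    "fit_cpm",
    "predict_cpm",
    "loocv_internal_validation",
    "permutation_test",
    "external_validation",
    "spearman_rho",
]

_EPS = np.finfo(float).eps


class EmptySelectionError(ValueError):
    """No feature passed the significance screen; consider relaxing alpha."""


class DegenerateModelError(ValueError):
    """The training predictions carry no variance; z-scoring is undefined."""


# ---------------------------------------------------------------------------
# rank-correlation primitives
# ---------------------------------------------------------------------------

def _rank1d(a: np.ndarray) -> np.ndarray:
    """Average ranks (1-based); argsort fast path, scipy fallback on ties."""
    order = np.argsort(a, kind="stable")
    sa = a[order]
    if np.any(sa[1:] == sa[:-1]):
        return stats.rankdata(a)
    ranks = np.empty(len(a))
    ranks[order] = np.arange(1, len(a) + 1, dtype=float)
    return ranks


def _rank2d(X: np.ndarray) -> np.ndarray:
    """Column-wise average ranks."""
    order = np.argsort(X, axis=0, kind="stable")
    sX = np.take_along_axis(X, order, axis=0)
    if np.any(sX[1:] == sX[:-1]):
        return stats.rankdata(X, axis=0)
    ranks = np.empty_like(X, dtype=float)
    np.put_along_axis(
        ranks, order,
        np.broadcast_to(np.arange(1, X.shape[0] + 1, dtype=float)[:, None], X.shape),
        axis=0,
    )
    return ranks


def spearman_rho(a, b) -> float:
    """Spearman rank correlation (average ranks for ties); nan if either
    argument is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ra, rb = _rank1d(a), _rank1d(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    na = np.sqrt(ra @ ra)
    nb = np.sqrt(rb @ rb)
    if na == 0 or nb == 0:
        return float("nan")
    return float((ra @ rb) / (na * nb))


def _critical_rho(n: int, alpha: float) -> float:
    """|rho| threshold equivalent to a two-sided asymptotic p <= alpha."""
    t_crit = stats.t.isf(alpha / 2.0, df=n - 2)
    return t_crit / np.sqrt(n - 2 + t_crit**2)


def _spearman_screen(X: np.ndarray, y: np.ndarray):
    """Vectorized per-column Spearman rho and two-sided asymptotic p-value.

    Constant columns get rho = 0, p = 1 and valid = False.  Matches
    ``scipy.stats.spearmanr``'s t-approximation column by column.
    """
    n = len(y)
    rX = _rank2d(X)
    ry = _rank1d(y)
    Xc = rX - rX.mean(axis=0)
    yc = ry - ry.mean()
    nx = np.sqrt((Xc**2).sum(axis=0))
    ny = np.sqrt(yc @ yc)
    valid = (nx > 0) & (ny > 0)
    rho = np.zeros(X.shape[1])
    if valid.any():
        rho[valid] = (Xc[:, valid].T @ yc) / (nx[valid] * ny)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stdtr(n - 2, -np.abs(t))
    p[~valid] = 1.0
    return rho, p, valid


def select_features(X: np.ndarray, y: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Boolean mask of features Spearman-correlated with behavior at ``alpha``.

    Constant features are never selected (their rank correlation is
    undefined).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if X.shape[0] != len(y):
        raise ValueError("features and behavior are misaligned")
    if len(y) < 4:
        raise ValueError("rank-correlation screening needs at least 4 subjects")
    _, p, valid = _spearman_screen(X, y)
    return valid & (p <= alpha)


def exclude_covariate_correlated(
    X: np.ndarray, covariates: np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """Keep-mask that is False for features correlated with ANY covariate.

    Applied before behavioral selection when nuisance covariates (e.g. motion
    summaries) are supplied.
    """
    X = np.asarray(X, dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    if covariates.shape[0] != X.shape[0]:
        raise ValueError("covariates and features are misaligned")
    keep = np.ones(X.shape[1], dtype=bool)
    for c in range(covariates.shape[1]):
        _, p, valid = _spearman_screen(X, covariates[:, c])
        keep &= ~(valid & (p <= alpha))
    return keep


# ---------------------------------------------------------------------------
# PCA + OLS engine
# ---------------------------------------------------------------------------

def _loo_simple_regression(v: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Held-out predictions of leave-one-out simple linear regression.

    Vectorized closed form for the single-feature (single-component) case:
    for each j, regress y on v using all points but j, predict point j.
    """
    n = len(v)
    sx, sy = v.sum(), y.sum()
    sxx, sxy = v @ v, v @ y
    m = n - 1
    mu = (sx - v) / m
    ybar = (sy - y) / m
    cxy = (sxy - v * y) - m * mu * ybar
    cxx = (sxx - v * v) - m * mu * mu
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(cxx > (np.abs(sxx) + 1.0) * m * _EPS, cxy / np.maximum(cxx, 1e-300), 0.0)
    return ybar + slope * (v - mu)


def _thin_svd(Xc: np.ndarray):
    """SVD of a centered matrix, with a cheap path for a single column."""
    if Xc.shape[1] == 1:
        nrm = float(np.sqrt(Xc[:, 0] @ Xc[:, 0]))
        if nrm == 0:
            return Xc, np.zeros(1), np.ones((1, 1))
        return Xc / nrm, np.array([nrm]), np.ones((1, 1))
    return np.linalg.svd(Xc, full_matrices=False)


def _inner_loocv_predictions(
    Xs: np.ndarray, y: np.ndarray, max_components: int
) -> np.ndarray:
    """Held-out predictions for every candidate component count.

    Returns ``preds`` of shape (max_components, n) where ``preds[c-1, j]``
    is subject j's prediction from a PCA(+OLS) model with c components
    fitted on the other n-1 subjects.  Components beyond a fold's PCA rank
    contribute nothing (their regression weight is zero), which realizes the
    rank cap min(c, fold rank).
    """
    n, s = Xs.shape
    if s == 1:
        # one feature -> one component; LOO regression in closed form
        return np.broadcast_to(
            _loo_simple_regression(Xs[:, 0], y), (max_components, n)
        ).copy()
    preds = np.empty((max_components, n))
    counts = np.arange(1, max_components + 1)
    idx = np.arange(n)
    for j in range(n):
        mask = idx != j
        Xtr = Xs[mask]
        ytr = y[mask]
        mu = Xtr.mean(axis=0)
        Xc = Xtr - mu
        u, sv, vt = _thin_svd(Xc)
        tol = sv[0] * max(Xc.shape) * _EPS if sv.size else 0.0
        ybar = ytr.mean()
        proj = (u * sv).T @ (ytr - ybar)  # scores^T (y - ybar)
        with np.errstate(divide="ignore", invalid="ignore"):
            coef = np.where(sv > tol, proj / np.maximum(sv**2, 1e-300), 0.0)
        contrib = ((Xs[j] - mu) @ vt.T) * coef
        cum = np.cumsum(contrib)
        take = np.minimum(counts, len(cum))
        preds[:, j] = ybar + cum[take - 1]
    return preds


def _choose_from_predictions(preds: np.ndarray, y: np.ndarray) -> tuple[int, np.ndarray]:
    rhos = np.array([spearman_rho(p, y) for p in preds])
    scores = np.where(np.isnan(rhos), -np.inf, rhos)
    best = int(np.argmax(scores))  # argmax returns the first (smallest) max
    return best + 1, rhos


def choose_n_components(Xs: np.ndarray, y: np.ndarray) -> int:
    """Inner-LOOCV choice of the PCA component count.

    Candidates run from 1 to min(n_subjects - 1, n_selected_features); each
    is scored by the Spearman correlation of its held-out predictions with
    behavior, and the smallest count achieving the maximum wins.
    """
    Xs = np.asarray(Xs, dtype=float)
    y = np.asarray(y, dtype=float)
    n, s = Xs.shape
    if n < 3:
        raise ValueError("component selection needs at least 3 subjects")
    if s < 1:
        raise EmptySelectionError("no selected features; relax alpha")
    c_max = min(n - 1, s)
    preds = _inner_loocv_predictions(Xs, y, c_max)
    c, _ = _choose_from_predictions(preds, y)
    return c


# ---------------------------------------------------------------------------
# model fitting / prediction
# ---------------------------------------------------------------------------

@dataclass
class TrainedCpmModel:
    """Frozen CPM: feature mask, PCA transform, regression, z-population stats."""

    selected_mask: np.ndarray
    pca_center: np.ndarray  # per selected feature
    pca_loadings: np.ndarray  # n_components x n_selected
    n_components: int
    regression_intercept: float
    regression_coefficients: np.ndarray  # per component
    train_pred_mean: float
    train_pred_sd: float
    selection_alpha: float = 0.05
    feature_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.selected_mask = np.asarray(self.selected_mask, dtype=bool)
        self.pca_center = np.asarray(self.pca_center, dtype=float)
        self.pca_loadings = np.asarray(self.pca_loadings, dtype=float)
        self.regression_coefficients = np.asarray(
            self.regression_coefficients, dtype=float
        )
        if self.pca_loadings.shape != (self.n_components, int(self.selected_mask.sum())):
            raise ValueError("loadings shape must be n_components x n_selected")
        if not self.train_pred_sd > 0:
            raise DegenerateModelError("train_pred_sd must be > 0")

    def to_dict(self) -> dict:
        return {
            "selected_mask": self.selected_mask.astype(int).tolist(),
            "pca_center": self.pca_center.tolist(),
            "pca_loadings": self.pca_loadings.tolist(),
            "n_components": int(self.n_components),
            "regression_intercept": float(self.regression_intercept),
            "regression_coefficients": self.regression_coefficients.tolist(),
            "train_pred_mean": float(self.train_pred_mean),
            "train_pred_sd": float(self.train_pred_sd),
            "selection_alpha": float(self.selection_alpha),
            "feature_labels": self.feature_labels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedCpmModel":
        return cls(
            selected_mask=np.asarray(d["selected_mask"], dtype=bool),
            pca_center=np.asarray(d["pca_center"], dtype=float),
            pca_loadings=np.asarray(d["pca_loadings"], dtype=float),
            n_components=int(d["n_components"]),
            regression_intercept=float(d["regression_intercept"]),
            regression_coefficients=np.asarray(
                d["regression_coefficients"], dtype=float
            ),
            train_pred_mean=float(d["train_pred_mean"]),
            train_pred_sd=float(d["train_pred_sd"]),
            selection_alpha=float(d.get("selection_alpha", 0.05)),
            feature_labels=d.get("feature_labels"),
        )


def fit_cpm(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    covariates: np.ndarray | None = None,
    feature_labels: list[str] | None = None,
) -> TrainedCpmModel:
    """Fit the full CPM on a training cohort.

    Order of operations: covariate exclusion (optional) -> Spearman selection
    -> inner-LOOCV component choice -> PCA + OLS on the whole training set.
    The z-scoring population (``train_pred_mean``/``sd``) comes from the
    inner-LOOCV predictions of every training subject at the chosen
    component count, each made by a model fitted without that subject.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be subjects x features aligned with y")
    mask = np.ones(X.shape[1], dtype=bool)
    if covariates is not None:
        mask &= exclude_covariate_correlated(X, covariates, alpha)
    sel = np.zeros(X.shape[1], dtype=bool)
    sel[mask] = select_features(X[:, mask], y, alpha)
    if not sel.any():
        raise EmptySelectionError(
            "no feature passed Spearman selection; relax alpha"
        )
    Xs = X[:, sel]
    n, s = Xs.shape
    c_max = min(n - 1, s)
    preds = _inner_loocv_predictions(Xs, y, c_max)
    n_comp, _ = _choose_from_predictions(preds, y)
    inner = preds[n_comp - 1]

    mu = Xs.mean(axis=0)
    Xc = Xs - mu
    u, sv, vt = _thin_svd(Xc)
    tol = sv[0] * max(Xc.shape) * _EPS if sv.size else 0.0
    rank = int((sv > tol).sum())
    n_comp_eff = min(n_comp, rank) if rank else 1
    loadings = vt[:n_comp_eff]
    scores = Xc @ loadings.T
    design = np.column_stack([np.ones(n), scores])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)

    sd = float(np.std(inner, ddof=1))
    if not sd > 0:
        raise DegenerateModelError(
            "inner-LOOCV training predictions are constant; z-scoring undefined"
        )
    return TrainedCpmModel(
        selected_mask=sel,
        pca_center=mu,
        pca_loadings=loadings,
        n_components=n_comp_eff,
        regression_intercept=float(beta[0]),
        regression_coefficients=beta[1:],
        train_pred_mean=float(np.mean(inner)),
        train_pred_sd=sd,
        selection_alpha=alpha,
        feature_labels=feature_labels,
    )


def predict_cpm(model: TrainedCpmModel, X: np.ndarray):
    """Apply a frozen CPM: raw predictions and their training-population z-scores.

    No refitting occurs; the training-set PCA transform and regression are
    applied as-is.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(model.selected_mask):
        raise ValueError(
            f"expected {len(model.selected_mask)} features, got {X.shape[1]}"
        )
    scores = (X[:, model.selected_mask] - model.pca_center) @ model.pca_loadings.T
    raw = model.regression_intercept + scores @ model.regression_coefficients
    z = (raw - model.train_pred_mean) / model.train_pred_sd
    return raw, z


# ---------------------------------------------------------------------------
# leave-one-out engine (shared by validation and permutation testing)
# ---------------------------------------------------------------------------

@dataclass
class _Fold:
    test_index: int
    train_mask: np.ndarray
    Xtr: np.ndarray  # training rows, all features
    keep: np.ndarray  # feature indices surviving covariate exclusion
    rXc: np.ndarray  # centered column ranks of Xtr[:, keep]
    rX_norm: np.ndarray  # rank-column norms (0 for constant columns)


def _build_fold_cache(
    X: np.ndarray, covariates: np.ndarray | None, alpha: float
) -> list[_Fold]:
    n = X.shape[0]
    folds = []
    for i in range(n):
        tr = np.arange(n) != i
        Xtr = X[tr]
        keep = np.ones(X.shape[1], dtype=bool)
        if covariates is not None:
            keep = exclude_covariate_correlated(Xtr, covariates[tr], alpha)
        kidx = np.flatnonzero(keep)
        rX = _rank2d(Xtr[:, kidx]) if kidx.size else np.empty((n - 1, 0))
        rXc = rX - rX.mean(axis=0)
        folds.append(
            _Fold(
                test_index=i,
                train_mask=tr,
                Xtr=Xtr,
                keep=kidx,
                rXc=rXc,
                rX_norm=np.sqrt((rXc**2).sum(axis=0)),
            )
        )
    return folds


def _fold_predict(
    fold: _Fold, x_test: np.ndarray, y: np.ndarray, alpha: float, rho_crit: float
):
    """One fold of the full pipeline; returns (raw, z, sel_idx, c) or raises."""
    ytr = y[fold.train_mask]
    ry = _rank1d(ytr)
    ryc = ry - ry.mean()
    ny = np.sqrt(ryc @ ryc)
    if ny == 0:
        raise EmptySelectionError("behavior is constant in this fold")
    ok = fold.rX_norm > 0
    rho = np.zeros(len(fold.keep))
    rho[ok] = (fold.rXc[:, ok].T @ ryc) / (fold.rX_norm[ok] * ny)
    sel_local = np.flatnonzero(ok & (np.abs(rho) >= rho_crit))
    if sel_local.size == 0:
        raise EmptySelectionError("no feature passed Spearman selection")
    sel_idx = fold.keep[sel_local]
    Xs = fold.Xtr[:, sel_idx]
    m, s = Xs.shape
    preds = _inner_loocv_predictions(Xs, ytr, min(m - 1, s))
    c, _ = _choose_from_predictions(preds, ytr)
    inner = preds[c - 1]
    sd = float(np.std(inner, ddof=1))
    if not sd > 0:
        raise DegenerateModelError("constant inner predictions")
    mean = float(np.mean(inner))
    # final fold model, closed form (orthogonal centered scores)
    mu = Xs.mean(axis=0)
    Xc = Xs - mu
    u, sv, vt = _thin_svd(Xc)
    tol = sv[0] * max(Xc.shape) * _EPS if sv.size else 0.0
    ybar = ytr.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.where(sv > tol, (u * sv).T @ (ytr - ybar) / np.maximum(sv**2, 1e-300), 0.0)
    cc = min(c, len(coef))
    raw = float(ybar + ((x_test[sel_idx] - mu) @ vt[:cc].T) @ coef[:cc])
    z = (raw - mean) / sd
    return raw, z, sel_idx, c


def _loocv_engine(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    cache: list[_Fold],
    on_empty_selection: str,
):
    n = len(y)
    rho_crit = _critical_rho(n - 1, alpha)
    raw = np.empty(n)
    z = np.empty(n)
    details = []
    for fold in cache:
        i = fold.test_index
        try:
            raw[i], z[i], sel_idx, c = _fold_predict(fold, X[i], y, alpha, rho_crit)
            details.append((sel_idx, c, False))
        except (EmptySelectionError, DegenerateModelError) as exc:
            if on_empty_selection == "error":
                raise EmptySelectionError(
                    f"fold with subject {i} left out: {exc}"
                ) from exc
            raw[i] = float(y[fold.train_mask].mean())
            z[i] = 0.0
            details.append((None, 0, True))
    return raw, z, details


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class FoldDetail:
    """Audit record of one leave-one-out fold."""

    test_index: int
    train_indices: np.ndarray
    selected_mask: np.ndarray | None
    n_components: int
    raw_prediction: float
    z_prediction: float
    empty_selection: bool
    train_checksum: str


@dataclass
class LoocvResult:
    z_scores: np.ndarray
    raw_predictions: np.ndarray
    rho: float
    folds: list[FoldDetail] = field(default_factory=list)


def _checksum(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


def loocv_internal_validation(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    covariates: np.ndarray | None = None,
    seed: int | None = None,
    on_empty_selection: str = "error",
) -> LoocvResult:
    """Leave-one-out validation with the full pipeline re-run per fold.

    Each subject is predicted exactly once by a model whose selection, PCA,
    component choice and regression saw only the other subjects.  Returns
    the Spearman correlation between z-scored predictions and behavior.

    ``on_empty_selection``: "error" aborts (naming the offending fold) when
    a fold's selection is empty; "mean" lets such folds predict the
    fold-training mean (z = 0), which keeps the statistic defined on null
    data — required for permutation testing.

    ``seed`` is accepted for interface symmetry; the procedure is
    deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 4:
        raise ValueError("LOOCV validation needs at least 4 subjects")
    if on_empty_selection not in ("error", "mean"):
        raise ValueError("on_empty_selection must be 'error' or 'mean'")
    cache = _build_fold_cache(X, covariates, alpha)
    raw, z, details = _loocv_engine(X, y, alpha, cache, on_empty_selection)
    folds = []
    for fold, (sel_idx, c, empty) in zip(cache, details):
        i = fold.test_index
        mask = None
        if sel_idx is not None:
            mask = np.zeros(X.shape[1], dtype=bool)
            mask[sel_idx] = True
        folds.append(
            FoldDetail(
                test_index=i,
                train_indices=np.flatnonzero(fold.train_mask),
                selected_mask=mask,
                n_components=c,
                raw_prediction=raw[i],
                z_prediction=z[i],
                empty_selection=empty,
                train_checksum=_checksum(X[fold.train_mask], y[fold.train_mask]),
            )
        )
    return LoocvResult(
        z_scores=z, raw_predictions=raw, rho=spearman_rho(z, y), folds=folds
    )


@dataclass
class PermutationResult:
    p_value: float
    observed_rho: float
    null_rhos: np.ndarray
    n_iterations: int


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    n_iterations: int = 1000,
    seed: int = 0,
    covariates: np.ndarray | None = None,
    alternative: str = "greater",
    on_empty_selection: str = "mean",
) -> PermutationResult:
    """Permutation significance of the LOOCV prediction correlation.

    Behavior scores are shuffled and the *entire* pipeline (selection,
    component choice, LOOCV) is re-run per iteration, preserving
    exchangeability.  ``p = (1 + #{null rho >= observed}) / (1 + n)`` for
    ``alternative='greater'`` ("as extreme as" in the trained direction);
    ``'two-sided'`` compares absolute values.  An undefined rho (constant
    predictions) counts as 0.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    cache = _build_fold_cache(X, covariates, alpha)

    def run(yv: np.ndarray) -> float:
        _, z, _ = _loocv_engine(X, yv, alpha, cache, on_empty_selection)
        r = spearman_rho(z, yv)
        return 0.0 if np.isnan(r) else r

    obs = run(y)
    rng = np.random.default_rng(seed)
    null = np.empty(n_iterations)
    for it in range(n_iterations):
        null[it] = run(rng.permutation(y))
    eps = 1e-12
    if alternative == "greater":
        exceed = np.sum(null >= obs - eps)
    else:
        exceed = np.sum(np.abs(null) >= abs(obs) - eps)
    p = (1.0 + exceed) / (1.0 + n_iterations)
    return PermutationResult(
        p_value=float(p), observed_rho=obs, null_rhos=null, n_iterations=n_iterations
    )


def external_validation(
    train_X: np.ndarray,
    train_y: np.ndarray,
    test_X: np.ndarray,
    alpha: float = 0.05,
    covariates: np.ndarray | None = None,
    test_y: np.ndarray | None = None,
):
    """Train once on the full training cohort, apply frozen to new subjects.

    Returns ``(z_scores, rho)``; ``rho`` is None unless ``test_y`` with at
    least two subjects is provided.  No test-set information enters fitting.
    """
    model = fit_cpm(train_X, train_y, alpha=alpha, covariates=covariates)
    _, z = predict_cpm(model, test_X)
    rho = None
    if test_y is not None and len(np.atleast_1d(test_y)) > 1:
        rho = spearman_rho(z, test_y)
    return z, rho


# ---------------------------------------------------------------------------
# sklearn estimator facade
# ---------------------------------------------------------------------------

class CpmRegressor(RegressorMixin, BaseEstimator):
    """Connectome-based predictive model as a scikit-learn regressor.

    Parameters
    ----------
    alpha : float, default 0.05
        Two-sided significance threshold of the Spearman feature screen
        (also used for optional covariate exclusion).

    Attributes (after ``fit``)
    --------------------------
    model_ : TrainedCpmModel
        The frozen pipeline (mask, PCA transform, regression, z stats).
    selected_mask_ : ndarray of bool
    n_components_ : int
    n_features_in_ : int

    Examples
    --------
    >>> reg = CpmRegressor(alpha=0.05).fit(X_train, y_train)
    >>> z = reg.predict_z(X_new)
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y, covariates=None, feature_labels=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.model_ = fit_cpm(
            X, y, alpha=self.alpha, covariates=covariates,
            feature_labels=feature_labels,
        )
        self.selected_mask_ = self.model_.selected_mask
        self.n_components_ = self.model_.n_components
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        self._check_fitted()
        raw, _ = predict_cpm(self.model_, X)
        return raw

    def predict_z(self, X):
        """Predictions standardized against the training z-population."""
        self._check_fitted()
        _, z = predict_cpm(self.model_, X)
        return z

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("CpmRegressor is not fitted yet; call fit first")
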