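"""End-to-end wiring: panels -> TE -> flow features -> CPM, plus a transformer
that drops into scikit-learn pipelines.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import io as ioutil
from .cpm import loocv_internal_validation, fit_cpm, permutation_test
from .flow import compute_full_if_matrix, flatten_features, reduce_if_matrix
from .panel import GroupScheme, TimeSeriesPanel
from .te import KsgConfig, build_te_matrix, sparsify_te_matrix

__all__ = ["InformationFlowExtractor", "panel_flow_features", "RunConfig", "run_pipeline"]


def panel_flow_features(
    panel: TimeSeriesPanel,
    scheme: GroupScheme | None,
    ksg_config: KsgConfig | None = None,
    variant: str = "reduced",
):
    """One subject's flattened information-flow feature vector.

    ``variant`` selects which flow matrix is flattened (row-major, diagonal
    included): "reduced" (group x group, the default and the best-performing
    choice), "full_restricted" or "full_unrestricted".
    """
    te_sparse = sparsify_te_matrix(build_te_matrix(panel, ksg_config))
    if variant == "full_unrestricted":
        ifm = compute_full_if_matrix(te_sparse, restricted=False)
    elif variant == "full_restricted":
        ifm = compute_full_if_matrix(te_sparse, scheme, restricted=True)
    elif variant == "reduced":
        full = compute_full_if_matrix(te_sparse, scheme, restricted=True)
        ifm = reduce_if_matrix(full, scheme)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return flatten_features(ifm)


class InformationFlowExtractor(TransformerMixin, BaseEstimator):
    """Transformer: list of TimeSeriesPanel -> subjects x features flow matrix.

    Stateless (``fit`` only records feature labels); composes with
    ``CpmRegressor`` in a scikit-learn ``Pipeline``.

    Parameters mirror the KSG estimator configuration plus the flow variant.
    """

    def __init__(
        self,
        scheme: GroupScheme | None = None,
        variant: str = "reduced",
        k_neighbors: int = 4,
        history_target: int = 1,
        history_source: int = 1,
        jitter_sd: float = 1e-8,
        units: str = "bits",
        seed: int = 0,
    ):
        self.scheme = scheme
        self.variant = variant
        self.k_neighbors = k_neighbors
        self.history_target = history_target
        self.history_source = history_source
        self.jitter_sd = jitter_sd
        self.units = units
        self.seed = seed

    def _config(self) -> KsgConfig:
        return KsgConfig(
            k_neighbors=self.k_neighbors,
            history_target=self.history_target,
            history_source=self.history_source,
            jitter_sd=self.jitter_sd,
            units=self.units,
            seed=self.seed,
        )

    def fit(self, X=None, y=None):
        self.n_features_in_ = None  # panels, not a feature matrix
        return self

    def transform(self, panels):
        rows = []
        labels = None
        for panel in panels:
            vec, labels = panel_flow_features(
                panel, self.scheme, self._config(), self.variant
            )
            rows.append(vec)
        self.feature_labels_ = labels
        return np.asarray(rows)

    def get_feature_names_out(self, input_features=None):
        if not hasattr(self, "feature_labels_"):
            raise AttributeError("call transform first")
        return np.asarray(self.feature_labels_, dtype=object)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    An explicit seed is mandatory: every stochastic stage derives from it
    and it is recorded in every output header.
    """

    output_dir: Path
    seed: int
    alpha: float = 0.05
    flow_variant: str = "reduced"
    permutation_iterations: int = 1000
    ksg: KsgConfig = field(default_factory=KsgConfig)
    scheme_path: Path | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("an explicit seed is required")
        self.output_dir = Path(self.output_dir)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: RunConfig,
    panels: list[TimeSeriesPanel],
    behavior: np.ndarray,
    scheme: GroupScheme | None = None,
    log=sys.stderr,
) -> dict:
    """Run TE -> flow -> CPM end to end and write all artifacts.

    Emits, under ``config.output_dir``: per-subject TE^full/TE^sparse and
    flow matrices, the feature table, the trained model, per-subject LOOCV
    predictions, the prediction correlation, the permutation p-value, and a
    manifest of parameters, versions and file checksums.
    """
    from . import __version__

    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    if scheme is None and config.scheme_path is not None:
        scheme = ioutil.read_group_scheme(config.scheme_path)
    if scheme is None and config.flow_variant != "full_unrestricted":
        raise ValueError("a group scheme is required for restricted/reduced flow")
    behavior = np.asarray(behavior, dtype=float)
    if len(behavior) != len(panels):
        raise ValueError("behavior vector misaligned with panels")

    ksg = KsgConfig(
        k_neighbors=config.ksg.k_neighbors,
        history_target=config.ksg.history_target,
        history_source=config.ksg.history_source,
        jitter_sd=config.ksg.jitter_sd,
        units=config.ksg.units,
        seed=config.seed,
    )
    stamp = {"seed": str(config.seed), "units": ksg.units,
             "k_neighbors": str(ksg.k_neighbors)}

    def stage(name):
        print(f"[infoflow] {name}", file=log)

    features = []
    labels = None
    stage("estimating transfer entropy and information flow")
    for panel in panels:
        te_full = build_te_matrix(panel, ksg)
        te_sparse = sparsify_te_matrix(te_full)
        ioutil.write_te_matrix(out / f"{panel.subject_id}.te_full.tsv", te_full, stamp)
        ioutil.write_te_matrix(out / f"{panel.subject_id}.te_sparse.tsv", te_sparse, stamp)
        if config.flow_variant == "full_unrestricted":
            ifm = compute_full_if_matrix(te_sparse, restricted=False)
        else:
            full = compute_full_if_matrix(te_sparse, scheme, restricted=True)
            ifm = full if config.flow_variant == "full_restricted" else \
                reduce_if_matrix(full, scheme)
        ioutil.write_if_matrix(out / f"{panel.subject_id}.if_{config.flow_variant}.tsv",
                               ifm, stamp)
        vec, labels = flatten_features(ifm)
        features.append(vec)
    X = np.asarray(features)

    stage("training CPM and running leave-one-out validation")
    model = fit_cpm(X, behavior, alpha=config.alpha, feature_labels=labels)
    ioutil.save_model(out / "model.json", model, {"seed": config.seed})
    loocv = loocv_internal_validation(X, behavior, alpha=config.alpha)
    with open(out / "predictions.tsv", "w") as fh:
        fh.write(_header_comment(stamp))
        fh.write("subject_id\traw\tz\n")
        for panel, r, z in zip(panels, loocv.raw_predictions, loocv.z_scores):
            fh.write(f"{panel.subject_id}\t{r:.17g}\t{z:.17g}\n")

    stage(f"permutation test ({config.permutation_iterations} iterations)")
    perm = permutation_test(
        X, behavior, alpha=config.alpha,
        n_iterations=config.permutation_iterations, seed=config.seed,
    )

    results = {
        "spearman_rho": loocv.rho,
        "permutation_p": perm.p_value,
        "n_subjects": len(panels),
        "n_features": X.shape[1],
        "n_components": model.n_components,
    }
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=1)
        fh.write("\n")

    manifest = {
        "infoflow_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "flow_variant": config.flow_variant,
        "permutation_iterations": config.permutation_iterations,
        "ksg": {
            "k_neighbors": ksg.k_neighbors,
            "history_target": ksg.history_target,
            "history_source": ksg.history_source,
            "jitter_sd": ksg.jitter_sd,
            "units": ksg.units,
        },
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return results


def _header_comment(stamp: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in stamp.items())
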