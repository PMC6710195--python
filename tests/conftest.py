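import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20259)


@pytest.fixture
def bivar_model():
    """One-way coupled bivariate VAR(1): node 0 drives node 1 with weight 0.5."""
    from infoflow import VarModel

    return VarModel(coupling=np.array([[0.0, 0.5], [0.0, 0.0]]), noise_sd=1.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Planted-effect cohort at unit-test scale (6 nodes, 3 groups, T=160)."""
    from infoflow.simulate import CohortSpec, cohort_template, simulate_cohort

    model, scheme = cohort_template(n_nodes=6, n_groups=3, seed=0)
    weights = np.zeros((3, 3))
    weights[0, 1] = 1.0
    spec = CohortSpec(
        n_subjects=8,
        panel_template=model,
        planted_weights=weights,
        behavior_noise_sd=0.0,
        seed=42,
    )
    return simulate_cohort(spec, scheme, n_timepoints=160), scheme
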