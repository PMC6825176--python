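import numpy as np
import pytest

from airscore.synthetic import SimulationConfig, simulate_cohort

#: Seven planted genera at per-SD log-hazards spanning HR 1.32..1.45,
#: the magnitude regime of the real-data associations.
PLANTED_SEVEN = {
    idx: float(np.log(hr))
    for idx, hr in zip(
        (2, 9, 17, 25, 33, 41, 55),
        np.exp(np.linspace(np.log(1.32), np.log(1.45), 7)),
    )
}

#: Two suppressed and two induced mediators (TNF-a, IL-1b down; CCL2, CCL17 up).
MEDIATOR_LOADINGS = tuple(
    [-0.30, -0.25, 0.30, 0.25] + [0.0] * 16
)


@pytest.fixture(scope="session")
def null_cohort():
    """No planted taxon, covariate or mediator effects; n=300, 30 genera."""
    return simulate_cohort(SimulationConfig(n_children=300, n_taxa=30, seed=101))


@pytest.fixture(scope="session")
def planted_cohort():
    """Seven informative genera among 60 plus a 4-mediator immune signature."""
    cfg = SimulationConfig(
        n_children=600,
        n_taxa=60,
        planted_taxa=dict(PLANTED_SEVEN),
        mediator_loadings=MEDIATOR_LOADINGS,
        covariate_effects={"paternal_asthma": 0.4, "older_siblings": -0.2},
        seed=202,
    )
    return simulate_cohort(cfg)
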