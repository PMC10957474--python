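import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mbdynamics.pipeline import run_longitudinal
from mbdynamics.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale synthetic cohort shared across tests (60 patients, 20 features)."""
    cfg = SimConfig.small(seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """Fitted longitudinal model on the small cohort, with the main contrast."""
    return run_longitudinal(
        small_sim.table, small_sim.meta, S=400, seed=3, contrast_names=("pfs12",)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
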