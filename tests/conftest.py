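import numpy as np
import pytest

from coldsim import SimulationConfig, build_synthetic_cohort
from coldsim.cohort import ExpressionCohort


@pytest.fixture(scope="session")
def cohort554():
    """The default synthetic TCGA-PRAD-like cohort (n = 554, fixed seed)."""
    return build_synthetic_cohort(n=554, rng_seed=1)


@pytest.fixture()
def tiny_cohort():
    return ExpressionCohort(samples=np.array([0.5, 1.0, 1.48, 2.0, 9.5]), source="loaded")


@pytest.fixture()
def tiny_config():
    """A 12x12 configuration small enough for fast step-level tests."""
    return SimulationConfig(
        grid_l=12,
        grid_w=12,
        n_tumour0=20,
        n_immune0=10,
        max_steps=60,
        base_seed=7,
        arm_id="tiny",
    )
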