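import numpy as np
import pytest

from pairprog import PipelineConfig, SimulationConfig, generate_paired_cohort


@pytest.fixture
def cfg():
    return PipelineConfig()


@pytest.fixture
def small_cfg():
    # permissive grouping for tiny toy inputs
    return PipelineConfig(min_group_size=2, min_group_fraction=0.05)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded cohort at generator defaults, shared across tests."""
    return generate_paired_cohort(SimulationConfig(seed=42))


def random_survival(rng, n, event_rate=0.7, scale=2.0):
    times = rng.exponential(scale, n)
    events = (rng.random(n) < event_rate).astype(float)
    return times, events
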