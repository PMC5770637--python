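import numpy as np
import pandas as pd
import pytest

from pulse15n.datasets import (
    load_published_deltas,
    load_published_recovery,
    published_means_as_measurements,
)
from pulse15n.simulate import SimulationConfig, simulate_tracer_fate


@pytest.fixture(scope="session")
def published_deltas() -> pd.DataFrame:
    return load_published_deltas()


@pytest.fixture(scope="session")
def published_recovery() -> pd.DataFrame:
    return load_published_recovery()


@pytest.fixture(scope="session")
def published_measurements() -> pd.DataFrame:
    return published_means_as_measurements()


@pytest.fixture(scope="session")
def noise_free_sim():
    """Deterministic tracer-fate simulation without any noise sources."""
    cfg = SimulationConfig(delta_noise_sd=0.0, rate_jitter_sd=0.0, seed=3)
    return simulate_tracer_fate(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    """Default-noise simulation for pipeline smoke checks."""
    return simulate_tracer_fate(SimulationConfig(seed=5))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20259)
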