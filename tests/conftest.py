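import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tddemux.pair_scoring import train_model
from tddemux.synthetic_data import SimConfig, make_pair_training_set, simulate_run

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def random_xic(rng: np.random.Generator, k: int = 64) -> np.ndarray:
    """Random truncated-Gaussian XIC with at least one positive entry."""
    center = rng.uniform(3, k - 2)
    sigma = rng.uniform(0.4, 4.0)
    peak = 10 ** rng.uniform(3, 7)
    cycles = np.arange(1, k + 1, dtype=float)
    x = peak * np.exp(-0.5 * ((cycles - center) / sigma) ** 2)
    x[x < 0.01 * peak] = 0.0
    if not x.any():
        x[int(round(center)) - 1] = peak
    return x


@pytest.fixture(scope="session")
def training_run():
    return simulate_run(SimConfig(seed=101))


@pytest.fixture(scope="session")
def trained_model(training_run):
    pairs = make_pair_training_set(training_run)
    return train_model(pairs, split_ratio=0.7, seed=0)


@pytest.fixture(scope="session")
def small_run():
    return simulate_run(
        SimConfig(seed=7, num_proteoforms=6, decoy_fragments_per_window=40)
    )
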