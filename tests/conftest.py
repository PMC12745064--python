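import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from seqchains import ChainSimConfig, SequenceSet, random_set, simulate_chain

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def two_seq_set() -> SequenceSet:
    return SequenceSet(["RGB", "RGY"])


@pytest.fixture
def small_random_set() -> SequenceSet:
    return random_set(n_seq=10, seq_len=12, seed=42)


@pytest.fixture(scope="session")
def sim_chain():
    """One 10-generation simulated chain with events, shared across tests."""
    return simulate_chain(ChainSimConfig(seed=7))


@pytest.fixture(scope="session")
def random_sets_200():
    """200 generation-zero-style random sets from one seeded stream."""
    rng = np.random.default_rng(np.random.SeedSequence([2024, 0]))
    return [random_set(rng=rng) for _ in range(200)]
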