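import pytest

from castesim import ModelConfig, SplitMix64, default_caste_params


@pytest.fixture
def params():
    return default_caste_params()


@pytest.fixture
def rng():
    return SplitMix64(12345)


@pytest.fixture
def small_config():
    """A 30-agent desk-scale configuration for fast deterministic runs."""
    return ModelConfig(
        caste_sizes=(10, 10, 10),
        ticks=10_000,
        seed=777,
        snapshot_interval=500,
    )


@pytest.fixture
def reduced_config():
    """300 agents, the reduced scale used for the stochastic property checks."""
    return ModelConfig(
        caste_sizes=(100, 100, 100),
        ticks=200_000,
        seed=11,
        snapshot_interval=10_000,
    )
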