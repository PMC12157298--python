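import pytest

from dynsit import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A 3-participant cohort: full protocol structure at reduced size."""
    return SimConfig(n_participants=3, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """The full default cohort (20 participants, 9600 frames), seed 42."""
    return generate_dataset(SimConfig(seed=42))
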