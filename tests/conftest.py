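import numpy as np
import pytest

from hybridblup import SimulationConfig, simulate_factorial


def tiny_config(**overrides):
    """A fast, fully-featured factorial for unit tests."""
    base = dict(
        n_markers=60,
        n_transcripts=40,
        n_causal=12,
        replicates_per_line=3,
        seed=11,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def tiny_dataset():
    return simulate_factorial(tiny_config())


@pytest.fixture(scope="session")
def study_dataset():
    """Study-structure factorial (7x14, h2=0.8, SCA:GCA=1.12) with a
    reduced predictor panel so cross-validation tests stay fast."""
    return simulate_factorial(
        SimulationConfig(n_markers=300, n_transcripts=200, n_causal=30, seed=5)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
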