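import pytest

from plasmidfate import synthetic_data as sd


@pytest.fixture(scope="session")
def default_config() -> sd.SyntheticExperimentConfig:
    return sd.SyntheticExperimentConfig(seed=11)


@pytest.fixture(scope="session")
def bundle(default_config) -> sd.ExperimentBundle:
    """One full simulated experiment, shared read-only across tests."""
    return sd.make_experiment(default_config)


@pytest.fixture(scope="session")
def small_config() -> sd.SyntheticExperimentConfig:
    """A cheap experiment for IO/CLI round-trips."""
    return sd.SyntheticExperimentConfig(n_replicates=2, seq_depth=5000, seed=7)
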