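import pytest

from wheatspec.synthetic import SyntheticConfig, generate_experiment


@pytest.fixture(scope="session")
def default_experiment():
    """One default synthetic experiment (seed 7): dataset + paired series."""
    return generate_experiment(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def default_dataset(default_experiment):
    return default_experiment[0]
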