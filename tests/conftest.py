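import numpy as np
import pytest

from ergochoice import ExperimentConfig, generate_bet_table, generate_dataset


@pytest.fixture(scope="session")
def couples():
    """One fixed 80-couple bet table shared across tests."""
    return generate_bet_table(seed=42)


@pytest.fixture(scope="session")
def default_config():
    return ExperimentConfig(seed=11)


@pytest.fixture(scope="session")
def responses(couples, default_config):
    """One fixed synthetic respondent-choice table (100 respondents x 80)."""
    return generate_dataset(default_config, couples)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
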