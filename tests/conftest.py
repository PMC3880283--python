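import pytest

from aidequity.config import FEModelSpec, GeneratorConfig
from aidequity.synthetic_data import (
    generate_birth_histories,
    generate_country_panel,
    generate_households,
)


@pytest.fixture(scope="session")
def small_config():
    """A fast 4-country configuration used by many module tests."""
    return GeneratorConfig(
        n_countries=4, households_per_survey=250, seed=42
    ).validate()


@pytest.fixture(scope="session")
def small_data(small_config):
    """(panel, households, births) generated once per session."""
    panel = generate_country_panel(small_config)
    households = generate_households(small_config)
    births = generate_birth_histories(households, panel, small_config)
    return panel, households, births


@pytest.fixture(scope="session")
def base_spec():
    return FEModelSpec()
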