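import warnings

import pytest

from taxalag import GeneratorConfig, generate, lag_table

SMALL_SIZES = {"Ecuador": 30, "India": 30, "Madagascar": 30, "Melanesia": 30}


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(region_sizes=dict(SMALL_SIZES), seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate(small_config)


@pytest.fixture(scope="session")
def small_records(small_dataset):
    return small_dataset[0]


@pytest.fixture(scope="session")
def small_truth(small_dataset):
    return small_dataset[1]


@pytest.fixture(scope="session")
def small_lags(small_records):
    return lag_table(small_records)


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size dataset under the study conditions (896 species)."""
    return generate(GeneratorConfig(seed=5))


@pytest.fixture(autouse=True)
def _quiet_statsmodels():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        yield
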