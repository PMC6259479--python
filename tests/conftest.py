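import pytest
from hypothesis import HealthCheck, settings

from soilmetals import datasets

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tissue_summaries():
    return datasets.load_tissue_summaries()


@pytest.fixture(scope="session")
def soil_summaries():
    return datasets.load_soil_summaries()


@pytest.fixture(scope="session")
def cf_table():
    return datasets.load_contamination_factors()


@pytest.fixture(scope="session")
def scheme():
    return datasets.load_lacatusu_scheme()


@pytest.fixture(scope="session")
def limits():
    return datasets.load_regulatory_limits()
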