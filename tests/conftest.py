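import pytest

from acetoflux import (
    build_reference_network,
    published_flux_table,
    strain_rates,
)


@pytest.fixture(scope="session")
def reconciled_model():
    return build_reference_network("reconciled")


@pytest.fixture(scope="session")
def as_printed_model():
    return build_reference_network("as_printed")


@pytest.fixture(scope="session")
def engineered_rates():
    return strain_rates("engineered")


@pytest.fixture(scope="session")
def original_rates():
    return strain_rates("original")


@pytest.fixture(scope="session")
def engineered_printed():
    return published_flux_table("engineered")


@pytest.fixture(scope="session")
def original_printed():
    return published_flux_table("original")
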