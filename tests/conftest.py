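import pytest
from hypothesis import HealthCheck, settings

from vdrmeta.core_data import fixture_table1

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_datasets():
    """Packaged study table keyed by SNP."""
    return {ds.snp: ds for ds in fixture_table1()}


@pytest.fixture(scope="session")
def rs1544410(fixture_datasets):
    return fixture_datasets["rs1544410"]


@pytest.fixture(scope="session")
def rs2228570(fixture_datasets):
    return fixture_datasets["rs2228570"]
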