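import pytest

from ntmcost.catalog import (
    WeightConfig,
    build_regimens,
    default_drug_catalog,
    default_fee_schedule,
)
from ntmcost.options import enumerate_options


@pytest.fixture(scope="session")
def drug_catalog():
    return default_drug_catalog()


@pytest.fixture(scope="session")
def drugs_by_abbrev(drug_catalog):
    return {d.abbreviation: d for d in drug_catalog}


@pytest.fixture(scope="session")
def regimens(drug_catalog):
    return {r.label: r for r in build_regimens(drug_catalog)}


@pytest.fixture(scope="session")
def fee_schedule():
    return default_fee_schedule()


@pytest.fixture(scope="session")
def fees_by_code(fee_schedule):
    return {f.code: f for f in fee_schedule}


@pytest.fixture(scope="session")
def published_options():
    return enumerate_options(mode="as_published")


@pytest.fixture(scope="session")
def weight_config():
    return WeightConfig()
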