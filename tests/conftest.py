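import pytest

from sandch4.gas_solubility import (
    AtmosphereSpec,
    SeawaterConditions,
    load_constants,
)


@pytest.fixture(scope="session")
def ch4_bunsen():
    return load_constants("ch4", "bunsen")


@pytest.fixture(scope="session")
def ch4_nmol_fit():
    return load_constants("ch4", "nmol-per-L-atm")


@pytest.fixture
def temperate_seawater():
    return SeawaterConditions.from_celsius(20.0, 35.0)


@pytest.fixture
def southern_atmosphere():
    return AtmosphereSpec.from_ppb(1800.0, sd_ppb=15.0)
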