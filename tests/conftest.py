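import pytest

from protoact.catalog import load_catalog
from protoact.labconfig import load_lab_config
from protoact.units import load_unit_table

TCA_TEXT = "Adjust to 10% TCA.\nIncubate at 30°C overnight."
BSA_RECONSTITUTE = (
    "Reconstitute bFGF and EGF with 0.1% BSA solution at a concentration of 100 μg/mL."
)
BSA_NOTE = "You will need 20 μL of each per 100 mL of complete medium."


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def config():
    return load_lab_config()


@pytest.fixture(scope="session")
def units():
    return load_unit_table()
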