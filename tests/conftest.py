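import pytest

from permkit import default_drug_panel, default_flow_cell


@pytest.fixture(scope="session")
def panel():
    return default_drug_panel()


@pytest.fixture(scope="session")
def panel_by_abbrev(panel):
    return {d.abbrev: d for d in panel}


@pytest.fixture(scope="session")
def cell():
    return default_flow_cell()
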