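import pytest

from ferriflux import thermo


@pytest.fixture
def cond_100um():
    """Built-in table conditions at 1e-4 acetate activity."""
    return thermo.table_conditions(1e-4)


@pytest.fixture
def cond_10mm():
    """Built-in table conditions at 1e-2 acetate activity."""
    return thermo.table_conditions(1e-2)


@pytest.fixture
def standard_cond():
    """All activities 1, pH 0 (unit proton activity)."""
    return thermo.ChemicalConditions(
        pH=0.0,
        activities={"HCO3-": 1.0, "Fe2+": 1.0, "CH4(aq)": 1.0, "acetate": 1.0},
    )
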