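import pytest

from methalk.carbonate_system import equilibrium_constants


@pytest.fixture(scope="session")
def ideal25():
    """Ideal-activity constants at 25 degC (gamma = 1, pKa 6.33 / 10.33)."""
    return equilibrium_constants(298.15, 0.0, "ideal")


@pytest.fixture(scope="session")
def davies01():
    """Davies-model constants at 25 degC, ionic strength 0.1 mol/L."""
    return equilibrium_constants(298.15, 0.1, "davies")
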