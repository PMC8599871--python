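import pytest

from bldna.core_model import PhaseParams, TetherSpec, Thermal
from bldna.phase_transition import default_config
from bldna.plectoneme import PlectonemeParams


@pytest.fixture
def thermal():
    return Thermal()  # kT = 4.28 pN nm (310 K)


@pytest.fixture
def tether():
    return TetherSpec(n_bp=4642)


@pytest.fixture
def phase_b():
    return PhaseParams(persistence_length=50.0, rise_per_bp=0.34)


@pytest.fixture
def phase_l():
    return PhaseParams(persistence_length=3.8, rise_per_bp=0.34 * 1.4)


@pytest.fixture
def wt_config():
    """Two-phase model with WT-like L form (L_pL = 3.8 nm, rise ratio 1.4)."""
    return default_config(lpl=3.8, ratio_l0=1.4)


@pytest.fixture
def dap_config():
    """Two-phase model with DAP-like L form (L_pL = 6.0 nm, rise ratio 1.4)."""
    return default_config(lpl=6.0, ratio_l0=1.4)


@pytest.fixture
def plect():
    return PlectonemeParams()
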