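import numpy as np
import pytest

from vclamp.amplifier import AmplifierSettings, CellProperties
from vclamp.ionic import GenericINa, ModelCell
from vclamp.protocols import build_step_protocol


@pytest.fixture(scope="session")
def model_cell_setup():
    """Model-cell validation rig: machine estimates match the true values."""
    settings = AmplifierSettings(
        alpha_R=0.0, alpha_P=0.0, Rs_est=30.0, Cm_est=22.0, Cp_est=4.0
    )
    cell = CellProperties(Rs=30.0, Cm=22.0, Cp=4.0)
    return settings, cell, ModelCell()


@pytest.fixture(scope="session")
def big_step_protocol():
    """The large model-cell validation step: −80 → 50 mV for 20 ms."""
    return build_step_protocol(-80.0, 20.0, 50.0, 20.0, 20.0)


@pytest.fixture(scope="session")
def ina_model():
    return GenericINa()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
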