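import numpy as np
import pytest

from gelswell.presets import pa_gel_params
from gelswell.thermo import (
    ElasticParams,
    FloryHugginsParams,
    GelThermoParams,
    IonicBath,
    SolventSpec,
)


@pytest.fixture(scope="session")
def solvent():
    return SolventSpec()


@pytest.fixture(scope="session")
def reference_chi():
    """Interaction parameters of the reference gel in 40 mM NaCl."""
    return FloryHugginsParams(chi0=0.448, chi1=0.21)


@pytest.fixture(scope="session")
def pa_params():
    """Reference polyacrylate-like parameter set."""
    return pa_gel_params()


@pytest.fixture(scope="session")
def nacl_bath():
    return IonicBath.monovalent(40.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
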