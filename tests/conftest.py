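import numpy as np
import pytest
from hypothesis import settings

from awcsim.engine import SimulationResult
from awcsim.model import AwcTransductionModel
from awcsim.params import ParameterSet
from awcsim.stimulus import StimulusProtocol

settings.register_profile("suite", deadline=None, max_examples=25,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref_params() -> ParameterSet:
    return ParameterSet.reference()


@pytest.fixture(scope="session")
def ref_model(ref_params) -> AwcTransductionModel:
    model = AwcTransductionModel(ref_params)
    model.equilibrate()
    return model


@pytest.fixture(scope="session")
def ref_simulations(ref_model):
    """All seven reference-protocol simulations of the reference fit."""
    return ref_model.simulate_all()


def make_trace(t, ca, resting_ca=0.05, protocol=None) -> SimulationResult:
    """Build a minimal SimulationResult carrying a synthetic calcium trace."""
    from awcsim.network import N_SPECIES, idx
    y = np.zeros((N_SPECIES + 1, t.size))
    y[idx("Ca")] = ca
    rest = np.zeros(N_SPECIES + 1)
    rest[idx("Ca")] = resting_ca
    protocol = protocol or StimulusProtocol(((10.0, 300.0),))
    return SimulationResult(np.asarray(t, float), y, protocol,
                            ParameterSet(), rest)
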