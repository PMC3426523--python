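"""awcsim: ODE model of odor signal transduction in the C. elegans AWC neuron.

The package simulates a cGMP-mediated transduction cascade in which odor
stimulation suppresses guanylate cyclase through an activated G protein;
odor removal releases the suppression and a calcium transient follows,
shaped by GCAP-mediated negative feedback, calmodulin buffering and a
calmodulin-activated phosphodiesterase.  A genetic-algorithm search
(`AwcTransductionModel.fit`) selects rate constants satisfying the
physiological requirements measured in calcium-imaging experiments, and a
noise module screens parameters and species for sensitivity to random
pulse-train perturbations.
"""

from .params import ParameterSet, fit_bounds
from .network import (SPECIES, STATE_VARS, Reaction, ConservedMoiety,
                      ReactionNetwork, build_network, mass_action_rate,
                      chemical_rhs, brute_force_rhs, idx)
from .membrane import (cng_open_fraction, cng_ca_flux, vdcc_ca_flux,
                       cax_efflux, membrane_rhs, gcamp_fluorescence)
from .stimulus import StimulusProtocol, reference_protocols
from .engine import (SolverOptions, SimulationResult, SolverError,
                     EquilibrationError, equilibrate, run_simulation)
from .metrics import RequirementReport, evaluate_requirements

__all__ = [
    "ParameterSet", "fit_bounds", "SPECIES", "STATE_VARS", "Reaction",
    "ConservedMoiety", "ReactionNetwork", "build_network", "mass_action_rate",
    "chemical_rhs", "brute_force_rhs", "idx", "cng_open_fraction",
    "cng_ca_flux", "vdcc_ca_flux", "cax_efflux", "membrane_rhs",
    "gcamp_fluorescence", "StimulusProtocol", "reference_protocols",
    "SolverOptions", "SimulationResult", "SolverError", "EquilibrationError",
    "equilibrate", "run_simulation", "RequirementReport",
    "evaluate_requirements",
    "AwcTransductionModel",
]

__version__ = "0.1.0"


def __getattr__(name):
    # deferred to avoid a hard import cycle at package import time
    if name == "AwcTransductionModel":
        from .model import AwcTransductionModel
        return AwcTransductionModel
    raise AttributeError(name)
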