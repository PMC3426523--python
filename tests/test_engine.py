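"""Equilibration and protocol integration."""

import numpy as np
import pytest

from awcsim.engine import (FevBudget, SolverOptions, equilibrate,
                           run_simulation)
from awcsim.network import build_network, idx, mass_action_rate
from awcsim.params import ParameterSet
from awcsim.stimulus import StimulusProtocol


@pytest.fixture(scope="module")
def params():
    return ParameterSet()


@pytest.fixture(scope="module")
def network(params):
    return build_network(params)


@pytest.fixture(scope="module")
def resting(network, params):
    return equilibrate(network, params)


class TestEquilibrate:
    def test_residuals_vanish_at_rest(self, network, params, resting):
        from awcsim.engine import full_rhs
        dy = full_rhs(0.0, resting, network, params)
        assert np.abs(np.delete(dy[:-1], idx("Odor"))).max() < 1e-9
        assert abs(dy[-1]) < 1e-6

    def test_fixed_point_property(self, network, params, resting):
        again = equilibrate(network, params, y0=resting.copy())
        assert np.abs(again[:-1] - resting[:-1]).max() < 1e-9

    def test_odor_free_species_strictly_positive(self, resting):
        """Every species not downstream of odor binding has a strictly
        positive resting concentration (odor-dependent forms decay to 0)."""
        from awcsim.network import SPECIES
        odor_dependent = {"Odor", "Odor_R", "Ga", "G_GCY", "G_GCY_GCAPa",
                          "G_GCY_GCAPb"}
        for name in SPECIES:
            if name not in odor_dependent:
                assert resting[idx(name)] > 0.0, name

    def test_budget_exhaustion_raises(self, network, params):
        from awcsim.engine import BudgetExceeded
        with pytest.raises(BudgetExceeded):
            equilibrate(network, params, budget=FevBudget(50))


class TestDetailedBalance:
    def test_reversible_skeleton_equilibrates_with_zero_fluxes(self, params):
        """With catalytic turnovers zeroed the remaining network is a tree of
        reversible bindings, so every individual reaction flux must vanish at
        equilibrium (detailed balance)."""
        net = build_network(params, catalytic=False)
        rest = equilibrate(net, params, chem_tol=1e-10)
        for rxn in net.reactions:
            flux = mass_action_rate(rxn, rest[:-1])
            assert abs(flux) < 1e-8, rxn.label


class TestRunSimulation:
    def test_no_pulse_protocol_stays_at_rest(self, network, params, resting):
        proto = StimulusProtocol((), duration=120.0)
        res = run_simulation(network, params, proto, resting_state=resting)
        rest_species = resting[:-1]
        scale = np.maximum(np.abs(rest_species), 1e-6)
        dev = np.abs(res.y[:-1] - rest_species[:, None]) / scale[:, None]
        assert dev.max() < 1e-3
        assert np.abs(res.v - resting[-1]).max() < 0.1

    def test_time_grid_strictly_increasing_and_fine_after_edges(self, network, params, resting):
        proto = StimulusProtocol(((10.0, 60.0),))
        res = run_simulation(network, params, proto, resting_state=resting)
        assert np.all(np.diff(res.t) > 0)
        for edge in proto.edges:
            window = (res.t >= edge) & (res.t <= edge + 60.0)
            assert np.diff(res.t[window]).max() <= 0.1 + 1e-9

    def test_conservation_along_trajectory(self, network, params, resting):
        proto = StimulusProtocol(((10.0, 60.0),))
        res = run_simulation(network, params, proto, resting_state=resting)
        assert res.conservation_drift(network) < 1e-6

    def test_tsv_roundtrip_columns(self, network, params, resting, tmp_path):
        import pandas as pd
        proto = StimulusProtocol(((10.0, 60.0),))
        res = run_simulation(network, params, proto, resting_state=resting)
        path = tmp_path / "trace.tsv"
        res.to_tsv(path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns[:2]) == ["time_s", "Odor"]
        assert list(df.columns[-3:]) == ["V_mV", "F_au", "dFoverF"]
        assert len(df) == res.t.size

    def test_invalid_solver_options_rejected(self):
        with pytest.raises(ValueError):
            SolverOptions(rtol=0.0)
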