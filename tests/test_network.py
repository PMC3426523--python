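"""Reaction-network structure, mass-action rates and conservation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import null_space

from awcsim.network import (N_SPECIES, SPECIES, Reaction, build_network,
                            brute_force_rhs, chemical_rhs, idx,
                            mass_action_rate)
from awcsim.params import ParameterSet
from awcsim.stimulus import StimulusProtocol


@pytest.fixture(scope="module")
def params():
    return ParameterSet()


@pytest.fixture(scope="module")
def network(params):
    return build_network(params)


def random_states(n, seed=0):
    rng = np.random.default_rng(seed)
    # concentrations spanning the physiological range, plus a voltage slot
    states = rng.uniform(0.0, 5.0, size=(n, N_SPECIES + 1))
    states[:, -1] = rng.uniform(-80.0, 20.0, size=n)
    return states


class TestStructure:
    def test_all_declared_moieties_lie_in_left_null_space(self, network):
        """Independent linear-algebra oracle: the stoichiometry matrix's left
        null space must contain every conserved-moiety weight vector."""
        ns = null_space(network.stoich.T)
        for moiety in network.moieties:
            w = moiety.weight_vector()
            # residual of w after projection onto the null space
            proj = ns @ (ns.T @ w)
            assert np.allclose(proj, w, atol=1e-10), moiety.name
        expected = {"total_R", "total_Ga", "total_GCY", "total_GCAPa",
                    "total_GCAPb", "total_PDE", "total_CaM"}
        assert {m.name for m in network.moieties} == expected

    def test_gcap_calcium_binding_removal_shrinks_moiety(self, params):
        """Without the calcium-inactivation step the Ca-bound GCAP forms
        drop out of the GCAP moieties (they become frozen species)."""
        net = build_network(params, omit_groups=(9,))
        gcapa = next(m for m in net.moieties if m.name == "total_GCAPa")
        members = {sp for sp, _ in gcapa.members}
        assert members == {"GCAPa", "GCY_GCAPa", "G_GCY_GCAPa", "GCY_GCAPa_GTP"}

    def test_missing_rate_constant_is_reported_by_name(self, params):
        broken = params.to_dict()
        del broken["K_p1_CaM_Ca"]
        with pytest.raises(KeyError, match="K_p1_CaM_Ca"):
            build_network(broken)

    def test_undeclared_species_rejected(self):
        with pytest.raises(KeyError, match="Unknown_X"):
            Reaction("bad", (("Unknown_X", 1),), (), 1.0)

    def test_nonpositive_stoichiometry_rejected(self):
        with pytest.raises(ValueError, match="stoichiometry"):
            Reaction("bad", (("Ca", 0),), (), 1.0)

    def test_negative_rate_constant_rejected(self):
        with pytest.raises(ValueError):
            Reaction("bad", (("Ca", 1),), (), -1.0)


class TestMassAction:
    def test_bimolecular_closed_form(self):
        rxn = Reaction("ab", (("Ca", 1), ("CaM", 1)), (("CaM_Ca1", 1),), kf=2.0)
        flux = mass_action_rate(rxn, {"Ca": 1.0, "CaM": 3.0, "CaM_Ca1": 7.0})
        assert flux == pytest.approx(6.0)

    def test_zero_reactant_gives_zero_flux(self):
        rxn = Reaction("ab", (("Ca", 1), ("CaM", 1)), (("CaM_Ca1", 1),), kf=2.0)
        assert mass_action_rate(rxn, {"Ca": 0.0, "CaM": 3.0, "CaM_Ca1": 0.0}) == 0.0

    def test_zero_order_supply_returns_kf(self):
        rxn = Reaction("supply", (), (("GTP", 1),), kf=0.25)
        state = dict.fromkeys(SPECIES, 0.0)
        assert mass_action_rate(rxn, state) == pytest.approx(0.25)

    def test_negative_concentration_rejected(self):
        rxn = Reaction("ab", (("Ca", 1),), (), kf=1.0)
        with pytest.raises(ValueError, match="negative"):
            mass_action_rate(rxn, {"Ca": -0.1})

    def test_reverse_term_subtracted(self):
        rxn = Reaction("ab", (("Ca", 1), ("CaM", 1)), (("CaM_Ca1", 1),),
                       kf=2.0, kr=0.5)
        flux = mass_action_rate(rxn, {"Ca": 1.0, "CaM": 3.0, "CaM_Ca1": 4.0})
        assert flux == pytest.approx(6.0 - 2.0)


class TestRhs:
    def test_vectorised_rhs_matches_brute_force_oracle(self, network):
        """The compiled flux path must agree with a naive per-reaction
        stoichiometric summation on 100 random states to 1e-12 relative."""
        for y in random_states(100, seed=3):
            fast = network.species_rhs(y)
            slow = brute_force_rhs(y, network)
            scale = np.maximum(np.abs(slow), 1.0)
            assert np.max(np.abs(fast - slow) / scale) < 1e-12

    def test_conserved_moiety_derivatives_vanish(self, network):
        for y in random_states(20, seed=4):
            dy = network.species_rhs(y)
            for moiety in network.moieties:
                assert abs(moiety.weight_vector() @ dy) < 1e-10

    def test_odor_clamped_in_chemical_rhs(self, network):
        proto = StimulusProtocol(((0.0, 60.0),))
        y = random_states(1, seed=5)[0]
        dy = chemical_rhs(30.0, y, network, proto)
        assert dy[idx("Odor")] == 0.0

    def test_binding_term_linear_in_each_reactant(self, network, params):
        """Doubling [Ga] doubles the Ga->G::GCY association flux."""
        rxn = next(r for r in network.reactions if r.label == "Ga_GCY")
        state = dict.fromkeys(SPECIES, 0.0)
        state.update(Ga=0.3, GCY=0.7, G_GCY=0.0)
        f1 = mass_action_rate(rxn, state)
        state["Ga"] = 0.6
        assert mass_action_rate(rxn, state) == pytest.approx(2 * f1)


@given(st.floats(0.0, 10.0), st.floats(0.0, 10.0), st.floats(0.01, 100.0))
def test_mass_action_flux_sign_follows_imbalance(a, b, kf):
    """Forward-only flux is nonnegative and zero iff a reactant is absent."""
    rxn = Reaction("ab", (("Ca", 1), ("CaM", 1)), (("CaM_Ca1", 1),), kf=kf)
    flux = mass_action_rate(rxn, {"Ca": a, "CaM": b, "CaM_Ca1": 0.0})
    assert flux >= 0.0
    assert (flux == 0.0) == (a == 0.0 or b == 0.0)
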