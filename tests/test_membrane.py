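"""Channel, extrusion and indicator flux relations."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from awcsim import membrane
from awcsim.params import ParameterSet


@pytest.fixture(scope="module")
def p():
    return ParameterSet()


class TestCngChannel:
    def test_half_maximal_at_ec50(self, p):
        assert membrane.cng_open_fraction(p["EC50_CNG"], p) == pytest.approx(0.5)

    def test_closed_without_cgmp(self, p):
        assert membrane.cng_open_fraction(0.0, p) == 0.0

    def test_hill_identity_at_twice_ec50(self, p):
        p2 = p.replace(n_CNG=2.0)
        assert membrane.cng_open_fraction(2 * p2["EC50_CNG"], p2) == pytest.approx(0.8)

    def test_flux_zero_at_reversal_and_without_cgmp(self, p):
        assert membrane.cng_ca_flux(0.0, -60.0, p) == 0.0
        assert membrane.cng_ca_flux(5.0, p["E_CNG"], p) == 0.0

    def test_flux_monotone_in_cgmp_below_reversal(self, p):
        cg = np.linspace(0.0, 20.0, 50)
        flux = [membrane.cng_ca_flux(c, -40.0, p) for c in cg]
        assert np.all(np.diff(flux) >= 0)
        assert all(f >= 0 for f in flux)

    @given(st.floats(0.0, 50.0))
    def test_open_fraction_bounded(self, cgmp):
        p = ParameterSet()
        f = membrane.cng_open_fraction(cgmp, p)
        assert 0.0 <= f <= 1.0


class TestVdcc:
    def test_zero_at_calcium_reversal(self, p):
        assert membrane.vdcc_ca_flux(p["E_Ca"], p) == 0.0

    def test_deep_hyperpolarisation_tail(self, p):
        V = p["V_half"] - 10 * p["s_V"]
        drive = (p["E_Ca"] - V) / (p["E_Ca"] + 80.0)
        assert membrane.vdcc_ca_flux(V, p) < 1e-4 * p["g_VDCC_max"] * drive

    def test_activation_monotone_in_voltage(self, p):
        vs = np.linspace(-80.0, 20.0, 60)
        act = [membrane.vdcc_activation(v, p) for v in vs]
        assert np.all(np.diff(act) > 0)


class TestCax:
    def test_no_efflux_without_calcium(self, p):
        assert membrane.cax_efflux(0.0, 0.1, p) == 0.0

    def test_no_efflux_with_zero_scalar(self, p):
        p0 = p.replace(Ef_CaX=0.0)
        assert membrane.cax_efflux(1.0, 1.0, p0) == 0.0

    def test_monotone_in_calcium_and_modulator(self, p):
        effl = [membrane.cax_efflux(c, 0.05, p) for c in np.linspace(0, 2, 40)]
        assert np.all(np.diff(effl) >= 0)
        assert membrane.cax_efflux(0.3, 0.2, p) >= membrane.cax_efflux(0.3, 0.1, p)


class TestGcamp:
    def test_fluorescence_midpoint_at_ec50(self, p):
        f = membrane.gcamp_fluorescence(p["EC50_GCaMP"], p)
        assert f == pytest.approx(p["F_min"] + 0.5 * (p["F_max"] - p["F_min"]))

    def test_fluorescence_floor_without_calcium(self, p):
        assert membrane.gcamp_fluorescence(0.0, p) == pytest.approx(p["F_min"])

    def test_dff_of_baseline_is_zero(self, p):
        f = membrane.gcamp_fluorescence(np.full(10, 0.05), p)
        dff = membrane.delta_f_over_f(f, float(f.mean()))
        assert np.allclose(dff, 0.0)

    def test_strictly_increasing(self, p):
        ca = np.linspace(0.0, 2.0, 50)
        f = membrane.gcamp_fluorescence(ca, p)
        assert np.all(np.diff(f) > 0)
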