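"""Membrane fluxes: CNG channel, voltage-dependent calcium channel, calcium
extrusion, membrane-potential dynamics and the G-CaMP fluorescence readout.

Channel kinetics are fast relative to the calcium changes in this neuron, so
channel fluxes are written directly as concentration fluxes (µM/s) given by
Hill activation terms multiplied by a normalised linear driving factor; the
conversion from charge to concentration is absorbed into the flux scalars.
Voltage obeys a current-balance equation built from the channel open
fractions, a linear leak fitted to give the measured −28 mV resting
potential, and effective conductances expressed in s⁻¹ (so that currents
carry units of mV/s).
"""

from __future__ import annotations

import numpy as np

from .network import idx

__all__ = [
    "cng_open_fraction",
    "cng_ca_flux",
    "vdcc_activation",
    "vdcc_ca_flux",
    "cax_efflux",
    "membrane_currents",
    "membrane_rhs",
    "gcamp_fluorescence",
    "delta_f_over_f",
]

_V_FLOOR = -80.0  # driving factors are normalised to 1 at this potential


def _drive(V: float, E_rev: float) -> float:
    """Normalised inward driving factor: 1 at −80 mV, 0 at the reversal."""
    return max(E_rev - V, 0.0) / (E_rev - _V_FLOOR)


def cng_open_fraction(cgmp: float, p) -> float:
    """Fraction of CNG channels opened by cGMP (Hill equation, in [0, 1])."""
    if cgmp <= 0.0:
        return 0.0
    ec50 = p["EC50_CNG"]
    if ec50 <= 0.0:  # reachable only under external-noise perturbation
        return 1.0
    x = (cgmp / ec50) ** p["n_CNG"]
    return x / (1.0 + x)


def cng_ca_flux(cgmp: float, V: float, p) -> float:
    """Calcium influx through CNG channels (µM/s, nonnegative for V < E_CNG)."""
    return p["g_CNG_max"] * cng_open_fraction(cgmp, p) * _drive(V, p["E_CNG"])


def vdcc_activation(V: float, p) -> float:
    """Sigmoidal voltage activation of the VDCC."""
    x = (V - p["V_half"]) / p["s_V"]
    # guard against overflow for extreme voltages
    if x > 40.0:
        return 1.0
    if x < -40.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-x))


def vdcc_ca_flux(V: float, p) -> float:
    """Calcium influx through the voltage-dependent calcium channel (µM/s)."""
    return p["g_VDCC_max"] * vdcc_activation(V, p) * _drive(V, p["E_Ca"])


def cax_saturation(cam_ca4: float, p) -> float:
    """Saturating CaM::Ca4 occupancy term modulating the extruder."""
    c = max(cam_ca4, 0.0)
    return c / (c + p["K_CaX_mod"])


def cax_efflux(ca: float, cam_ca4: float, p) -> float:
    """Calcium extrusion rate (µM/s, reported positive).

    Hill-type dependence on free calcium, multiplicatively enhanced by the
    fully loaded calmodulin complex.
    """
    if ca <= 0.0:
        return 0.0
    h = ca ** p["n_CaX"]
    hill = h / (h + p["K_CaX"] ** p["n_CaX"])
    return p["Ef_CaX"] * (1.0 + p["m_CaX"] * cax_saturation(cam_ca4, p)) * hill


def membrane_currents(V: float, cgmp: float, p) -> tuple[float, float, float]:
    """(I_CNG, I_VDCC, I_whole) in mV/s-equivalent units (g's are s⁻¹).

    I_whole is the parametric whole-cell current without stimulation: a
    linear leak whose reversal is chosen so that the fitted model rests at
    the measured potential.
    """
    i_cng = p["gc_CNG"] * cng_open_fraction(cgmp, p) * (V - p["E_CNG"])
    i_vdcc = p["gc_VDCC"] * vdcc_activation(V, p) * (V - p["E_Ca"])
    i_whole = p["g_leak"] * (V - p["E_leak"])
    return i_cng, i_vdcc, i_whole


def membrane_rhs(y: np.ndarray, p) -> tuple[float, float]:
    """Membrane contributions: (dV/dt in mV/s, dCa/dt in µM/s).

    The calcium term contains only channel influx and extrusion; calcium
    binding to calmodulin and the GCAPs is part of the chemical network.
    """
    V = y[-1]
    cgmp = y[idx("cGMP")]
    ca = y[idx("Ca")]
    cam4 = y[idx("CaM_Ca4")]
    i_cng, i_vdcc, i_whole = membrane_currents(V, cgmp, p)
    dv = -(i_cng + i_vdcc + i_whole) / p["C_m"]
    dca = p["alpha_conv"] * (cng_ca_flux(cgmp, V, p) + vdcc_ca_flux(V, p)) \
        - cax_efflux(ca, cam4, p)
    return dv, dca


def gcamp_fluorescence(ca, p):
    """G-CaMP fluorescence (a.u.) for free calcium via a Hill relation.

    Indicator constants default to the cell-free G-CaMP calibration
    (EC50 235 nM, Hill coefficient 3.3) and may be overridden in the
    parameter config.  Accepts scalars or arrays.
    """
    ca = np.maximum(np.asarray(ca, dtype=float), 0.0)
    x = (ca / p["EC50_GCaMP"]) ** p["n_GCaMP"]
    return p["F_min"] + (p["F_max"] - p["F_min"]) * x / (1.0 + x)


def delta_f_over_f(f: np.ndarray, f_baseline: float) -> np.ndarray:
    """ΔF/F relative to the pre-stimulus baseline fluorescence."""
    if f_baseline <= 0:
        raise ValueError("baseline fluorescence must be positive")
    return (np.asarray(f) - f_baseline) / f_baseline
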