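"""Simulation engine: assembles the full ODE system (chemistry + membrane),
equilibrates to rest and integrates stimulation protocols.

The network mixes fast binding steps (hundreds per second) with slow
accumulation (minutes), so a stiff-capable adaptive solver (LSODA) is the
default.  The odor species is clamped, which makes the right-hand side
discontinuous at stimulus edges; integration is therefore restarted at every
edge so that event boundaries are exact rather than interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import membrane
from .network import N_SPECIES, SPECIES, STATE_VARS, ReactionNetwork, idx
from .stimulus import StimulusProtocol

__all__ = [
    "SolverOptions",
    "SimulationResult",
    "SolverError",
    "EquilibrationError",
    "full_rhs",
    "equilibrate",
    "run_simulation",
]

_IDX_ODOR = idx("Odor")
_IDX_CA = idx("Ca")
_IDX_V = N_SPECIES  # V is the last state variable

# fine/coarse output sampling (s); fine within EDGE_WINDOW after a stimulus edge
_DT_FINE = 0.05
_DT_COARSE = 0.5
_EDGE_WINDOW = 60.0


class BudgetExceeded(RuntimeError):
    """Deterministic cap on right-hand-side evaluations was hit."""


class FevBudget:
    """Shared counter limiting total RHS evaluations across an evaluation.

    Gives parameter-search objectives a deterministic way to abandon
    pathological parameter sets (e.g. limit cycles that never equilibrate)
    without wall-clock dependence.
    """

    def __init__(self, limit: int):
        self.limit = int(limit)
        self.count = 0

    def spend(self) -> None:
        self.count += 1
        if self.count > self.limit:
            raise BudgetExceeded(f"RHS evaluation budget of {self.limit} exhausted")


def _counted(budget: "FevBudget | None"):
    if budget is None:
        return full_rhs

    def wrapped(t, y, *args):
        budget.spend()
        return full_rhs(t, y, *args)
    return wrapped


class SolverError(RuntimeError):
    """ODE solver failure, carrying the failure time and state snapshot."""

    def __init__(self, message: str, t: float, y: np.ndarray):
        super().__init__(message)
        self.t = t
        self.y = y


class EquilibrationError(RuntimeError):
    """Resting-state search did not converge; carries the residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class SolverOptions:
    rtol: float = 1e-7
    atol: float = 1e-10
    max_step: float = np.inf
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("solver tolerances must be positive")


@dataclass
class SimulationResult:
    """Time grid plus full state trajectory for one protocol run."""

    t: np.ndarray
    y: np.ndarray               # (n_state, n_t): species rows then V
    protocol: StimulusProtocol
    params: object
    resting_state: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    def species(self, name: str) -> np.ndarray:
        return self.y[idx(name)]

    @property
    def ca(self) -> np.ndarray:
        return self.y[_IDX_CA]

    @property
    def v(self) -> np.ndarray:
        return self.y[_IDX_V]

    @property
    def resting_ca(self) -> float:
        return float(self.resting_state[_IDX_CA])

    @property
    def fluorescence(self) -> np.ndarray:
        return membrane.gcamp_fluorescence(self.ca, self.params)

    @property
    def dff(self) -> np.ndarray:
        """ΔF/F against the mean fluorescence of the 10 s before the first pulse."""
        if self.protocol.pulses:
            onset = self.protocol.pulses[0][0]
            mask = (self.t >= onset - 10.0) & (self.t < onset)
        else:
            mask = slice(None)
        f = self.fluorescence
        return membrane.delta_f_over_f(f, float(np.mean(f[mask])))

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"time_s": self.t}
        for i, name in enumerate(SPECIES):
            cols[name] = self.y[i]
        cols["V_mV"] = self.v
        cols["F_au"] = self.fluorescence
        cols["dFoverF"] = self.dff
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.8g")

    def conservation_drift(self, network: ReactionNetwork) -> float:
        """Worst relative drift of any conserved moiety over the trajectory."""
        worst = 0.0
        for m in network.moieties:
            tot = m.evaluate(self.y.T)
            worst = max(worst, float(np.abs(tot - m.total).max() / m.total))
        return worst


def full_rhs(t: float, y: np.ndarray, network: ReactionNetwork, params,
             clamps: Sequence[tuple[int, Callable, Callable]] = ()) -> np.ndarray:
    """Complete time derivative for the (species..., V) state vector.

    ``clamps`` holds (species_index, value_fn, deriv_fn) triples for species
    whose concentration is externally imposed (the odor clamp is handled by
    the per-segment integration, species-noise clamps arrive here).
    """
    if clamps:
        y = y.copy()
        for i, value_fn, _ in clamps:
            y[i] = max(value_fn(t), 0.0)
    dy = np.empty(N_SPECIES + 1)
    dy[:N_SPECIES] = network.species_rhs(y)
    dv, dca = membrane.membrane_rhs(y, params)
    dy[_IDX_CA] += dca
    dy[_IDX_V] = dv
    dy[_IDX_ODOR] = 0.0
    for i, _, deriv_fn in clamps:
        dy[i] = deriv_fn(t)
    return dy


def _residual_norms(y: np.ndarray, network: ReactionNetwork, params) -> tuple[float, float]:
    dy = full_rhs(0.0, y, network, params)
    chem = float(np.abs(np.delete(dy[:N_SPECIES], _IDX_ODOR)).max())
    return chem, abs(float(dy[_IDX_V]))


# Species eliminated through conserved totals during the steady-state polish:
# each is the free (unbound) carrier of exactly one moiety.
_ELIMINATED = {
    "R": "total_R", "Ga_inactive": "total_Ga", "GCY": "total_GCY",
    "GCAPa": "total_GCAPa", "GCAPb": "total_GCAPb",
    "PDE": "total_PDE", "CaM": "total_CaM",
}
_FREE_IDX = [i for i, s in enumerate(STATE_VARS)
             if s not in _ELIMINATED and s != "Odor"]


def _polish_steady_state(y: np.ndarray, network: ReactionNetwork, params) -> np.ndarray:
    """Newton-polish the integrated state on the conservation manifold."""
    moieties = {m.name: m for m in network.moieties}

    def expand(x: np.ndarray) -> np.ndarray:
        full = np.zeros(N_SPECIES + 1)
        full[_FREE_IDX] = x
        for sp, total_name in _ELIMINATED.items():
            m = moieties[total_name]
            bound = sum(mult * full[idx(s)] for s, mult in m.members if s != sp)
            full[idx(sp)] = m.total - bound
        return full

    def fun(x: np.ndarray) -> np.ndarray:
        return full_rhs(0.0, expand(x), network, params)[_FREE_IDX]

    sol = root(fun, y[_FREE_IDX], method="hybr", tol=1e-13)
    if not sol.success:
        return y
    polished = expand(sol.x)
    if polished[:N_SPECIES].min() < -1e-9:
        return y  # reject unphysical roots
    polished[:N_SPECIES] = np.maximum(polished[:N_SPECIES], 0.0)
    return polished


def equilibrate(network: ReactionNetwork, params, opts: SolverOptions | None = None,
                y0: np.ndarray | None = None, max_time: float = 10_000.0,
                chem_tol: float = 1e-9, v_tol: float = 1e-6,
                budget: FevBudget | None = None) -> np.ndarray:
    """Integrate to rest with odor ≡ 0, then Newton-polish the fixed point.

    Raises :class:`EquilibrationError` if the residual criterion (max
    chemical derivative below ``chem_tol`` µM/s and voltage derivative below
    ``v_tol`` mV/s) cannot be met within ``max_time`` seconds of model time.
    """
    opts = opts or SolverOptions(rtol=1e-9, atol=1e-12)
    if y0 is None:
        y0 = np.append(network.initial_state(), -30.0)
    y = np.asarray(y0, dtype=float).copy()
    y[_IDX_ODOR] = 0.0
    t_elapsed = 0.0
    chunk = 500.0
    fun = _counted(budget)
    while t_elapsed < max_time:
        sol = solve_ivp(fun, (0.0, chunk), y, args=(network, params),
                        method=opts.method, rtol=opts.rtol, atol=opts.atol,
                        dense_output=False)
        if not sol.success:
            raise SolverError(f"equilibration solver failure: {sol.message}",
                              t_elapsed, y)
        y = sol.y[:, -1]
        t_elapsed += chunk
        y = _polish_steady_state(y, network, params)
        chem, dv = _residual_norms(y, network, params)
        if chem < chem_tol and dv < v_tol:
            y[:N_SPECIES] = np.maximum(y[:N_SPECIES], 0.0)
            return y
    chem, dv = _residual_norms(y, network, params)
    raise EquilibrationError(
        f"no steady state within {max_time:.0f} s "
        f"(residual {chem:.3g} uM/s, dV/dt {dv:.3g} mV/s)", max(chem, dv))


def _output_grid(protocol: StimulusProtocol, duration: float) -> np.ndarray:
    """Fine sampling (≤0.1 s) for 60 s after every stimulus edge, coarse
    elsewhere; resolves the sub-second rise after odor removal."""
    edges = protocol.edges
    pts = [0.0]
    t = 0.0
    while t < duration:
        fine = any(e <= t < e + _EDGE_WINDOW for e in edges)
        t = round(t + (_DT_FINE if fine else _DT_COARSE), 6)
        pts.append(min(t, duration))
    return np.unique(np.asarray(pts))


def run_simulation(network: ReactionNetwork, params, protocol: StimulusProtocol,
                   opts: SolverOptions | None = None,
                   resting_state: np.ndarray | None = None,
                   modifiers: Sequence = (),
                   budget: FevBudget | None = None) -> SimulationResult:
    """Integrate a stimulation protocol from the resting state.

    ``modifiers`` (see :mod:`awcsim.noise`) may add segment breakpoints,
    override parameter values per segment, and clamp species concentrations;
    the integration restarts at every breakpoint.
    """
    opts = opts or SolverOptions()
    if resting_state is None:
        resting_state = equilibrate(network, params)
    duration = float(protocol.duration)

    breaks = {0.0, duration}
    breaks.update(e for e in protocol.edges if 0.0 < e < duration)
    for mod in modifiers:
        breaks.update(b for b in mod.breakpoints(duration) if 0.0 < b < duration)
    seg_bounds = sorted(breaks)

    grid = _output_grid(protocol, duration)
    y = resting_state.copy()
    ts: list[np.ndarray] = [np.array([0.0])]
    ys: list[np.ndarray] = [y[:, None].copy()]
    nfev = 0

    base_net = network
    for t0, t1 in zip(seg_bounds[:-1], seg_bounds[1:]):
        t_mid = 0.5 * (t0 + t1)
        y[_IDX_ODOR] = protocol.odor_level(t_mid)

        overrides: dict[str, float] = {}
        clamps: list[tuple[int, Callable, Callable]] = []
        for mod in modifiers:
            overrides.update(mod.param_overrides(t_mid))
            clamps.extend(mod.species_clamps(t_mid))
        if overrides:
            seg_params = params.perturbed(**overrides)
            kin = [k for k in overrides if not _is_membrane_param(k)]
            seg_net = _rebuild(base_net, seg_params) if kin else base_net
        else:
            seg_params, seg_net = params, base_net
        for i, value_fn, _ in clamps:
            y[i] = max(value_fn(t0), 0.0)

        t_eval = grid[(grid > t0) & (grid <= t1)]
        t_eval = np.concatenate(([t0], t_eval)) if (t_eval.size == 0 or t_eval[0] > t0) else t_eval
        if t_eval[-1] < t1:
            t_eval = np.append(t_eval, t1)
        sol = solve_ivp(_counted(budget), (t0, t1), y, args=(seg_net, seg_params, clamps),
                        method=opts.method, rtol=opts.rtol, atol=opts.atol,
                        max_step=opts.max_step, t_eval=t_eval)
        if not sol.success:
            raise SolverError(f"solver failure at t={sol.t[-1] if sol.t.size else t0:.2f} s: "
                              f"{sol.message}", t0, y)
        nfev += sol.nfev
        y = sol.y[:, -1].copy()
        keep = sol.t > t0
        ts.append(sol.t[keep])
        ys.append(sol.y[:, keep])

    t_all = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    # clamp tiny negative excursions in reported traces
    tiny = (y_all[:N_SPECIES] > -1e-9) & (y_all[:N_SPECIES] < 0.0)
    y_all[:N_SPECIES][tiny] = 0.0
    result = SimulationResult(t_all, y_all, protocol, params, resting_state,
                              diagnostics={"nfev": nfev, "segments": len(seg_bounds) - 1})
    result.diagnostics["max_conservation_drift"] = result.conservation_drift(network)
    return result


def _is_membrane_param(name: str) -> bool:
    return name in {
        "EC50_CNG", "n_CNG", "g_CNG_max", "E_CNG", "g_VDCC_max", "V_half",
        "s_V", "E_Ca", "gc_CNG", "gc_VDCC", "g_leak", "E_leak", "C_m",
        "alpha_conv", "Ef_CaX", "K_CaX", "n_CaX", "m_CaX", "K_CaX_mod",
        "EC50_GCaMP", "n_GCaMP", "F_min", "F_max",
    }


def _rebuild(network: ReactionNetwork, params) -> ReactionNetwork:
    from .network import build_network
    return build_network(params)
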