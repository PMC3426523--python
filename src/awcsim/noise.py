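"""Noise-sensitivity screen: multiplicative random pulse trains applied to a
single parameter or species concentration, the 5 %-deviation classifier, and
pairwise synergy screening.

A pulse train perturbs its target to ``A(1+R)`` during each pulse, where
``A`` is the unperturbed value (fixed for a parameter; the instantaneous
noise-free trajectory value for a species) and ``R`` is uniform noise drawn
from [−m, m] per pulse for a magnitude ``m`` in [0, 1].  Pulse widths are
uniform on [1, 5] s, inter-pulse gaps uniform on [0.1, 10] s.  A target is
classified *sensitive* when the maximal deviation of [Ca²⁺] from the
noise-free trace exceeds 5 % of the resting [Ca²⁺] without odor stimulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import SimulationResult, SolverOptions, run_simulation
from .network import N_SPECIES, SPECIES, ReactionNetwork, idx
from .stimulus import StimulusProtocol

__all__ = [
    "NoiseTrain",
    "generate_pulse_train",
    "simulate_with_noise",
    "classify_sensitivity",
    "SensitivityResult",
    "sensitivity_screen",
    "pairwise_synergy",
    "SynergyReport",
]

WIDTH_RANGE_S = (1.0, 5.0)
GAP_RANGE_S = (0.1, 10.0)
SENSITIVITY_THRESHOLD = 0.05  # fraction of resting [Ca²⁺]


@dataclass(frozen=True)
class NoiseTrain:
    """A realised random pulse train for one target."""

    target: str                      # parameter name or species name
    base: float | None               # A for a parameter target; None for species
    magnitude: float                 # m in [0, 1]
    seed: int
    pulses: tuple[tuple[float, float, float], ...]  # (start_s, width_s, R)
    duration: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.magnitude <= 1.0:
            raise ValueError("noise magnitude must lie in [0, 1]")
        prev_end = None
        for start, width, r in self.pulses:
            if not WIDTH_RANGE_S[0] <= width <= WIDTH_RANGE_S[1]:
                raise ValueError(f"pulse width {width} outside {WIDTH_RANGE_S}")
            if start < 0:
                raise ValueError("pulse start before t=0")
            if prev_end is not None:
                gap = start - prev_end
                if gap < GAP_RANGE_S[0] - 1e-9 or gap > GAP_RANGE_S[1] + 1e-9:
                    raise ValueError(f"inter-pulse gap {gap} outside {GAP_RANGE_S}")
            if abs(r) > self.magnitude + 1e-12:
                raise ValueError("scaled noise R outside [-m, m]")
            prev_end = start + width

    @property
    def is_species(self) -> bool:
        return self.target in SPECIES

    def factor_at(self, t: float) -> float:
        """Multiplicative factor (1+R) at time ``t`` (1 between pulses)."""
        for start, width, r in self.pulses:
            if start <= t < start + width:
                return 1.0 + r
        return 1.0

    def edges(self) -> list[float]:
        out = []
        for start, width, _ in self.pulses:
            out.extend((start, start + width))
        return out


def generate_pulse_train(target: str, A: float | None, m: float, seed: int,
                         duration: float) -> NoiseTrain:
    """Draw a pulse train left-to-right until ``duration`` is covered.

    Deterministic for a given seed.  Heights are ``A(1+R)`` with R uniform on
    [−m, m] (the magnitude scales the width of the uniform noise).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    pulses: list[tuple[float, float, float]] = []
    t = float(rng.uniform(*GAP_RANGE_S))
    while t < duration:
        width = float(rng.uniform(*WIDTH_RANGE_S))
        r = float(rng.uniform(-1.0, 1.0)) * m
        pulses.append((t, width, r))
        t += width + float(rng.uniform(*GAP_RANGE_S))
    return NoiseTrain(target, A, m, seed, tuple(pulses), duration)


class _NoiseModifier:
    """Adapts one or more NoiseTrains to the engine's modifier interface."""

    def __init__(self, trains, baseline: SimulationResult):
        self.trains = list(trains)
        self._t = baseline.t
        self._traj = {}
        for tr in self.trains:
            if tr.is_species:
                ca = baseline.species(tr.target)
                self._traj[tr.target] = (ca, np.gradient(ca, baseline.t))

    def breakpoints(self, duration: float) -> list[float]:
        out: list[float] = []
        for tr in self.trains:
            out.extend(e for e in tr.edges() if e < duration)
        return out

    def param_overrides(self, t: float) -> dict[str, float]:
        out = {}
        for tr in self.trains:
            if not tr.is_species:
                f = tr.factor_at(t)
                if f != 1.0:
                    out[tr.target] = max(tr.base * f, 0.0)
        return out

    def species_clamps(self, t: float):
        clamps = []
        for tr in self.trains:
            if tr.is_species:
                f = tr.factor_at(t)
                if f != 1.0:
                    traj, dtraj = self._traj[tr.target]
                    tt = self._t
                    value_fn = (lambda s, traj=traj, tt=tt, f=f:
                                max(float(np.interp(s, tt, traj)) * f, 0.0))
                    deriv_fn = (lambda s, dtraj=dtraj, tt=tt, f=f:
                                float(np.interp(s, tt, dtraj)) * f)
                    clamps.append((idx(tr.target), value_fn, deriv_fn))
        return clamps


def simulate_with_noise(network: ReactionNetwork, params,
                        trains, protocol: StimulusProtocol,
                        baseline: SimulationResult,
                        opts: SolverOptions | None = None) -> SimulationResult:
    """Re-run a protocol with one or more noise trains applied.

    Parameter targets become piecewise-constant in time; species targets are
    clamped to the perturbed multiple of the instantaneous noise-free
    trajectory during each pulse and released at the pulse end.
    """
    if isinstance(trains, NoiseTrain):
        trains = [trains]
    for tr in trains:
        if not tr.is_species and tr.target not in params:
            raise KeyError(f"unknown noise target {tr.target!r}")
    mod = _NoiseModifier(trains, baseline)
    return run_simulation(network, params, protocol, opts,
                          resting_state=baseline.resting_state, modifiers=[mod])


@dataclass(frozen=True)
class SensitivityResult:
    target: str
    magnitude: float
    max_deviation_uM: float
    deviation_pct_of_rest: float
    sensitive: bool
    max_up_uM: float
    max_down_uM: float

    @property
    def upward_dominant(self) -> bool:
        return self.max_up_uM > self.max_down_uM


def classify_sensitivity(baseline: SimulationResult, perturbed: SimulationResult,
                         resting_ca: float, target: str = "",
                         magnitude: float = float("nan")) -> SensitivityResult:
    """Apply the 5 %-of-resting-[Ca²⁺] rule to a perturbed trace."""
    if resting_ca <= 0:
        raise ValueError("resting calcium must be positive")
    ca_p = np.interp(baseline.t, perturbed.t, perturbed.ca)
    if baseline.t[-1] > perturbed.t[-1] + 1e-6:
        raise ValueError("perturbed trace does not cover the baseline grid")
    delta = ca_p - baseline.ca
    up = float(max(delta.max(), 0.0))
    down = float(max(-delta.min(), 0.0))
    dev = max(up, down)
    return SensitivityResult(
        target=target, magnitude=magnitude, max_deviation_uM=dev,
        deviation_pct_of_rest=100.0 * dev / resting_ca,
        sensitive=dev > SENSITIVITY_THRESHOLD * resting_ca,
        max_up_uM=up, max_down_uM=down)


def sensitivity_screen(network: ReactionNetwork, params, target: str,
                       protocol: StimulusProtocol, baseline: SimulationResult,
                       magnitude: float = 1.0, seeds=range(5),
                       opts: SolverOptions | None = None) -> SensitivityResult:
    """Worst-case classification of one target over several noise seeds."""
    base_value = None if target in SPECIES else float(params[target])
    worst: SensitivityResult | None = None
    for seed in seeds:
        train = generate_pulse_train(target, base_value, magnitude, seed,
                                     float(protocol.duration))
        pert = simulate_with_noise(network, params, train, protocol, baseline, opts)
        res = classify_sensitivity(baseline, pert, baseline.resting_ca,
                                   target, magnitude)
        if worst is None or res.max_deviation_uM > worst.max_deviation_uM:
            worst = res
    return worst


@dataclass(frozen=True)
class SynergyReport:
    targets: tuple[str, str]
    magnitude: float
    deviation_single: tuple[float, float]   # each target alone (µM)
    deviation_combined: float               # both trains applied (µM)
    synergy_factor_threshold: float
    synergy: bool


def pairwise_synergy(network: ReactionNetwork, params, targets,
                     protocol: StimulusProtocol, baseline: SimulationResult,
                     magnitude: float = 1.0, seeds=(0, 1000),
                     synergy_factor: float = 1.5,
                     opts: SolverOptions | None = None) -> SynergyReport:
    """Apply independent noise trains to two targets, alone and combined.

    The synergy flag is raised when the combined maximal [Ca²⁺] deviation
    exceeds the larger single-target deviation by the declared factor.
    """
    a, b = targets
    if a == b:
        raise ValueError("need two distinct targets")
    dur = float(protocol.duration)
    trains = []
    for target, seed in zip((a, b), seeds):
        base_value = None if target in SPECIES else float(params[target])
        trains.append(generate_pulse_train(target, base_value, magnitude, seed, dur))
    singles = []
    for train in trains:
        pert = simulate_with_noise(network, params, train, protocol, baseline, opts)
        singles.append(classify_sensitivity(baseline, pert, baseline.resting_ca,
                                            train.target, magnitude).max_deviation_uM)
    pert = simulate_with_noise(network, params, trains, protocol, baseline, opts)
    combined = classify_sensitivity(baseline, pert, baseline.resting_ca,
                                    "+".join(targets), magnitude).max_deviation_uM
    return SynergyReport(
        targets=(a, b), magnitude=magnitude,
        deviation_single=(singles[0], singles[1]),
        deviation_combined=combined,
        synergy_factor_threshold=synergy_factor,
        synergy=combined > synergy_factor * max(singles))
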