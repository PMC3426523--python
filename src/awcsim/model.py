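"""Model facade: a fittable model object with results carrying estimates,
diagnostics and a summary table.

`AwcTransductionModel` wraps the reaction network, membrane fluxes and
simulation engine behind one object; its :meth:`fit` runs the genetic
algorithm and returns a :class:`GAFitResults` object in the style of the
statistical-modelling packages (``results.params``, ``results.summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import metrics, noise
from .engine import SolverOptions, SimulationResult, equilibrate, run_simulation
from .fitting import GAConfig, GAFitResult, ObjectiveWeights, objective, run_ga
from .network import ReactionNetwork, build_network, idx
from .params import ParameterSet, fit_bounds
from .stimulus import StimulusProtocol, reference_protocols

__all__ = ["AwcTransductionModel", "GAFitResults"]


class AwcTransductionModel:
    """ODE model of the AWC odor-transduction pathway for one parameter set.

    Parameters
    ----------
    params
        Complete :class:`~awcsim.params.ParameterSet`; defaults to the
        package defaults (the shipped reference fit uses
        :meth:`from_reference`).
    solver
        Integration options shared by all simulations of this instance.

    Examples
    --------
    >>> model = AwcTransductionModel.from_reference()
    >>> res = model.simulate("pulse5min")
    >>> report = model.check_requirements()
    >>> report.overall_pass
    True
    """

    def __init__(self, params: ParameterSet | None = None,
                 solver: SolverOptions | None = None):
        self.params = params or ParameterSet()
        self.solver = solver or SolverOptions()
        self._network: ReactionNetwork | None = None
        self._rest: np.ndarray | None = None

    # -- constructors -------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path, **kwargs) -> "AwcTransductionModel":
        return cls(ParameterSet.from_yaml(path), **kwargs)

    @classmethod
    def from_reference(cls, **kwargs) -> "AwcTransductionModel":
        """Model with the shipped GA-fitted reference parameter set."""
        return cls(ParameterSet.reference(), **kwargs)

    # -- lazy state ---------------------------------------------------------
    @property
    def network(self) -> ReactionNetwork:
        if self._network is None:
            self._network = build_network(self.params)
        return self._network

    def equilibrate(self, **kwargs) -> np.ndarray:
        """Resting state (odor ≡ 0); cached after the first call."""
        if self._rest is None:
            self._rest = equilibrate(self.network, self.params, **kwargs)
        return self._rest

    @property
    def resting_potential(self) -> float:
        return float(self.equilibrate()[-1])

    @property
    def resting_ca(self) -> float:
        return float(self.equilibrate()[idx("Ca")])

    # -- simulation ---------------------------------------------------------
    def simulate(self, protocol: StimulusProtocol | str) -> SimulationResult:
        if isinstance(protocol, str):
            try:
                protocol = reference_protocols()[protocol]
            except KeyError:
                raise KeyError(f"unknown protocol {protocol!r}; known: "
                               f"{sorted(reference_protocols())}") from None
        return run_simulation(self.network, self.params, protocol, self.solver,
                              resting_state=self.equilibrate())

    def simulate_all(self) -> dict[str, SimulationResult]:
        return {name: self.simulate(name) for name in reference_protocols()}

    def check_requirements(self, results: dict[str, SimulationResult] | None = None
                           ) -> metrics.RequirementReport:
        return metrics.evaluate_requirements(results or self.simulate_all())

    def score(self, **kwargs) -> float:
        """Penalty score of this parameter set (0 = feasible)."""
        return objective(self.params, **kwargs)

    # -- noise screen -------------------------------------------------------
    def noise_screen(self, target: str, magnitude: float = 1.0, seeds=range(5),
                     protocol: str = "pulse5min") -> noise.SensitivityResult:
        proto = reference_protocols()[protocol]
        baseline = self.simulate(proto)
        return noise.sensitivity_screen(self.network, self.params, target,
                                        proto, baseline, magnitude, seeds,
                                        self.solver)

    def synergy(self, targets, magnitude: float = 1.0, seeds=(0, 1000),
                protocol: str = "pulse5min") -> noise.SynergyReport:
        proto = reference_protocols()[protocol]
        baseline = self.simulate(proto)
        return noise.pairwise_synergy(self.network, self.params, targets,
                                      proto, baseline, magnitude, seeds,
                                      opts=self.solver)

    # -- fitting ------------------------------------------------------------
    def fit(self, bounds: dict[str, tuple[float, float]] | None = None,
            ga_config: GAConfig | None = None,
            weights: ObjectiveWeights = ObjectiveWeights()) -> "GAFitResults":
        """Genetic-algorithm search from this model's parameters as base.

        Parameters not named in ``bounds`` stay at their current values.
        Returns a results object; ``results.model()`` builds a new model
        from the best parameters found.
        """
        raw = run_ga(ga_config or GAConfig(), bounds or fit_bounds(),
                     base_params=self.params, weights=weights)
        return GAFitResults(raw)


@dataclass
class GAFitResults:
    """Results of a genetic-algorithm fit.

    Attributes
    ----------
    params : ParameterSet
        Best parameter set found.
    score : float
        Its penalty score (0 means every requirement and constraint holds).
    candidates : list[(score, ParameterSet)]
        All feasible (score-0) parameter sets encountered.
    history : list[float]
        Best score per generation (non-increasing).
    """

    _raw: GAFitResult
    params: ParameterSet = field(init=False)
    score: float = field(init=False)

    def __post_init__(self) -> None:
        self.params = self._raw.best_params
        self.score = self._raw.best_score

    @property
    def candidates(self):
        return self._raw.candidates

    @property
    def history(self):
        return self._raw.history

    @property
    def feasible(self) -> bool:
        return self._raw.feasible

    def model(self, rank: int = 0) -> AwcTransductionModel:
        """Model built from the best (or rank-th feasible) candidate."""
        if rank == 0 and not self.candidates:
            return AwcTransductionModel(self.params)
        return AwcTransductionModel(self.candidates[rank][1])

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        cfg = self._raw.config
        lines = [
            "AWC transduction model — genetic-algorithm fit",
            "=" * 54,
            f"{'population':<28}{cfg.population:>10}",
            f"{'generations':<28}{len(self.history) - 1:>10}",
            f"{'objective evaluations':<28}{self._raw.evaluations:>10}",
            f"{'seed':<28}{cfg.seed:>10}",
            f"{'best score':<28}{self.score:>10.4f}",
            f"{'feasible candidates':<28}{len(self.candidates):>10}",
            "-" * 54,
            f"{'parameter':<24}{'estimate':>14}{'bounds':>16}",
        ]
        for name in sorted(self._raw.bounds):
            lo, hi = self._raw.bounds[name]
            lines.append(f"{name:<24}{self.params[name]:>14.5g}"
                         f"  [{lo:.3g}, {hi:.3g}]")
        lines.append("=" * 54)
        return "\n".join(lines)
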