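"""Model parameters: rate constants, totals, membrane and indicator constants.

All concentrations are in µM, time in s.  Rate constants are s⁻¹ for
unimolecular and (µM·s)⁻¹ for bimolecular steps; zero-order supply terms are
µM/s.  Membrane potential is in mV.

Naming convention follows the symbols used for this pathway where they have
printed names (``K_m1_GTPsupp`` for the first-order GTP removal constant,
``EC50_CNG``, ``n_CNG``, ``Ef_CaX`` for the cyclic-nucleotide-gated channel
and the calcium extruder, ``K_p1_PDEactive`` for the catalytic constant of
calmodulin-activated phosphodiesterase, and the ``K_p1_CaM*`` family for the
stepwise calmodulin–calcium association constants).  ``K_p1_X_Y``/``K_m1_X_Y``
denote forward/reverse constants of the binding step X + Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import yaml


@dataclass(frozen=True)
class ParamSpec:
    """Declaration of a single model parameter."""

    default: float
    lower: float
    upper: float
    units: str = ""
    fit: bool = True  # whether the genetic algorithm may vary it
    log: bool = True  # whether the GA encodes it on a log10 scale


# ---------------------------------------------------------------------------
# Parameter registry.  Defaults form a working baseline parameterisation; the
# GA-fitted reference set ships separately in data/reference_fit.yaml
# (ParameterSet.reference()).  The (lower, upper) pairs are the outer limits
# the fitting module will ever search; physiologically anchored constants
# (reversal potentials, indicator calibration) are excluded from the search.
# ---------------------------------------------------------------------------
PARAM_SPECS: dict[str, ParamSpec] = {
    # -- step 1: odor + receptor -------------------------------------------
    "K_p1_odor_R": ParamSpec(5.0, 0.1, 100.0, "1/(uM s)"),
    "K_m1_odor_R": ParamSpec(2.0, 0.1, 100.0, "1/s"),
    # -- step 2: G-protein activation (receptor-catalysed) ------------------
    "K_p1_R_Ga": ParamSpec(10.0, 0.1, 100.0, "1/(uM s)"),
    "K_m1_Ga": ParamSpec(2.0, 0.1, 100.0, "1/s"),
    # -- step 3: Ga binding to the cyclase species --------------------------
    "K_p1_Ga_GCY": ParamSpec(2.0, 1e-3, 500.0, "1/(uM s)"),
    "K_m1_Ga_GCY": ParamSpec(4.0, 1e-3, 100.0, "1/s"),
    "K_p1_Ga_GCYGCAPa": ParamSpec(50.0, 1e-2, 500.0, "1/(uM s)"),
    "K_m1_Ga_GCYGCAPa": ParamSpec(1.0, 1e-3, 100.0, "1/s"),
    "K_p1_Ga_GCYGCAPb": ParamSpec(175.0, 1e-2, 500.0, "1/(uM s)"),
    "K_m1_Ga_GCYGCAPb": ParamSpec(0.35, 1e-3, 100.0, "1/s"),
    # -- step 4: cGMP synthesis --------------------------------------------
    "K_p1_GCY_GTP": ParamSpec(10.0, 1e-2, 100.0, "1/(uM s)"),
    "K_m1_GCY_GTP": ParamSpec(0.1, 1e-3, 100.0, "1/s"),
    "K_cat_GCY": ParamSpec(0.01, 1e-4, 100.0, "1/s"),
    "K_p1_GCYGCAPa_GTP": ParamSpec(10.0, 1e-2, 100.0, "1/(uM s)"),
    "K_m1_GCYGCAPa_GTP": ParamSpec(0.1, 1e-3, 100.0, "1/s"),
    "K_cat_GCYGCAPa": ParamSpec(2.0, 1e-3, 1000.0, "1/s"),
    "K_p1_GCYGCAPb_GTP": ParamSpec(10.0, 1e-2, 100.0, "1/(uM s)"),
    "K_m1_GCYGCAPb_GTP": ParamSpec(0.1, 1e-3, 100.0, "1/s"),
    "K_cat_GCYGCAPb": ParamSpec(8.0, 1e-3, 1000.0, "1/s"),
    # -- step 4: GTP supply/removal (unknown process) -----------------------
    "K_GTPsupp": ParamSpec(0.1, 1e-4, 10.0, "uM/s"),
    "K_m1_GTPsupp": ParamSpec(0.02, 1e-4, 10.0, "1/s"),
    # -- step 4': cGMP decomposition by PDE ---------------------------------
    "K_p1_PDE_cGMP": ParamSpec(0.1, 1e-4, 100.0, "1/(uM s)"),
    "K_m1_PDE_cGMP": ParamSpec(0.2, 1e-3, 100.0, "1/s"),
    "K_cat_PDE": ParamSpec(0.05, 1e-4, 100.0, "1/s"),
    "K_p1_PDEa_cGMP": ParamSpec(5.0, 1e-3, 100.0, "1/(uM s)"),
    "K_m1_PDEa_cGMP": ParamSpec(0.5, 1e-3, 100.0, "1/s"),
    "K_p1_PDEactive": ParamSpec(15.0, 1e-2, 1000.0, "1/s"),
    # -- step 8: calmodulin-calcium buffering -------------------------------
    "K_p1_CaM_Ca": ParamSpec(10.0, 1e-2, 500.0, "1/(uM s)"),
    "K_m1_CaM_Ca": ParamSpec(20.0, 1e-2, 500.0, "1/s"),
    "K_p1_CaMCa_Ca": ParamSpec(10.0, 1e-2, 500.0, "1/(uM s)"),
    "K_m1_CaMCa_Ca": ParamSpec(10.0, 1e-2, 500.0, "1/s"),
    "K_p1_CaMCa2_Ca": ParamSpec(10.0, 1e-2, 500.0, "1/(uM s)"),
    "K_m1_CaMCa2_Ca": ParamSpec(5.0, 1e-2, 500.0, "1/s"),
    "K_p1_CaMCa3_Ca": ParamSpec(10.0, 1e-2, 500.0, "1/(uM s)"),
    "K_m1_CaMCa3_Ca": ParamSpec(1.0, 1e-2, 500.0, "1/s"),
    "K_p1_PDE_CaMCa4": ParamSpec(5.0, 1e-2, 500.0, "1/(uM s)"),
    "K_m1_PDE_CaMCa4": ParamSpec(1.0, 1e-3, 100.0, "1/s"),
    # -- step 9: GCAP inactivation by calcium, GCAP binding to the cyclase --
    "K_p1_GCAPa_Ca": ParamSpec(10.0, 1e-2, 500.0, "1/(uM s)"),
    "K_m1_GCAPa_Ca": ParamSpec(0.05, 1e-4, 100.0, "1/s"),
    "K_p1_GCAPb_Ca": ParamSpec(1.0, 1e-2, 500.0, "1/(uM s)"),
    "K_m1_GCAPb_Ca": ParamSpec(0.002, 1e-4, 100.0, "1/s"),
    "K_p1_GCY_GCAPa": ParamSpec(0.002, 1e-5, 10.0, "1/(uM s)"),
    "K_m1_GCY_GCAPa": ParamSpec(0.06, 1e-4, 100.0, "1/s"),
    "K_p1_GCY_GCAPb": ParamSpec(0.0016, 1e-5, 10.0, "1/(uM s)"),
    "K_m1_GCY_GCAPb": ParamSpec(0.15, 1e-4, 100.0, "1/s"),
    # -- conserved totals ---------------------------------------------------
    "total_R": ParamSpec(0.5, 0.01, 10.0, "uM"),
    "total_Ga": ParamSpec(2.0, 0.01, 10.0, "uM"),
    "total_GCY": ParamSpec(1.0, 0.01, 10.0, "uM"),
    "total_GCAPa": ParamSpec(1.0, 0.01, 10.0, "uM"),
    "total_GCAPb": ParamSpec(2.0, 0.01, 10.0, "uM"),
    "total_PDE": ParamSpec(0.5, 0.01, 10.0, "uM"),
    "total_CaM": ParamSpec(5.0, 0.01, 10.0, "uM"),
    # -- membrane / channel block ------------------------------------------
    "EC50_CNG": ParamSpec(4.0, 0.01, 10.0, "uM"),
    "n_CNG": ParamSpec(3.0, 1.0, 4.0, "", log=False),
    "g_CNG_max": ParamSpec(2.5, 1e-3, 100.0, "uM/s"),
    "E_CNG": ParamSpec(10.0, 10.0, 10.0, "mV", fit=False, log=False),
    "g_VDCC_max": ParamSpec(1.0, 1e-3, 100.0, "uM/s"),
    "V_half": ParamSpec(-10.0, -40.0, 10.0, "mV", fit=False, log=False),
    "s_V": ParamSpec(6.0, 2.0, 20.0, "mV", fit=False, log=False),
    "E_Ca": ParamSpec(60.0, 60.0, 60.0, "mV", fit=False, log=False),
    "gc_CNG": ParamSpec(2.0, 1e-3, 100.0, "1/s"),
    "gc_VDCC": ParamSpec(0.1, 1e-4, 10.0, "1/s"),
    "g_leak": ParamSpec(1.0, 1e-2, 100.0, "1/s"),
    "E_leak": ParamSpec(-34.0, -90.0, 0.0, "mV", log=False),
    "C_m": ParamSpec(1.0, 1.0, 1.0, "", fit=False, log=False),
    "alpha_conv": ParamSpec(1.0, 1.0, 1.0, "", fit=False, log=False),
    # -- calcium extrusion (CaX) -------------------------------------------
    "Ef_CaX": ParamSpec(2.5, 1e-3, 100.0, "uM/s"),
    "K_CaX": ParamSpec(0.2, 1e-3, 10.0, "uM"),
    "n_CaX": ParamSpec(2.0, 1.0, 4.0, "", log=False),
    "m_CaX": ParamSpec(2.0, 0.0, 10.0, "", log=False),
    "K_CaX_mod": ParamSpec(0.001, 1e-5, 1.0, "uM"),
    # -- G-CaMP indicator (cell-free calibration; overridable in config) ----
    "EC50_GCaMP": ParamSpec(0.235, 0.235, 0.235, "uM", fit=False, log=False),
    "n_GCaMP": ParamSpec(3.3, 3.3, 3.3, "", fit=False, log=False),
    "F_min": ParamSpec(1.0, 1.0, 1.0, "au", fit=False, log=False),
    "F_max": ParamSpec(5.5, 5.5, 5.5, "au", fit=False, log=False),
}

PARAM_NAMES: tuple[str, ...] = tuple(PARAM_SPECS)


class ParameterSet(Mapping[str, float]):
    """A complete set of model parameters.

    Behaves as an immutable-by-convention mapping with attribute access.
    Values can be overridden at construction or via :meth:`replace`.
    """

    __slots__ = ("_values",)

    def __init__(self, values: Mapping[str, float] | None = None, **overrides: float):
        base = {name: spec.default for name, spec in PARAM_SPECS.items()}
        for src in (values or {}), overrides:
            for key, val in src.items():
                if key not in PARAM_SPECS:
                    raise KeyError(f"unknown parameter {key!r}")
                base[key] = float(val)
        object.__setattr__(self, "_values", base)
        self.validate()

    # -- mapping / attribute protocol --------------------------------------
    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __getattr__(self, key: str) -> float:
        try:
            return self._values[key]
        except KeyError:
            raise AttributeError(key) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ParameterSet({len(self)} parameters)"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ParameterSet) and self._values == other._values

    # -- construction helpers ----------------------------------------------
    def replace(self, **overrides: float) -> "ParameterSet":
        return ParameterSet(self._values, **overrides)

    def perturbed(self, **overrides: float) -> "ParameterSet":
        """Replace without re-validation.

        External-noise experiments multiply parameters by (1+R) with R in
        [−1, 1], which may transiently leave the range a fitted set must
        satisfy (e.g. a Hill coefficient below 1); the flux functions remain
        well defined there.
        """
        new = object.__new__(ParameterSet)
        vals = dict(self._values)
        for key, val in overrides.items():
            if key not in PARAM_SPECS:
                raise KeyError(f"unknown parameter {key!r}")
            vals[key] = float(val)
        object.__setattr__(new, "_values", vals)
        return new

    def to_dict(self) -> dict[str, float]:
        return dict(self._values)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterSet":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a flat key/value mapping")
        return cls(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: float(v) for k, v in self._values.items()},
                fh,
                sort_keys=False,
            )

    @classmethod
    def reference(cls) -> "ParameterSet":
        """The shipped reference fitted parameter set."""
        return cls.from_yaml(Path(__file__).parent / "data" / "reference_fit.yaml")

    # -- validation ----------------------------------------------------------
    def validate(self) -> None:
        for name, value in self._values.items():
            if value < 0 and not name.startswith("E_") and name not in ("V_half", "E_leak"):
                raise ValueError(f"parameter {name} must be nonnegative, got {value}")
        for total in ("total_R", "total_Ga", "total_GCY", "total_GCAPa",
                      "total_GCAPb", "total_PDE", "total_CaM"):
            if self._values[total] <= 0:
                raise ValueError(f"{total} must be positive")
        if self._values["EC50_CNG"] <= 0 or self._values["n_CNG"] < 1:
            raise ValueError("EC50_CNG must be > 0 and n_CNG >= 1")
        if self._values["F_max"] <= self._values["F_min"] or self._values["F_min"] < 0:
            raise ValueError("need F_max > F_min >= 0")


def fit_bounds(names: list[str] | None = None) -> dict[str, tuple[float, float]]:
    """GA search bounds (lower, upper) for fittable parameters."""
    out = {}
    for name, spec in PARAM_SPECS.items():
        if names is not None and name not in names:
            continue
        if spec.fit and spec.upper > spec.lower:
            out[name] = (spec.lower, spec.upper)
    return out


def bounds_from_yaml(path: str | Path) -> dict[str, tuple[float, float]]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for name, pair in raw.items():
        if name not in PARAM_SPECS:
            raise KeyError(f"unknown parameter {name!r} in bounds file")
        lo, hi = float(pair[0]), float(pair[1])
        if not lo <= hi:
            raise ValueError(f"bad bounds for {name}: {pair}")
        out[name] = (lo, hi)
    return out
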