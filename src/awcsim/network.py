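"""Mass-action reaction network for the AWC odor-transduction pathway.

The chemical scheme couples a G-protein-coupled odor receptor to a guanylate
cyclase (GCY) that is suppressed by active Gα during stimulation, with two
guanylate-cyclase-activating proteins (GCAPa, GCAPb) forming a
calcium-dependent negative feedback on cGMP synthesis, one
calmodulin-activated phosphodiesterase, and stepwise calmodulin–calcium
buffering.  Every step obeys the mass-action law: binding rates are
proportional to the product of reactant concentrations.

Channel fluxes, extrusion and membrane potential live in
:mod:`awcsim.membrane`; this module owns the purely chemical part of the
right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SPECIES",
    "STATE_VARS",
    "N_SPECIES",
    "idx",
    "Reaction",
    "ConservedMoiety",
    "ReactionNetwork",
    "build_network",
    "mass_action_rate",
    "chemical_rhs",
    "brute_force_rhs",
]

# Ordered species list.  "Odor" is clamped to the stimulus level by the
# engine, never integrated.  Membrane potential V is appended by the engine
# as the last state variable.
SPECIES: tuple[str, ...] = (
    "Odor",
    "R",
    "Odor_R",
    "Ga_inactive",
    "Ga",
    "GCY",
    "GCAPa",
    "GCAPb",
    "GCAPa_Ca",
    "GCAPb_Ca",
    "GCY_GCAPa",
    "GCY_GCAPb",
    "G_GCY",
    "G_GCY_GCAPa",
    "G_GCY_GCAPb",
    "GTP",
    "cGMP",
    "GCY_GTP",
    "GCY_GCAPa_GTP",
    "GCY_GCAPb_GTP",
    "PDE",
    "PDE_cGMP",
    "PDEa",
    "PDEa_cGMP",
    "CaM",
    "CaM_Ca1",
    "CaM_Ca2",
    "CaM_Ca3",
    "CaM_Ca4",
    "Ca",
)
N_SPECIES = len(SPECIES)
STATE_VARS: tuple[str, ...] = SPECIES + ("V",)
_INDEX = {name: i for i, name in enumerate(SPECIES)}


def idx(name: str) -> int:
    """State-vector index of a species."""
    return _INDEX[name]


@dataclass(frozen=True)
class Reaction:
    """One (optionally reversible) mass-action reaction.

    ``reactants``/``products`` are tuples of (species name, stoichiometry).
    An empty reactant tuple denotes a zero-order supply step whose forward
    flux is simply ``kf``.  ``kf_name``/``kr_name`` record which parameters
    the rate constants came from, for error messages and SBML export.
    """

    label: str
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    kf: float
    kr: float = 0.0
    kf_name: str = ""
    kr_name: str = ""
    group: int = 0

    def __post_init__(self) -> None:
        if self.kf < 0 or self.kr < 0:
            raise ValueError(f"{self.label}: rate constants must be >= 0")
        for sp, st in self.reactants + self.products:
            if st <= 0 or int(st) != st:
                raise ValueError(f"{self.label}: stoichiometry of {sp} must be a positive integer")
            if sp not in _INDEX:
                raise KeyError(f"{self.label}: species {sp!r} is not declared")

    @property
    def reversible(self) -> bool:
        return self.kr > 0


@dataclass(frozen=True)
class ConservedMoiety:
    """A weighted species set whose total concentration the stoichiometry
    leaves invariant (no synthesis or degradation of the carrier protein)."""

    name: str
    members: tuple[tuple[str, int], ...]
    total: float

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError(f"moiety {self.name}: total must be > 0")

    def weight_vector(self) -> np.ndarray:
        w = np.zeros(N_SPECIES)
        for sp, mult in self.members:
            w[idx(sp)] = mult
        return w

    def evaluate(self, y: np.ndarray) -> float:
        """Weighted concentration sum at a state (or trajectory slice)."""
        return sum(mult * y[..., idx(sp)] for sp, mult in self.members)


# Full moiety membership (with every reaction group present).  Member species
# that end up disconnected when groups are omitted are dropped dynamically in
# build_network.
_MOIETY_MEMBERS: dict[str, tuple[tuple[str, int], ...]] = {
    "total_R": (("R", 1), ("Odor_R", 1)),
    "total_Ga": (
        ("Ga_inactive", 1), ("Ga", 1), ("G_GCY", 1),
        ("G_GCY_GCAPa", 1), ("G_GCY_GCAPb", 1),
    ),
    "total_GCY": (
        ("GCY", 1), ("GCY_GCAPa", 1), ("GCY_GCAPb", 1), ("G_GCY", 1),
        ("G_GCY_GCAPa", 1), ("G_GCY_GCAPb", 1), ("GCY_GTP", 1),
        ("GCY_GCAPa_GTP", 1), ("GCY_GCAPb_GTP", 1),
    ),
    "total_GCAPa": (
        ("GCAPa", 1), ("GCAPa_Ca", 1), ("GCY_GCAPa", 1),
        ("G_GCY_GCAPa", 1), ("GCY_GCAPa_GTP", 1),
    ),
    "total_GCAPb": (
        ("GCAPb", 1), ("GCAPb_Ca", 1), ("GCY_GCAPb", 1),
        ("G_GCY_GCAPb", 1), ("GCY_GCAPb_GTP", 1),
    ),
    "total_PDE": (
        ("PDE", 1), ("PDE_cGMP", 1), ("PDEa", 1), ("PDEa_cGMP", 1),
    ),
    "total_CaM": (
        ("CaM", 1), ("CaM_Ca1", 1), ("CaM_Ca2", 1), ("CaM_Ca3", 1),
        ("CaM_Ca4", 1), ("PDEa", 1), ("PDEa_cGMP", 1),
    ),
}


def _reaction_table(p, catalytic: bool = True) -> list[Reaction]:
    """Assemble the reaction list from a parameter mapping.

    ``catalytic=False`` zeroes every irreversible catalytic turnover constant
    (used by the detailed-balance diagnostic, where the remaining purely
    reversible system must equilibrate with zero flux through each reaction).
    """

    def k(name: str) -> float:
        try:
            return float(p[name])
        except KeyError:
            raise KeyError(f"missing rate constant {name!r} required by the reaction network") from None

    cat = (lambda name: k(name)) if catalytic else (lambda name: 0.0)
    rxns: list[Reaction] = [
        # step 1: odor binding
        Reaction("odor_binding", (("Odor", 1), ("R", 1)), (("Odor_R", 1),),
                 k("K_p1_odor_R"), k("K_m1_odor_R"), "K_p1_odor_R", "K_m1_odor_R", group=1),
        # step 2: receptor-catalysed G-protein activation and spontaneous decay
        Reaction("Ga_activation", (("Odor_R", 1), ("Ga_inactive", 1)),
                 (("Odor_R", 1), ("Ga", 1)),
                 k("K_p1_R_Ga"), 0.0, "K_p1_R_Ga", group=2),
        Reaction("Ga_decay", (("Ga", 1),), (("Ga_inactive", 1),),
                 k("K_m1_Ga"), 0.0, "K_m1_Ga", group=2),
        # step 3: Ga binds (and thereby suppresses) each cyclase species
        Reaction("Ga_GCY", (("Ga", 1), ("GCY", 1)), (("G_GCY", 1),),
                 k("K_p1_Ga_GCY"), k("K_m1_Ga_GCY"), "K_p1_Ga_GCY", "K_m1_Ga_GCY", group=3),
        Reaction("Ga_GCY_GCAPa", (("Ga", 1), ("GCY_GCAPa", 1)), (("G_GCY_GCAPa", 1),),
                 k("K_p1_Ga_GCYGCAPa"), k("K_m1_Ga_GCYGCAPa"),
                 "K_p1_Ga_GCYGCAPa", "K_m1_Ga_GCYGCAPa", group=3),
        Reaction("Ga_GCY_GCAPb", (("Ga", 1), ("GCY_GCAPb", 1)), (("G_GCY_GCAPb", 1),),
                 k("K_p1_Ga_GCYGCAPb"), k("K_m1_Ga_GCYGCAPb"),
                 "K_p1_Ga_GCYGCAPb", "K_m1_Ga_GCYGCAPb", group=3),
        # step 4: GTP binding and cGMP synthesis by each active cyclase form
        Reaction("GCY_GTP_binding", (("GCY", 1), ("GTP", 1)), (("GCY_GTP", 1),),
                 k("K_p1_GCY_GTP"), k("K_m1_GCY_GTP"), "K_p1_GCY_GTP", "K_m1_GCY_GTP", group=4),
        Reaction("GCY_turnover", (("GCY_GTP", 1),), (("GCY", 1), ("cGMP", 1)),
                 cat("K_cat_GCY"), 0.0, "K_cat_GCY", group=4),
        Reaction("GCYGCAPa_GTP_binding", (("GCY_GCAPa", 1), ("GTP", 1)), (("GCY_GCAPa_GTP", 1),),
                 k("K_p1_GCYGCAPa_GTP"), k("K_m1_GCYGCAPa_GTP"),
                 "K_p1_GCYGCAPa_GTP", "K_m1_GCYGCAPa_GTP", group=4),
        Reaction("GCYGCAPa_turnover", (("GCY_GCAPa_GTP", 1),), (("GCY_GCAPa", 1), ("cGMP", 1)),
                 cat("K_cat_GCYGCAPa"), 0.0, "K_cat_GCYGCAPa", group=4),
        Reaction("GCYGCAPb_GTP_binding", (("GCY_GCAPb", 1), ("GTP", 1)), (("GCY_GCAPb_GTP", 1),),
                 k("K_p1_GCYGCAPb_GTP"), k("K_m1_GCYGCAPb_GTP"),
                 "K_p1_GCYGCAPb_GTP", "K_m1_GCYGCAPb_GTP", group=4),
        Reaction("GCYGCAPb_turnover", (("GCY_GCAPb_GTP", 1),), (("GCY_GCAPb", 1), ("cGMP", 1)),
                 cat("K_cat_GCYGCAPb"), 0.0, "K_cat_GCYGCAPb", group=4),
        # step 4: GTP supply (zero-order in) and removal (first-order out),
        # written as one reversible exchange with an external pool
        Reaction("GTP_supply", (), (("GTP", 1),),
                 k("K_GTPsupp"), k("K_m1_GTPsupp"), "K_GTPsupp", "K_m1_GTPsupp", group=4),
        # step 4': cGMP decomposition (GMP is an untracked sink)
        Reaction("PDE_cGMP_binding", (("PDE", 1), ("cGMP", 1)), (("PDE_cGMP", 1),),
                 k("K_p1_PDE_cGMP"), k("K_m1_PDE_cGMP"),
                 "K_p1_PDE_cGMP", "K_m1_PDE_cGMP", group=4),
        Reaction("PDE_hydrolysis", (("PDE_cGMP", 1),), (("PDE", 1),),
                 cat("K_cat_PDE"), 0.0, "K_cat_PDE", group=4),
        Reaction("PDEa_cGMP_binding", (("PDEa", 1), ("cGMP", 1)), (("PDEa_cGMP", 1),),
                 k("K_p1_PDEa_cGMP"), k("K_m1_PDEa_cGMP"),
                 "K_p1_PDEa_cGMP", "K_m1_PDEa_cGMP", group=4),
        Reaction("PDEa_hydrolysis", (("PDEa_cGMP", 1),), (("PDEa", 1),),
                 cat("K_p1_PDEactive"), 0.0, "K_p1_PDEactive", group=4),
        # step 8: stepwise calmodulin-calcium binding, PDE activation
        Reaction("CaM_Ca1_binding", (("CaM", 1), ("Ca", 1)), (("CaM_Ca1", 1),),
                 k("K_p1_CaM_Ca"), k("K_m1_CaM_Ca"), "K_p1_CaM_Ca", "K_m1_CaM_Ca", group=8),
        Reaction("CaM_Ca2_binding", (("CaM_Ca1", 1), ("Ca", 1)), (("CaM_Ca2", 1),),
                 k("K_p1_CaMCa_Ca"), k("K_m1_CaMCa_Ca"), "K_p1_CaMCa_Ca", "K_m1_CaMCa_Ca", group=8),
        Reaction("CaM_Ca3_binding", (("CaM_Ca2", 1), ("Ca", 1)), (("CaM_Ca3", 1),),
                 k("K_p1_CaMCa2_Ca"), k("K_m1_CaMCa2_Ca"), "K_p1_CaMCa2_Ca", "K_m1_CaMCa2_Ca", group=8),
        Reaction("CaM_Ca4_binding", (("CaM_Ca3", 1), ("Ca", 1)), (("CaM_Ca4", 1),),
                 k("K_p1_CaMCa3_Ca"), k("K_m1_CaMCa3_Ca"), "K_p1_CaMCa3_Ca", "K_m1_CaMCa3_Ca", group=8),
        Reaction("PDE_activation", (("PDE", 1), ("CaM_Ca4", 1)), (("PDEa", 1),),
                 k("K_p1_PDE_CaMCa4"), k("K_m1_PDE_CaMCa4"),
                 "K_p1_PDE_CaMCa4", "K_m1_PDE_CaMCa4", group=8),
        # step 9: calcium inactivation of free GCAPs; GCAP binding to GCY
        Reaction("GCAPa_Ca_binding", (("GCAPa", 1), ("Ca", 1)), (("GCAPa_Ca", 1),),
                 k("K_p1_GCAPa_Ca"), k("K_m1_GCAPa_Ca"), "K_p1_GCAPa_Ca", "K_m1_GCAPa_Ca", group=9),
        Reaction("GCAPb_Ca_binding", (("GCAPb", 1), ("Ca", 1)), (("GCAPb_Ca", 1),),
                 k("K_p1_GCAPb_Ca"), k("K_m1_GCAPb_Ca"), "K_p1_GCAPb_Ca", "K_m1_GCAPb_Ca", group=9),
        # complex assembly routes (scheme steps 3/9): GCAPs bind only free GCY
        Reaction("GCY_GCAPa_binding", (("GCY", 1), ("GCAPa", 1)), (("GCY_GCAPa", 1),),
                 k("K_p1_GCY_GCAPa"), k("K_m1_GCY_GCAPa"),
                 "K_p1_GCY_GCAPa", "K_m1_GCY_GCAPa", group=3),
        Reaction("GCY_GCAPb_binding", (("GCY", 1), ("GCAPb", 1)), (("GCY_GCAPb", 1),),
                 k("K_p1_GCY_GCAPb"), k("K_m1_GCY_GCAPb"),
                 "K_p1_GCY_GCAPb", "K_m1_GCY_GCAPb", group=3),
    ]
    return rxns


@dataclass
class ReactionNetwork:
    """Compiled network: reactions, stoichiometry matrix, conserved moieties.

    All reactions in this scheme are at most bimolecular with unit
    stoichiometries, which the compiled fast path exploits; the general
    mass-action product form remains available through
    :func:`mass_action_rate` and :func:`brute_force_rhs`.
    """

    reactions: list[Reaction]
    moieties: list[ConservedMoiety]
    params: object  # ParameterSet
    stoich: np.ndarray = field(repr=False, default=None)  # (n_species, n_rxn)
    # compiled index arrays for vectorised flux evaluation
    _ri: np.ndarray = field(repr=False, default=None)
    _pi: np.ndarray = field(repr=False, default=None)
    _kf: np.ndarray = field(repr=False, default=None)
    _kr: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        n_rxn = len(self.reactions)
        N = np.zeros((N_SPECIES, n_rxn))
        ri = np.full((n_rxn, 2), N_SPECIES, dtype=np.intp)  # dummy index -> 1.0
        pi = np.full((n_rxn, 2), N_SPECIES, dtype=np.intp)
        kf = np.zeros(n_rxn)
        kr = np.zeros(n_rxn)
        for j, rxn in enumerate(self.reactions):
            slots_r, slots_p = 0, 0
            for sp, st in rxn.reactants:
                N[idx(sp), j] -= st
                for _ in range(st):
                    ri[j, slots_r] = idx(sp)
                    slots_r += 1
            for sp, st in rxn.products:
                N[idx(sp), j] += st
                for _ in range(st):
                    pi[j, slots_p] = idx(sp)
                    slots_p += 1
            if slots_r > 2 or slots_p > 2:
                raise ValueError(f"{rxn.label}: fast path supports at most two reactant/product slots")
            kf[j], kr[j] = rxn.kf, rxn.kr
        self.stoich = N
        self._ri, self._pi, self._kf, self._kr = ri, pi, kf, kr
        # structural check: every declared moiety lies in the left null space
        for m in self.moieties:
            w = m.weight_vector()
            drift = np.abs(w @ self.stoich).max()
            if drift > 1e-12:
                raise ValueError(f"moiety {m.name} is not conserved by the stoichiometry")

    # ------------------------------------------------------------------
    def fluxes(self, y: np.ndarray) -> np.ndarray:
        """Net mass-action flux of every reaction at state ``y`` (µM/s)."""
        c = np.append(y[:N_SPECIES], 1.0)  # dummy concentration for empty slots
        fwd = self._kf * c[self._ri[:, 0]] * c[self._ri[:, 1]]
        rev = self._kr * c[self._pi[:, 0]] * c[self._pi[:, 1]]
        return fwd - rev

    def species_rhs(self, y: np.ndarray) -> np.ndarray:
        """Stoichiometric sum of fluxes (µM/s) for every species."""
        return self.stoich @ self.fluxes(y)

    def initial_state(self) -> np.ndarray:
        """All carrier proteins free, small-molecule pools at plausible levels."""
        p = self.params
        y = np.zeros(N_SPECIES)
        y[idx("R")] = p["total_R"]
        y[idx("Ga_inactive")] = p["total_Ga"]
        y[idx("GCY")] = p["total_GCY"]
        y[idx("GCAPa")] = p["total_GCAPa"]
        y[idx("GCAPb")] = p["total_GCAPb"]
        y[idx("PDE")] = p["total_PDE"]
        y[idx("CaM")] = p["total_CaM"]
        y[idx("GTP")] = p["K_GTPsupp"] / max(p["K_m1_GTPsupp"], 1e-12)
        y[idx("cGMP")] = 1.0
        y[idx("Ca")] = 0.05
        return y


def build_network(params, omit_groups: tuple[int, ...] = (), catalytic: bool = True) -> ReactionNetwork:
    """Build the reaction network for a parameter set.

    Parameters
    ----------
    params
        Mapping with every rate constant and conserved total; a missing
        constant raises ``KeyError`` naming it.
    omit_groups
        Reaction-step numbers (1–9) to leave out, for structural analyses.
        Moiety membership shrinks accordingly: species left without any
        reaction are dropped from the moiety (they are individually frozen).
    catalytic
        When False, all irreversible catalytic turnover constants are set to
        zero, leaving the purely reversible binding skeleton.
    """
    reactions = [r for r in _reaction_table(params, catalytic=catalytic)
                 if r.group not in omit_groups]
    active: set[str] = set()
    for r in reactions:
        for sp, _ in r.reactants + r.products:
            active.add(sp)
    moieties = []
    for total_name, members in _MOIETY_MEMBERS.items():
        kept = tuple((sp, mult) for sp, mult in members if sp in active)
        if kept:
            moieties.append(ConservedMoiety(total_name, kept, float(params[total_name])))
    return ReactionNetwork(reactions, moieties, params)


def mass_action_rate(reaction: Reaction, state) -> float:
    """Net flux of one reaction (µM/s) by the mass-action law.

    ``state`` is a species-name → concentration mapping or a state vector.
    Zero-order supply steps return ``kf`` minus any reverse term.
    """

    def conc(sp: str) -> float:
        c = state[idx(sp)] if isinstance(state, np.ndarray) else state[sp]
        if c < 0:
            raise ValueError(f"negative concentration for {sp}: {c}")
        return float(c)

    fwd = reaction.kf
    for sp, st in reaction.reactants:
        fwd *= conc(sp) ** st
    rev = reaction.kr
    for sp, st in reaction.products:
        rev *= conc(sp) ** st
    return fwd - rev


def chemical_rhs(t: float, y: np.ndarray, network: ReactionNetwork, stim=None) -> np.ndarray:
    """Chemical part of the time derivative (µM/s) at time ``t``.

    The odor species is clamped to the stimulus level (derivative zero); the
    calcium derivative contains only the binding fluxes — channel influx and
    extrusion are added by the simulation engine.
    """
    if stim is not None:
        y = y.copy()
        y[idx("Odor")] = stim.odor_level(t)
    dy = network.species_rhs(y)
    dy[idx("Odor")] = 0.0
    return dy


def brute_force_rhs(y: np.ndarray, network: ReactionNetwork) -> np.ndarray:
    """Independent per-reaction summation oracle for the species derivatives.

    Loops over reactions and applies each stoichiometry explicitly, using the
    general product form of :func:`mass_action_rate`; kept deliberately naive
    as a cross-check of the vectorised path.
    """
    dy = np.zeros(N_SPECIES)
    for rxn in network.reactions:
        v = mass_action_rate(rxn, y)
        for sp, st in rxn.reactants:
            dy[idx(sp)] -= st * v
        for sp, st in rxn.products:
            dy[idx(sp)] += st * v
    return dy
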