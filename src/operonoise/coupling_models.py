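"""Two-gene expression systems under three transcriptional coupling modes,
composed with the interaction-module classes.

The three coupling configurations:

* ``COTRANSLATED`` — one promoter, one polycistronic transcript, one
  translation channel producing proteins A and B together (single ribosome
  binding site); strongest coupling.
* ``COTRANSCRIBED_SEPARATE_RBS`` — one promoter and transcript but
  independent translation events for A and B.
* ``UNCOUPLED`` — two independent promoters and transcripts.

Per-gene transcription, translation and degradation rates are identical
across configurations, so the mean and marginal noise of each protein match
between members of a comparison pair; only the coupling topology differs.

Interaction module classes appended on top of the expression system: a
linear metabolic pathway (A then B catalyze successive steps), redundant
enzymes (A and B catalyze the same step), a metabolic branch point,
redundant transcriptional regulators with OR logic, heterodimer formation,
covalent modification of A by B, and a reduced lac-like import/conversion
cascade with inducer feedback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .reaction_core import (
    RateLaw,
    Reaction,
    ReactionSystem,
    Species,
    simulate_ensemble,
    steady_state_mean_field,
)

__all__ = [
    "CouplingMode",
    "ModuleClass",
    "BurstingParams",
    "ExpressionParams",
    "ModuleParams",
    "ComparisonPair",
    "build_expression",
    "build_module",
    "build_comparison",
    "burst_duty_cycle",
    "total_protein_species",
    "module_readout",
    "stationary_initial_states",
    "simulate_module_ensemble",
    "verify_matched_controls",
    "randomize_extrinsic",
    "molecules_per_fL",
]

#: Avogadro-based conversion: 1 uM in a 1 fL volume is ~602.2 molecules.
_MOLECULES_PER_FL_PER_UM = 6.02214076e23 * 1e-6 * 1e-15


def molecules_per_fL(conc_uM: float) -> float:
    """Convert a concentration in micromolar to molecules per femtoliter."""
    return conc_uM * _MOLECULES_PER_FL_PER_UM


class CouplingMode(str, Enum):
    COTRANSLATED = "cotranslated"
    COTRANSCRIBED_SEPARATE_RBS = "cotranscribed_separate_rbs"
    UNCOUPLED = "uncoupled"


class ModuleClass(str, Enum):
    LINEAR_PATHWAY = "linear_pathway"
    REDUNDANT_ENZYMES = "redundant_enzymes"
    BRANCH_POINT = "branch_point"
    DUAL_REGULATORS_OR = "dual_regulators_or"
    PHYSICAL_INTERACTION = "physical_interaction"
    COVALENT_MODIFICATION = "covalent_modification"
    LAC_REDUCED = "lac_reduced"


@dataclass(frozen=True)
class BurstingParams:
    """Two-state promoter switching (on -> off at k_goff, off -> on at k_gon);
    defaults are the measured E. coli switching rates."""

    k_goff: float = 0.0028
    k_gon: float = 0.00045
    enabled: bool = True

    def __post_init__(self):
        # k_goff = 0 is the degenerate always-on promoter (duty cycle 1)
        if self.enabled and (self.k_goff < 0 or self.k_gon <= 0):
            raise ValueError("switching rates must be positive when bursting is enabled")


def burst_duty_cycle(bursting: BurstingParams) -> float:
    """Stationary fraction of time the promoter spends in the on state,
    k_gon/(k_gon + k_goff); 1 when bursting is disabled."""
    if not bursting.enabled:
        return 1.0
    if bursting.k_goff == 0:
        return 1.0
    return bursting.k_gon / (bursting.k_gon + bursting.k_goff)


@dataclass(frozen=True)
class ExpressionParams:
    """Per-gene expression kinetics, identical for genes A and B.

    k_tx    mRNA s^-1 per active promoter
    k_tl    protein s^-1 per mRNA (per gene)
    delta_m mRNA degradation rate, 1/tau_mRNA
    k_deg   protein dilution/degradation, 1/tau_protein
            (default ln2/1800 s^-1: dilution at a 30 min doubling time)
    """

    k_tx: float = 0.05
    k_tl: float = 0.02037
    delta_m: float = 0.005
    k_deg: float = math.log(2) / 1800.0

    def __post_init__(self):
        if min(self.k_tx, self.k_tl, self.delta_m, self.k_deg) <= 0:
            raise ValueError("expression rates must be > 0")

    @property
    def mean_mrna(self) -> float:
        return self.k_tx / self.delta_m

    @property
    def mean_protein(self) -> float:
        return self.mean_mrna * self.k_tl / self.k_deg


@dataclass(frozen=True)
class ModuleParams:
    """Kinetic constants of the posttranslational interaction module; which
    fields matter depends on the module class.  All copy-number-like
    quantities are in copies, rates in s^-1 or copies s^-1."""

    # metabolic classes
    k_cat1: float = 0.0
    k_cat2: float = 0.0
    K_m1: float = 1.0
    K_m2: float = 1.0
    S0: float = 0.0            # held-constant substrate reservoir (copies)
    J: float = 0.0             # constant substrate influx (copies/s)
    k_out: float = 0.0         # metabolite/product removal rate
    # OR-gate regulators
    V_max: float = 0.0
    K_hill: float = 1.0
    n_hill: float = 1.0
    # physical interaction
    k_b: float = 0.0
    k_unb: float = 0.0
    # covalent modification
    k_p: float = 0.0
    k_demod: float = 0.0
    saturating: bool = False   # Michaelis-Menten (zero-order) variant
    K_mA: float = 1.0
    K_mAstar: float = 1.0
    # reduced lac cascade
    lactose_ext: float = 0.0
    k_catY: float = 0.0
    K_mY: float = 1.0
    k_catZ1: float = 0.0
    K_mZ1: float = 1.0
    k_catZ2: float = 0.0
    K_mZ2: float = 1.0
    n_repressor: int = 0
    k_rb: float = 0.0
    k_ru: float = 0.0
    k_pb: float = 0.0
    k_pu: float = 0.0


# ---------------------------------------------------------------------------
# expression systems


def _promoter(reactions, species, tag, bursting):
    """Add a two-state promoter; returns the name of the 'on' species or None
    for a constitutive promoter."""
    if not bursting.enabled:
        return None
    on, off = f"g{tag}_on", f"g{tag}_off"
    species += [Species(on, 1, is_conserved_unit=True), Species(off, 0, is_conserved_unit=True)]
    reactions += [
        Reaction({on: 1}, {off: 1}, {}, RateLaw.mass_action(bursting.k_goff), name=f"goff:{tag}"),
        Reaction({off: 1}, {on: 1}, {}, RateLaw.mass_action(bursting.k_gon), name=f"gon:{tag}"),
    ]
    return on


def _transcription(reactions, mrna, promoter_on, k_tx, tag, gate=None):
    mods = {}
    if promoter_on is not None:
        mods[promoter_on] = 1
    if gate is not None:
        mods[gate] = 1
    reactions.append(Reaction({}, {mrna: 1}, mods, RateLaw.mass_action(k_tx), name=f"tx:{tag}"))


def build_expression(mode: CouplingMode, bursting: BurstingParams,
                     expr: ExpressionParams) -> ReactionSystem:
    """Two-gene expression system for one coupling configuration.

    Species: proteins A and B, mRNAs (``m`` shared, or ``m1``/``m2``), and
    promoter on/off states when bursting is enabled.  Initial copies are set
    to the rounded stationary means so ensembles start near stationarity.
    """
    mode = CouplingMode(mode)
    phi = burst_duty_cycle(bursting)
    m_mean = phi * expr.k_tx / expr.delta_m
    p_mean = m_mean * expr.k_tl / expr.k_deg
    species: list = []
    reactions: list = []

    def protein(name):
        species.append(Species(name, int(round(p_mean))))
        reactions.append(Reaction({name: 1}, {}, {}, RateLaw.mass_action(expr.k_deg), name=f"deg:{name}"))

    def mrna(name):
        species.append(Species(name, int(round(m_mean))))
        reactions.append(Reaction({name: 1}, {}, {}, RateLaw.mass_action(expr.delta_m), name=f"mdeg:{name}"))

    if mode is CouplingMode.UNCOUPLED:
        on1 = _promoter(reactions, species, "1", bursting)
        on2 = _promoter(reactions, species, "2", bursting)
        mrna("m1"); mrna("m2")
        _transcription(reactions, "m1", on1, expr.k_tx, "m1")
        _transcription(reactions, "m2", on2, expr.k_tx, "m2")
        protein("A"); protein("B")
        reactions.append(Reaction({}, {"A": 1}, {"m1": 1}, RateLaw.mass_action(expr.k_tl), name="tl:A"))
        reactions.append(Reaction({}, {"B": 1}, {"m2": 1}, RateLaw.mass_action(expr.k_tl), name="tl:B"))
    else:
        on = _promoter(reactions, species, "12", bursting)
        mrna("m")
        _transcription(reactions, "m", on, expr.k_tx, "m")
        protein("A"); protein("B")
        if mode is CouplingMode.COTRANSLATED:
            reactions.append(Reaction({}, {"A": 1, "B": 1}, {"m": 1}, RateLaw.mass_action(expr.k_tl), name="tl:AB"))
        else:
            reactions.append(Reaction({}, {"A": 1}, {"m": 1}, RateLaw.mass_action(expr.k_tl), name="tl:A"))
            reactions.append(Reaction({}, {"B": 1}, {"m": 1}, RateLaw.mass_action(expr.k_tl), name="tl:B"))
    return ReactionSystem(species, reactions)


# ---------------------------------------------------------------------------
# interaction modules


def build_module(cls: ModuleClass, mode: CouplingMode, bursting: BurstingParams,
                 expr: ExpressionParams, mod: ModuleParams) -> ReactionSystem:
    """Append one interaction module class to the two-gene expression system."""
    cls = ModuleClass(cls)
    if cls is ModuleClass.LAC_REDUCED:
        return _build_lac_reduced(mode, bursting, expr, mod)
    base = build_expression(mode, bursting, expr)
    species = list(base.species)
    reactions = list(base.reactions)

    if cls is ModuleClass.LINEAR_PATHWAY:
        species += [Species("S", int(mod.S0), clamped=True), Species("I", 0), Species("P", 0)]
        reactions += [
            Reaction({"S": 1}, {"I": 1}, {"A": 1}, RateLaw.michaelis_menten(mod.k_cat1, mod.K_m1), name="cat1"),
            Reaction({"I": 1}, {"P": 1}, {"B": 1}, RateLaw.michaelis_menten(mod.k_cat2, mod.K_m2), name="cat2"),
            Reaction({"P": 1}, {}, {}, RateLaw.mass_action(mod.k_out), name="deg:P"),
        ]
    elif cls is ModuleClass.REDUNDANT_ENZYMES:
        species += [Species("S", int(mod.S0), clamped=True), Species("P", 0)]
        reactions += [
            Reaction({"S": 1}, {"P": 1}, {"A": 1}, RateLaw.michaelis_menten(mod.k_cat1, mod.K_m1), name="cat1"),
            Reaction({"S": 1}, {"P": 1}, {"B": 1}, RateLaw.michaelis_menten(mod.k_cat2, mod.K_m2), name="cat2"),
            Reaction({"P": 1}, {}, {}, RateLaw.mass_action(mod.k_out), name="deg:P"),
        ]
    elif cls is ModuleClass.BRANCH_POINT:
        species += [Species("s", 0), Species("P1", 0), Species("P2", 0)]
        reactions += [
            Reaction({}, {"s": 1}, {}, RateLaw.mass_action(mod.J), name="influx"),
            Reaction({"s": 1}, {"P1": 1}, {"A": 1}, RateLaw.michaelis_menten(mod.k_cat1, mod.K_m1), name="cat1"),
            Reaction({"s": 1}, {"P2": 1}, {"B": 1}, RateLaw.michaelis_menten(mod.k_cat2, mod.K_m2), name="cat2"),
            Reaction({"P1": 1}, {}, {}, RateLaw.mass_action(mod.k_out), name="deg:P1"),
            Reaction({"P2": 1}, {}, {}, RateLaw.mass_action(mod.k_out), name="deg:P2"),
        ]
    elif cls is ModuleClass.DUAL_REGULATORS_OR:
        species += [Species("mp", 0), Species("P", 0)]
        reactions += [
            Reaction({}, {"mp": 1}, {"A": 1, "B": 1},
                     RateLaw.hill_or(mod.V_max, mod.K_hill, mod.n_hill, mod.K_hill, mod.n_hill),
                     name="tx:mp"),
            Reaction({"mp": 1}, {}, {}, RateLaw.mass_action(expr.delta_m), name="mdeg:mp"),
            Reaction({}, {"P": 1}, {"mp": 1}, RateLaw.mass_action(expr.k_tl), name="tl:P"),
            Reaction({"P": 1}, {}, {}, RateLaw.mass_action(expr.k_deg), name="deg:P"),
        ]
    elif cls is ModuleClass.PHYSICAL_INTERACTION:
        species += [Species("AB", 0)]
        reactions += [
            Reaction({"A": 1, "B": 1}, {"AB": 1}, {}, RateLaw.mass_action(mod.k_b), name="bind"),
            Reaction({"AB": 1}, {"A": 1, "B": 1}, {}, RateLaw.mass_action(mod.k_unb), name="unbind"),
            Reaction({"AB": 1}, {}, {}, RateLaw.mass_action(expr.k_deg), name="deg:AB"),
        ]
    elif cls is ModuleClass.COVALENT_MODIFICATION:
        species += [Species("Astar", 0)]
        if mod.saturating:
            species += [Species("Edem", 1, clamped=True)]
            reactions += [
                Reaction({"A": 1}, {"Astar": 1}, {"B": 1},
                         RateLaw.michaelis_menten(mod.k_p, mod.K_mA), name="modify"),
                Reaction({"Astar": 1}, {"A": 1}, {"Edem": 1},
                         RateLaw.michaelis_menten(mod.k_demod, mod.K_mAstar), name="demodify"),
            ]
        else:
            reactions += [
                Reaction({"A": 1}, {"Astar": 1}, {"B": 1}, RateLaw.mass_action(mod.k_p), name="modify"),
                Reaction({"Astar": 1}, {"A": 1}, {}, RateLaw.mass_action(mod.k_demod), name="demodify"),
            ]
        reactions.append(Reaction({"Astar": 1}, {}, {}, RateLaw.mass_action(expr.k_deg), name="deg:Astar"))
    else:  # pragma: no cover
        raise ValueError(f"unknown module class {cls!r}")
    return ReactionSystem(species, reactions)


def _build_lac_reduced(mode: CouplingMode, bursting: BurstingParams,
                       expr: ExpressionParams, mod: ModuleParams) -> ReactionSystem:
    """Reduced lac-like cascade: permease-mediated import, conversion of
    internal lactose to the inducer (allolactose) and onward consumption,
    with the inducer sequestering a repressor that gates transcription of the
    two genes from a shared (coupled) or split (uncoupled) promoter.

    Promoter occupancy by the repressor replaces the generic on/off bursting
    switch; translation of the shared transcript is cotranslated in the
    coupled configuration.
    """
    mode = CouplingMode(mode)
    species = [
        Species("Lext", int(mod.lactose_ext), clamped=True),
        Species("Lin", 0),
        Species("Alac", 0),
        Species("R", mod.n_repressor),
        Species("RA", 0),
    ]
    reactions = [
        # repressor sequestration by the inducer
        Reaction({"Alac": 1, "R": 1}, {"RA": 1}, {}, RateLaw.mass_action(mod.k_rb), name="rbind"),
        Reaction({"RA": 1}, {"Alac": 1, "R": 1}, {}, RateLaw.mass_action(mod.k_ru), name="runbind"),
    ]

    def gene(tag, mrna_name, promoter=True):
        free, bound = f"p{tag}_free", f"p{tag}_R"
        species.extend([Species(free, 1, is_conserved_unit=True), Species(bound, 0, is_conserved_unit=True)])
        reactions.extend([
            Reaction({free: 1, "R": 1}, {bound: 1}, {}, RateLaw.mass_action(mod.k_pb), name=f"rep:{tag}"),
            Reaction({bound: 1}, {free: 1, "R": 1}, {}, RateLaw.mass_action(mod.k_pu), name=f"derep:{tag}"),
        ])
        species.append(Species(mrna_name, 0))
        _transcription(reactions, mrna_name, free, expr.k_tx, mrna_name)
        reactions.append(Reaction({mrna_name: 1}, {}, {}, RateLaw.mass_action(expr.delta_m), name=f"mdeg:{mrna_name}"))

    for prot in ("Y", "Z"):
        species.append(Species(prot, 0))
        reactions.append(Reaction({prot: 1}, {}, {}, RateLaw.mass_action(expr.k_deg), name=f"deg:{prot}"))

    if mode is CouplingMode.UNCOUPLED:
        gene("y", "my"); gene("z", "mz")
        reactions.append(Reaction({}, {"Y": 1}, {"my": 1}, RateLaw.mass_action(expr.k_tl), name="tl:Y"))
        reactions.append(Reaction({}, {"Z": 1}, {"mz": 1}, RateLaw.mass_action(expr.k_tl), name="tl:Z"))
    else:
        gene("yz", "myz")
        if mode is CouplingMode.COTRANSLATED:
            reactions.append(Reaction({}, {"Y": 1, "Z": 1}, {"myz": 1}, RateLaw.mass_action(expr.k_tl), name="tl:YZ"))
        else:
            reactions.append(Reaction({}, {"Y": 1}, {"myz": 1}, RateLaw.mass_action(expr.k_tl), name="tl:Y"))
            reactions.append(Reaction({}, {"Z": 1}, {"myz": 1}, RateLaw.mass_action(expr.k_tl), name="tl:Z"))

    reactions += [
        Reaction({"Lext": 1}, {"Lin": 1}, {"Y": 1}, RateLaw.michaelis_menten(mod.k_catY, mod.K_mY), name="import"),
        Reaction({"Lin": 1}, {"Alac": 1}, {"Z": 1}, RateLaw.michaelis_menten(mod.k_catZ1, mod.K_mZ1), name="convert"),
        Reaction({"Alac": 1}, {}, {"Z": 1}, RateLaw.michaelis_menten(mod.k_catZ2, mod.K_mZ2), name="consume"),
    ]
    return ReactionSystem(species, reactions)


#: species making up "total protein from each gene" per module class
def total_protein_species(cls: ModuleClass) -> dict:
    cls = ModuleClass(cls)
    if cls is ModuleClass.PHYSICAL_INTERACTION:
        return {"A": ["A", "AB"], "B": ["B", "AB"]}
    if cls is ModuleClass.COVALENT_MODIFICATION:
        return {"A": ["A", "Astar"], "B": ["B"]}
    if cls is ModuleClass.LAC_REDUCED:
        return {"A": ["Y"], "B": ["Z"]}
    return {"A": ["A"], "B": ["B"]}


def module_readout(cls: ModuleClass) -> str:
    """Designated noise readout species for each interaction class."""
    return {
        ModuleClass.LINEAR_PATHWAY: "I",
        ModuleClass.REDUNDANT_ENZYMES: "P",
        ModuleClass.BRANCH_POINT: "s",
        ModuleClass.DUAL_REGULATORS_OR: "P",
        ModuleClass.PHYSICAL_INTERACTION: "A",
        ModuleClass.COVALENT_MODIFICATION: "A",
        ModuleClass.LAC_REDUCED: "Alac",
    }[ModuleClass(cls)]


# ---------------------------------------------------------------------------
# matched comparison pairs


@dataclass
class ComparisonPair:
    """Coupled vs uncoupled builds of the same module, identical except for
    the coupling topology."""

    coupled_system: ReactionSystem
    uncoupled_system: ReactionSystem
    module_class: ModuleClass
    coupled_mode: CouplingMode
    expr: ExpressionParams
    mod: ModuleParams
    bursting: BurstingParams


def build_comparison(cls: ModuleClass, expr: ExpressionParams, mod: ModuleParams,
                     bursting: BurstingParams,
                     coupled_mode: CouplingMode = CouplingMode.COTRANSLATED) -> ComparisonPair:
    """Default comparison: cotranslated vs transcriptionally uncoupled."""
    cls = ModuleClass(cls)
    return ComparisonPair(
        build_module(cls, coupled_mode, bursting, expr, mod),
        build_module(cls, CouplingMode.UNCOUPLED, bursting, expr, mod),
        cls, CouplingMode(coupled_mode), expr, mod, bursting,
    )


# ---------------------------------------------------------------------------
# simulation helpers


def stationary_initial_states(system: ReactionSystem, n_runs: int, seed: int,
                              bursting: BurstingParams = None) -> np.ndarray:
    """Per-run initial states: mean-field steady state rounded to integers,
    with each promoter's on/off pair drawn from its stationary occupancy."""
    x_star = steady_state_mean_field(system)
    names = system.names
    base = np.round(x_star).astype(np.float64)
    for sp in system.species:  # clamped reservoirs keep their set level
        if sp.clamped:
            base[names.index(sp.name)] = sp.initial_copies
    x0 = np.tile(base, (n_runs, 1))
    rng = np.random.default_rng(seed)
    i = 0
    while i < len(names):
        nm = names[i]
        if nm.endswith("_on") or nm.endswith("_free"):
            partner = nm.replace("_on", "_off").replace("_free", "_R")
            if partner in names:
                j = names.index(partner)
                phi = x_star[i] / max(x_star[i] + x_star[j], 1e-12)
                on = rng.random(n_runs) < phi
                x0[:, i] = on
                x0[:, j] = 1 - on
        i += 1
    return x0


def simulate_module_ensemble(system: ReactionSystem, n_runs: int, t_end: float,
                             master_seed: int, n_points: int = 200,
                             bursting: BurstingParams = None):
    """SSA ensemble started at the stationary mean-field state (promoter
    states Bernoulli-sampled at their duty cycle)."""
    x0 = stationary_initial_states(system, n_runs, master_seed ^ 0x5EED, bursting)
    return simulate_ensemble(system, n_runs, t_end, master_seed, n_points, x0_per_run=x0)


# ---------------------------------------------------------------------------
# matched-control verification


@dataclass
class ControlCheck:
    gene: str
    statistic: str  # "mean" or "cv"
    coupled: float
    uncoupled: float
    z: float


@dataclass
class ControlReport:
    passed: bool
    checks: list
    tol_sigma: float

    def failures(self):
        return [c for c in self.checks if abs(c.z) > self.tol_sigma]


def verify_matched_controls(pair: ComparisonPair, ensemble_coupled, ensemble_uncoupled,
                            tol_sigma: float = 3.0, burn_in: float = 0.5) -> ControlReport:
    """Check that total protein per gene has matching mean and CV between the
    coupled and uncoupled configurations, within ``tol_sigma`` Monte-Carlo
    standard errors (bootstrap over trajectories)."""
    from .noise_stats import summarize  # deferred to avoid import cycle

    totals = total_protein_species(pair.module_class)
    s_c = summarize(ensemble_coupled, burn_in)
    s_u = summarize(ensemble_uncoupled, burn_in)
    checks = []
    for gene, sps in totals.items():
        for stat in ("mean", "cv"):
            vc, ec = s_c.stat_of_sum(sps, stat)
            vu, eu = s_u.stat_of_sum(sps, stat)
            se = math.hypot(ec, eu)
            z = (vc - vu) / se if se > 0 else 0.0
            checks.append(ControlCheck(gene, stat, vc, vu, z))
    return ControlReport(all(abs(c.z) <= tol_sigma for c in checks), checks, tol_sigma)


# ---------------------------------------------------------------------------
# extrinsic noise


def randomize_extrinsic(system: ReactionSystem, cv_ext: float, seed: int, n_runs: int):
    """Per-run globally perturbed copies of a system, mimicking extrinsic
    noise: one multiplier per rate class (transcription, translation), drawn
    uniformly from [1-w, 1+w], applied identically to both genes."""
    if not (0 <= cv_ext <= 0.5):
        raise ValueError("cv_ext must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_runs):
        if cv_ext == 0:
            out.append(system)
            continue
        f_tx, f_tl = rng.uniform(1 - cv_ext, 1 + cv_ext, size=2)
        reactions = []
        for r in system.reactions:
            if r.name.startswith("tx:"):
                if r.law.kind == "mass_action":
                    law = RateLaw.mass_action(r.law.params[0] * f_tx)
                else:  # Hill-regulated transcription: scale V_max
                    law = RateLaw(r.law.kind, (r.law.params[0] * f_tx,) + r.law.params[1:])
                reactions.append(replace(r, law=law))
            elif r.name.startswith("tl:"):
                reactions.append(replace(r, law=RateLaw.mass_action(r.law.params[0] * f_tl)))
            else:
                reactions.append(r)
        out.append(ReactionSystem(list(system.species), reactions, system.volume_Omega))
    return out
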