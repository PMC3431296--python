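"""Synthetic inputs for the full pipeline: operon universes, interacting-pair
tables with a controlled same-operon enrichment, single-cell-style
copy-number tables with a planted expression-coupling relationship, and the
versioned kinetic parameter fixtures for the interaction modules.

The generators emulate the structure of curated bacterial datasets (operon
membership maps, interacting-pair lists, single-cell average copy numbers)
without reproducing any real genome: operon sizes follow a truncated
geometric law, copy numbers are log-normal spanning roughly 1-10^4 per cell,
and the probability that a gene's interaction partner is in the same operon
declines logistically with log10 copy number when the planted slope beta is
negative — the signature expected if noise minimization favors coupling of
weakly expressed pairs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .coupling_models import (
    BurstingParams,
    ExpressionParams,
    ModuleClass,
    ModuleParams,
    burst_duty_cycle,
    molecules_per_fL,
)

__all__ = [
    "UniverseSpec",
    "PairGenSpec",
    "ExpressionGenSpec",
    "gen_universe",
    "gen_pairs",
    "gen_expression",
    "gen_module_fixture",
    "covalent_saturating_fixture",
    "load_fixture_file",
]


@dataclass(frozen=True)
class UniverseSpec:
    n_genes: int = 1000
    mu_size: float = 3.0          # mean operon size (truncated geometric)
    max_size: int = 12
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 2 or self.mu_size < 1:
            raise ValueError("need n_genes >= 2 and mu_size >= 1")


@dataclass(frozen=True)
class PairGenSpec:
    n_pairs: int = 1000
    f_target: float | None = 0.1  # None: unbiased uniform random pairs
    seed: int = 0

    def __post_init__(self):
        if self.f_target is not None and not (0 <= self.f_target <= 1):
            raise ValueError("f_target must be in [0, 1]")


@dataclass(frozen=True)
class ExpressionGenSpec:
    mu_log: float = math.log(50.0)   # log-normal copy-number location
    sigma_log: float = 2.3           # ~1 decade SD on the log10 scale
    beta: float = 0.0                # log-odds of same-operon per log10 copies
    baseline_logodds: float = -0.62  # ~0.35 coupling at the central copy number
    n_rows: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.sigma_log <= 0:
            raise ValueError("sigma_log must be > 0")


def gen_universe(spec: UniverseSpec) -> pd.DataFrame:
    """Genes partitioned into operons with truncated-geometric sizes."""
    rng = np.random.default_rng(spec.seed)
    genes, operons = [], []
    g = 0
    op = 0
    p = 1.0 / spec.mu_size
    while g < spec.n_genes:
        if spec.mu_size <= 1:
            size = 1
        else:
            size = int(min(rng.geometric(p), spec.max_size))
        size = min(size, spec.n_genes - g)
        for _ in range(size):
            genes.append(f"g{g:05d}")
            operons.append(f"op{op:05d}")
            g += 1
        op += 1
    return pd.DataFrame({"gene": genes, "operon_id": operons})


def gen_pairs(universe: pd.DataFrame, spec: PairGenSpec) -> pd.DataFrame:
    """Interacting gene pairs with a target same-operon fraction.

    Each pair is within-operon with probability ``f_target`` (operons chosen
    weighted by their number of internal pairs) and between-operon otherwise;
    ``f_target=None`` draws unbiased uniform random distinct pairs.
    """
    rng = np.random.default_rng(spec.seed)
    ops = universe.groupby("operon_id")["gene"].apply(list)
    sizes = ops.str.len().to_numpy()
    multi = ops[sizes >= 2]
    if spec.f_target not in (None, 0) and len(multi) == 0:
        raise ValueError("no multi-gene operons: within-operon pairs infeasible")
    genes = universe["gene"].to_numpy()
    op_of = universe.set_index("gene")["operon_id"]
    rows_a, rows_b = [], []
    if spec.f_target is None:
        for _ in range(spec.n_pairs):
            a, b = rng.choice(len(genes), size=2, replace=False)
            rows_a.append(genes[a]); rows_b.append(genes[b])
    else:
        weights = np.array([len(g) * (len(g) - 1) / 2 for g in multi], dtype=float)
        weights = weights / weights.sum() if weights.size else weights
        within = rng.random(spec.n_pairs) < spec.f_target
        for w in within:
            if w:
                members = multi.iloc[rng.choice(len(multi), p=weights)]
                a, b = rng.choice(len(members), size=2, replace=False)
                rows_a.append(members[a]); rows_b.append(members[b])
            else:
                while True:
                    a, b = rng.choice(len(genes), size=2, replace=False)
                    if op_of[genes[a]] != op_of[genes[b]]:
                        break
                rows_a.append(genes[a]); rows_b.append(genes[b])
    return pd.DataFrame({"gene_a": rows_a, "gene_b": rows_b})


def gen_expression(universe: pd.DataFrame, pairs: pd.DataFrame,
                   spec: ExpressionGenSpec) -> pd.DataFrame:
    """Single-cell-style average copy numbers with a planted
    expression-coupling relationship.

    One row per interacting gene (taken from the pair list, or from the
    universe if more rows are requested than the pair list provides); copy
    numbers are log-normal and the probability that the row's interaction is
    same-operon follows logistic(baseline + beta * log10(copies)).
    """
    rng = np.random.default_rng(spec.seed)
    interacting = pd.unique(pd.concat([pairs["gene_a"], pairs["gene_b"]])) \
        if len(pairs) else universe["gene"].to_numpy()
    if len(interacting) < spec.n_rows:
        extra = universe.loc[~universe["gene"].isin(interacting), "gene"].to_numpy()
        interacting = np.concatenate([interacting, extra])
    sel = interacting[: spec.n_rows]
    copies = rng.lognormal(spec.mu_log, spec.sigma_log, size=len(sel))
    logit = spec.baseline_logodds + spec.beta * (np.log10(copies)
                                                 - spec.mu_log / math.log(10))
    prob = 1.0 / (1.0 + np.exp(-logit))
    flags = (rng.random(len(sel)) < prob).astype(int)
    return pd.DataFrame({"gene": sel, "copy_number": copies,
                         "same_operon_interaction": flags})


# ---------------------------------------------------------------------------
# versioned kinetic fixtures


def load_fixture_file() -> dict:
    with resources.files("operonoise.data").joinpath("module_fixtures.json").open() as fh:
        return json.load(fh)


def gen_module_fixture(cls: ModuleClass, level: str = "mid", bursting: bool | None = None):
    """Default kinetic parameter set for one interaction module class.

    Returns (ExpressionParams, ModuleParams, BurstingParams) from the
    versioned fixture file.  ``level`` selects the low/mid/high protein
    expression preset (copies per gene per cell; the regulator module uses
    its own lower ladder).  With bursting enabled, k_tx is divided by the
    promoter duty cycle so the mean transcript count is preserved.

    ``bursting=None`` uses the per-class default: promoter bursting on, except
    for the branch point, whose substrate statistics are studied in the
    translational-bursting-only regime (promoter bursting drives that module
    into a bimodal spike-dominated regime where the CV misrepresents the
    variability; see the methods note).
    """
    cls = ModuleClass(cls)
    fx = load_fixture_file()
    if bursting is None:
        bursting = fx["modules"].get(cls.value, {}).get("bursting_default", True)
    ex = fx["expression"]
    ladder = ex["protein_levels_regulator_module"] if cls is ModuleClass.DUAL_REGULATORS_OR \
        else ex["protein_levels"]
    p_target = ladder[level]
    burst = BurstingParams(fx["bursting"]["k_goff"], fx["bursting"]["k_gon"], enabled=bursting)
    phi = burst_duty_cycle(burst)
    m_mean = ex["mean_mrna"]
    if cls is ModuleClass.LAC_REDUCED:
        p_target = ex["protein_levels"]["low"]
    expr = ExpressionParams(
        k_tx=ex["k_tx"] / phi,
        k_tl=p_target * ex["k_deg"] / m_mean,
        delta_m=ex["delta_m"],
        k_deg=ex["k_deg"],
    )

    if cls is ModuleClass.LINEAR_PATHWAY:
        m = dict(fx["modules"]["linear_pathway"])
        r0 = m.pop("ratio_target")
        sat = m["S0"] / (m["K_m1"] + m["S0"])
        m["k_cat1"] = r0 * m["k_cat2"] * p_target / (p_target * sat)
        mod = ModuleParams(**m)
    elif cls is ModuleClass.REDUNDANT_ENZYMES:
        mod = ModuleParams(**fx["modules"]["redundant_enzymes"])
    elif cls is ModuleClass.BRANCH_POINT:
        m = dict(fx["modules"]["branch_point"])
        m.pop("bursting_default", None)
        r0 = m.pop("ratio_target")
        m["J"] = r0 * (m["k_cat1"] + m["k_cat2"]) * p_target
        mod = ModuleParams(**m)
    elif cls is ModuleClass.DUAL_REGULATORS_OR:
        m = dict(fx["modules"]["dual_regulators_or"])
        m["K_hill"] = p_target
        mod = ModuleParams(**m)
    elif cls is ModuleClass.PHYSICAL_INTERACTION:
        mod = ModuleParams(**fx["modules"]["physical_interaction"])
    elif cls is ModuleClass.COVALENT_MODIFICATION:
        m = dict(fx["modules"]["covalent_modification"])
        m["k_p"] = m["k_demod"] / p_target
        mod = ModuleParams(**m)
    elif cls is ModuleClass.LAC_REDUCED:
        m = dict(fx["modules"]["lac_reduced"])
        levels = m.pop("lactose_levels_uM")
        key = {"low": "minimal", "mid": "mid", "high": "excess"}[level]
        m["lactose_ext"] = molecules_per_fL(levels[key])
        mod = ModuleParams(**m)
    else:  # pragma: no cover
        raise ValueError(cls)
    return expr, mod, burst


def covalent_saturating_fixture(level: str = "mid", bursting: bool = True):
    """Zero-order (Michaelis-Menten) variant of the covalent-modification
    module, used for ultrasensitive-threshold analysis."""
    expr, _, burst = gen_module_fixture(ModuleClass.COVALENT_MODIFICATION, level, bursting)
    mod = ModuleParams(**load_fixture_file()["modules"]["covalent_modification_saturating"])
    return expr, mod, burst
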