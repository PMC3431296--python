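"""Configuration-driven orchestration: build -> simulate -> summarize ->
compare -> report, plus the bioinformatic enrichment track.

Every stochastic step derives its stream from the single master seed in the
config, so re-running an identical config reproduces every number exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__
from .coupling_models import (
    CouplingMode,
    ModuleClass,
    build_comparison,
    module_readout,
    simulate_module_ensemble,
    total_protein_species,
    verify_matched_controls,
)
from .lna import delta_cv2, predict_sign
from .noise_stats import summarize
from .operon_stats import bootstrap_diff_test, median_split, randomize_pairs
from .synthetic_data import (
    ExpressionGenSpec,
    PairGenSpec,
    UniverseSpec,
    gen_expression,
    gen_module_fixture,
    gen_pairs,
    gen_universe,
)
from .ultrasense import crossing_fraction

log = logging.getLogger("operonoise")

__all__ = ["RunConfig", "ComparisonReport", "run_comparison", "run_enrichment"]


@dataclass
class RunConfig:
    module_class: str = "linear_pathway"
    coupled_mode: str = "cotranslated"
    bursting: bool | None = None
    expression_level: str = "mid"
    n_runs: int = 2000
    t_end: float = 16000.0
    n_points: int = 100
    burn_in: float = 0.5
    seed: int = 1
    with_lna: bool = True
    with_ultra: bool = True

    def __post_init__(self):
        if self.n_runs <= 0:
            raise ValueError("n_runs must be > 0")
        if not (0 <= self.burn_in < 1):
            raise ValueError("burn_in must be in [0, 1)")
        ModuleClass(self.module_class)
        CouplingMode(self.coupled_mode)

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**d)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class ComparisonReport:
    config: dict
    config_hash: str
    version: str
    readout: str
    cv2_coupled: float
    cv2_coupled_se: float
    cv2_uncoupled: float
    cv2_uncoupled_se: float
    delta_cv2_ssa: float
    delta_cv2_se: float
    delta_cv2_lna: float | None
    predicted_sign: str
    verdict: str
    sign_concordant: bool | None
    controls_passed: bool
    crossing_coupled: float | None
    crossing_uncoupled: float | None
    gene_totals: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


def run_comparison(config: RunConfig) -> ComparisonReport:
    """Full coupled-vs-uncoupled comparison for one interaction module."""
    t0 = time.time()
    cls = ModuleClass(config.module_class)
    expr, mod, burst = gen_module_fixture(cls, config.expression_level, config.bursting)
    pair = build_comparison(cls, expr, mod, burst, CouplingMode(config.coupled_mode))
    log.info("built %s comparison (%s vs uncoupled)", cls.value, config.coupled_mode)

    ens_c = simulate_module_ensemble(pair.coupled_system, config.n_runs, config.t_end,
                                     config.seed, config.n_points)
    ens_u = simulate_module_ensemble(pair.uncoupled_system, config.n_runs, config.t_end,
                                     config.seed + 1, config.n_points)
    log.info("simulated 2 x %d runs in %.1fs", config.n_runs, time.time() - t0)

    s_c = summarize(ens_c, config.burn_in)
    s_u = summarize(ens_u, config.burn_in)
    readout = module_readout(cls)
    cv2_c, cv2_u = s_c.cv2_of(readout), s_u.cv2_of(readout)
    se_c, se_u = s_c.cv2_se_of(readout), s_u.cv2_se_of(readout)
    delta = cv2_u - cv2_c
    delta_se = float(np.hypot(se_c, se_u))

    try:
        sign = predict_sign(cls, readout)
    except KeyError:
        sign = "small_either"
    verdict = ("cotranscribed lower CV(%s)" % readout) if delta > 0 else \
              ("uncoupled lower CV(%s)" % readout)
    concordant = None
    if sign != "small_either":
        concordant = (delta > 0) == (sign == "positive") and abs(delta) > 3 * delta_se

    dlna = None
    if config.with_lna:
        try:
            expr_nb, mod_nb, burst_nb = gen_module_fixture(cls, config.expression_level, False)
            pair_nb = build_comparison(cls, expr_nb, mod_nb, burst_nb,
                                       CouplingMode(config.coupled_mode))
            dlna = delta_cv2(pair_nb, readout, cls).value
        except Exception as exc:  # LNA can legitimately fail near thresholds
            log.warning("LNA unavailable for %s: %s", cls.value, exc)

    cross_c = cross_u = None
    if config.with_ultra and cls in (ModuleClass.LINEAR_PATHWAY, ModuleClass.BRANCH_POINT,
                                     ModuleClass.PHYSICAL_INTERACTION):
        keep = slice(int(config.burn_in * config.n_points), None)
        cross_c = float(np.nanmean(crossing_fraction(
            ens_c.states[:, keep, :], ens_c.names, cls, mod, expr)))
        cross_u = float(np.nanmean(crossing_fraction(
            ens_u.states[:, keep, :], ens_u.names, cls, mod, expr)))

    controls = verify_matched_controls(pair, ens_c, ens_u, burn_in=config.burn_in)
    totals = {}
    for gene, sps in total_protein_species(cls).items():
        totals[gene] = {
            "coupled_mean": s_c.stat_of_sum(sps, "mean")[0],
            "uncoupled_mean": s_u.stat_of_sum(sps, "mean")[0],
        }
    log.info("comparison %s done in %.1fs", cls.value, time.time() - t0)
    return ComparisonReport(
        config=config.to_dict(), config_hash=config.digest(), version=__version__,
        readout=readout, cv2_coupled=cv2_c, cv2_coupled_se=se_c,
        cv2_uncoupled=cv2_u, cv2_uncoupled_se=se_u,
        delta_cv2_ssa=delta, delta_cv2_se=delta_se, delta_cv2_lna=dlna,
        predicted_sign=sign, verdict=verdict, sign_concordant=concordant,
        controls_passed=controls.passed,
        crossing_coupled=cross_c, crossing_uncoupled=cross_u, gene_totals=totals,
    )


@dataclass
class EnrichmentConfig:
    n_genes: int = 8000
    mu_size: float = 3.0
    max_size: int = 12
    n_pairs: int = 3938
    f_target: float | None = 0.35
    n_reps_randomization: int = 1000
    n_rows_expression: int = 300
    beta: float = -1.0
    n_reps_bootstrap: int = 10000
    seed: int = 1


def run_enrichment(config: EnrichmentConfig) -> dict:
    """Synthetic enrichment + expression-split analysis; returns a JSON-able
    dict with the randomization and median-split results."""
    universe = gen_universe(UniverseSpec(config.n_genes, config.mu_size,
                                         config.max_size, config.seed))
    pairs = gen_pairs(universe, PairGenSpec(config.n_pairs, config.f_target,
                                            config.seed + 1))
    rand = randomize_pairs(pairs, universe, config.n_reps_randomization,
                           config.seed + 2, alternative="greater")
    table = gen_expression(universe, pairs,
                           ExpressionGenSpec(beta=config.beta,
                                             n_rows=config.n_rows_expression,
                                             seed=config.seed + 3))
    split = median_split(table)
    p_boot = bootstrap_diff_test(table, config.n_reps_bootstrap, config.seed + 4)
    verdict = "Coupled" if (not rand.degenerate and rand.p < 1e-6) else (
        "Uncoupled" if (not rand.degenerate and rand.z < 0 and rand.p > 1 - 1e-6) else "ns")
    return {
        "randomization": {
            "f_observed": rand.f_observed, "mu_r": rand.mu_r, "sigma_r": rand.sigma_r,
            "z": rand.z, "p": rand.p, "n_reps": rand.n_reps, "verdict": verdict,
        },
        "median_split": {
            "f_low": split.f_low, "f_high": split.f_high, "diff": split.diff,
            "p_boot": p_boot,
        },
        "seed": config.seed,
    }
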