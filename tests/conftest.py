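"""Shared fixtures.

The heavyweight session fixture ``module_ensembles`` simulates the full
coupled/uncoupled SSA ensembles (n_runs per configuration) for all six
interaction module classes once and exposes summaries, crossing fractions and
LNA results; the acceptance tests for sign concordance, LNA/SSA agreement and
threshold asymmetry all share it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from operonoise.coupling_models import (
    CouplingMode,
    ModuleClass,
    build_comparison,
    module_readout,
    simulate_module_ensemble,
    total_protein_species,
)
from operonoise.lna import LNAResult, lna_result
from operonoise.noise_stats import EnsembleSummary, summarize
from operonoise.reaction_core import (
    RateLaw,
    Reaction,
    ReactionSystem,
    Species,
    simulate_ensemble,
)
from operonoise.synthetic_data import gen_module_fixture
from operonoise.ultrasense import crossing_fraction

#: ensemble size for the full comparison (paper-scale is 10,000; this
#: desk-scale default matches the package's documented study conditions)
N_RUNS = 2000
T_END = 16000.0
N_POINTS = 100
BURN_IN = 0.5

SIX_CLASSES = [
    ModuleClass.LINEAR_PATHWAY,
    ModuleClass.REDUNDANT_ENZYMES,
    ModuleClass.BRANCH_POINT,
    ModuleClass.DUAL_REGULATORS_OR,
    ModuleClass.PHYSICAL_INTERACTION,
    ModuleClass.COVALENT_MODIFICATION,
]


def birth_death(k=1.0, gamma=0.1, x0=0) -> ReactionSystem:
    return ReactionSystem(
        [Species("X", x0)],
        [
            Reaction({}, {"X": 1}, {}, RateLaw.mass_action(k), name="birth"),
            Reaction({"X": 1}, {}, {}, RateLaw.mass_action(gamma), name="death"),
        ],
    )


@dataclass
class ModuleComparison:
    cls: ModuleClass
    expr: object
    mod: object
    bursting: object
    readout: str
    summary_coupled: EnsembleSummary
    summary_uncoupled: EnsembleSummary
    lna_coupled: LNAResult
    lna_uncoupled: LNAResult
    crossing_coupled: np.ndarray | None
    crossing_uncoupled: np.ndarray | None
    controls_passed: bool

    @property
    def delta_cv2(self) -> float:
        return self.summary_uncoupled.cv2_of(self.readout) - self.summary_coupled.cv2_of(self.readout)

    @property
    def delta_cv2_se(self) -> float:
        return float(np.hypot(self.summary_uncoupled.cv2_se_of(self.readout),
                              self.summary_coupled.cv2_se_of(self.readout)))


def _run_class(cls: ModuleClass, seed: int) -> ModuleComparison:
    from operonoise.coupling_models import verify_matched_controls

    expr, mod, burst = gen_module_fixture(cls)
    pair = build_comparison(cls, expr, mod, burst, CouplingMode.COTRANSLATED)
    ens_c = simulate_module_ensemble(pair.coupled_system, N_RUNS, T_END, seed, N_POINTS)
    ens_u = simulate_module_ensemble(pair.uncoupled_system, N_RUNS, T_END, seed + 1, N_POINTS)
    s_c = summarize(ens_c, BURN_IN)
    s_u = summarize(ens_u, BURN_IN)
    cross_c = cross_u = None
    if cls in (ModuleClass.LINEAR_PATHWAY, ModuleClass.BRANCH_POINT):
        keep = slice(int(BURN_IN * N_POINTS), None)
        cross_c = crossing_fraction(ens_c.states[:, keep, :], ens_c.names, cls, mod, expr)
        cross_u = crossing_fraction(ens_u.states[:, keep, :], ens_u.names, cls, mod, expr)
    controls = verify_matched_controls(pair, ens_c, ens_u, burn_in=BURN_IN)
    return ModuleComparison(
        cls, expr, mod, burst, module_readout(cls), s_c, s_u,
        lna_result(pair.coupled_system), lna_result(pair.uncoupled_system),
        cross_c, cross_u, controls.passed,
    )


@pytest.fixture(scope="session")
def module_ensembles():
    """Coupled/uncoupled SSA ensembles for all six module classes at the
    default study conditions (built once per session)."""
    return {cls: _run_class(cls, seed=2 * i + 101) for i, cls in enumerate(SIX_CLASSES)}


@pytest.fixture(scope="session")
def bd_stationary_samples():
    """2000 independent stationary samples of the birth-death process with
    mean 10 (one terminal sample per trajectory)."""
    sys_ = birth_death(1.0, 0.1, x0=10)
    ens = simulate_ensemble(sys_, 2000, 120.0, master_seed=42, n_points=4)
    return ens.states[:, -1, 0].astype(int)
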