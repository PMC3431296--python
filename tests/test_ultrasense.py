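"""Ultrasensitive thresholds: mean-field response curves, logarithmic
sensitivity, capacity flux-ratio traces and spike detection."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from operonoise.coupling_models import (
    BurstingParams,
    CouplingMode,
    ModuleClass,
    build_comparison,
    simulate_module_ensemble,
)
from operonoise.reaction_core import Trajectory
from operonoise.synthetic_data import covalent_saturating_fixture, gen_module_fixture
from operonoise.ultrasense import (
    ResponseCurve,
    crossing_fraction,
    detect_spikes,
    effective_sensitivity,
    flux_ratio_trace,
    response_curve,
)


# ---------------------------------------------------------------------------
# response curves


def test_linear_pathway_closed_form():
    """Michaelis-Menten flux balance: I* = K_m * r/(1-r), to 1e-6 relative
    on r in [0.05, 0.95]."""
    expr, mod, _ = gen_module_fixture(ModuleClass.LINEAR_PATHWAY, bursting=False)
    grid = np.linspace(0.05, 0.95, 46)
    curve = response_curve(ModuleClass.LINEAR_PATHWAY, mod, grid, expr)
    expected = mod.K_m2 * grid / (1 - grid)
    ok = ~curve.diverged
    assert ok.all()
    np.testing.assert_allclose(curve.output[ok], expected[ok], rtol=1e-6)


def test_divergence_flag_past_saturation():
    expr, mod, _ = gen_module_fixture(ModuleClass.LINEAR_PATHWAY, bursting=False)
    curve = response_curve(ModuleClass.LINEAR_PATHWAY, mod, np.array([0.5, 0.99, 1.0, 1.3]), expr)
    assert list(curve.diverged) == [False, False, True, True]
    assert np.isnan(curve.output[2])


def test_effective_sensitivity_closed_forms():
    expr, mod, _ = gen_module_fixture(ModuleClass.LINEAR_PATHWAY, bursting=False)
    # local sensitivity at r = 0.9 equals 1/(1-r) = 10
    local = response_curve(ModuleClass.LINEAR_PATHWAY, mod,
                           0.9 * np.exp(np.linspace(-1e-3, 1e-3, 5)), expr)
    assert abs(effective_sensitivity(local) - 10.0) < 0.2

    # a linear curve (output proportional to ratio) has sensitivity exactly 1
    grid = np.linspace(0.2, 2.0, 30)
    lin = ResponseCurve(grid, 7.0 * grid, np.zeros_like(grid, dtype=bool), "P")
    assert abs(effective_sensitivity(lin) - 1.0) < 1e-9

    # Hill n=4: maximal log-log slope approaches 4 below K
    x = np.geomspace(0.05, 10.0, 200)
    h = x ** 4 / (1 + x ** 4)
    hill = ResponseCurve(x, h, np.zeros_like(x, dtype=bool), "h")
    assert abs(effective_sensitivity(hill) - 4.0) < 0.1


def test_effective_sensitivity_needs_points():
    grid = np.array([0.5, 0.7, 0.9])
    c = ResponseCurve(grid, np.full(3, np.nan), np.ones(3, dtype=bool), "I")
    with pytest.raises(ValueError):
        effective_sensitivity(c)


def test_ultrasensitivity_of_nonredundant_classes():
    """All four non-redundant module classes have an ultrasensitive readout
    (max log sensitivity > 1); the redundant readout does not (<= 1.2)."""
    sens = {}
    for cls in (ModuleClass.LINEAR_PATHWAY, ModuleClass.BRANCH_POINT):
        expr, mod, _ = gen_module_fixture(cls, bursting=False)
        curve = response_curve(cls, mod, np.linspace(0.05, 0.95, 91), expr)
        sens[cls] = effective_sensitivity(curve)
    for cls in (ModuleClass.PHYSICAL_INTERACTION,):
        expr, mod, _ = gen_module_fixture(cls, bursting=False)
        curve = response_curve(cls, mod, np.linspace(0.5, 1.5, 101), expr)
        sens[cls] = effective_sensitivity(curve)
    expr, mod, _ = covalent_saturating_fixture(bursting=False)
    curve = response_curve(ModuleClass.COVALENT_MODIFICATION, mod, np.linspace(0.5, 1.5, 101), expr)
    sens[ModuleClass.COVALENT_MODIFICATION] = effective_sensitivity(curve)

    for cls, s in sens.items():
        assert s > 1.0, f"{cls} readout not ultrasensitive (max sensitivity {s:.2f})"

    expr, mod, _ = gen_module_fixture(ModuleClass.REDUNDANT_ENZYMES, bursting=False)
    curve = response_curve(ModuleClass.REDUNDANT_ENZYMES, mod, np.linspace(0.2, 2.0, 50), expr)
    assert effective_sensitivity(curve) <= 1.2


def test_titration_switch_shape():
    """Free monomer is near zero while the partner is in excess and grows
    roughly linearly past ratio 1 (molecular titration)."""
    expr, mod, _ = gen_module_fixture(ModuleClass.PHYSICAL_INTERACTION, bursting=False)
    grid = np.array([0.6, 0.9, 1.0, 1.1, 1.5, 2.0])
    c = response_curve(ModuleClass.PHYSICAL_INTERACTION, mod, grid, expr)
    p = expr.mean_protein
    assert c.output[0] < 0.02 * p            # B in excess: free A titrated away
    assert c.output[-1] > 0.4 * p            # A in excess: grows with production
    # approximately linear growth in the excess regime
    slope = (c.output[-1] - c.output[-2]) / (grid[-1] - grid[-2]) / p
    assert 0.7 < slope < 1.3


# ---------------------------------------------------------------------------
# flux-ratio traces


def _flat_traj(names, rows):
    rows = np.asarray(rows, dtype=np.float64)
    return Trajectory(np.arange(rows.shape[0], dtype=float) + 1.0, rows, names)


def test_flux_ratio_constant_for_equal_enzymes():
    expr, mod, _ = gen_module_fixture(ModuleClass.LINEAR_PATHWAY, bursting=False)
    tr = _flat_traj(["A", "B"], np.full((10, 2), 500.0))
    ratio = flux_ratio_trace(tr, ModuleClass.LINEAR_PATHWAY, mod, expr)
    assert np.allclose(ratio, ratio[0])
    sat = mod.S0 / (mod.K_m1 + mod.S0)
    np.testing.assert_allclose(ratio[0], mod.k_cat1 * sat / mod.k_cat2, rtol=1e-12)


def test_flux_ratio_zero_denominator_flagged():
    expr, mod, _ = gen_module_fixture(ModuleClass.LINEAR_PATHWAY, bursting=False)
    tr = _flat_traj(["A", "B"], [[500.0, 0.0], [500.0, 400.0]])
    ratio = flux_ratio_trace(tr, ModuleClass.LINEAR_PATHWAY, mod, expr)
    assert np.isnan(ratio[0]) and np.isfinite(ratio[1])


def test_linear_pathway_crossing_asymmetry():
    """The uncoupled linear pathway spends more time past V+/V- = 1 than the
    cotranslated configuration (one-sided Mann-Whitney, alpha = 0.05)."""
    expr, mod, burst = gen_module_fixture(ModuleClass.LINEAR_PATHWAY)
    pair = build_comparison(ModuleClass.LINEAR_PATHWAY, expr, mod, burst)
    ens_c = simulate_module_ensemble(pair.coupled_system, 250, 16000, 61, 80)
    ens_u = simulate_module_ensemble(pair.uncoupled_system, 250, 16000, 62, 80)
    fc = crossing_fraction(ens_c.states[:, 40:, :], ens_c.names, ModuleClass.LINEAR_PATHWAY, mod, expr)
    fu = crossing_fraction(ens_u.states[:, 40:, :], ens_u.names, ModuleClass.LINEAR_PATHWAY, mod, expr)
    assert np.nanmean(fu) > np.nanmean(fc)
    assert mannwhitneyu(fu, fc, alternative="greater").pvalue < 0.05
    # ratio variance is itself smaller when cotranscribed (same means)
    assert np.nanmean(fc) < 0.05


def test_physical_module_ratio_trace_uses_transcripts():
    expr, mod, _ = gen_module_fixture(ModuleClass.PHYSICAL_INTERACTION)
    tr = _flat_traj(["m", "A", "B", "AB"], np.tile([8.0, 20, 25, 500], (5, 1)))
    ratio = flux_ratio_trace(tr, ModuleClass.PHYSICAL_INTERACTION, mod, expr)
    assert np.allclose(ratio, 1.0)  # shared transcript: production fluxes identical
    tr2 = _flat_traj(["m1", "m2", "A", "B", "AB"], np.tile([12.0, 6.0, 20, 25, 500], (5, 1)))
    ratio2 = flux_ratio_trace(tr2, ModuleClass.PHYSICAL_INTERACTION, mod, expr)
    assert np.allclose(ratio2, 2.0)


# ---------------------------------------------------------------------------
# spikes


def test_detect_spikes_constant_trace():
    tr = _flat_traj(["I"], np.full((50, 1), 20.0))
    assert detect_spikes(tr, "I") == []


def test_detect_spikes_square_pulses():
    x = np.full(200, 10.0)
    x[40:60] = 200.0        # long spike (20 s at dt=1)
    x[100:103] = 200.0      # too short
    tr = _flat_traj(["I"], x[:, None])
    ratio = np.where(x > 100, 2.0, 0.5)
    events = detect_spikes(tr, "I", threshold_mult=5.0, min_duration=10.0,
                           baseline=10.0, ratio=ratio)
    assert len(events) == 1
    ev = events[0]
    assert ev.peak == 200.0
    assert ev.crossing
    assert ev.end - ev.start >= 10.0


def test_detect_spikes_validation():
    tr = _flat_traj(["I"], np.full((10, 1), 1.0))
    with pytest.raises(ValueError):
        detect_spikes(tr, "I", threshold_mult=1.0)


def test_uncoupled_linear_pathway_spikes_more(module_ensembles):
    """Spike counts (5x ensemble median for >= 1 sample interval) are higher
    in the uncoupled linear pathway, and uncoupled spikes coincide with
    threshold crossings."""
    comp = module_ensembles[ModuleClass.LINEAR_PATHWAY]
    # reuse summaries' medians via fresh small ensembles for trajectories
    expr, mod, burst = comp.expr, comp.mod, comp.bursting
    pair = build_comparison(ModuleClass.LINEAR_PATHWAY, expr, mod, burst)
    ens_c = simulate_module_ensemble(pair.coupled_system, 200, 16000, 71, 80)
    ens_u = simulate_module_ensemble(pair.uncoupled_system, 200, 16000, 72, 80)
    dt = ens_c.times[1] - ens_c.times[0]
    counts = {}
    cross_hits = 0
    cross_tot = 0
    for tag, ens in (("c", ens_c), ("u", ens_u)):
        med = float(np.median(ens.species_runs("I")[:, 40:]))
        n = 0
        for i in range(ens.n_runs):
            tr = ens.trajectory(i)
            ratio = flux_ratio_trace(tr, ModuleClass.LINEAR_PATHWAY, mod, expr)
            evs = detect_spikes(tr, "I", threshold_mult=5.0, min_duration=dt,
                                baseline=med, ratio=ratio)
            n += len(evs)
            if tag == "u":
                cross_tot += len(evs)
                cross_hits += sum(e.crossing for e in evs)
        counts[tag] = n
    assert counts["u"] > counts["c"]
    assert cross_tot > 20
    assert cross_hits / cross_tot >= 0.8
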