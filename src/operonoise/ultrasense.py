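"""Ultrasensitive-threshold analysis.

Non-redundant interaction modules hide a zero-order ultrasensitive switch:
the steady-state readout responds sharply when the ratio of production to
consumption capacity (V+/V-) crosses 1, because consumption is enzyme-
mediated and saturable (linear pathway, branch point) or the readout is set
by molecular titration (heterodimer, covalent modification).  This module
computes mean-field response curves of the readout versus V+/V-, their
maximal logarithmic sensitivity, capacity flux-ratio traces along stochastic
trajectories, and spike statistics of the readout.

Ratio traces use enzyme *capacity* (V_max-type) fluxes computed from copy
numbers, not instantaneous realized fluxes, so the threshold at V+/V- = 1 is
meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .coupling_models import ExpressionParams, ModuleClass, ModuleParams

__all__ = ["ResponseCurve", "SpikeEvent", "response_curve",
           "effective_sensitivity", "flux_ratio_trace", "detect_spikes",
           "crossing_fraction"]


@dataclass
class ResponseCurve:
    ratio_grid: np.ndarray
    output: np.ndarray
    diverged: np.ndarray
    readout: str

    def __post_init__(self):
        if np.any(np.diff(self.ratio_grid) <= 0):
            raise ValueError("ratio grid must be strictly increasing")


@dataclass
class SpikeEvent:
    start: float
    end: float
    peak: float
    crossing: bool


_READOUTS = {
    ModuleClass.LINEAR_PATHWAY: "I",
    ModuleClass.BRANCH_POINT: "s",
    ModuleClass.PHYSICAL_INTERACTION: "A",
    ModuleClass.COVALENT_MODIFICATION: "A",
    ModuleClass.REDUNDANT_ENZYMES: "P",
}


def response_curve(cls: ModuleClass, mod: ModuleParams, ratio_grid,
                   expr: ExpressionParams = None) -> ResponseCurve:
    """Steady-state readout versus the production/consumption capacity ratio.

    The relevant production flux is rescaled so V+/V- equals each grid value
    (protein levels held at their stationary means, taken from ``expr``);
    points with no finite steady state are flagged as diverged.
    """
    cls = ModuleClass(cls)
    if cls not in _READOUTS:
        raise ValueError(f"no response-curve readout defined for {cls}")
    expr = expr or ExpressionParams()
    grid = np.asarray(ratio_grid, dtype=np.float64)
    p = expr.mean_protein                    # stationary copies of A and B
    out = np.full_like(grid, np.nan)
    div = np.zeros_like(grid, dtype=bool)

    if cls in (ModuleClass.LINEAR_PATHWAY, ModuleClass.BRANCH_POINT):
        # saturable consumption V- = total k_cat capacity; production rescaled
        if cls is ModuleClass.LINEAR_PATHWAY:
            vminus = mod.k_cat2 * p
            km = mod.K_m2
        else:
            vminus = (mod.k_cat1 + mod.k_cat2) * p
            km = mod.K_m1
        for i, r in enumerate(grid):
            if r >= 1.0:
                div[i] = True
                continue
            j = r * vminus
            out[i] = brentq(lambda s: j - vminus * s / (km + s), 0.0,
                            1e12, xtol=1e-12, rtol=1e-12)
    elif cls is ModuleClass.REDUNDANT_ENZYMES:
        # linear removal: readout proportional to the production/removal ratio
        sat = mod.S0 / (mod.K_m1 + mod.S0)
        base = (mod.k_cat1 + mod.k_cat2) * p * sat
        out = grid * base / mod.k_out
    elif cls is ModuleClass.PHYSICAL_INTERACTION:
        # molecular titration: ratio of production fluxes of A and B
        keff = (mod.k_unb + expr.k_deg) / mod.k_b
        tb = p
        for i, r in enumerate(grid):
            ta = r * tb
            # (ta-ab)(tb-ab) = keff*ab
            bq = -(ta + tb + keff)
            ab = (-bq - math.sqrt(bq * bq - 4 * ta * tb)) / 2.0
            out[i] = ta - ab
    elif cls is ModuleClass.COVALENT_MODIFICATION:
        # unmodified A vs production-flux ratio of A to B; zero-order
        # (saturating) kinetics required for a sharp threshold
        tb = p
        for i, r in enumerate(grid):
            ta = r * tb
            if mod.saturating:
                def bal(a):
                    astar = ta - a
                    vmod = mod.k_p * tb * a / (mod.K_mA + a)
                    vdem = mod.k_demod * astar / (mod.K_mAstar + astar)
                    return vmod - vdem - expr.k_deg * astar
            else:
                def bal(a):
                    astar = ta - a
                    return mod.k_p * tb * a - mod.k_demod * astar - expr.k_deg * astar
            out[i] = brentq(bal, 0.0, ta, xtol=1e-12, rtol=1e-12)
    return ResponseCurve(grid, out, div, _READOUTS[cls])


def effective_sensitivity(curve: ResponseCurve) -> float:
    """Maximum |d ln(output) / d ln(ratio)| over the non-diverged part of the
    curve (finite differences on the log-log curve); a response is called
    ultrasensitive when this exceeds 1."""
    ok = (~curve.diverged) & np.isfinite(curve.output) & (curve.output > 0)
    if ok.sum() < 3:
        raise ValueError("need at least 3 non-diverged points")
    lr = np.log(curve.ratio_grid[ok])
    lo = np.log(curve.output[ok])
    return float(np.max(np.abs(np.gradient(lo, lr))))


# ---------------------------------------------------------------------------
# capacity flux-ratio traces


def _mrna_series(traj, gene):
    names = traj.names
    if "m" in names:
        return traj.series("m")
    return traj.series("m1" if gene == "A" else "m2")


def flux_ratio_trace(traj, cls: ModuleClass, mod: ModuleParams,
                     expr: ExpressionParams = None) -> np.ndarray:
    """Time series of the class-specific V+/V- capacity ratio computed from
    copy numbers along a trajectory; undefined (zero-denominator) points are
    returned as NaN."""
    cls = ModuleClass(cls)
    expr = expr or ExpressionParams()
    if cls is ModuleClass.LINEAR_PATHWAY:
        vplus = mod.k_cat1 * traj.series("A") * mod.S0 / (mod.K_m1 + mod.S0)
        vminus = mod.k_cat2 * traj.series("B")
    elif cls is ModuleClass.BRANCH_POINT:
        vplus = np.full(len(traj.times), mod.J)
        vminus = mod.k_cat1 * traj.series("A") + mod.k_cat2 * traj.series("B")
    elif cls is ModuleClass.PHYSICAL_INTERACTION:
        vplus = expr.k_tl * _mrna_series(traj, "A")
        vminus = expr.k_tl * _mrna_series(traj, "B")
    elif cls is ModuleClass.COVALENT_MODIFICATION:
        vplus = expr.k_tl * _mrna_series(traj, "A") + mod.k_demod
        vminus = mod.k_p * traj.series("B")
    else:
        raise ValueError(f"no capacity flux ratio defined for {cls}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(vminus > 0, vplus / vminus, np.nan)
    return ratio


def crossing_fraction(states, names, cls, mod, expr=None) -> np.ndarray:
    """Per-trajectory fraction of time with V+/V- > 1 for an ensemble state
    array (n_runs, n_times, n_species)."""
    from .reaction_core import Trajectory

    out = np.empty(states.shape[0])
    tgrid = np.arange(states.shape[1], dtype=float) + 1.0
    for i in range(states.shape[0]):
        traj = Trajectory(tgrid, np.asarray(states[i], dtype=np.float64), list(names))
        ratio = flux_ratio_trace(traj, cls, mod, expr)
        ok = np.isfinite(ratio)
        out[i] = np.mean(ratio[ok] > 1.0) if ok.any() else np.nan
    return out


# ---------------------------------------------------------------------------
# spikes


def detect_spikes(traj, species: str, threshold_mult: float = 5.0,
                  min_duration: float = 60.0, baseline: float = None,
                  ratio: np.ndarray = None) -> list:
    """Events where a species exceeds ``threshold_mult`` times its baseline
    (ensemble median, or the trajectory median if none is given) for at least
    ``min_duration`` seconds; each event is annotated with whether V+/V-
    exceeded 1 at any point during it."""
    if threshold_mult <= 1:
        raise ValueError("threshold_mult must be > 1")
    x = traj.series(species)
    base = float(np.median(x)) if baseline is None else float(baseline)
    thr = threshold_mult * max(base, 1.0)
    above = x > thr
    events = []
    t = traj.times
    i = 0
    n = len(x)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            start, end = t[i], t[j]
            if end - start >= min_duration:
                crossing = bool(np.nanmax(ratio[i:j + 1]) > 1.0) if ratio is not None else False
                events.append(SpikeEvent(float(start), float(end), float(x[i:j + 1].max()), crossing))
            i = j + 1
        else:
            i += 1
    return events
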