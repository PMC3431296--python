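"""Core simulation engine: propensities, exact SSA, tau-leaping, mean-field
steady states and stationary windows."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare, ks_2samp, poisson

from operonoise.coupling_models import BurstingParams, CouplingMode, ExpressionParams, build_expression
from operonoise.reaction_core import (
    Ensemble,
    NoFiniteSteadyState,
    RateLaw,
    Reaction,
    ReactionSystem,
    Species,
    propensity_vector,
    simulate_ensemble,
    simulate_ssa,
    simulate_tau_leap,
    stationary_window,
    steady_state_mean_field,
)

from conftest import birth_death


# ---------------------------------------------------------------------------
# propensities


@pytest.mark.parametrize(
    "system, state, expected",
    [
        # bimolecular mass action: k*a*b/Omega
        (
            ReactionSystem(
                [Species("A", 2), Species("B", 3)],
                [Reaction({"A": 1, "B": 1}, {}, {}, RateLaw.mass_action(2.0))],
            ),
            [2, 3],
            [12.0],
        ),
        # any required reactant at 0 copies -> 0
        (
            ReactionSystem(
                [Species("A", 0), Species("B", 3)],
                [Reaction({"A": 1, "B": 1}, {}, {}, RateLaw.mass_action(2.0))],
            ),
            [0, 3],
            [0.0],
        ),
        # dimerization combinatorics: k*a*(a-1)/2
        (
            ReactionSystem(
                [Species("A", 5)],
                [Reaction({"A": 2}, {}, {}, RateLaw.mass_action(1.0))],
            ),
            [5],
            [10.0],
        ),
        # Michaelis-Menten at half saturation: k_cat*e*s/(K_m+s)
        (
            ReactionSystem(
                [Species("S", 100), Species("E", 5)],
                [Reaction({"S": 1}, {}, {"E": 1}, RateLaw.michaelis_menten(10.0, 100.0))],
            ),
            [100, 5],
            [25.0],
        ),
        # Hill production at the half-saturation point
        (
            ReactionSystem(
                [Species("X", 50), Species("P", 0)],
                [Reaction({}, {"P": 1}, {"X": 1}, RateLaw.hill(4.0, 50.0, 2.0))],
            ),
            [50, 0],
            [2.0],
        ),
    ],
)
def test_propensity_examples(system, state, expected):
    np.testing.assert_allclose(propensity_vector(system, state), expected, rtol=1e-12)


def test_propensity_volume_scaling():
    sys_ = ReactionSystem(
        [Species("A", 2), Species("B", 3)],
        [Reaction({"A": 1, "B": 1}, {}, {}, RateLaw.mass_action(2.0))],
        volume_Omega=2.0,
    )
    np.testing.assert_allclose(propensity_vector(sys_, [2, 3]), [6.0])


def test_propensity_rejects_bad_input():
    sys_ = birth_death()
    with pytest.raises(ValueError):
        propensity_vector(sys_, [-1])
    with pytest.raises(ValueError):
        propensity_vector(sys_, [1, 2])
    with pytest.raises(ValueError):
        ReactionSystem.from_json(
            '{"species": [{"name": "X"}], "reactions": '
            '[{"reactants": {}, "products": {"X": 1}, "law": {"kind": "bogus", "params": [1]}}]}'
        )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    k=st.floats(0.0, 100.0),
    a=st.integers(0, 50),
    b=st.integers(0, 50),
)
def test_propensity_nonnegative_and_zero_rule(k, a, b):
    """Propensities are never negative and vanish whenever a required
    reactant is absent."""
    sys_ = ReactionSystem(
        [Species("A", 0), Species("B", 0)],
        [Reaction({"A": 1, "B": 2}, {}, {}, RateLaw.mass_action(k))],
    )
    (v,) = propensity_vector(sys_, [a, b])
    assert v >= 0
    if a == 0 or b < 2:
        assert v == 0


# ---------------------------------------------------------------------------
# exact SSA


def test_ssa_determinism_and_freeze():
    sys_ = birth_death(1.0, 0.1)
    grid = np.linspace(0, 500, 60)
    t1 = simulate_ssa(sys_, 500, grid, seed=7)
    t2 = simulate_ssa(sys_, 500, grid, seed=7)
    assert np.array_equal(t1.states, t2.states)
    t3 = simulate_ssa(sys_, 500, grid, seed=8)
    assert not np.array_equal(t1.states, t3.states)

    # pure decay: monotone non-increasing, frozen at 0 once absorbed
    dec = birth_death(0.0, 0.1, x0=50)
    td = simulate_ssa(dec, 2000, np.linspace(0, 2000, 100), seed=1)
    x = td.states[:, 0]
    assert np.all(np.diff(x) <= 0)
    assert x[-1] >= 0


def test_ssa_birth_death_poisson_stationary(bd_stationary_samples):
    """Stationary law of the birth-death process is Poisson(k/gamma):
    chi-square goodness of fit at alpha=0.01 over 2000 independent runs."""
    x = bd_stationary_samples
    mean = 10.0
    assert abs(x.mean() - mean) < 3 * math.sqrt(mean / len(x))
    assert abs(x.var() - mean) < 4 * mean * math.sqrt(2.0 / len(x))
    # bin counts with expected >= 5 by pooling the tails
    lo, hi = 4, 17
    edges = list(range(lo, hi + 1))
    obs = np.zeros(len(edges) + 1)
    obs[0] = np.sum(x < lo)
    for i, v in enumerate(edges[:-1]):
        obs[i + 1] = np.sum(x == v)
    obs[-1] = np.sum(x >= hi)
    exp = np.zeros_like(obs)
    exp[0] = poisson.cdf(lo - 1, mean)
    for i, v in enumerate(edges[:-1]):
        exp[i + 1] = poisson.pmf(v, mean)
    exp[-1] = poisson.sf(hi - 1, mean)
    exp *= len(x)
    stat, p = chisquare(obs, exp, ddof=0)
    assert p > 0.01


def test_conserved_promoter_units():
    """Promoter on+off states keep a constant total along every trajectory."""
    sys_ = build_expression(CouplingMode.COTRANSCRIBED_SEPARATE_RBS,
                            BurstingParams(), ExpressionParams())
    ens = simulate_ensemble(sys_, 20, 8000, master_seed=5, n_points=50)
    i_on = ens.names.index("g12_on")
    i_off = ens.names.index("g12_off")
    total = ens.states[:, :, i_on] + ens.states[:, :, i_off]
    assert np.all(total == 1)


def test_ensemble_seeds_distinct_and_reproducible():
    sys_ = birth_death()
    e1 = simulate_ensemble(sys_, 10, 100, master_seed=3, n_points=10)
    e2 = simulate_ensemble(sys_, 10, 100, master_seed=3, n_points=10)
    assert np.array_equal(e1.states, e2.states)
    assert len(set(e1.seeds.tolist())) == 10
    with pytest.raises(ValueError):
        Ensemble(e1.times, e1.states, e1.names, np.zeros(10, dtype=int))


# ---------------------------------------------------------------------------
# tau-leaping


def test_tau_leap_stationary_mean_within_2pct():
    sys_ = birth_death(10.0, 0.1, x0=100)
    means = []
    for s in range(150):
        tr = simulate_tau_leap(sys_, 150, np.linspace(0, 150, 60), seed=s, epsilon=0.03)
        means.append(tr.states[20:, 0].mean())
    assert abs(np.mean(means) - 100.0) / 100.0 < 0.02


def test_tau_leap_matches_ssa_distribution():
    """Stationary distributions from tau-leaping and exact SSA agree
    (two-sample KS, alpha=0.01)."""
    sys_ = birth_death(10.0, 0.1, x0=100)
    tau_samples = np.array([
        simulate_tau_leap(sys_, 120, np.linspace(0, 120, 4), seed=s, epsilon=0.01).states[-1, 0]
        for s in range(600)
    ])
    ens = simulate_ensemble(sys_, 600, 120, master_seed=99, n_points=4)
    ssa_samples = ens.states[:, -1, 0]
    _, p = ks_2samp(tau_samples, ssa_samples)
    assert p > 0.01


def test_tau_leap_low_count_fallback_is_exact():
    """With every reactant below the exact-SSA threshold, no leap steps are
    taken at all."""
    sys_ = birth_death(0.2, 0.1, x0=2)
    tr = simulate_tau_leap(sys_, 300, np.linspace(0, 300, 30), seed=3)
    assert tr.n_leap_steps == 0
    assert tr.n_exact_steps > 0
    # counts stay integral under exact stepping
    assert np.all(tr.states == np.round(tr.states))


def test_tau_leap_epsilon_validation():
    with pytest.raises(ValueError):
        simulate_tau_leap(birth_death(), 10, seed=0, epsilon=0.5)


# ---------------------------------------------------------------------------
# mean-field steady state


def test_steady_state_birth_death():
    x = steady_state_mean_field(birth_death(1.0, 0.1))
    np.testing.assert_allclose(x, [10.0], rtol=1e-8)


def test_steady_state_conserved_promoter():
    sys_ = build_expression(CouplingMode.UNCOUPLED, BurstingParams(), ExpressionParams())
    x = steady_state_mean_field(sys_)
    names = sys_.names
    on = x[names.index("g1_on")] + x[names.index("g1_off")]
    np.testing.assert_allclose(on, 1.0, atol=1e-9)
    duty = 0.00045 / (0.00045 + 0.0028)
    np.testing.assert_allclose(x[names.index("g1_on")], duty, rtol=1e-6)


def test_steady_state_flux_imbalance_diverges():
    """Constant influx past a saturable consumption capacity has no finite
    fixed point and must be reported as such."""
    sys_ = ReactionSystem(
        [Species("I", 0), Species("E", 1, clamped=True)],
        [
            Reaction({}, {"I": 1}, {}, RateLaw.mass_action(2.0), name="influx"),
            Reaction({"I": 1}, {}, {"E": 1}, RateLaw.michaelis_menten(1.0, 50.0), name="consume"),
        ],
    )
    with pytest.raises(NoFiniteSteadyState):
        steady_state_mean_field(sys_)


# ---------------------------------------------------------------------------
# stationary windows


def _manual_ensemble(states):
    states = np.asarray(states, dtype=np.float32)
    n_t = states.shape[1]
    return Ensemble(np.arange(n_t, dtype=float) + 1.0, states,
                    [f"s{i}" for i in range(states.shape[2])],
                    np.arange(states.shape[0]))


def test_stationary_window_constant_and_ramp():
    const = _manual_ensemble(np.full((5, 40, 1), 7.0))
    w = stationary_window(const, 0.0)
    assert w.states.shape[1] == 40
    assert not w.nonstationary.any()

    ramp = _manual_ensemble(np.arange(40, dtype=float).reshape(1, 40, 1) * np.ones((6, 1, 1)))
    w2 = stationary_window(ramp, 0.25)
    assert w2.nonstationary.all()


def test_stationary_window_validation():
    const = _manual_ensemble(np.full((3, 10, 1), 1.0))
    with pytest.raises(ValueError):
        stationary_window(const, 1.0)
    with pytest.raises(ValueError):
        stationary_window(const, -0.1)


def test_stationary_window_birth_death_mean(bd_stationary_samples):
    """Retained window mean of a stationary birth-death ensemble is within
    3 SE of k/gamma."""
    sys_ = birth_death(1.0, 0.1, x0=10)
    ens = simulate_ensemble(sys_, 400, 200, master_seed=11, n_points=40)
    w = stationary_window(ens, 0.5)
    m = w.species_runs("X").mean(axis=1)
    se = m.std(ddof=1) / math.sqrt(len(m))
    assert abs(m.mean() - 10.0) < 3 * se


# ---------------------------------------------------------------------------
# serialization


def test_reaction_system_json_roundtrip():
    sys_ = build_expression(CouplingMode.COTRANSLATED, BurstingParams(), ExpressionParams())
    sys2 = ReactionSystem.from_json(sys_.to_json())
    assert sys2.names == sys_.names
    assert len(sys2.reactions) == len(sys_.reactions)
    t1 = simulate_ssa(sys_, 500, np.linspace(0, 500, 20), seed=4)
    t2 = simulate_ssa(sys2, 500, np.linspace(0, 500, 20), seed=4)
    assert np.array_equal(t1.states, t2.states)


def test_trajectory_tsv():
    tr = simulate_ssa(birth_death(1.0, 0.1), 50, np.linspace(0, 50, 5), seed=0)
    text = tr.to_tsv()
    lines = text.strip().split("\n")
    assert lines[0] == "time\tX"
    assert len(lines) == 6


def test_ensemble_hdf5_roundtrip(tmp_path):
    ens = simulate_ensemble(birth_death(1.0, 0.1, x0=10), 5, 100, master_seed=1, n_points=8)
    path = str(tmp_path / "ens.h5")
    ens.to_hdf5(path)
    back = Ensemble.from_hdf5(path)
    assert back.names == ens.names
    assert np.array_equal(back.states, ens.states)
    assert np.array_equal(back.seeds, ens.seeds)
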