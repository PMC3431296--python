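"""Elementary-step reaction networks with exact and approximate stochastic simulation.

Copy numbers (not concentrations) are the state variables; time is in seconds
and the cell volume ``Omega`` is in femtoliters, so with the default
``Omega = 1`` fL one copy per cell corresponds to one molecule per femtoliter.

The module provides

* :class:`ReactionSystem` — species + reactions + volume, the common substrate
  for stochastic simulation, mean-field analysis and the linear noise
  approximation,
* :func:`simulate_ssa` — exact Gillespie direct-method sampling of the
  chemical master equation (numba-compiled inner loop),
* :func:`simulate_tau_leap` — explicit tau-leaping with exact-SSA fallback at
  low copy numbers,
* :func:`steady_state_mean_field` — damped-Newton fixed point of the
  macroscopic rate equations with an ODE-integration fallback,
* :func:`stationary_window` — burn-in removal with a stationarity check.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

__all__ = [
    "Species",
    "RateLaw",
    "Reaction",
    "ReactionSystem",
    "Trajectory",
    "Ensemble",
    "NoFiniteSteadyState",
    "propensity_vector",
    "simulate_ssa",
    "simulate_tau_leap",
    "simulate_ensemble",
    "steady_state_mean_field",
    "stationary_window",
    "spawn_seeds",
]

MASS_ACTION = 0
MICHAELIS_MENTEN = 1
HILL = 2
HILL_OR = 3

_KIND_NAMES = {
    "mass_action": MASS_ACTION,
    "michaelis_menten": MICHAELIS_MENTEN,
    "hill": HILL,
    "hill_or": HILL_OR,
}
_KIND_CODES = {v: k for k, v in _KIND_NAMES.items()}


class NoFiniteSteadyState(RuntimeError):
    """Raised when the macroscopic rate equations admit no finite fixed point
    (e.g. upstream flux exceeding a saturable downstream capacity)."""


@dataclass(frozen=True)
class Species:
    """A molecular species tracked by copy number.

    ``is_conserved_unit`` marks members of a conservation pool (e.g. promoter
    on/off states that always sum to one copy).  ``clamped`` marks boundary
    species held at a fixed copy number (an external substrate reservoir);
    reactions may read or nominally consume them but their count never
    changes.
    """

    name: str
    initial_copies: int = 0
    is_conserved_unit: bool = False
    clamped: bool = False

    def __post_init__(self):
        if self.initial_copies < 0:
            raise ValueError(f"initial_copies must be >= 0 for {self.name!r}")


@dataclass(frozen=True)
class RateLaw:
    """Propensity law for a reaction.

    kinds
        ``mass_action(k)``
            propensity ``k * prod(falling factorials of reactant counts)
            * prod(modifier counts) / Omega**(order-1)``; e.g. ``k*a*b/Omega``
            for A+B and ``k*a*(a-1)/(2*Omega)`` for 2A.
        ``michaelis_menten(k_cat, K_m)``
            ``k_cat * e * s / (K_m + s)`` with enzyme ``e`` the reaction's
            first modifier and substrate ``s`` its single reactant.
        ``hill(V_max, K, n)``
            ``V_max * x**n / (K**n + x**n)`` with regulator ``x`` the first
            modifier (production reaction, no reactants).
        ``hill_or(V_max, K_a, n_a, K_b, n_b)``
            probabilistic-OR of two Hill activations,
            ``V_max * (1 - (1-h_a)(1-h_b))``; saturates at ``V_max`` so either
            regulator alone has the same maximal effect.
    """

    kind: str
    params: tuple

    @staticmethod
    def mass_action(k: float) -> "RateLaw":
        if k < 0:
            raise ValueError("rate constant must be >= 0")
        return RateLaw("mass_action", (float(k),))

    @staticmethod
    def michaelis_menten(k_cat: float, K_m: float) -> "RateLaw":
        if k_cat < 0 or K_m < 0:
            raise ValueError("Michaelis-Menten constants must be >= 0")
        return RateLaw("michaelis_menten", (float(k_cat), float(K_m)))

    @staticmethod
    def hill(V_max: float, K: float, n: float) -> "RateLaw":
        if V_max < 0 or K < 0 or n < 1:
            raise ValueError("Hill law requires V_max, K >= 0 and n >= 1")
        return RateLaw("hill", (float(V_max), float(K), float(n)))

    @staticmethod
    def hill_or(V_max: float, K_a: float, n_a: float, K_b: float, n_b: float) -> "RateLaw":
        if V_max < 0 or K_a < 0 or K_b < 0 or n_a < 1 or n_b < 1:
            raise ValueError("hill_or law requires V_max, K >= 0 and n >= 1")
        return RateLaw("hill_or", (float(V_max), float(K_a), float(n_a), float(K_b), float(n_b)))


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction: reactants are consumed, products produced and
    modifiers (enzymes, promoter states, regulators) affect the rate without
    being changed by the firing."""

    reactants: dict = field(default_factory=dict)
    products: dict = field(default_factory=dict)
    modifiers: dict = field(default_factory=dict)
    law: RateLaw = field(default_factory=lambda: RateLaw.mass_action(0.0))
    name: str = ""

    def __post_init__(self):
        for d in (self.reactants, self.products, self.modifiers):
            for sp, nu in d.items():
                if int(nu) != nu or nu <= 0:
                    raise ValueError(f"stoichiometry of {sp!r} must be a positive integer")
        if self.law.kind == "michaelis_menten":
            if len(self.reactants) != 1 or sum(self.reactants.values()) != 1:
                raise ValueError("Michaelis-Menten reaction needs exactly one substrate (stoich 1)")
            if len(self.modifiers) < 1:
                raise ValueError("Michaelis-Menten reaction needs the enzyme as first modifier")
        if self.law.kind == "hill" and len(self.modifiers) < 1:
            raise ValueError("Hill production needs the regulator as first modifier")
        if self.law.kind == "hill_or" and len(self.modifiers) < 2:
            raise ValueError("hill_or production needs two regulator modifiers")


@dataclass
class ReactionSystem:
    species: list
    reactions: list
    volume_Omega: float = 1.0

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        if self.volume_Omega <= 0:
            raise ValueError("volume_Omega must be > 0")
        known = set(names)
        for r in self.reactions:
            for d in (r.reactants, r.products, r.modifiers):
                for sp in d:
                    if sp not in known:
                        raise ValueError(f"reaction references unknown species {sp!r}")
        self._compiled = None

    # -- basic accessors ---------------------------------------------------
    @property
    def names(self):
        return [s.name for s in self.species]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_copies for s in self.species], dtype=np.float64)

    # -- compilation to flat arrays ---------------------------------------
    def compiled(self) -> "_Compiled":
        if self._compiled is None:
            self._compiled = _compile(self)
        return self._compiled

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "species": [
                {
                    "name": s.name,
                    "initial": s.initial_copies,
                    "conserved": s.is_conserved_unit,
                    "clamped": s.clamped,
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "reactants": r.reactants,
                    "products": r.products,
                    "modifiers": r.modifiers,
                    "law": {"kind": r.law.kind, "params": list(r.law.params)},
                    "name": r.name,
                }
                for r in self.reactions
            ],
            "omega": self.volume_Omega,
        }
        return json.dumps(doc, indent=1)

    @staticmethod
    def from_json(text: str) -> "ReactionSystem":
        doc = json.loads(text)
        species = [
            Species(d["name"], d.get("initial", 0), d.get("conserved", False), d.get("clamped", False))
            for d in doc["species"]
        ]
        reactions = []
        for d in doc["reactions"]:
            law = RateLaw(d["law"]["kind"], tuple(d["law"]["params"]))
            if law.kind not in _KIND_NAMES:
                raise ValueError(f"unknown rate-law kind {law.kind!r}")
            reactions.append(
                Reaction(dict(d["reactants"]), dict(d["products"]), dict(d.get("modifiers", {})), law, d.get("name", ""))
            )
        return ReactionSystem(species, reactions, doc.get("omega", 1.0))


@dataclass
class Trajectory:
    """Sampled copy-number time course on a fixed grid."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_species)
    names: list

    def __post_init__(self):
        if self.states.shape != (len(self.times), len(self.names)):
            raise ValueError("state array shape mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.states < 0):
            raise ValueError("negative copy numbers in trajectory")

    def series(self, name: str) -> np.ndarray:
        return self.states[:, self.names.index(name)]

    def to_tsv(self) -> str:
        header = "time\t" + "\t".join(self.names)
        rows = [
            f"{t:.6g}\t" + "\t".join(f"{v:g}" for v in row)
            for t, row in zip(self.times, self.states)
        ]
        return "\n".join([header] + rows) + "\n"


@dataclass
class Ensemble:
    """A set of trajectories on a common sampling grid (one RNG stream each)."""

    times: np.ndarray
    states: np.ndarray  # (n_runs, n_times, n_species)
    names: list
    seeds: np.ndarray

    def __post_init__(self):
        if len(set(int(s) for s in self.seeds)) != len(self.seeds):
            raise ValueError("per-trajectory seeds must be distinct")
        if self.states.shape[0] != len(self.seeds):
            raise ValueError("one seed per trajectory required")

    @property
    def n_runs(self) -> int:
        return self.states.shape[0]

    def species_runs(self, name: str) -> np.ndarray:
        """(n_runs, n_times) array for one species."""
        return self.states[:, :, self.names.index(name)]

    def trajectory(self, i: int) -> Trajectory:
        return Trajectory(self.times, np.asarray(self.states[i], dtype=np.float64), self.names)

    def to_hdf5(self, path: str) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=self.times)
            fh.create_dataset("states", data=self.states, compression="gzip")
            fh.create_dataset("seeds", data=np.asarray(self.seeds, dtype=np.int64))
            fh.attrs["species"] = np.array(self.names, dtype="S")

    @staticmethod
    def from_hdf5(path: str) -> "Ensemble":
        import h5py

        with h5py.File(path, "r") as fh:
            return Ensemble(
                fh["times"][:], fh["states"][:],
                [n.decode() for n in fh.attrs["species"]], fh["seeds"][:],
            )


# ---------------------------------------------------------------------------
# compilation


class _Compiled:
    __slots__ = (
        "names", "net", "fac_ptr", "fac_sp", "fac_nu", "fac_fall",
        "kind", "params", "idx2", "omega", "x0", "conserved_mask", "clamped_mask",
    )


def _compile(system: ReactionSystem) -> _Compiled:
    names = system.names
    ns, nr = len(names), len(system.reactions)
    idx = {n: i for i, n in enumerate(names)}
    omega = float(system.volume_Omega)

    net = np.zeros((nr, ns), dtype=np.int64)
    kind = np.zeros(nr, dtype=np.int64)
    params = np.zeros((nr, 5), dtype=np.float64)
    idx2 = np.full((nr, 2), -1, dtype=np.int64)
    fac_ptr = [0]
    fac_sp, fac_nu, fac_fall = [], [], []

    clamped = np.array([s.clamped for s in system.species])

    for r, rx in enumerate(system.reactions):
        for sp, nu in rx.reactants.items():
            net[r, idx[sp]] -= nu
        for sp, nu in rx.products.items():
            net[r, idx[sp]] += nu
        k = rx.law.kind
        kind[r] = _KIND_NAMES[k]
        if k == "mass_action":
            order = sum(rx.reactants.values()) + sum(rx.modifiers.values())
            keff = rx.law.params[0] * omega ** (1 - order)
            for sp, nu in rx.reactants.items():
                keff /= math.factorial(nu)
                fac_sp.append(idx[sp]); fac_nu.append(nu); fac_fall.append(1)
            for sp, nu in rx.modifiers.items():
                fac_sp.append(idx[sp]); fac_nu.append(nu); fac_fall.append(0)
            params[r, 0] = keff
        elif k == "michaelis_menten":
            params[r, :2] = rx.law.params
            idx2[r, 0] = idx[next(iter(rx.modifiers))]     # enzyme
            idx2[r, 1] = idx[next(iter(rx.reactants))]     # substrate
        elif k == "hill":
            params[r, :3] = rx.law.params
            idx2[r, 0] = idx[next(iter(rx.modifiers))]
        elif k == "hill_or":
            params[r, :5] = rx.law.params
            mods = list(rx.modifiers)
            idx2[r, 0] = idx[mods[0]]
            idx2[r, 1] = idx[mods[1]]
        else:  # pragma: no cover - rejected earlier
            raise ValueError(f"unknown rate-law kind {k!r}")
        fac_ptr.append(len(fac_sp))

    net[:, clamped] = 0  # boundary species never change

    c = _Compiled()
    c.names = names
    c.net = net
    c.fac_ptr = np.array(fac_ptr, dtype=np.int64)
    c.fac_sp = np.array(fac_sp, dtype=np.int64) if fac_sp else np.zeros(0, dtype=np.int64)
    c.fac_nu = np.array(fac_nu, dtype=np.int64) if fac_nu else np.zeros(0, dtype=np.int64)
    c.fac_fall = np.array(fac_fall, dtype=np.int64) if fac_fall else np.zeros(0, dtype=np.int64)
    c.kind = kind
    c.params = params
    c.idx2 = idx2
    c.omega = omega
    c.x0 = system.initial_state()
    c.conserved_mask = np.array([s.is_conserved_unit for s in system.species])
    c.clamped_mask = clamped
    return c


# ---------------------------------------------------------------------------
# propensities (shared by SSA kernel, tau-leap and the mean-field limit)


@njit(cache=True)
def _propensities(x, net, fac_ptr, fac_sp, fac_nu, fac_fall, kind, params, idx2, a):
    nr = net.shape[0]
    for r in range(nr):
        knd = kind[r]
        if knd == 0:
            v = params[r, 0]
            for j in range(fac_ptr[r], fac_ptr[r + 1]):
                xs = x[fac_sp[j]]
                nu = fac_nu[j]
                if fac_fall[j] == 1:
                    for q in range(nu):
                        v *= xs - q
                else:
                    for q in range(nu):
                        v *= xs
            if v < 0.0:
                v = 0.0
        elif knd == 1:
            e = x[idx2[r, 0]]
            s = x[idx2[r, 1]]
            v = params[r, 0] * e * s / (params[r, 1] + s) if s > 0.0 else 0.0
        elif knd == 2:
            xr = x[idx2[r, 0]]
            if xr <= 0.0:
                v = 0.0
            else:
                xn = xr ** params[r, 2]
                v = params[r, 0] * xn / (params[r, 1] ** params[r, 2] + xn)
        else:
            xa = x[idx2[r, 0]]
            xb = x[idx2[r, 1]]
            ha = 0.0
            hb = 0.0
            if xa > 0.0:
                xan = xa ** params[r, 2]
                ha = xan / (params[r, 1] ** params[r, 2] + xan)
            if xb > 0.0:
                xbn = xb ** params[r, 4]
                hb = xbn / (params[r, 3] ** params[r, 4] + xbn)
            v = params[r, 0] * (1.0 - (1.0 - ha) * (1.0 - hb))
        a[r] = v
    return a


@njit(cache=True)
def _ssa_kernel(net, fac_ptr, fac_sp, fac_nu, fac_fall, kind, params, idx2,
                x0, t_grid, seed, out):
    np.random.seed(seed)
    ns = net.shape[1]
    nr = net.shape[0]
    ng = t_grid.shape[0]
    x = x0.copy()
    a = np.empty(nr, dtype=np.float64)
    t = 0.0
    gi = 0
    while gi < ng:
        _propensities(x, net, fac_ptr, fac_sp, fac_nu, fac_fall, kind, params, idx2, a)
        atot = 0.0
        for r in range(nr):
            atot += a[r]
        if atot <= 0.0:
            # no reaction possible: trajectory frozen at the last state
            while gi < ng:
                for s in range(ns):
                    out[gi, s] = x[s]
                gi += 1
            break
        t_next = t - math.log(np.random.random()) / atot
        while gi < ng and t_grid[gi] < t_next:
            for s in range(ns):
                out[gi, s] = x[s]
            gi += 1
        if gi >= ng:
            break
        u = np.random.random() * atot
        acc = 0.0
        pick = nr - 1
        for r in range(nr):
            acc += a[r]
            if u < acc:
                pick = r
                break
        for s in range(ns):
            x[s] += net[pick, s]
        t = t_next
    return out


def propensity_vector(system: ReactionSystem, state) -> np.ndarray:
    """Per-reaction propensities (s^-1) at the given copy-number state."""
    x = np.asarray(state, dtype=np.float64)
    c = system.compiled()
    if x.shape != (len(c.names),):
        raise ValueError("state dimension does not match species count")
    if np.any(x < 0):
        raise ValueError("negative copy numbers")
    a = np.empty(len(system.reactions), dtype=np.float64)
    _propensities(x, c.net, c.fac_ptr, c.fac_sp, c.fac_nu, c.fac_fall,
                  c.kind, c.params, c.idx2, a)
    return a


def _default_grid(t_end: float, n_points: int) -> np.ndarray:
    return np.linspace(0.0, t_end, n_points)


def spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """Derive ``n`` independent 32-bit stream seeds as (master, run_index)."""
    seeds = np.empty(n, dtype=np.int64)
    for i in range(n):
        seeds[i] = np.random.SeedSequence((int(master_seed), i)).generate_state(1, np.uint32)[0]
    # SeedSequence collisions are effectively impossible; guard anyway
    if len(np.unique(seeds)) != n:  # pragma: no cover
        seeds = np.arange(n, dtype=np.int64) + int(master_seed)
    return seeds


def simulate_ssa(system: ReactionSystem, t_end: float, sampling_times=None,
                 seed: int = 0, x0=None) -> Trajectory:
    """Exact Gillespie direct-method sample of the chemical master equation.

    The same (system, seed, sampling grid) always yields the identical
    trajectory.  If no reaction is possible the trajectory stays frozen at the
    last state.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    c = system.compiled()
    grid = np.asarray(sampling_times, dtype=np.float64) if sampling_times is not None \
        else _default_grid(t_end, 200)
    start = c.x0 if x0 is None else np.asarray(x0, dtype=np.float64)
    out = np.empty((len(grid), len(c.names)), dtype=np.float64)
    _ssa_kernel(c.net, c.fac_ptr, c.fac_sp, c.fac_nu, c.fac_fall, c.kind,
                c.params, c.idx2, start, grid, np.uint32(seed), out)
    return Trajectory(grid, out, list(c.names))


def simulate_ensemble(system: ReactionSystem, n_runs: int, t_end: float,
                      master_seed: int, n_points: int = 200, x0=None,
                      x0_per_run=None) -> Ensemble:
    """Run ``n_runs`` independent SSA trajectories on a shared grid.

    Per-run RNG streams are spawned as (master_seed, run_index) so the
    ensemble is reproducible regardless of execution order.  ``x0_per_run``
    optionally supplies one initial state per run (e.g. promoter states drawn
    from their stationary occupancy).
    """
    c = system.compiled()
    grid = _default_grid(t_end, n_points)
    seeds = spawn_seeds(master_seed, n_runs)
    out = np.empty((n_runs, n_points, len(c.names)), dtype=np.float32)
    buf = np.empty((n_points, len(c.names)), dtype=np.float64)
    base = c.x0 if x0 is None else np.asarray(x0, dtype=np.float64)
    for i in range(n_runs):
        start = base if x0_per_run is None else np.asarray(x0_per_run[i], dtype=np.float64)
        _ssa_kernel(c.net, c.fac_ptr, c.fac_sp, c.fac_nu, c.fac_fall, c.kind,
                    c.params, c.idx2, start, grid, np.uint32(seeds[i]), buf)
        out[i] = buf
    return Ensemble(grid, out, list(c.names), seeds)


# ---------------------------------------------------------------------------
# tau-leaping


def simulate_tau_leap(system: ReactionSystem, t_end: float, sampling_times=None,
                      seed: int = 0, epsilon: float = 0.03, x0=None,
                      exact_threshold: int = 10) -> Trajectory:
    """Explicit tau-leaping with the standard epsilon-bounded relative
    propensity-change criterion.

    Falls back to exact SSA steps whenever any reactant of an active reaction
    is below ``exact_threshold`` copies; negative-count proposals are rejected
    and retried with a halved leap.
    """
    if not (0 < epsilon <= 0.1):
        raise ValueError("epsilon must be in (0, 0.1]")
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    c = system.compiled()
    grid = np.asarray(sampling_times, dtype=np.float64) if sampling_times is not None \
        else _default_grid(t_end, 200)
    rng = np.random.default_rng(seed)
    x = (c.x0 if x0 is None else np.asarray(x0, dtype=np.float64)).copy()
    nr, ns = c.net.shape
    a = np.empty(nr, dtype=np.float64)
    out = np.empty((len(grid), ns), dtype=np.float64)
    # species that appear as consumed reactants of each reaction
    consumed = c.net < 0
    t = 0.0
    gi = 0
    n_exact = 0
    n_leap = 0
    net = c.net.astype(np.float64)
    while gi < len(grid):
        _propensities(x, c.net, c.fac_ptr, c.fac_sp, c.fac_nu, c.fac_fall,
                      c.kind, c.params, c.idx2, a)
        atot = a.sum()
        if atot <= 0:
            out[gi:] = x
            break
        low = (x < exact_threshold) & consumed.any(axis=0)
        if low.any():
            # exact SSA step
            t_next = t + rng.exponential(1.0 / atot)
            while gi < len(grid) and grid[gi] < t_next:
                out[gi] = x
                gi += 1
            if gi >= len(grid):
                break
            pick = np.searchsorted(np.cumsum(a), rng.random() * atot)
            x += net[min(pick, nr - 1)]
            t = t_next
            n_exact += 1
            continue
        mu = net.T @ a
        sig2 = (net.T ** 2) @ a
        bound = np.maximum(epsilon * x, 1.0)
        with np.errstate(divide="ignore"):
            tau = min(
                np.min(np.where(mu != 0, bound / np.abs(mu), np.inf)),
                np.min(np.where(sig2 > 0, bound ** 2 / sig2, np.inf)),
            )
        tau = min(tau, t_end - t + 1e-9)
        while True:
            fires = rng.poisson(a * tau)
            x_new = x + net.T @ fires
            if np.all(x_new >= 0):
                break
            tau *= 0.5  # rejected leap: retry with halved step
        t_next = t + tau
        while gi < len(grid) and grid[gi] < t_next:
            out[gi] = x
            gi += 1
        x = x_new
        t = t_next
        n_leap += 1
    traj = Trajectory(grid, np.clip(out, 0, None), list(c.names))
    traj.n_exact_steps = n_exact
    traj.n_leap_steps = n_leap
    return traj


# ---------------------------------------------------------------------------
# mean-field


def macroscopic_rates(system: ReactionSystem, x) -> np.ndarray:
    """Macroscopic (deterministic-limit) rate vector f(x): falling factorials
    replaced by plain powers, otherwise identical to the propensities."""
    c = system.compiled()
    x = np.asarray(x, dtype=np.float64)
    f = np.empty(len(system.reactions), dtype=np.float64)
    for r, rx in enumerate(system.reactions):
        knd = c.kind[r]
        if knd == MASS_ACTION:
            v = c.params[r, 0]
            for j in range(c.fac_ptr[r], c.fac_ptr[r + 1]):
                v *= max(x[c.fac_sp[j]], 0.0) ** c.fac_nu[j]
        elif knd == MICHAELIS_MENTEN:
            e, s = x[c.idx2[r, 0]], max(x[c.idx2[r, 1]], 0.0)
            v = c.params[r, 0] * e * s / (c.params[r, 1] + s) if s > 0 else 0.0
        elif knd == HILL:
            xr = max(x[c.idx2[r, 0]], 0.0)
            v = 0.0 if xr == 0 else c.params[r, 0] * xr ** c.params[r, 2] / (
                c.params[r, 1] ** c.params[r, 2] + xr ** c.params[r, 2])
        else:
            xa = max(x[c.idx2[r, 0]], 0.0)
            xb = max(x[c.idx2[r, 1]], 0.0)
            ha = 0.0 if xa == 0 else xa ** c.params[r, 2] / (c.params[r, 1] ** c.params[r, 2] + xa ** c.params[r, 2])
            hb = 0.0 if xb == 0 else xb ** c.params[r, 4] / (c.params[r, 3] ** c.params[r, 4] + xb ** c.params[r, 4])
            v = c.params[r, 0] * (1.0 - (1.0 - ha) * (1.0 - hb))
        f[r] = v
    return f


def stoichiometric_subspace(system: ReactionSystem) -> np.ndarray:
    """Orthonormal basis U (columns) of the reachable subspace spanned by the
    net stoichiometric change vectors; conservation constraints (promoter
    totals etc.) are the orthogonal complement."""
    net = system.compiled().net.astype(np.float64)
    if not net.any():
        return np.zeros((net.shape[1], 0))
    u, s, _ = np.linalg.svd(net.T, full_matrices=False)
    rank = int(np.sum(s > 1e-10 * s[0]))
    return u[:, :rank]


def steady_state_mean_field(system: ReactionSystem, x0=None, t_relax: float = None,
                            tol: float = 1e-9) -> np.ndarray:
    """Fixed point of dx/dt = S f(x) by damped Newton in the stoichiometric
    subspace, with an ODE-relaxation fallback for poor initial guesses.

    Conserved pools (e.g. a promoter's on+off states) keep their initial
    totals.  Raises :class:`NoFiniteSteadyState` when the flux balance admits
    no finite fixed point (e.g. influx past a saturable capacity).
    """
    c = system.compiled()
    net = c.net.astype(np.float64)
    U = stoichiometric_subspace(system)
    base = (c.x0 if x0 is None else np.asarray(x0, dtype=np.float64)).copy()

    def F(x):
        return net.T @ macroscopic_rates(system, x)

    def scale_at(x):
        f = macroscopic_rates(system, x)
        return max(1.0, float(np.max(np.abs(f))) if f.size else 1.0)

    if U.shape[1] == 0:
        return base

    def newton(xstart, max_iter=200):
        x = xstart.copy()
        for _ in range(max_iter):
            r = U.T @ F(x)
            nr0 = np.linalg.norm(r)
            if nr0 < tol * scale_at(x):
                return x
            # finite-difference Jacobian in reduced coordinates
            m = U.shape[1]
            J = np.empty((m, m))
            for j in range(m):
                h = 1e-6 * max(1.0, np.linalg.norm(x))
                J[:, j] = (U.T @ F(x + h * U[:, j]) - r) / h
            try:
                dy = np.linalg.solve(J, -r)
            except np.linalg.LinAlgError:
                return None
            lam = 1.0
            for _bt in range(40):
                x_new = x + lam * (U @ dy)
                if np.all(x_new > -1e-9) and np.linalg.norm(U.T @ F(np.clip(x_new, 0, None))) < nr0:
                    x = np.clip(x_new, 0.0, None)
                    break
                lam *= 0.5
            else:
                return None
        return None

    x = newton(base)
    if x is None:
        # continuation fallback: relax along the ODE flow, then polish
        if t_relax is None:
            t_relax = 1e7
        big = 1e12

        def rhs(_t, x):
            return F(np.clip(x, 0.0, None))

        def diverged(_t, x):
            return big - np.max(np.abs(x))
        diverged.terminal = True

        sol = solve_ivp(rhs, (0.0, t_relax), base, method="LSODA",
                        events=diverged, rtol=1e-8, atol=1e-8)
        if sol.t_events[0].size or not sol.success:
            raise NoFiniteSteadyState("macroscopic flow diverges: no finite steady state")
        x = newton(np.clip(sol.y[:, -1], 0.0, None))
        if x is None:
            xe = np.clip(sol.y[:, -1], 0.0, None)
            if np.linalg.norm(U.T @ F(xe)) < 1e-6 * scale_at(xe):
                x = xe
            else:
                raise NoFiniteSteadyState("no finite steady state found")
    if np.linalg.norm(U.T @ F(x)) >= max(tol, 1e-9) * scale_at(x) * 10:
        raise NoFiniteSteadyState("residual too large at candidate steady state")
    return x


# ---------------------------------------------------------------------------
# stationary windows


@dataclass
class StationaryWindow:
    times: np.ndarray
    states: np.ndarray            # (n_runs, n_kept, n_species)
    names: list
    nonstationary: np.ndarray     # per-species flag

    def species_runs(self, name: str) -> np.ndarray:
        return self.states[:, :, self.names.index(name)]


def stationary_window(ensemble: Ensemble, burn_in_fraction: float = 0.5) -> StationaryWindow:
    """Discard the initial fraction of every trajectory and flag species whose
    retained first- and second-half means differ by more than 3 pooled SE
    (computed across trajectories, so autocorrelation within a run does not
    deflate the error estimate)."""
    if not (0 <= burn_in_fraction < 1):
        raise ValueError("burn_in_fraction must be in [0, 1)")
    n_t = len(ensemble.times)
    start = int(np.floor(burn_in_fraction * n_t))
    if start >= n_t:
        raise ValueError("empty stationary window")
    kept = ensemble.states[:, start:, :].astype(np.float64)
    half = kept.shape[1] // 2
    flags = np.zeros(kept.shape[2], dtype=bool)
    if half >= 1:
        m1 = kept[:, :half, :].mean(axis=1)   # per-run means, first half
        m2 = kept[:, half:, :].mean(axis=1)
        n = kept.shape[0]
        diff = m1.mean(axis=0) - m2.mean(axis=0)
        if n > 1:
            se = np.sqrt((m1.var(axis=0, ddof=1) + m2.var(axis=0, ddof=1)) / n)
        else:  # single trajectory: fall back to within-run spread
            se = np.sqrt((kept[0, :half, :].var(axis=0, ddof=1) / max(half, 2)
                          + kept[0, half:, :].var(axis=0, ddof=1) / max(half, 2)))
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(se > 0, np.abs(diff) / se,
                         np.where(np.abs(diff) > 0, np.inf, 0.0))
        flags = z > 3.0
    return StationaryWindow(ensemble.times[start:], kept, list(ensemble.names), flags)
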