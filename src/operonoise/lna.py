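"""Linear noise approximation around the macroscopic steady state.

Fluctuations are Gaussian with covariance ``Sigma`` solving the stationary
fluctuation-dissipation (Lyapunov) equation

    M Sigma + Sigma M^T + Omega N = 0,

where ``M`` is the Jacobian of the macroscopic system at the fixed point and
``N = S diag(f) S^T / Omega`` the diffusion matrix built from the stationary
reaction fluxes.  Noise is reported as the normalized covariance matrix
``eta_ij = sigma_ij / (<x_i><x_j>)`` whose diagonal is the squared coefficient
of variation per species.

Conserved pools (promoter on/off states) make ``M`` singular in the full
space; the equation is solved on the stoichiometric subspace, where the
relaxation must be stable, and lifted back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_continuous_lyapunov

from .reaction_core import (
    ReactionSystem,
    macroscopic_rates,
    steady_state_mean_field,
    stoichiometric_subspace,
)

__all__ = [
    "LNAModel",
    "LNAResult",
    "DeltaCV2",
    "UnstableSteadyState",
    "build_lna",
    "solve_lyapunov",
    "lna_result",
    "eta_operon_closed_form",
    "log_gain",
    "delta_cv2",
    "predict_sign",
    "SIGN_TABLE",
]


class UnstableSteadyState(RuntimeError):
    pass


@dataclass
class LNAModel:
    x_star: np.ndarray
    M: np.ndarray          # Jacobian (s^-1)
    N: np.ndarray          # diffusion matrix (copies^2 s^-1 per volume)
    Omega: float
    U: np.ndarray          # orthonormal basis of the stoichiometric subspace
    names: list


@dataclass
class LNAResult:
    names: list
    mean: np.ndarray
    Sigma: np.ndarray      # covariances sigma_ij (copies^2)
    eta: np.ndarray        # sigma_ij / (<x_i><x_j>)
    cv2: np.ndarray        # diagonal of eta
    residual: float

    def _i(self, name):
        return self.names.index(name)

    def cv2_of(self, name: str) -> float:
        return float(self.cv2[self._i(name)])

    def eta_of(self, a: str, b: str) -> float:
        return float(self.eta[self._i(a), self._i(b)])

    def var_of_sum(self, species: list) -> float:
        """Variance of a sum of species (e.g. total protein, free + bound)."""
        ii = [self._i(s) for s in species]
        return float(self.Sigma[np.ix_(ii, ii)].sum())

    def cv2_of_sum(self, species: list) -> float:
        ii = [self._i(s) for s in species]
        mu = float(self.mean[ii].sum())
        return self.var_of_sum(species) / mu ** 2


def _jacobian(system: ReactionSystem, x_star: np.ndarray, rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of S f(x); uniform across rate-law kinds."""
    net = system.compiled().net.astype(np.float64)

    def F(x):
        return net.T @ macroscopic_rates(system, x)

    n = len(x_star)
    M = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(abs(x_star[j]), 1.0)
        xp = x_star.copy(); xp[j] += h
        xm = x_star.copy(); xm[j] -= h
        M[:, j] = (F(xp) - F(xm)) / (2 * h)
    return M


def build_lna(system: ReactionSystem, x_star=None) -> LNAModel:
    """Assemble the LNA ingredients at the mean-field steady state.

    Raises :class:`UnstableSteadyState` (naming the offending eigenvalues) if
    the Jacobian restricted to the stoichiometric subspace is not Hurwitz.
    """
    if x_star is None:
        x_star = steady_state_mean_field(system)
    x_star = np.asarray(x_star, dtype=np.float64)
    c = system.compiled()
    M = _jacobian(system, x_star)
    f = macroscopic_rates(system, x_star)
    S = c.net.astype(np.float64).T            # (species x reactions)
    N = S @ np.diag(f) @ S.T / c.omega
    U = stoichiometric_subspace(system)
    if U.shape[1]:
        ev = np.linalg.eigvals(U.T @ M @ U)
        if np.any(ev.real >= -1e-12):
            raise UnstableSteadyState(f"steady state not stable; eigenvalues {np.sort(ev.real)[::-1][:4]}")
    return LNAModel(x_star, M, N, c.omega, U, list(c.names))


def solve_lyapunov(model: LNAModel) -> LNAResult:
    """Solve M Sigma + Sigma M^T + Omega N = 0 on the stoichiometric
    subspace; residual is checked against 1e-8 * ||Omega N||."""
    U = model.U
    ON = model.Omega * model.N
    if U.shape[1] == 0:
        Sigma = np.zeros_like(model.N)
    else:
        Mr = U.T @ model.M @ U
        Nr = U.T @ ON @ U
        Sr = solve_continuous_lyapunov(Mr, -Nr)
        Sr = 0.5 * (Sr + Sr.T)
        Sigma = U @ Sr @ U.T
    resid = np.linalg.norm(model.M @ Sigma + Sigma @ model.M.T + ON)
    nrm = np.linalg.norm(ON)
    if nrm > 0 and resid >= 1e-8 * nrm:
        raise RuntimeError(f"Lyapunov residual {resid:.3g} exceeds tolerance ({1e-8 * nrm:.3g})")
    mu = model.x_star
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = Sigma / np.outer(mu, mu)
    eta[~np.isfinite(eta)] = np.nan
    return LNAResult(list(model.names), mu.copy(), Sigma, eta, np.diag(eta).copy(), resid)


def lna_result(system: ReactionSystem, x_star=None) -> LNAResult:
    return solve_lyapunov(build_lna(system, x_star))


# ---------------------------------------------------------------------------
# closed-form normalized covariance for the pure two-gene expression cascade


def eta_operon_closed_form(expr, mode) -> float:
    """Normalized protein covariance eta_AB = sigma_AB/(<A><B>) for two genes
    expressed without posttranslational reactions or promoter bursting.

    Shared transcript, separate ribosome binding sites:

        eta_AB = (1/<m>) * tau_mRNA / (tau_mRNA + tau_protein)

    Cotranslation (one translation channel producing A and B together) adds
    the Poisson pair term 1/(2<A>).  Uncoupled transcription gives 0: with
    independent promoters there is no shared intrinsic noise source.
    """
    from .coupling_models import CouplingMode  # local import avoids a cycle

    mode = CouplingMode(mode)
    if mode is CouplingMode.UNCOUPLED:
        return 0.0
    m_mean = expr.k_tx / expr.delta_m
    tau_m = 1.0 / expr.delta_m
    tau_p = 1.0 / expr.k_deg
    eta = (1.0 / m_mean) * tau_m / (tau_m + tau_p)
    if mode is CouplingMode.COTRANSLATED:
        a_mean = m_mean * expr.k_tl / expr.k_deg
        eta += 1.0 / (2.0 * a_mean)
    return eta


# ---------------------------------------------------------------------------
# logarithmic gains


def log_gain(flux_ratio, species_index: int, x_star, rel_step: float = 1e-6) -> float:
    """Logarithmic gain H = (y/R) dR/dy of a flux ratio (or any positive
    output) with respect to species y, at steady state, by central
    differences."""
    x_star = np.asarray(x_star, dtype=np.float64)
    y = x_star[species_index]
    R0 = flux_ratio(x_star)
    if R0 == 0:
        raise ZeroDivisionError("flux ratio is zero at the steady state")
    h = rel_step * max(abs(y), 1.0)
    xp = x_star.copy(); xp[species_index] += h
    xm = x_star.copy(); xm[species_index] -= h
    return float(y * (flux_ratio(xp) - flux_ratio(xm)) / (2 * h * R0))


# ---------------------------------------------------------------------------
# CV^2 differences between coupling configurations


@dataclass
class DeltaCV2:
    species: str
    value: float            # CV^2(uncoupled) - CV^2(cotranscribed)
    predicted_sign: str     # positive / negative / small_either
    cv2_uncoupled: float
    cv2_cotranscribed: float


#: Sign of CV^2(uncoupled) - CV^2(cotranscribed) per module class and readout.
#: "positive" means the cotranscribed configuration is the low-noise one.
SIGN_TABLE = {
    ("linear_pathway", "I"): "positive",
    ("linear_pathway", "P"): "small_either",
    ("redundant_enzymes", "P"): "negative",
    ("branch_point", "s"): "negative",
    ("dual_regulators_or", "P"): "negative",
    ("physical_interaction", "A"): "positive",
    ("physical_interaction", "B"): "positive",
    ("physical_interaction", "AB"): "negative",
    ("covalent_modification", "A"): "positive",
    ("covalent_modification", "Astar"): "small_either",
}


def predict_sign(cls, species_role: str) -> str:
    """Predicted sign of the noise difference CV^2_unc - CV^2_cot for a
    module class readout; "positive" = cotranscribed has lower noise."""
    key = (getattr(cls, "value", cls), species_role)
    try:
        return SIGN_TABLE[key]
    except KeyError:
        raise KeyError(f"no sign prediction for {key}") from None


def delta_cv2(pair, species: str, cls=None) -> DeltaCV2:
    """LNA noise difference CV^2(uncoupled) - CV^2(cotranscribed) for one
    species of a matched comparison pair.  Positive values mean the
    cotranscribed configuration is quieter."""
    res_c = lna_result(pair.coupled_system)
    res_u = lna_result(pair.uncoupled_system)
    cv2_c = res_c.cv2_of(species)
    cv2_u = res_u.cv2_of(species)
    cls = cls if cls is not None else getattr(pair, "module_class", None)
    try:
        sign = predict_sign(cls, species) if cls is not None else "small_either"
    except KeyError:
        sign = "small_either"
    return DeltaCV2(species, cv2_u - cv2_c, sign, cv2_u, cv2_c)
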