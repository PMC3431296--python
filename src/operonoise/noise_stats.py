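"""Ensemble statistics: CV, covariance, correlation, decorrelation and
bootstrap error bars.

To avoid autocorrelation bias, every statistic is pooled over per-trajectory
time averages of the relevant moments (one sample per trajectory): the
ensemble average of a time-averaged moment is an unbiased estimate of the
stationary moment, and bootstrap resampling of whole trajectories gives an
honest Monte-Carlo standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .reaction_core import Ensemble, StationaryWindow, stationary_window

__all__ = ["EnsembleSummary", "CrossCorrelation", "summarize",
           "decorrelation_degree", "cross_correlation"]

_N_BOOT = 1000


@dataclass
class EnsembleSummary:
    names: list
    n_runs: int
    mean: np.ndarray
    var: np.ndarray
    cv: np.ndarray
    cv2: np.ndarray
    cov: np.ndarray              # full covariance matrix
    corr: np.ndarray             # Pearson r matrix
    skewness: np.ndarray
    skewed: np.ndarray           # |skewness| > 2 flag per species
    mean_sd: np.ndarray          # bootstrap SDs
    cv_sd: np.ndarray
    cv2_sd: np.ndarray
    cov_sd: np.ndarray
    corr_sd: np.ndarray
    # per-run first/second moments retained for derived statistics
    _m1: np.ndarray = None       # (n_runs, S) time-averaged X
    _m2: np.ndarray = None       # (n_runs, S, S) time-averaged outer product

    def _i(self, name):
        return self.names.index(name)

    def mean_of(self, name):
        return float(self.mean[self._i(name)])

    def cv_of(self, name):
        return float(self.cv[self._i(name)])

    def cv2_of(self, name):
        return float(self.cv2[self._i(name)])

    def cv2_se_of(self, name):
        return float(self.cv2_sd[self._i(name)])

    def corr_of(self, a, b):
        return float(self.corr[self._i(a), self._i(b)])

    def eta_of(self, a, b):
        i, j = self._i(a), self._i(b)
        return float(self.cov[i, j] / (self.mean[i] * self.mean[j]))

    def stat_of_sum(self, species, stat):
        """(value, bootstrap SE) of the mean or CV of a sum of species."""
        ii = [self._i(s) for s in species]
        w = np.zeros(len(self.names)); w[ii] = 1.0
        m1 = self._m1 @ w                                # per-run mean of sum
        q = np.einsum("rij,i,j->r", self._m2, w, w)      # per-run E[(sum)^2]
        mu = m1.mean()
        var = q.mean() - mu ** 2
        val = mu if stat == "mean" else math.sqrt(max(var, 0.0)) / mu
        rng = np.random.default_rng(12345)
        boots = np.empty(_N_BOOT)
        n = len(m1)
        for b in range(_N_BOOT):
            idx = rng.integers(0, n, n)
            mb = m1[idx].mean()
            if stat == "mean":
                boots[b] = mb
            else:
                vb = q[idx].mean() - mb ** 2
                boots[b] = math.sqrt(max(vb, 0.0)) / mb
        return float(val), float(boots.std(ddof=1))


def _window(ensemble, burn_in):
    if isinstance(ensemble, StationaryWindow):
        return ensemble
    return stationary_window(ensemble, burn_in)


def summarize(ensemble, burn_in: float = 0.5, n_boot: int = _N_BOOT,
              boot_seed: int = 12345) -> EnsembleSummary:
    """Stationary summary statistics for an ensemble.

    Per-trajectory time averages of X, X X^T and X^3 are pooled across
    trajectories; bootstrap SDs come from resampling trajectories with
    replacement.  Species with mean 0 get NaN CV (flagged by the NaN itself);
    distributions with |skewness| > 2 are flagged as skewed, where bootstrap
    CV summaries are known to be unreliable.
    """
    w = _window(ensemble, burn_in)
    x = w.states.astype(np.float64)            # (runs, time, species)
    n_runs = x.shape[0]
    m1 = x.mean(axis=1)                        # (runs, S)
    m2 = np.einsum("rts,rtu->rsu", x, x) / x.shape[1]
    m3 = (x ** 3).mean(axis=1)

    mean = m1.mean(axis=0)
    exx = m2.mean(axis=0)
    cov = exx - np.outer(mean, mean)
    var = np.clip(np.diag(cov).copy(), 0.0, None)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
        corr = cov / np.outer(sd, sd)
    corr[~np.isfinite(corr)] = np.nan
    np.fill_diagonal(corr, 1.0)
    # third central moment -> skewness
    ex3 = m3.mean(axis=0)
    mu3 = ex3 - 3 * mean * np.diag(exx) + 2 * mean ** 3
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(sd > 0, mu3 / sd ** 3, 0.0)

    rng = np.random.default_rng(boot_seed)
    bm = np.empty((n_boot, len(mean)))
    bcv = np.empty_like(bm)
    bcv2 = np.empty_like(bm)
    bcov = np.empty((n_boot,) + cov.shape)
    bcorr = np.empty_like(bcov)
    for b in range(n_boot):
        idx = rng.integers(0, n_runs, n_runs)
        mu_b = m1[idx].mean(axis=0)
        exx_b = m2[idx].mean(axis=0)
        cov_b = exx_b - np.outer(mu_b, mu_b)
        var_b = np.clip(np.diag(cov_b), 0.0, None)
        sd_b = np.sqrt(var_b)
        bm[b] = mu_b
        with np.errstate(divide="ignore", invalid="ignore"):
            bcv[b] = np.where(mu_b > 0, sd_b / mu_b, np.nan)
            bcv2[b] = np.where(mu_b > 0, var_b / mu_b ** 2, np.nan)
            bcorr[b] = cov_b / np.outer(sd_b, sd_b)
        bcov[b] = cov_b
    import warnings
    with warnings.catch_warnings():
        # species with zero variance or zero mean give all-NaN bootstrap slices
        warnings.simplefilter("ignore", RuntimeWarning)
        cv_sd = np.nanstd(bcv, axis=0, ddof=1)
        cv2_sd = np.nanstd(bcv2, axis=0, ddof=1)
        corr_sd = np.nanstd(bcorr, axis=0, ddof=1)
    return EnsembleSummary(
        names=list(w.names), n_runs=n_runs, mean=mean, var=var, cv=cv,
        cv2=cv ** 2, cov=cov, corr=corr, skewness=skew,
        skewed=np.abs(skew) > 2.0,
        mean_sd=bm.std(axis=0, ddof=1), cv_sd=cv_sd,
        cv2_sd=cv2_sd, cov_sd=bcov.std(axis=0, ddof=1),
        corr_sd=corr_sd, _m1=m1, _m2=m2,
    )


def decorrelation_degree(summary: EnsembleSummary, pair) -> float:
    """1 - Pearson r(A, B): 0 for perfectly correlated partners, ~1 for
    independent ones (anticorrelation can push it toward 2)."""
    a, b = pair
    if not (summary.mean_of(a) > 0 and summary.mean_of(b) > 0):
        raise ValueError("decorrelation degree needs positive means")
    r = summary.corr_of(a, b)
    if not np.isfinite(r):
        raise ValueError("correlation undefined (zero variance)")
    return 1.0 - r


@dataclass
class CrossCorrelation:
    lags: np.ndarray
    value: np.ndarray
    sem: np.ndarray
    species: tuple


def cross_correlation(ensemble, species_a: str, species_b: str, lags,
                      burn_in: float = 0.5) -> CrossCorrelation:
    """Ensemble-averaged normalized time correlation
    corr(a(t), b(t+lag)) over the stationary window.

    Moments are pooled across runs and time (the same estimator as
    :func:`summarize`, so the lag-0 value equals the stationary Pearson r);
    the SEM is the run-to-run spread of per-run correlations.
    """
    w = _window(ensemble, burn_in)
    dt = w.times[1] - w.times[0]
    steps = np.unique(np.round(np.asarray(lags, dtype=float) / dt).astype(int))
    n_t = w.states.shape[1]
    if np.any(np.abs(steps) >= n_t):
        raise ValueError("lag exceeds the stationary window span")
    a = w.states[:, :, w.names.index(species_a)].astype(np.float64)
    b = w.states[:, :, w.names.index(species_b)].astype(np.float64)
    mu_a, mu_b = a.mean(), b.mean()
    sd_a, sd_b = a.std(), b.std()
    vals, sems = [], []
    for k in steps:
        if k >= 0:
            xa, xb = a[:, : n_t - k], b[:, k:]
        else:
            xa, xb = a[:, -k:], b[:, : n_t + k]
        pooled = ((xa - mu_a) * (xb - mu_b)).mean() / (sd_a * sd_b)
        per_run = ((xa - mu_a) * (xb - mu_b)).mean(axis=1) / (sd_a * sd_b)
        vals.append(pooled)
        sems.append(per_run.std(ddof=1) / math.sqrt(len(per_run)))
    return CrossCorrelation(steps * dt, np.array(vals), np.array(sems),
                            (species_a, species_b))
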