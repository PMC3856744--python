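"""Markovian submodels for the incompletely observed insect covariates.

Two parallel process models supply full conditionals for the latent
(unsampled) covariate days inside the Gibbs sweep:

* ln(count+1) indices follow a year-specific Gaussian AR(1),

      I_t | I_{t-1} ~ Normal( alpha_y + rho_y (I_{t-1} - alpha_y), 1/tau_y ),

  with the stationary distribution Normal(alpha_y, 1/(tau_y (1 - rho_y^2)))
  on the first day of a series.

* binary indices (presence, >90% quantile) follow the process portion of a
  dynamic occupancy model: an occupied nest-day persists with probability
  phi_y and an unoccupied one is colonized with probability gamma_y; the
  first day uses the stationary occupancy psi_y = gamma_y/(gamma_y+1-phi_y).

Both chains are Markov, so a stretch of omitted days collapses exactly into
a k-step transition: the AR(1) k-step coefficient is rho^k with conditional
variance sigma_s^2 (1 - rho^{2k}), and the two-state chain's k-step
transition probabilities follow from its second eigenvalue lambda = phi -
gamma.  The k-step helpers here are shared with the reduced-grid sampler
kernels; everything else in this module operates on complete nest × day
matrices and serves both as the public API and as the reference
implementation the fast path is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AR1Params",
    "OccupancyParams",
    "ar1_loglik",
    "impute_ar1",
    "update_ar1_params",
    "occupancy_loglik",
    "impute_occupancy",
    "update_occupancy_params",
    "ar1_kstep",
    "occupancy_kstep",
    "stationary_occupancy",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class AR1Params:
    """Year-specific AR(1) parameters (arrays indexed by year)."""

    alpha: np.ndarray
    rho: np.ndarray
    tau: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        self.tau = np.atleast_1d(np.asarray(self.tau, dtype=float))
        if np.any(np.abs(self.rho) >= 1):
            raise ValueError("|rho| must be < 1 for a stationary AR(1)")
        if np.any(self.tau <= 0):
            raise ValueError("precision tau must be > 0")

    @property
    def stationary_var(self) -> np.ndarray:
        return 1.0 / (self.tau * (1.0 - self.rho**2))


@dataclass
class OccupancyParams:
    """Year-specific patch survival (phi) and colonization (gamma)."""

    phi: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.phi = np.atleast_1d(np.asarray(self.phi, dtype=float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        if np.any((self.phi <= 0) | (self.phi >= 1) | (self.gamma <= 0) | (self.gamma >= 1)):
            raise ValueError("phi and gamma must lie strictly in (0, 1)")

    @property
    def psi(self) -> np.ndarray:
        return stationary_occupancy(self.phi, self.gamma)


def stationary_occupancy(phi, gamma):
    """Stationary occupancy psi = gamma / (gamma + 1 - phi)."""
    return gamma / (gamma + 1.0 - phi)


def ar1_kstep(alpha, rho, tau, k):
    """k-step AR(1) transition: returns (coefficient rho^k, conditional var).

    The conditional law of I_{t+k} given I_t is
    Normal(alpha + rho^k (I_t - alpha), sigma_s^2 (1 - rho^{2k})) with
    sigma_s^2 = 1/(tau (1 - rho^2)); k = 1 recovers the one-step model.
    """
    a = np.power(rho, k)
    var = (1.0 - a * a) / (tau * (1.0 - rho**2))
    return a, var


def occupancy_kstep(phi, gamma, k):
    """k-step transition probabilities (p11, p01) of the two-state chain."""
    psi = stationary_occupancy(phi, gamma)
    lam = np.power(phi - gamma, k)
    return psi + (1.0 - psi) * lam, psi * (1.0 - lam)


def _norm_logpdf(x, mean, var):
    return -0.5 * (_LOG2PI + np.log(var) + (x - mean) ** 2 / var)


# ---------------------------------------------------------------------------
# AR(1): likelihood, imputation, parameter updates
# ---------------------------------------------------------------------------

def ar1_loglik(values, years, params: AR1Params) -> float:
    """Complete-data AR(1) log likelihood of nest × day series.

    ``values`` must be complete (observed + currently imputed); ``years``
    gives each row's year index into ``params``.  Day 1 of every row uses
    the stationary distribution.
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(years, dtype=int)
    if np.isnan(values).any():
        raise ValueError("series must be complete (impute missing values first)")
    a = params.alpha[years][:, None]
    r = params.rho[years][:, None]
    t = params.tau[years][:, None]
    ll = _norm_logpdf(values[:, :1], a, 1.0 / (t * (1.0 - r**2))).sum()
    mean = a + r * (values[:, :-1] - a)
    ll += _norm_logpdf(values[:, 1:], mean, 1.0 / t).sum()
    return float(ll)


def impute_ar1(
    values,
    observed,
    years,
    params: AR1Params,
    rng: np.random.Generator,
    survival_logcontrib=None,
) -> np.ndarray:
    """One fixed-order sweep of single-site updates over missing entries.

    Each missing I_{i,t} is redrawn from its full conditional: the Gaussian
    implied by its AR(1) neighbours (one-sided at series boundaries), times
    the survival-likelihood factor of the day it feeds.  Without a survival
    term the draw is the exact Gaussian conditional; with one, a Metropolis
    step proposes from that Gaussian and accepts on the survival log-ratio
    ``survival_logcontrib(i, t, z)`` (t 0-based within the matrix).
    """
    z = np.array(values, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    n, T = z.shape
    for i in range(n):
        y = int(years[i])
        al, rho, tau = float(params.alpha[y]), float(params.rho[y]), float(params.tau[y])
        svar = 1.0 / (tau * (1.0 - rho**2))
        for t in range(T):
            if observed[i, t]:
                continue
            if t == 0 and T == 1:
                m, v = al, svar
            elif t == 0:
                # stationary prior x one forward neighbour collapses to the
                # time-reversed one-step conditional
                m = al + rho * (z[i, 1] - al)
                v = 1.0 / tau
            elif t == T - 1:
                m = al + rho * (z[i, t - 1] - al)
                v = 1.0 / tau
            else:
                p = tau * (1.0 + rho**2)
                m = al + rho * ((z[i, t - 1] - al) + (z[i, t + 1] - al)) / (1.0 + rho**2)
                v = 1.0 / p
            prop = m + np.sqrt(v) * rng.standard_normal()
            if survival_logcontrib is None:
                z[i, t] = prop
            else:
                logr = survival_logcontrib(i, t, prop) - survival_logcontrib(i, t, z[i, t])
                if np.log(rng.uniform()) < logr:
                    z[i, t] = prop
    return z


def update_ar1_params(
    values,
    years,
    params: AR1Params,
    rng: np.random.Generator,
    normal_var: float = 1000.0,
    gamma_shape: float = 0.1,
    gamma_rate: float = 0.1,
    rho_step: float = 0.2,
) -> AR1Params:
    """Draw (alpha_y, tau_y, rho_y) for each year from their full conditionals.

    alpha and tau are conjugate (Normal and Gamma, both including the
    stationary first-day term); rho takes a random-walk Metropolis step with
    reflection at ±1 under its Uniform(−1, 1) prior.
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(years, dtype=int)
    alpha = params.alpha.copy()
    rho = params.rho.copy()
    tau = params.tau.copy()
    for y in range(len(alpha)):
        rows = values[years == y]
        if rows.size == 0:
            # no data: sample the priors directly
            alpha[y] = rng.normal(0.0, np.sqrt(normal_var))
            tau[y] = rng.gamma(gamma_shape, 1.0 / gamma_rate)
            rho[y] = _rho_metropolis(0.0, 0.0, 0.0, 0, 0, tau[y], rho[y], rho_step, rng)
            continue
        z1, zt, zp = rows[:, 0], rows[:, 1:].ravel(), rows[:, :-1].ravel()
        N1, N2 = z1.size, zt.size
        r = rho[y]
        # alpha | rest
        prec = 1.0 / normal_var + tau[y] * ((1 - r**2) * N1 + (1 - r) ** 2 * N2)
        num = tau[y] * ((1 - r**2) * z1.sum() + (1 - r) * (zt - r * zp).sum())
        alpha[y] = num / prec + rng.standard_normal() / np.sqrt(prec)
        # tau | rest
        d1 = z1 - alpha[y]
        resid = zt - alpha[y] - r * (zp - alpha[y])
        ss = (1 - r**2) * (d1**2).sum() + (resid**2).sum()
        tau[y] = rng.gamma(gamma_shape + 0.5 * (N1 + N2), 1.0 / (gamma_rate + 0.5 * ss))
        # rho | rest (Metropolis)
        dt, dp = zt - alpha[y], zp - alpha[y]
        rho[y] = _rho_metropolis(
            (d1**2).sum(), (dt * dp).sum(), (dp**2).sum(), N1, (dt**2).sum(),
            tau[y], r, rho_step, rng,
        )
    return AR1Params(alpha, rho, tau)


def _rho_metropolis(sd1, scross, sprev, n1, scur, tau, rho, step, rng):
    """Reflecting random-walk Metropolis for rho on (-1, 1)."""

    def logtarget(r):
        return 0.5 * n1 * np.log1p(-r**2) - 0.5 * tau * (
            (1 - r**2) * sd1 + scur - 2 * r * scross + r**2 * sprev
        )

    prop = rho + step * rng.standard_normal()
    while prop <= -1.0 or prop >= 1.0:  # reflect at the boundaries
        if prop >= 1.0:
            prop = 2.0 - prop
        if prop <= -1.0:
            prop = -2.0 - prop
    if np.log(rng.uniform()) < logtarget(prop) - logtarget(rho):
        return prop
    return rho


# ---------------------------------------------------------------------------
# dynamic occupancy process: likelihood, imputation, parameter updates
# ---------------------------------------------------------------------------

def occupancy_loglik(values, years, params: OccupancyParams) -> float:
    """Complete-data log likelihood of binary nest × day series.

    Success probability for day t is phi_y I_{t-1} + gamma_y (1 - I_{t-1});
    day 1 is Bernoulli(psi_y) with the stationary occupancy.
    """
    values = np.asarray(values, dtype=float)
    years = np.asarray(years, dtype=int)
    if np.isnan(values).any():
        raise ValueError("series must be complete (impute missing values first)")
    if not np.isin(values, (0.0, 1.0)).all():
        raise ValueError("occupancy series must be binary")
    phi = params.phi[years][:, None]
    gam = params.gamma[years][:, None]
    psi = stationary_occupancy(phi, gam)
    z1 = values[:, :1]
    ll = (z1 * np.log(psi) + (1 - z1) * np.log1p(-psi)).sum()
    p = phi * values[:, :-1] + gam * (1 - values[:, :-1])
    zt = values[:, 1:]
    ll += (zt * np.log(p) + (1 - zt) * np.log1p(-p)).sum()
    return float(ll)


def impute_occupancy(
    values,
    observed,
    years,
    params: OccupancyParams,
    rng: np.random.Generator,
    survival_logcontrib=None,
) -> np.ndarray:
    """Exact single-site Gibbs sweep over missing binary entries.

    The state is binary, so the full conditional is enumerated exactly:
    Pr(I=1) ∝ (backward chain term) × (forward chain term) × exp(survival
    log-contribution at 1), and likewise for 0.
    """
    z = np.array(values, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    n, T = z.shape
    for i in range(n):
        y = int(years[i])
        phi, gam = float(params.phi[y]), float(params.gamma[y])
        psi = gam / (gam + 1.0 - phi)
        for t in range(T):
            if observed[i, t]:
                continue
            l1 = np.log(psi) if t == 0 else (
                np.log(phi) if z[i, t - 1] == 1 else np.log(gam)
            )
            l0 = np.log1p(-psi) if t == 0 else (
                np.log1p(-phi) if z[i, t - 1] == 1 else np.log1p(-gam)
            )
            if t < T - 1:
                nxt = z[i, t + 1]
                l1 += np.log(phi) if nxt == 1 else np.log1p(-phi)
                l0 += np.log(gam) if nxt == 1 else np.log1p(-gam)
            if survival_logcontrib is not None:
                l1 += survival_logcontrib(i, t, 1.0)
                l0 += survival_logcontrib(i, t, 0.0)
            p1 = 1.0 / (1.0 + np.exp(l0 - l1))
            z[i, t] = float(rng.uniform() < p1)
    return z


def occupancy_transition_counts(values, years, n_years: int) -> np.ndarray:
    """Per-year counts (n11, n10, n01, n00, first-day ones, first-day zeros)."""
    values = np.asarray(values, dtype=float)
    years = np.asarray(years, dtype=int)
    out = np.zeros((n_years, 6))
    prev, cur = values[:, :-1], values[:, 1:]
    for y in range(n_years):
        m = years == y
        p, c = prev[m], cur[m]
        out[y, 0] = (p * c).sum()
        out[y, 1] = (p * (1 - c)).sum()
        out[y, 2] = ((1 - p) * c).sum()
        out[y, 3] = ((1 - p) * (1 - c)).sum()
        out[y, 4] = values[m, 0].sum()
        out[y, 5] = (1 - values[m, 0]).sum()
    return out


def update_occupancy_params(
    values,
    years,
    params: OccupancyParams,
    rng: np.random.Generator,
) -> OccupancyParams:
    """Draw (phi_y, gamma_y) under Uniform(0,1) priors.

    Beta full conditionals given the transition counts (Uniform = Beta(1,1))
    serve as an independence proposal; the first-day stationary Bernoulli(psi)
    terms, which break exact conjugacy, enter through a Metropolis
    accept/reject correction.
    """
    phi = params.phi.copy()
    gam = params.gamma.copy()
    counts = occupancy_transition_counts(values, years, len(phi))
    for y in range(len(phi)):
        n11, n10, n01, n00, f1, f0 = counts[y]
        phi_p = rng.beta(1.0 + n11, 1.0 + n10)
        gam_p = rng.beta(1.0 + n01, 1.0 + n00)
        # proposal and transition-likelihood x prior terms cancel; the MH
        # ratio reduces to the first-day stationary terms
        def _day1(ph, ga):
            psi = ga / (ga + 1.0 - ph)
            return f1 * np.log(psi) + f0 * np.log1p(-psi)

        if np.log(rng.uniform()) < _day1(phi_p, gam_p) - _day1(phi[y], gam[y]):
            phi[y], gam[y] = phi_p, gam_p
    return OccupancyParams(phi, gam)
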