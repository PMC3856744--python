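"""Daily nest-survival likelihood and its parameter updates.

The daily survival probability of nest *i* over the transition from day *t*
to *t+1* is

    logit S_{i,t} = beta0[pair_i] + beta_renest * renest_i
                    + sum_m w_m beta_m Z_{m,i,t+1},

with a Normal(mu_pair, sigma_pair) random intercept per nesting pair, a
fixed renesting effect, and M candidate insect covariates gated by binary
Kuo–Mallick inclusion indicators w_m.  Covariates are indexed at the
destination day of the transition.  An encounter history contributes log S
for every transition whose destination state is certainly alive (this
includes checked-alive days and interior unchecked days between two alive
observations) and, when a failure is observed after an unchecked stretch,
log(1 - prod S) over the stretch — the unknown failure day marginalized
analytically.  A successful nest's record ends the day before hatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .io_data import EncounterHistory, ValidationError

__all__ = [
    "PriorConfig",
    "SurvivalParams",
    "SurvivalDesign",
    "daily_survival",
    "survival_loglik",
    "update_survival_params",
    "compute_eta",
    "logistic",
]


def logistic(x):
    from scipy.special import expit

    return expit(np.asarray(x, dtype=float))


@dataclass
class PriorConfig:
    """Prior settings (defaults follow the fitted model's specification).

    Mean-zero normal with variance 1000 for unconstrained location terms,
    Gamma(0.1, 0.1) for precisions, Uniform(0,1) for occupancy
    probabilities, Uniform(-1,1) for AR(1) autocorrelations,
    Bernoulli(0.5) for inclusion indicators, and Gamma(shape 3.29,
    rate 7.8) for the total covariate-block prior variance V; each
    covariate coefficient has prior Normal(0, V/K') with K' = max(K, 1)
    and K the current number of included effects, keeping total prior
    uncertainty constant across model dimensions.
    """

    normal_var: float = 1000.0
    gamma_shape: float = 0.1
    gamma_rate: float = 0.1
    v_shape: float = 3.29
    v_rate: float = 7.8
    w_prior: float = 0.5


@dataclass
class SurvivalParams:
    """Current survival-model parameter state."""

    b0: np.ndarray              # per-pair intercepts, logit scale
    mu_pair: float
    sigma_pair: float
    beta_renest: float
    beta: np.ndarray            # per-covariate effects (always defined)
    w: np.ndarray               # binary inclusion indicators
    V: float                    # total prior variance of the covariate block

    def __post_init__(self) -> None:
        self.b0 = np.atleast_1d(np.asarray(self.b0, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float)) if np.size(self.beta) else np.zeros(0)
        self.w = np.atleast_1d(np.asarray(self.w, dtype=np.int8)) if np.size(self.w) else np.zeros(0, np.int8)
        if self.sigma_pair <= 0:
            raise ValueError("sigma_pair must be > 0")
        if self.V <= 0:
            raise ValueError("V must be > 0")
        if not np.isin(self.w, (0, 1)).all():
            raise ValueError("w must be binary")
        if self.beta.shape != self.w.shape:
            raise ValueError("beta and w must align")

    @property
    def K(self) -> int:
        return int(self.w.sum())

    @property
    def K_eff(self) -> int:
        return max(self.K, 1)


class SurvivalDesign:
    """Flattened transition layout of a set of encounter histories.

    Transitions with a certainly-alive destination come first (``n_alive``
    of them), then death-gap transitions grouped per gap with CSR offsets
    ``gap_ptr``.  ``cov_col`` gives the 0-based day-of-season column of the
    covariate each transition uses (the destination day).
    """

    def __init__(self, histories: list[EncounterHistory], n_days: int,
                 covariate_timing: str = "next_day"):
        if covariate_timing not in ("next_day", "same_day"):
            raise ValueError("covariate_timing must be 'next_day' or 'same_day'")
        self.covariate_timing = covariate_timing
        self.histories = histories
        self.n_days = int(n_days)
        self.n = len(histories)
        pair_ids: list[str] = []
        pair_lookup: dict[str, int] = {}
        self.years = sorted({h.year for h in histories})
        year_lookup = {y: k for k, y in enumerate(self.years)}
        self.pair_index = np.zeros(self.n, dtype=np.int64)
        self.year_index = np.zeros(self.n, dtype=np.int64)
        self.renest = np.zeros(self.n, dtype=np.int64)
        alive_nest: list[int] = []
        alive_from: list[int] = []
        gap_nest: list[int] = []
        gap_from: list[list[int]] = []
        for i, h in enumerate(histories):
            if h.days[-1] > n_days:
                raise ValidationError(f"nest {h.nest_id}: day {h.days[-1]} beyond season {n_days}")
            skey = h.pair_id
            if skey not in pair_lookup:
                pair_lookup[skey] = len(pair_ids)
                pair_ids.append(skey)
            self.pair_index[i] = pair_lookup[skey]
            self.year_index[i] = year_lookup[h.year]
            self.renest[i] = h.renest
            d0 = h.detection_day
            la = h.last_alive_day
            for t in range(d0, la):
                alive_nest.append(i)
                alive_from.append(t)
            if h.failed:
                fd = h.failure_day
                gap_nest.append(i)
                gap_from.append(list(range(la, fd)))
        self.pair_ids = pair_ids
        self.n_pairs = len(pair_ids)
        self.n_alive = len(alive_nest)
        gptr = [0]
        for g in gap_from:
            gptr.append(gptr[-1] + len(g))
        self.gap_ptr = np.asarray(gptr, dtype=np.int64)
        self.n_gaps = len(gap_nest)
        self.trans_nest = np.asarray(
            alive_nest + [gn for gn, g in zip(gap_nest, gap_from) for _ in g], dtype=np.int64
        )
        self.trans_from = np.asarray(
            alive_from + [t for g in gap_from for t in g], dtype=np.int64
        )
        self.n_trans = self.trans_nest.size
        # covariate column (0-based): the destination day t+1 (== from-day as
        # a 0-based index) by default, or the origin day for the same-day
        # sensitivity analysis
        self.cov_col = self.trans_from.copy()
        if covariate_timing == "same_day":
            self.cov_col = np.maximum(self.cov_col - 1, 0)
        if self.n_trans and self.cov_col.max() > n_days - 1:
            raise ValidationError("transition uses a covariate day beyond the season")
        self.pair_of_trans = self.pair_index[self.trans_nest]
        self.renest_of_trans = self.renest[self.trans_nest].astype(float)
        # gap index per transition (-1 for certain-alive)
        self.trans_gap = np.full(self.n_trans, -1, dtype=np.int64)
        for g in range(self.n_gaps):
            lo = self.n_alive + self.gap_ptr[g]
            hi = self.n_alive + self.gap_ptr[g + 1]
            self.trans_gap[lo:hi] = g

    def gather_covariates(self, Z: np.ndarray) -> np.ndarray:
        """(M, n, T) complete covariate array -> (M, n_trans) at transitions."""
        Z = np.asarray(Z, dtype=float)
        if Z.ndim == 2:
            Z = Z[None]
        zact = Z[:, self.trans_nest, self.cov_col]
        if np.isnan(zact).any():
            raise ValidationError("missing covariate value at a survival transition "
                                  "(impute latent days first)")
        return zact


def compute_eta(design: SurvivalDesign, params: SurvivalParams, zact: np.ndarray | None) -> np.ndarray:
    eta = params.b0[design.pair_of_trans] + params.beta_renest * design.renest_of_trans
    if zact is not None and len(params.beta):
        wb = params.w * params.beta
        eta = eta + wb @ zact
    return eta


def daily_survival(params: SurvivalParams, covariates, renest: int, pair: int | None = None) -> float:
    """Daily survival probability for one nest-day.

    ``covariates`` supplies the M metric values at the destination day
    (observed or currently imputed); ``pair`` selects a pair intercept,
    defaulting to the population mean mu_pair.  Excluded covariates
    (w_m = 0) do not affect the result.
    """
    covariates = np.atleast_1d(np.asarray(covariates, dtype=float)) if np.size(covariates) else np.zeros(0)
    if len(params.beta) != covariates.size:
        raise ValidationError(f"expected {len(params.beta)} covariate values, got {covariates.size}")
    if np.isnan(covariates).any():
        raise ValidationError("missing covariate value with no imputation")
    b0 = params.mu_pair if pair is None else params.b0[pair]
    eta = b0 + params.beta_renest * renest + float((params.w * params.beta) @ covariates)
    return float(logistic(eta))


def survival_loglik(
    histories: list[EncounterHistory],
    params: SurvivalParams,
    covariates: np.ndarray | None = None,
    n_days: int | None = None,
    design: SurvivalDesign | None = None,
) -> float:
    """Log likelihood of encounter histories under the daily survival model.

    ``covariates`` is a complete (M, n, T) array aligned with ``histories``
    (pass None for a covariate-free model).  Certainly-alive transitions
    contribute log S; a death after an unchecked stretch contributes
    log(1 - prod S) over the stretch.
    """
    if design is None:
        if n_days is None:
            n_days = max(int(h.days[-1]) for h in histories)
        design = SurvivalDesign(histories, n_days)
    zact = design.gather_covariates(covariates) if covariates is not None else None
    eta = compute_eta(design, params, zact)
    return float(_kernels.survival_ll(eta, design.n_alive, design.gap_ptr))


# ---------------------------------------------------------------------------
# Gibbs-block update
# ---------------------------------------------------------------------------

class LikCache:
    """Per-transition log-S cache enabling incremental likelihood deltas.

    ``terms[j]`` is log S (or log of the survival term) at transition j for
    the current ``eta``; ``gapG[g]`` the running sum of log S over death gap
    g.  ``cand``/``gnew`` are scratch for proposed moves.  The cache is
    refreshed once per sweep (after the pair-intercept pass) and maintained
    incrementally by every accepted move elsewhere.
    """

    def __init__(self, design: SurvivalDesign):
        self.terms = np.zeros(design.n_trans)
        self.cand = np.zeros(design.n_trans)
        self.gapG = np.zeros(design.n_gaps)
        self.gnew = np.zeros(design.n_gaps)

    def refresh(self, design: SurvivalDesign, eta: np.ndarray) -> None:
        _kernels.elementwise_logsig(eta, self.terms)
        _kernels.gap_logsums(eta, design.n_alive, design.gap_ptr, self.gapG)


@dataclass
class ProposalScales:
    """Random-walk step sizes, adapted during burn-in only."""

    pair: np.ndarray
    beta: np.ndarray
    renest: float = 0.3
    logV: float = 0.8

    @classmethod
    def defaults(cls, n_pairs: int, n_metrics: int) -> "ProposalScales":
        return cls(pair=np.full(n_pairs, 0.5), beta=np.full(n_metrics, 0.3))


@dataclass
class AcceptTracker:
    counts: dict = field(default_factory=dict)
    totals: dict = field(default_factory=dict)

    def add(self, name, accepted, total=1):
        self.counts[name] = self.counts.get(name, 0) + float(np.sum(accepted))
        self.totals[name] = self.totals.get(name, 0) + total

    def rate(self, name):
        return self.counts.get(name, 0.0) / max(self.totals.get(name, 0), 1)

    def reset(self):
        self.counts.clear()
        self.totals.clear()


def update_survival_params(
    design: SurvivalDesign,
    zact: np.ndarray,
    params: SurvivalParams,
    eta: np.ndarray,
    rng: np.random.Generator,
    priors: PriorConfig,
    scales: ProposalScales,
    tracker: AcceptTracker | None = None,
    adapt: bool = False,
    cache: LikCache | None = None,
) -> None:
    """One Gibbs pass over the survival-block parameters (in place).

    Pair intercepts, the renest effect and included covariate effects take
    random-walk Metropolis steps on the logit-scale likelihood times their
    priors; mu_pair and the pair precision are conjugate (Normal, Gamma);
    excluded covariate effects are refreshed from their Normal(0, V/K')
    prior, which keeps the chain mixing across models.  ``eta`` is kept
    consistent with the updated parameters.
    """
    P = design.n_pairs
    # -- pair intercepts (joint pass, independent accept/reject) ----------
    accepted = np.zeros(P, dtype=np.bool_)
    _kernels.pair_block_update(
        eta, design.n_alive, design.gap_ptr, design.pair_of_trans,
        params.b0, params.mu_pair, params.sigma_pair**2,
        scales.pair, rng.standard_normal(P), np.log(rng.uniform(size=P)), accepted,
    )
    # pairs with no transitions have the prior as their full conditional
    idle = np.bincount(design.pair_of_trans, minlength=P) == 0
    if idle.any():
        params.b0[idle] = params.mu_pair + params.sigma_pair * rng.standard_normal(idle.sum())
        accepted[idle] = True
    if tracker is not None:
        tracker.add("pair", accepted.sum(), P)
    if adapt:
        scales.pair *= np.exp(0.05 * (accepted.astype(float) - 0.44))

    # -- mu_pair | b0 (conjugate normal) ----------------------------------
    prec = 1.0 / priors.normal_var + P / params.sigma_pair**2
    mean = (params.b0.sum() / params.sigma_pair**2) / prec
    params.mu_pair = mean + rng.standard_normal() / np.sqrt(prec)

    # -- sigma_pair^-2 | b0 (conjugate gamma) ------------------------------
    ss = float(((params.b0 - params.mu_pair) ** 2).sum())
    tau = rng.gamma(priors.gamma_shape + 0.5 * P, 1.0 / (priors.gamma_rate + 0.5 * ss))
    params.sigma_pair = 1.0 / np.sqrt(tau)

    if cache is None:
        cache = LikCache(design)
    cache.refresh(design, eta)  # the pair pass moved eta; rebuild the log-S cache

    # -- renest effect ------------------------------------------------------
    if not design.renest_of_trans.any():
        # no renesting attempt contributes a transition: conditional = prior
        params.beta_renest = float(np.sqrt(priors.normal_var) * rng.standard_normal())
    else:
        d = scales.renest * rng.standard_normal()
        dll = _kernels.propose_delta(
            eta, cache.terms, cache.gapG, design.n_alive, design.gap_ptr,
            design.renest_of_trans, d, cache.cand, cache.gnew,
        )
        new = params.beta_renest + d
        dprior = -(new**2 - params.beta_renest**2) / (2 * priors.normal_var)
        acc = np.log(rng.uniform()) < dll + dprior
        if acc:
            params.beta_renest = new
            _kernels.apply_delta(eta, cache.terms, cache.gapG,
                                 design.renest_of_trans, d, cache.cand, cache.gnew)
        if tracker is not None:
            tracker.add("renest", acc)
        if adapt:
            scales.renest *= np.exp(0.05 * (float(acc) - 0.44))

    # -- covariate effects --------------------------------------------------
    prior_var = params.V / params.K_eff
    for m in range(len(params.beta)):
        if params.w[m] == 0 or not zact[m].any():
            # excluded (or likelihood-inert) effects refresh from the prior
            params.beta[m] = np.sqrt(prior_var) * rng.standard_normal()
            continue
        d = scales.beta[m] * rng.standard_normal()
        dll = _kernels.propose_delta(
            eta, cache.terms, cache.gapG, design.n_alive, design.gap_ptr,
            zact[m], d, cache.cand, cache.gnew,
        )
        new = params.beta[m] + d
        dprior = -(new**2 - params.beta[m] ** 2) / (2 * prior_var)
        acc = np.log(rng.uniform()) < dll + dprior
        if acc:
            params.beta[m] = new
            _kernels.apply_delta(eta, cache.terms, cache.gapG,
                                 zact[m], d, cache.cand, cache.gnew)
        if tracker is not None:
            tracker.add(f"beta{m}", acc)
        if adapt:
            scales.beta[m] *= np.exp(0.05 * (float(acc) - 0.44))
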