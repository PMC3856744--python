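"""Kuo–Mallick indicator-variable model selection and Bayes factors.

Every candidate covariate effect enters the linear predictor multiplied by
a Bernoulli(0.5) indicator w_m; the posterior mean of w_m is the variable's
posterior inclusion probability and

    BF_m = [p_m / (1 - p_m)] / [w / (1 - w)],   w = prior inclusion = 0.5,

is the posterior-to-prior odds ratio for inclusion.  To keep total prior
uncertainty constant across model dimensions, each coefficient's prior is
Normal(0, V/K') with K' = max(sum w, 1) and V ~ Gamma(3.29, 7.8) (shape,
rate) on the total covariate-block variance — a prior under which the
induced marginal distribution of daily survival is roughly flat on (0, 1).
Flipping one indicator changes K and hence the prior density of *every*
coefficient; the exact Bernoulli full conditional used here accounts for
that prior-ratio term as well as the survival-likelihood ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .survival_model import PriorConfig, SurvivalDesign, SurvivalParams, logistic

__all__ = [
    "SelectionSummary",
    "bayes_factor",
    "update_indicators",
    "summarize_selection",
    "marginal_survival_prior_quantiles",
    "jeffreys_label",
]


def bayes_factor(p_m: float, prior_w: float = 0.5, n_draws: int | None = None):
    """Posterior-to-prior odds ratio for a variable's inclusion.

    Returns a float for interior ``p_m``.  At the boundary (every retained
    draw included, or none), the odds are only bounded by the Monte-Carlo
    resolution: with ``n_draws`` given, returns the bound as the string
    ``">N"`` (or ``"<N"``) computed by substituting 1/n_draws for the
    unobserved tail; without it, raises.
    """
    if not 0 < prior_w < 1:
        raise ValueError("prior inclusion probability must be in (0, 1)")
    prior_odds = prior_w / (1 - prior_w)
    if p_m in (0.0, 1.0):
        if n_draws is None:
            raise ValueError("boundary inclusion probability: pass n_draws to report a bound")
        eps = 1.0 / n_draws
        if p_m == 1.0:
            return f">{((1 - eps) / eps) / prior_odds:.2f}"
        return f"<{(eps / (1 - eps)) / prior_odds:.2f}"
    if not 0 < p_m < 1:
        raise ValueError("inclusion probability must lie in [0, 1]")
    return ((p_m / (1 - p_m))) / prior_odds


def jeffreys_label(bf: float) -> str:
    """Heuristic verbal scale (use with caution; evidence is a continuum)."""
    if bf > 12:
        return "strong support"
    if bf >= 3:
        return "some support"
    if bf > 1 / 3:
        return "little evidence either way"
    return "support against"


def _beta_prior_logdens_sum(beta: np.ndarray, var: float) -> float:
    return float(-0.5 * (len(beta) * np.log(2 * np.pi * var) + (beta**2).sum() / var))


def update_indicators(
    design: SurvivalDesign,
    zact: np.ndarray,
    params: SurvivalParams,
    eta: np.ndarray,
    rng: np.random.Generator,
    priors: PriorConfig,
    scales_logV: float = 0.8,
    subset: np.ndarray | None = None,
    tracker=None,
    cache=None,
) -> None:
    """Exact Bernoulli full-conditional updates of w, then a Metropolis
    step on the total variance V (in place; ``eta`` kept consistent).

    For each m the two states' unnormalized log posteriors differ by the
    survival-likelihood ratio plus the prior-density ratio of all M
    coefficients under the two implied K values (the Bernoulli(0.5) prior
    itself cancels for the default prior).
    """
    from .survival_model import LikCache

    M = len(params.beta)
    if cache is None:
        cache = LikCache(design)
        cache.refresh(design, eta)
    logit_prior_w = np.log(priors.w_prior) - np.log1p(-priors.w_prior)
    for m in subset if subset is not None else range(M):
        K = params.K
        if params.w[m] == 1:
            K1, K0 = K, K - 1
            d = -params.beta[m]
        else:
            K1, K0 = K + 1, K
            d = params.beta[m]
        # dll = log L(flipped state) - log L(current state)
        dll = _kernels.propose_delta(
            eta, cache.terms, cache.gapG, design.n_alive, design.gap_ptr,
            zact[m], d, cache.cand, cache.gnew,
        )
        dprior = (
            _beta_prior_logdens_sum(params.beta, params.V / max(K1, 1))
            - _beta_prior_logdens_sum(params.beta, params.V / max(K0, 1))
        )
        ll_on_minus_off = -dll if params.w[m] == 1 else dll
        logit_p1 = ll_on_minus_off + dprior + logit_prior_w
        new = int(rng.uniform() < logistic(logit_p1))
        if new != params.w[m]:
            params.w[m] = new
            _kernels.apply_delta(eta, cache.terms, cache.gapG,
                                 zact[m], d, cache.cand, cache.gnew)

    # -- V | beta, w --------------------------------------------------------
    def logtarget(logv):
        v = np.exp(logv)
        ke = params.K_eff
        return (
            priors.v_shape * logv  # Gamma(a,b) density x Jacobian of log transform
            - priors.v_rate * v
            + _beta_prior_logdens_sum(params.beta, v / ke)
        )

    cur = np.log(params.V)
    prop = cur + scales_logV * rng.standard_normal()
    acc = np.log(rng.uniform()) < logtarget(prop) - logtarget(cur)
    if acc:
        params.V = float(np.exp(prop))
    if tracker is not None:
        tracker.add("V", acc)


@dataclass
class SelectionSummary:
    """Posterior inclusion probabilities, Bayes factors and the top model."""

    names: list[str]
    inclusion: np.ndarray
    bayes_factors: list
    top_model: np.ndarray
    visited: "object"              # DataFrame: bit pattern, count, rank
    conditional_beta: "object"     # DataFrame: mean, sd, CI of included betas
    n_draws: int
    prior_w: float = 0.5

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "variable": self.names,
                "inclusion_probability": self.inclusion,
                "bayes_factor": self.bayes_factors,
                "evidence": [
                    jeffreys_label(b) if isinstance(b, float) else "bound"
                    for b in self.bayes_factors
                ],
            }
        )


def summarize_selection(w_draws: np.ndarray, beta_draws: np.ndarray, names: list[str],
                        prior_w: float = 0.5, ci: float = 0.95) -> SelectionSummary:
    """Posterior selection summaries from retained draws.

    ``w_draws``/``beta_draws`` are (n_draws, M) with chains already stacked.
    The top model is the most-visited indicator bit pattern; coefficient
    summaries are conditional on it (computed only over matching draws).
    """
    import pandas as pd

    w_draws = np.asarray(w_draws)
    beta_draws = np.asarray(beta_draws)
    n, M = w_draws.shape
    if n < 1:
        raise ValueError("no retained draws")
    incl = w_draws.mean(axis=0)
    bfs = [bayes_factor(float(p) if 0 < p < 1 else float(p), prior_w, n_draws=n) for p in incl]
    # visited models
    weights = 1 << np.arange(M, dtype=np.int64)
    codes = (w_draws.astype(np.int64) @ weights) if M else np.zeros(n, dtype=np.int64)
    uniq, counts = np.unique(codes, return_counts=True)
    order = np.argsort(-counts)
    patterns = [
        "".join(str((int(c) >> m) & 1) for m in range(M)) for c in uniq[order]
    ]
    visited = pd.DataFrame(
        {"model": patterns, "count": counts[order], "rank": np.arange(1, len(uniq) + 1)}
    )
    assert int(visited["count"].sum()) == n, "visit counts must conserve draws"
    top_code = uniq[order][0]
    top = np.array([(int(top_code) >> m) & 1 for m in range(M)], dtype=int)
    match = codes == top_code
    rows = []
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    for m in range(M):
        if top[m] == 1:
            bm = beta_draws[match, m]
            if bm.size == 0:
                raise RuntimeError("internal error: top model has no matching draws")
            rows.append(
                dict(variable=names[m], mean=bm.mean(), sd=bm.std(ddof=1),
                     lower=np.quantile(bm, lo), upper=np.quantile(bm, hi),
                     n_draws=bm.size)
            )
    conditional = pd.DataFrame(rows, columns=["variable", "mean", "sd", "lower", "upper", "n_draws"])
    return SelectionSummary(
        names=list(names), inclusion=incl, bayes_factors=bfs, top_model=top,
        visited=visited, conditional_beta=conditional, n_draws=n, prior_w=prior_w,
    )


def marginal_survival_prior_quantiles(
    n_draws: int = 100_000,
    v_shape: float = 3.29,
    v_rate: float = 7.8,
    K: int = 1,
    seed: int = 0,
    q=(0.05, 0.95),
):
    """Quantiles of the survival probability induced by the V prior.

    Simulates V ~ Gamma(shape, rate), beta ~ Normal(0, V/K), and returns
    quantiles of logistic(beta): a self-check that the prior on the
    covariate block induces a roughly flat marginal on daily survival
    (the 5%/95% quantiles should fall inside (0.03, 0.97)).
    """
    rng = np.random.default_rng(seed)
    v = rng.gamma(v_shape, 1.0 / v_rate, size=n_draws)
    beta = rng.standard_normal(n_draws) * np.sqrt(v / max(K, 1))
    s = logistic(beta)
    return tuple(float(np.quantile(s, qi)) for qi in q)
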