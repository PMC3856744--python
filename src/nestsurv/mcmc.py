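"""Metropolis-within-Gibbs orchestration, chains and diagnostics.

One sweep visits, in fixed order: (1) latent-covariate imputation per
metric, (2) covariate-model parameter updates (AR(1) per taxon, occupancy
per binary metric), (3) survival-block parameters (pair intercepts and
their hyperparameters, renest effect, covariate effects), (4) inclusion
indicators w and the total prior variance V.  Proposal scales adapt during
burn-in only and are frozen afterwards, preserving detailed balance of the
retained draws.  Chains are seeded independently and runs are bit
reproducible given (seed, chain count).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import _kernels
from ._latent import build_blocks
from .covariate_prep import CovariateSeries
from .io_data import EncounterHistory, ValidationError
from .selection import update_indicators
from .survival_model import (
    LikCache,
    PriorConfig,
    ProposalScales,
    SurvivalDesign,
    SurvivalParams,
    compute_eta,
    update_survival_params,
)

__all__ = [
    "ModelConfig",
    "AnalysisDataset",
    "PosteriorSamples",
    "SamplerState",
    "initialize_state",
    "run_mcmc",
    "gelman_rubin",
]


@dataclass
class ModelConfig:
    """MCMC and model controls.

    The default profile is desk scale (3 × 10,000 sweeps, 2,000 burn-in);
    ``paper_profile`` mirrors the full-length run (three chains totalling
    500,000 retained draws after a 20,000-sweep burn-in).
    """

    n_chains: int = 3
    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 1
    seed: int = 0
    priors: PriorConfig = field(default_factory=PriorConfig)
    covariate_update_period: int = 1   # impute/update covariate blocks every k-th sweep
    indicator_update_count: int | None = None  # indicators refreshed per sweep (None = all)
    store_pair_intercepts: bool = True
    store_latent_every: int = 0        # 0 disables latent-covariate storage
    covariate_timing: str = "next_day"  # or "same_day" (sensitivity analysis)
    track_log_posterior: bool = False

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("iterations must exceed burn-in")
        if self.n_chains < 1:
            raise ValueError("at least one chain required")

    @classmethod
    def paper_profile(cls, seed: int = 0) -> "ModelConfig":
        return cls(n_chains=3, n_iter=186_667, burn_in=20_000, seed=seed)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "priors" in d and isinstance(d["priors"], dict):
            d["priors"] = PriorConfig(**d["priors"])
        return cls(**d)


@dataclass
class AnalysisDataset:
    """Validated, aligned inputs for one fit."""

    histories: list[EncounterHistory]
    series: list[CovariateSeries]
    n_days: int

    def __post_init__(self) -> None:
        ids = [h.nest_id for h in self.histories]
        for s in self.series:
            if list(s.nest_ids) != ids:
                order = {nid: k for k, nid in enumerate(s.nest_ids)}
                missing = [nid for nid in ids if nid not in order]
                if missing:
                    raise ValidationError(f"series {s.name} lacks nests {missing[:3]}...")
                sel = [order[nid] for nid in ids]
                s.values = s.values[sel]
                s.observed = s.observed[sel]
                s.nest_ids = list(ids)
            if s.n_days != self.n_days:
                raise ValidationError(f"series {s.name} has {s.n_days} days, expected {self.n_days}")

    @property
    def metric_names(self) -> list[str]:
        return [s.name for s in self.series]


class SamplerState:
    """Mutable state of one chain."""

    def __init__(self, dataset: AnalysisDataset, config: ModelConfig, rng: np.random.Generator):
        self.design = SurvivalDesign(dataset.histories, dataset.n_days,
                                     covariate_timing=config.covariate_timing)
        self.blocks = build_blocks(dataset.series, self.design)
        self.config = config
        d = self.design
        M = len(self.blocks)
        for b in self.blocks:
            b.initialize(rng)
        # crude daily survival for the starting intercept
        s0 = (d.n_trans - d.n_gaps) / d.n_trans if d.n_trans else 0.5
        s0 = min(max(s0, 0.6), 0.99)
        mu0 = float(np.log(s0 / (1 - s0)))
        self.params = SurvivalParams(
            b0=np.full(d.n_pairs, mu0), mu_pair=mu0, sigma_pair=1.0,
            beta_renest=0.0, beta=np.zeros(M), w=np.ones(M, dtype=np.int8),
            V=config.priors.v_shape / config.priors.v_rate,
        )
        self.zact = np.zeros((M, d.n_trans))
        for m, b in enumerate(self.blocks):
            b.fill_zact(self.zact[m])
        self.eta = compute_eta(d, self.params, self.zact)
        self.cache = LikCache(d)
        self.cache.refresh(d, self.eta)
        self.gapG = self.cache.gapG
        self.scales = ProposalScales.defaults(d.n_pairs, M)
        from .survival_model import AcceptTracker

        self.tracker = AcceptTracker()
        if not np.isfinite(self.log_posterior()):
            raise RuntimeError(
                "non-finite log posterior at initialization; state dump: "
                f"params={self.params}, eta range=({self.eta.min() if self.eta.size else 0}, "
                f"{self.eta.max() if self.eta.size else 0})"
            )

    def survival_loglik(self) -> float:
        d = self.design
        return float(_kernels.survival_ll(self.eta, d.n_alive, d.gap_ptr))

    def log_posterior(self) -> float:
        """Joint log density of data, latent values and parameters (up to a
        constant); used for initialization checks and diagnostics."""
        pr = self.config.priors
        p = self.params
        lp = self.survival_loglik()
        lp += sum(b.chain_loglik() for b in self.blocks)
        lp += float(-0.5 * ((p.b0 - p.mu_pair) ** 2).sum() / p.sigma_pair**2
                    - len(p.b0) * np.log(p.sigma_pair))
        lp += -0.5 * (p.mu_pair**2 + p.beta_renest**2) / pr.normal_var
        tau = 1.0 / p.sigma_pair**2
        lp += (pr.gamma_shape - 1) * np.log(tau) - pr.gamma_rate * tau
        var = p.V / p.K_eff
        lp += float(-0.5 * (len(p.beta) * np.log(var) + (p.beta**2).sum() / var))
        lp += (pr.v_shape - 1) * np.log(p.V) - pr.v_rate * p.V
        for b in self.blocks:
            if b.kind == "ar1":
                lp += float(
                    (-0.5 * b.params.alpha**2 / pr.normal_var
                     + (pr.gamma_shape - 1) * np.log(b.params.tau)
                     - pr.gamma_rate * b.params.tau).sum()
                )
        return float(lp)

    def sweep(self, rng: np.random.Generator, it: int, adapt: bool) -> None:
        cfg = self.config
        d = self.design
        if it % cfg.covariate_update_period == 0:
            wb = self.params.w * self.params.beta
            for m, b in enumerate(self.blocks):
                b.impute(wb[m], self.eta, d.trans_gap, d.gap_ptr, self.gapG, self.zact[m], rng)
                b.update_params(rng, cfg.priors, adapt=adapt)
        update_survival_params(
            d, self.zact, self.params, self.eta, rng, cfg.priors, self.scales,
            adapt=adapt, cache=self.cache, tracker=self.tracker,
        )
        M = len(self.blocks)
        if cfg.indicator_update_count is not None and cfg.indicator_update_count < M:
            k = cfg.indicator_update_count
            start = (it * k) % M
            subset = np.arange(start, start + k) % M
        else:
            subset = None
        update_indicators(
            d, self.zact, self.params, self.eta, rng, cfg.priors,
            scales_logV=self.scales.logV, subset=subset, cache=self.cache,
        )


@dataclass
class PosteriorSamples:
    """Post burn-in draws of every chain, plus run metadata.

    Scalar parameters live in ``scalars`` as (chains, draws) arrays; the
    grouped arrays ``beta``/``w`` are (chains, draws, M), pair intercepts
    (chains, draws, P) when stored, and covariate-model parameters
    (chains, draws, Y) per block under ``block_params``.
    """

    scalars: dict
    beta: np.ndarray
    w: np.ndarray
    b0: np.ndarray | None
    block_params: dict
    metric_names: list
    pair_ids: list
    meta: dict

    @property
    def n_chains(self) -> int:
        return self.beta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.beta.shape[1]

    def get(self, parameter: str) -> np.ndarray:
        """Resolve a parameter name to its (chains, draws) sample array.

        Accepts scalar names (``mu_pair``), indexed covariate effects
        (``beta[taxon:metric]``, ``w[...]``), pair intercepts
        (``b0[pair]``) and covariate-model entries
        (``ar1_alpha[taxon:log_count][year]`` etc.).
        """
        if parameter in self.scalars:
            return self.scalars[parameter]
        if "[" in parameter:
            base, rest = parameter.split("[", 1)
            key = rest.rstrip("]").split("][")
            if base in ("beta", "w"):
                m = self.metric_names.index(key[0])
                return (self.beta if base == "beta" else self.w)[:, :, m]
            if base == "b0":
                if self.b0 is None:
                    raise KeyError("pair intercepts were not stored")
                return self.b0[:, :, self.pair_ids.index(key[0])]
            name = f"{base}[{key[0]}]"
            if name in self.block_params:
                return self.block_params[name][:, :, int(key[1])]
        raise KeyError(f"unknown parameter {parameter!r}")

    def names(self) -> list[str]:
        out = list(self.scalars)
        out += [f"beta[{n}]" for n in self.metric_names]
        out += [f"w[{n}]" for n in self.metric_names]
        for name, arr in self.block_params.items():
            out += [f"{name[:-1]}][{y}]" for y in range(arr.shape[2])]
        return out

    def stacked(self, grouped: str) -> np.ndarray:
        """(chains*draws, M) view of a grouped array ('beta' or 'w')."""
        arr = getattr(self, grouped)
        return arr.reshape(arr.shape[0] * arr.shape[1], arr.shape[2])

    def to_dataframe(self):
        import pandas as pd

        cols = {}
        for name, arr in self.scalars.items():
            cols[name] = arr.reshape(-1)
        for m, n in enumerate(self.metric_names):
            cols[f"beta[{n}]"] = self.beta[:, :, m].reshape(-1)
            cols[f"w[{n}]"] = self.w[:, :, m].reshape(-1)
        df = pd.DataFrame(cols)
        df.insert(0, "chain", np.repeat(np.arange(self.n_chains), self.n_draws))
        df.insert(1, "draw", np.tile(np.arange(self.n_draws), self.n_chains))
        return df

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def initialize_state(
    dataset: AnalysisDataset, config: ModelConfig, rng: np.random.Generator
) -> SamplerState:
    """Deterministically (given the generator) build a valid starting state:
    latent covariates at year means (AR(1)) or stationary-frequency draws
    (occupancy), effects at zero, all indicators on, variance terms at
    their prior means, intercepts at the crude daily-survival logit."""
    return SamplerState(dataset, config, rng)


def run_mcmc(dataset: AnalysisDataset, config: ModelConfig) -> PosteriorSamples:
    """Run the full Metropolis-within-Gibbs sampler.

    Returns post burn-in draws for every chain.  Two calls with the same
    config (including seed) produce bit-identical output.
    """
    M = len(dataset.series)
    retained = (config.n_iter - config.burn_in) // config.thin
    scalars = {
        k: np.zeros((config.n_chains, retained))
        for k in ("mu_pair", "sigma_pair", "beta_renest", "V", "K", "survival_loglik")
    }
    if config.track_log_posterior:
        scalars["log_posterior"] = np.zeros((config.n_chains, retained))
    beta = np.zeros((config.n_chains, retained, M))
    w = np.zeros((config.n_chains, retained, M), dtype=np.int8)
    b0 = None
    block_params: dict[str, np.ndarray] = {}
    states = []
    latent_store: list[list[np.ndarray]] = [[] for _ in range(config.n_chains)]
    for c in range(config.n_chains):
        rng = np.random.default_rng([config.seed, c])
        state = initialize_state(dataset, config, rng)
        if b0 is None and config.store_pair_intercepts:
            b0 = np.zeros((config.n_chains, retained, state.design.n_pairs))
        if not block_params:
            for blk in state.blocks:
                pre = "ar1" if blk.kind == "ar1" else "occ"
                names = ("alpha", "rho", "tau") if blk.kind == "ar1" else ("phi", "gamma")
                for pn in names:
                    block_params[f"{pre}_{pn}[{blk.name}]"] = np.zeros(
                        (config.n_chains, retained, blk.n_years)
                    )
        r = 0
        for it in range(config.n_iter):
            state.sweep(rng, it, adapt=it < config.burn_in)
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                p = state.params
                scalars["mu_pair"][c, r] = p.mu_pair
                scalars["sigma_pair"][c, r] = p.sigma_pair
                scalars["beta_renest"][c, r] = p.beta_renest
                scalars["V"][c, r] = p.V
                scalars["K"][c, r] = p.K
                scalars["survival_loglik"][c, r] = state.survival_loglik()
                if config.track_log_posterior:
                    scalars["log_posterior"][c, r] = state.log_posterior()
                beta[c, r] = p.beta
                w[c, r] = p.w
                if b0 is not None:
                    b0[c, r] = p.b0
                for blk in state.blocks:
                    if blk.kind == "ar1":
                        block_params[f"ar1_alpha[{blk.name}]"][c, r] = blk.params.alpha
                        block_params[f"ar1_rho[{blk.name}]"][c, r] = blk.params.rho
                        block_params[f"ar1_tau[{blk.name}]"][c, r] = blk.params.tau
                    else:
                        block_params[f"occ_phi[{blk.name}]"][c, r] = blk.params.phi
                        block_params[f"occ_gamma[{blk.name}]"][c, r] = blk.params.gamma
                if config.store_latent_every and r % config.store_latent_every == 0:
                    latent_store[c].append(
                        np.concatenate([blk.values[~blk.obs] for blk in state.blocks])
                    )
                r += 1
        states.append(state)
    meta = {
        "seed": config.seed,
        "n_iter": config.n_iter,
        "burn_in": config.burn_in,
        "thin": config.thin,
        "n_nests": len(dataset.histories),
        "n_days": dataset.n_days,
        "sweep_order": ["imputation", "covariate_params", "survival_params", "indicators"],
        "acceptance_rates": [
            {name: st.tracker.rate(name) for name in st.tracker.totals}
            for st in states
        ],
    }
    if config.store_latent_every:
        meta["latent_draws"] = [np.asarray(ls) for ls in latent_store]
    return PosteriorSamples(
        scalars=scalars, beta=beta, w=w, b0=b0, block_params=block_params,
        metric_names=dataset.metric_names,
        pair_ids=states[0].design.pair_ids, meta=meta,
    )


def gelman_rubin(samples: PosteriorSamples | np.ndarray, parameter: str | None = None) -> float:
    """Classic potential scale reduction factor (between/within variance).

    Accepts either a PosteriorSamples plus a parameter name, or a raw
    (chains, draws) array.  Requires at least two chains and 100 retained
    draws per chain.
    """
    if isinstance(samples, PosteriorSamples):
        if parameter is None:
            raise ValueError("parameter name required")
        x = samples.get(parameter)
    else:
        x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("R-hat needs >= 2 chains")
    C, S = x.shape
    if S < 100:
        raise ValueError("R-hat needs >= 100 retained draws per chain")
    within = x.var(axis=1, ddof=1).mean()
    between = S * x.mean(axis=1).var(ddof=1)
    if within == 0:
        return 1.0 if between == 0 else np.inf
    var_plus = (S - 1) / S * within + between / S
    return float(np.sqrt(var_plus / within))
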