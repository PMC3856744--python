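"""Synthetic data with the statistical structure the model assumes.

The generator inverts the fitted model: per-trap log-intensities follow a
year-specific AR(1), counts are Poisson draws of the exponentiated
intensity, a configurable subset of days is left unsampled (emulating
less-than-daily trapping: by default 50 of 72 season days in year one and
5 of 75 in year two), and daily nest survival is Bernoulli on the logit
scale with a pair random intercept, a renesting effect and a negative
effect of one taxon's ln(count+1) index.  Counts are simulated at trap
level and pushed through the same interpolation and metric-construction
path used for real data, so fixtures exercise masking and metric building
end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariate_prep import CovariateSeries, build_metric_series
from .io_data import EncounterHistory, NestSite, TrapCountTable
from .mcmc import AnalysisDataset
from .survival_model import logistic

__all__ = [
    "InsectTruth",
    "SimulatedInsects",
    "NestTruth",
    "Fixture",
    "simulate_insects",
    "simulate_nests",
    "make_default_fixture",
    "fixture_dataset",
    "DEFAULT_TAXA",
]

DEFAULT_TAXA = ("simulium_annulus", "simulium_johannseni", "tabanidae", "culicidae")


@dataclass
class InsectTruth:
    """Per-taxon, per-year truth for trap log-intensities.

    The log intensity every trap follows is a taxon-specific seasonal
    curve — baseline ``alpha`` plus a Gaussian-shaped emergence peak
    (``peak_day``, ``peak_amp``, ``peak_width``), the rise-and-decline
    wave biting insects show every season — plus a *shared* AR(1)
    deviation (autocorrelation ``rho``, innovation precision ``tau``)
    common to all traps, plus independent per-trap AR(1) deviations with
    innovation SD ``trap_sd`` (spatial heterogeneity around the wave).
    Setting ``peak_amp = 0`` and ``trap_sd = 0`` reduces every trap to a
    single stationary AR(1) log-intensity.
    """

    alpha: dict
    rho: dict
    tau: dict
    peak_day: dict = field(default_factory=dict)
    peak_amp: dict = field(default_factory=dict)
    peak_width: dict = field(default_factory=dict)
    trap_sd: float = 0.35

    @classmethod
    def default(cls) -> "InsectTruth":
        # adults are absent outside each taxon's emergence window and rise
        # through an order-of-magnitude wave inside it (black flies in late
        # April, horse flies and mosquitoes later in the season)
        alpha = {
            "simulium_annulus": (-2.5, -2.7),
            "simulium_johannseni": (-2.7, -2.8),
            "tabanidae": (-2.8, -2.9),
            "culicidae": (-2.6, -2.8),
        }
        rho = {t: (0.8, 0.8) for t in alpha}
        tau = {t: (6.0, 6.0) for t in alpha}
        peak_day = {"simulium_annulus": 25, "simulium_johannseni": 33,
                    "tabanidae": 48, "culicidae": 62}
        peak_amp = {"simulium_annulus": 5.5, "simulium_johannseni": 4.6,
                    "tabanidae": 4.0, "culicidae": 4.8}
        peak_width = {"simulium_annulus": 8.0, "simulium_johannseni": 9.0,
                      "tabanidae": 11.0, "culicidae": 10.0}
        return cls(alpha, rho, tau, peak_day, peak_amp, peak_width)

    def seasonal_mean(self, taxon: str, year_index: int, n_days: int) -> np.ndarray:
        t = np.arange(1, n_days + 1, dtype=float)
        base = np.full(n_days, float(self.alpha[taxon][year_index]))
        amp = self.peak_amp.get(taxon, 0.0)
        if amp:
            base = base + amp * np.exp(
                -0.5 * ((t - self.peak_day[taxon]) / self.peak_width[taxon]) ** 2
            )
        return base

    def emergence_window(self, taxon: str, n_days: int, margin: float = 2.5):
        """Days with any adult activity: peak ± margin·width, clipped to the
        season; None for taxa without a seasonal peak (always active)."""
        amp = self.peak_amp.get(taxon, 0.0)
        if not amp:
            return None
        lo = max(1, int(np.floor(self.peak_day[taxon] - margin * self.peak_width[taxon])))
        hi = min(n_days, int(np.ceil(self.peak_day[taxon] + margin * self.peak_width[taxon])))
        return lo, hi


@dataclass
class SimulatedInsects:
    table: TrapCountTable            # activity-masked table (the observable)
    full_table: TrapCountTable       # every day sampled (generator truth)
    latent: dict                     # (taxon, year) -> (traps, days) log-intensity


def simulate_insects(
    rng: np.random.Generator,
    truth: InsectTruth | None = None,
    traps: dict | None = None,
    season_days: dict | None = None,
    sampled_days: dict | None = None,
    trap_dropout: float = 0.03,
) -> SimulatedInsects:
    """Simulate per-trap daily counts and mark unsampled days inactive.

    ``traps`` maps year -> list of (trap_id, x, y); ``sampled_days`` maps
    year -> array of sampled day indices (None = all days sampled);
    ``trap_dropout`` knocks out individual trap-days at random on sampled
    days (a trap blown over), exercising the reduced-trap weighting.
    """
    truth = truth or InsectTruth.default()
    season_days = season_days or {2009: 72, 2010: 75}
    if traps is None:
        grid = [(2.0, 2.0), (10.0, 2.0), (6.0, 6.0), (2.0, 10.0), (10.0, 10.0),
                (6.0, 1.0), (1.0, 6.0)]
        years = sorted(season_days)
        traps = {
            years[0]: [(f"T{k+1}", x, y) for k, (x, y) in enumerate(grid)],
            years[1]: [(f"T{k+1}", x, y) for k, (x, y) in enumerate(grid[:3])],
        }
    rows_masked = []
    rows_full = []
    latent = {}
    yrs = sorted(season_days)
    for year in yrs:
        T = season_days[year]
        yi = yrs.index(year)
        sampled = set(range(1, T + 1)) if sampled_days is None or sampled_days.get(year) is None \
            else set(int(d) for d in sampled_days[year])
        for taxon in truth.alpha:
            al = truth.alpha[taxon][yi]
            rho = truth.rho[taxon][yi]
            tau = truth.tau[taxon][yi]
            sd_innov = 1.0 / np.sqrt(tau)
            sd_stat = sd_innov / np.sqrt(1 - rho**2)
            ntr = len(traps[year])
            # seasonal mean curve plus a shared AR(1) deviation
            mu_t = truth.seasonal_mean(taxon, yi, T)
            u = np.zeros(T)
            u[0] = sd_stat * rng.standard_normal()
            for t in range(1, T):
                u[t] = rho * u[t - 1] + sd_innov * rng.standard_normal()
            m = mu_t + u
            # per-trap deviations around the wave
            e = np.zeros((ntr, T))
            if truth.trap_sd > 0:
                e_stat = truth.trap_sd / np.sqrt(1 - rho**2)
                e[:, 0] = e_stat * rng.standard_normal(ntr)
                for t in range(1, T):
                    e[:, t] = rho * e[:, t - 1] + truth.trap_sd * rng.standard_normal(ntr)
            x = m[None, :] + e
            counts = rng.poisson(np.exp(x))
            window = truth.emergence_window(taxon, T)
            if window is not None:
                # no adults outside the emergence window
                days_all = np.arange(1, T + 1)
                counts[:, (days_all < window[0]) | (days_all > window[1])] = 0
            latent[(taxon, year)] = x
            drop = rng.uniform(size=(ntr, T)) < trap_dropout
            for k, (tid, tx, ty) in enumerate(traps[year]):
                for t in range(T):
                    day = t + 1
                    active = day in sampled and not drop[k, t]
                    base = dict(trap_id=tid, x=tx, y=ty, year=year, day=day, taxon=taxon)
                    rows_full.append(dict(base, count=float(counts[k, t]), active=1))
                    rows_masked.append(
                        dict(base, count=float(counts[k, t]) if active else np.nan,
                             active=int(active))
                    )
    return SimulatedInsects(
        TrapCountTable(pd.DataFrame(rows_masked)),
        TrapCountTable(pd.DataFrame(rows_full)),
        latent,
    )


@dataclass
class NestTruth:
    """Generating survival-model parameters."""

    mu_pair: float = 3.7
    sigma_pair: float = 0.5
    beta_renest: float = 0.5
    effects: dict = field(default_factory=lambda: {"simulium_annulus:log_count": -0.7})


def simulate_nests(
    rng: np.random.Generator,
    pair_sites: list,                 # (pair_id, year, x, y)
    covariates: dict,                 # name -> (nest_index_lookup) see below
    truth: NestTruth,
    season_days: dict,
    init_window: tuple = (5, 20),
    renest_prob: float = 0.55,
    renest_cutoff: int = 35,
    renest_delay: tuple = (5, 8),
    gap_probs: tuple = (0.8, 0.12, 0.08),
    incubation_days: int = 30,
) -> tuple[list[EncounterHistory], list[NestSite]]:
    """Simulate nests, daily survival and an observation schedule.

    Each pair initiates a first nest inside ``init_window``; a failure on
    or before day ``renest_cutoff`` triggers one renesting attempt with
    probability ``renest_prob`` after a short delay, provided a full
    incubation still fits in the season.  Daily survival follows the
    logit-linear truth with the pair's random intercept and the covariate
    values supplied by ``covariates`` (a callable (name, x, y, year, day)
    -> value).  Checks are daily with occasional gaps of 2-3 days
    (probabilities ``gap_probs``); failures are recorded at the first
    check after death and successful nests are observed on hatch day.
    """
    histories: list[EncounterHistory] = []
    sites: list[NestSite] = []
    for pair_id, year, px, py in pair_sites:
        b0 = truth.mu_pair + truth.sigma_pair * rng.standard_normal()
        season = season_days[year]
        init = int(rng.integers(init_window[0], init_window[1] + 1))
        attempt = 0
        while True:
            attempt += 1
            nest_id = f"{pair_id}N{attempt}"
            nx = px + 0.2 * rng.standard_normal()
            ny = py + 0.2 * rng.standard_normal()
            renest = int(attempt > 1)
            eta_base = b0 + truth.beta_renest * renest
            hatch = init + incubation_days
            alive_until = hatch  # first day the nest is NOT alive, if it fails
            failed = False
            for t in range(init, hatch):  # transition t -> t+1 uses day t+1
                eta = eta_base
                for name, beta in truth.effects.items():
                    eta += beta * covariates(name, nx, ny, year, t + 1)
                if rng.uniform() >= logistic(eta):
                    alive_until = t + 1
                    failed = True
                    break
            # observation schedule
            days = [init]
            d = init
            end = min(alive_until if failed else hatch, season)
            while d < end:
                g = 1 + int(rng.choice(3, p=gap_probs))
                d = min(d + g, end)
                days.append(d)
            codes = []
            for d in days:
                if failed and d >= alive_until:
                    codes.append(0.0)
                else:
                    codes.append(1.0)
            # keep at most one trailing 0
            if failed and codes.count(0.0) == 0:
                pass  # nest failed past season end but never observed dead: censored
            histories.append(
                EncounterHistory(nest_id=nest_id, pair_id=pair_id, year=year,
                                 renest=renest, days=np.array(days), codes=np.array(codes))
            )
            sites.append(NestSite(nest_id, nx, ny))
            if (
                failed
                and attempt == 1
                and alive_until <= renest_cutoff
                and rng.uniform() < renest_prob
            ):
                delay = int(rng.integers(renest_delay[0], renest_delay[1] + 1))
                init = alive_until + delay
                if init + incubation_days <= season:
                    continue
            break
    return histories, sites


@dataclass
class Fixture:
    """A full synthetic dataset plus its generating truth."""

    histories: list
    sites: list
    traps: TrapCountTable
    full_traps: TrapCountTable
    insect_truth: InsectTruth
    nest_truth: NestTruth
    season_days: dict
    n_days: int
    emergence_windows: dict = field(default_factory=dict)
    true_series: list = field(default_factory=list)

    @property
    def truth(self) -> dict:
        return {
            "mu_pair": self.nest_truth.mu_pair,
            "sigma_pair": self.nest_truth.sigma_pair,
            "beta_renest": self.nest_truth.beta_renest,
            "effects": dict(self.nest_truth.effects),
        }


def make_default_fixture(
    seed: int,
    pairs_per_year: int = 12,
    sampled_days_override: dict | None = None,
    nest_truth: NestTruth | None = None,
) -> Fixture:
    """Paper-shaped synthetic dataset: two years, 12 pairs each (so ~17
    nests per year including renests), 7 traps in year one and 3 in year
    two, 4 taxa with a true ln-count effect of -0.7 for the first taxon
    and null effects otherwise; 50 of 72 days trapped in year one, 5 of
    75 in year two.  Deterministic given the seed."""
    rng = np.random.default_rng(seed)
    season_days = {2009: 72, 2010: 75}
    truth = InsectTruth.default()
    if sampled_days_override is not None:
        sampled = sampled_days_override
    else:
        sampled = {
            2009: np.sort(rng.choice(np.arange(1, 73), size=50, replace=False)),
            2010: np.sort(rng.choice(np.arange(1, 76), size=5, replace=False)),
        }
    ins = simulate_insects(rng, truth, season_days=season_days, sampled_days=sampled)
    nest_truth = nest_truth or NestTruth()

    # interpolate the *full* tables once to look up true covariate values
    full = ins.full_table.table
    cov_cache: dict = {}

    def covariates(name: str, x: float, y: float, year: int, day: int) -> float:
        taxon, metric = name.split(":")
        key = (taxon, year)
        if key not in cov_cache:
            t = full[(full["taxon"] == taxon) & (full["year"] == year) & (full["active"] == 1)]
            coords = t.groupby("trap_id")[["x", "y"]].first()
            T = season_days[year]
            cmat = np.full((len(coords), T), np.nan)
            ti = {tid: k for k, tid in enumerate(coords.index)}
            cmat[[ti[tid] for tid in t["trap_id"]], t["day"].to_numpy() - 1] = t["count"].to_numpy()
            cov_cache[key] = (coords.to_numpy(), cmat)
        xy, cmat = cov_cache[key]
        d2 = (xy[:, 0] - x) ** 2 + (xy[:, 1] - y) ** 2
        wgt = 1.0 / np.maximum(d2, 1e-6)
        c = float((wgt @ cmat[:, day - 1]) / wgt.sum())
        if metric == "log_count":
            return float(np.log1p(c))
        if metric == "presence":
            return float(c > 0)
        raise ValueError(f"truth effects support log_count/presence, got {metric}")

    pair_sites = []
    for year in sorted(season_days):
        for p in range(pairs_per_year):
            pair_sites.append(
                (f"P{year}_{p+1:03d}", year,
                 float(rng.uniform(1, 11)), float(rng.uniform(1, 11)))
            )
    histories, sites = simulate_nests(
        rng, pair_sites, covariates, nest_truth, season_days
    )
    windows = {}
    for year in sorted(season_days):
        for taxon in truth.alpha:
            w = truth.emergence_window(taxon, season_days[year])
            if w is not None:
                windows[(taxon, year)] = w
    return Fixture(
        histories=histories, sites=sites, traps=ins.table, full_traps=ins.full_table,
        insect_truth=truth, nest_truth=nest_truth, season_days=season_days,
        n_days=max(season_days.values()), emergence_windows=windows,
    )


def fixture_dataset(fix: Fixture, taxa: list | None = None) -> AnalysisDataset:
    """Build the fit-ready dataset from a fixture through the standard
    pipeline: fill known zeros outside the emergence windows, interpolate
    the masked trap table, construct the three metrics per taxon."""
    from .io_data import fill_known_zeros

    traps = fix.traps
    if fix.emergence_windows:
        traps = fill_known_zeros(traps, fix.emergence_windows, season_days=fix.season_days)
    nest_years = {h.nest_id: h.year for h in fix.histories}
    series = build_metric_series(
        traps, fix.sites, nest_years, fix.n_days,
        taxa=list(taxa) if taxa is not None else list(DEFAULT_TAXA),
    )
    return AnalysisDataset(histories=fix.histories, series=series, n_days=fix.n_days)
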