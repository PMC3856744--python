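"""Spatial interpolation of trap counts and construction of insect metrics.

Trap counts are carried to each nest with the inverse-distance-squared
interpolator: on day *t* the nest-specific index is

    I_{i,t} = ( sum_l c_{l,t} / d_{i,l}^2 ) / ( sum_l 1 / d_{i,l}^2 )

over the traps active on day *t*; days with no active trap are missing.
Three per-taxon metrics are then built: ln(count + 1), a presence indicator
(interpolated count > 0), and an indicator for counts exceeding the 90%
quantile of all pooled observed interpolated counts for the taxon.
Covariates enter the survival model unstandardized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_data import NestSite, TrapCountTable, ValidationError

__all__ = [
    "CovariateSeries",
    "interpolate_counts",
    "make_log_count",
    "make_presence",
    "make_q90",
    "build_metric_series",
    "METRICS",
]

METRICS = ("log_count", "presence", "q90")


@dataclass
class CovariateSeries:
    """Nest × day covariate values for one (taxon, metric).

    ``values[i, t-1]`` is the metric for nest ``nest_ids[i]`` on day ``t``
    (1-based days of season); ``observed[i, t-1]`` marks entries derived from
    actual trapping, everything else is latent and to be imputed by the
    model.  ``presence`` and ``q90`` values are binary where observed.
    """

    taxon: str
    metric: str
    nest_ids: list[str]
    values: np.ndarray
    observed: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.metric not in METRICS:
            raise ValidationError(f"unknown metric {self.metric!r}")
        if self.values.shape != self.observed.shape or self.values.ndim != 2:
            raise ValidationError("values and observed must be matching nest × day matrices")
        if len(self.nest_ids) != self.values.shape[0]:
            raise ValidationError("one row per nest required")
        obs = self.values[self.observed]
        if self.metric == "log_count" and not self.meta.get("standardized") and np.any(obs < 0):
            raise ValidationError("log_count values must be nonnegative where observed")
        if self.metric in ("presence", "q90") and not np.isin(obs, (0.0, 1.0)).all():
            raise ValidationError(f"{self.metric} values must be binary where observed")

    @property
    def n_days(self) -> int:
        return self.values.shape[1]

    @property
    def name(self) -> str:
        return f"{self.taxon}:{self.metric}"


def interpolate_counts(
    counts: TrapCountTable,
    sites: list[NestSite],
    taxon: str,
    nest_years: dict[str, int],
    n_days: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-distance-squared interpolation of trap counts to nests.

    Returns ``(values, observed)`` of shape (n_nests, n_days): for each nest
    and day with at least one active trap in the nest's year, the weighted
    mean of that day's counts with weights 1/d²; other days are missing.
    A nest located exactly at a trap is rejected — offset the nest by a
    minimum distance (e.g. half the trap spacing) before interpolating.
    """
    t = counts.table
    t = t[(t["taxon"] == taxon) & (t["active"] == 1)]
    n = len(sites)
    values = np.full((n, n_days), np.nan)
    observed = np.zeros((n, n_days), dtype=bool)
    for year, ty in t.groupby("year"):
        idx = [i for i, s in enumerate(sites) if nest_years[s.nest_id] == year]
        if not idx:
            continue
        coords = ty.groupby("trap_id")[["x", "y"]].first()
        trap_ids = list(coords.index)
        xy = coords.to_numpy()
        nest_xy = np.array([[sites[i].x, sites[i].y] for i in idx])
        d = np.hypot(
            nest_xy[:, None, 0] - xy[None, :, 0], nest_xy[:, None, 1] - xy[None, :, 1]
        )  # (nests, traps)
        if np.any(d == 0):
            i, l = np.argwhere(d == 0)[0]
            raise ValidationError(
                f"nest {sites[idx[i]].nest_id!r} coincides with trap {trap_ids[l]!r} "
                "(distance 0); apply a minimum-distance offset to the nest coordinates"
            )
        w = 1.0 / d**2
        # count matrix (traps, days) with NaN where inactive
        cmat = np.full((len(trap_ids), n_days), np.nan)
        ti = {tid: k for k, tid in enumerate(trap_ids)}
        days = ty["day"].to_numpy()
        if days.max() > n_days:
            raise ValidationError(f"trap day {days.max()} beyond n_days={n_days}")
        cmat[[ti[tid] for tid in ty["trap_id"]], days - 1] = ty["count"].to_numpy()
        act = ~np.isnan(cmat)
        any_active = act.any(axis=0)
        wa = w[:, :, None] * act[None, :, :]  # (nests, traps, days)
        num = np.nansum(w[:, :, None] * np.where(act, cmat, 0.0)[None, :, :], axis=1)
        den = wa.sum(axis=1)
        vals = np.where(any_active[None, :], num / np.where(den > 0, den, 1.0), np.nan)
        values[idx, :] = vals
        observed[idx, :] = any_active[None, :]
    return values, observed


def make_log_count(values, observed, taxon: str, nest_ids: list[str]) -> CovariateSeries:
    """ln(count + 1) transform of interpolated counts; mask unchanged."""
    values = np.asarray(values, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    if np.any(values[observed] < 0):
        raise ValidationError("negative interpolated count")
    out = np.full_like(values, np.nan)
    out[observed] = np.log1p(values[observed])
    return CovariateSeries(taxon, "log_count", nest_ids, out, observed)


def make_presence(values, observed, taxon: str, nest_ids: list[str]) -> CovariateSeries:
    """Presence indicator: 1 where the interpolated count is strictly > 0."""
    values = np.asarray(values, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    out = np.full_like(values, np.nan)
    out[observed] = (values[observed] > 0).astype(float)
    return CovariateSeries(taxon, "presence", nest_ids, out, observed)


def make_q90(
    values,
    observed,
    taxon: str,
    nest_ids: list[str],
    q: float = 0.9,
    method: str = "linear",
) -> CovariateSeries:
    """Indicator for counts strictly exceeding the pooled 90% quantile.

    The threshold is the ``q`` quantile (default 0.9, linear interpolation
    between order statistics) of *all* observed interpolated counts pooled
    over nests and days for the taxon; exceedance is strict, so a value
    exactly at the threshold codes 0.
    """
    values = np.asarray(values, dtype=float)
    observed = np.asarray(observed, dtype=bool)
    pooled = values[observed]
    if pooled.size < 10:
        raise ValidationError(
            f"only {pooled.size} observed values; >=10 required for a stable quantile"
        )
    threshold = float(np.quantile(pooled, q, method=method))
    out = np.full_like(values, np.nan)
    out[observed] = (values[observed] > threshold).astype(float)
    return CovariateSeries(taxon, "q90", nest_ids, out, observed,
                           meta={"threshold": threshold, "q": q})


def build_metric_series(
    counts: TrapCountTable,
    sites: list[NestSite],
    nest_years: dict[str, int],
    n_days: int,
    taxa: list[str] | None = None,
    standardize: bool = False,
) -> list[CovariateSeries]:
    """Interpolate every taxon and build the three metrics for each.

    Returns series ordered taxon-major, metric-minor (log_count, presence,
    q90), the candidate-variable ordering used by the selection machinery.
    ``standardize=True`` centres and scales each ln-count series by its
    observed mean and SD (binary metrics are left alone); the default keeps
    the natural per-unit-ln-count effect scale.
    """
    nest_ids = [s.nest_id for s in sites]
    out: list[CovariateSeries] = []
    for taxon in taxa if taxa is not None else counts.taxa:
        vals, obs = interpolate_counts(counts, sites, taxon, nest_years, n_days)
        lc = make_log_count(vals, obs, taxon, nest_ids)
        if standardize:
            ov = lc.values[lc.observed]
            mu, sd = float(ov.mean()), float(ov.std()) or 1.0
            scaled = np.where(lc.observed, (lc.values - mu) / sd, np.nan)
            lc = CovariateSeries(taxon, "log_count", nest_ids, scaled, obs,
                                 meta={"standardized": True, "center": mu, "scale": sd})
        out.append(lc)
        out.append(make_presence(vals, obs, taxon, nest_ids))
        out.append(make_q90(vals, obs, taxon, nest_ids))
    return out
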