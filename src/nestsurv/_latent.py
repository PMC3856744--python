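"""Latent-covariate bookkeeping for the Gibbs sampler.

Each (taxon, metric) series is laid out on a reduced per-nest day grid:
the days with actual trap data plus the days the nest's survival
transitions consume.  Days outside both sets are marginalized out of the
Markov covariate models exactly, via k-step transition densities between
consecutive grid points (see covariate_models.ar1_kstep /
occupancy_kstep), so the sampler never touches them.  Sufficient
statistics for the parameter updates are accumulated per step length k,
which keeps every full-conditional evaluation O(k_max) instead of O(data).
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .covariate_models import AR1Params, OccupancyParams, stationary_occupancy
from .covariate_prep import CovariateSeries
from .survival_model import PriorConfig, SurvivalDesign

__all__ = ["AR1Block", "OccupancyBlock", "build_blocks"]


class _GridBlock:
    """Shared reduced-grid layout for one metric."""

    def __init__(self, series: CovariateSeries, design: SurvivalDesign):
        vals = np.asarray(series.values, dtype=float)
        obs = np.asarray(series.observed, dtype=bool)
        n, T = vals.shape
        if n != design.n or T != design.n_days:
            raise ValueError(f"series {series.name} misaligned with the nest design")
        self.name = series.name
        self.n_years = len(design.years)
        self.nest_year = design.year_index.astype(np.int64)
        # days each nest's transitions consume (1-based)
        need: list[set[int]] = [set() for _ in range(n)]
        for i, c in zip(design.trans_nest, design.cov_col):
            need[int(i)].add(int(c) + 1)
        days_l, obs_l, vals_l, act_l = [], [], [], []
        offsets = [0]
        trans_pos = np.full((n, T), -1, dtype=np.int64)
        trans_pos[design.trans_nest, design.cov_col] = np.arange(design.n_trans)
        for i in range(n):
            obs_days = set((np.flatnonzero(obs[i]) + 1).tolist())
            grid = sorted(obs_days | need[i])
            for d in grid:
                days_l.append(d)
                o = d in obs_days
                obs_l.append(o)
                vals_l.append(vals[i, d - 1] if o else np.nan)
                act_l.append(trans_pos[i, d - 1])
            offsets.append(len(days_l))
        self.days = np.asarray(days_l, dtype=np.int64)
        self.obs = np.asarray(obs_l, dtype=np.bool_)
        self.values = np.asarray(vals_l, dtype=float)
        self.act_ptr = np.asarray(act_l, dtype=np.int64)
        self.offsets = np.asarray(offsets, dtype=np.int64)
        self.n_latent = int((~self.obs).sum())
        # transition-pair index arrays (within-nest consecutive grid points)
        prev, cur = [], []
        first = []
        for i in range(n):
            lo, hi = self.offsets[i], self.offsets[i + 1]
            if hi > lo:
                first.append(lo)
                prev.extend(range(lo, hi - 1))
                cur.extend(range(lo + 1, hi))
        self.first_idx = np.asarray(first, dtype=np.int64)
        self.prev_idx = np.asarray(prev, dtype=np.int64)
        self.cur_idx = np.asarray(cur, dtype=np.int64)
        self.k = self.days[self.cur_idx] - self.days[self.prev_idx]
        self.kmax = int(self.k.max()) if self.k.size else 1
        nest_of_point = np.repeat(np.arange(n), np.diff(self.offsets))
        self.nest_of_point = nest_of_point
        self.year_of_trans = self.nest_year[nest_of_point[self.cur_idx]]
        self.year_of_first = self.nest_year[nest_of_point[self.first_idx]]
        self._key = self.year_of_trans * (self.kmax + 1) + self.k
        self._klen = self.n_years * (self.kmax + 1)
        # latent-site sweep arrays (fixed order)
        self.lat_idx = np.flatnonzero(~self.obs).astype(np.int64)
        li = self.lat_idx
        self.lat_prev = li > self.offsets[nest_of_point[li]]
        self.lat_next = li < self.offsets[nest_of_point[li] + 1] - 1
        self.lat_year = self.nest_year[nest_of_point[li]]

    # -- helpers -----------------------------------------------------------
    def _per_k(self, weights=None):
        return np.bincount(self._key, weights=weights, minlength=self._klen).reshape(
            self.n_years, self.kmax + 1
        )

    def fill_zact(self, zact_row: np.ndarray) -> None:
        has = self.act_ptr >= 0
        zact_row[self.act_ptr[has]] = self.values[has]

    def full_matrix(self, n: int, T: int) -> np.ndarray:
        """Scatter current grid values back to a nest × day matrix (NaN off-grid)."""
        out = np.full((n, T), np.nan)
        out[self.nest_of_point, self.days - 1] = self.values
        return out


class AR1Block(_GridBlock):
    """ln(count+1) metric with a year-specific Gaussian AR(1) process."""

    kind = "ar1"

    def __init__(self, series: CovariateSeries, design: SurvivalDesign):
        super().__init__(series, design)
        self.params = AR1Params(
            alpha=np.zeros(self.n_years), rho=np.zeros(self.n_years),
            tau=np.ones(self.n_years),
        )
        self.rho_step = np.full(self.n_years, 0.15)

    def initialize(self, rng: np.random.Generator) -> None:
        for y in range(self.n_years):
            nests = np.flatnonzero(self.nest_year == y)
            sel = np.concatenate(
                [np.arange(self.offsets[i], self.offsets[i + 1]) for i in nests]
            ) if nests.size else np.zeros(0, dtype=int)
            ov = self.values[sel][self.obs[sel]] if sel.size else np.zeros(0)
            mean = float(ov.mean()) if ov.size else 0.0
            var = float(ov.var()) if ov.size > 5 else 1.0
            self.params.alpha[y] = mean
            self.params.rho[y] = 0.0
            self.params.tau[y] = 1.0 / max(var, 1e-3)
            miss = sel[~self.obs[sel]] if sel.size else sel
            self.values[miss] = mean

    def impute(self, wbeta, eta, trans_gap, gap_ptr, gapG, zact_row, rng) -> None:
        p = self.params
        rho_pow = np.power(p.rho[:, None], np.arange(self.kmax + 1)[None, :])
        svar = 1.0 / (p.tau * (1.0 - p.rho**2))
        nl = self.n_latent
        _kernels.ar1_impute_metric(
            self.values, self.days, self.act_ptr,
            self.lat_idx, self.lat_prev, self.lat_next, self.lat_year,
            p.alpha, svar, rho_pow, float(wbeta),
            eta, trans_gap, gapG, zact_row,
            rng.standard_normal(nl), np.log(rng.uniform(size=nl)),
        )

    def _stats(self):
        v = self.values
        table = _kernels.ar1_stats(v, self.prev_idx, self.cur_idx, self._key, self._klen)
        shape = (self.n_years, self.kmax + 1)
        nk, svj, svp, svj2, svp2, scross = (row.reshape(shape) for row in table)
        yf = self.year_of_first
        n1 = np.bincount(yf, minlength=self.n_years).astype(float)
        s1 = np.bincount(yf, weights=v[self.first_idx], minlength=self.n_years)
        s12 = np.bincount(yf, weights=v[self.first_idx] ** 2, minlength=self.n_years)
        return nk, svj, svp, svj2, svp2, scross, n1, s1, s12

    def update_params(self, rng: np.random.Generator, priors: PriorConfig, adapt=False) -> None:
        """Gibbs draws of (alpha, tau) and a reflecting-walk step on rho,
        all from per-step-length sufficient statistics (exact)."""
        nk, svj, svp, svj2, svp2, scross, n1, s1, s12 = self._stats()
        p = self.params
        ks = np.arange(self.kmax + 1)
        for y in range(self.n_years):
            sel = nk[y] > 0
            k = ks[sel]
            n_k, vj, vp = nk[y, sel], svj[y, sel], svp[y, sel]
            vj2, vp2, cross = svj2[y, sel], svp2[y, sel], scross[y, sel]
            ntot = n_k.sum() + n1[y]
            if ntot == 0:
                p.alpha[y] = rng.normal(0, np.sqrt(priors.normal_var))
                p.tau[y] = rng.gamma(priors.gamma_shape, 1.0 / priors.gamma_rate)
                p.rho[y] = _reflect(p.rho[y] + self.rho_step[y] * rng.standard_normal())
                continue
            r = p.rho[y]
            a = np.power(r, k)
            c = (1.0 - r**2) / (1.0 - a**2)        # precision multiplier / tau
            # alpha | rho, tau
            prec = 1.0 / priors.normal_var + p.tau[y] * (
                (1 - r**2) * n1[y] + (c * (1 - a) ** 2 * n_k).sum()
            )
            lin = p.tau[y] * ((1 - r**2) * s1[y] + (c * (1 - a) * (vj - a * vp)).sum())
            p.alpha[y] = lin / prec + rng.standard_normal() / np.sqrt(prec)
            al = p.alpha[y]

            def ssq(r_, a_, c_):
                res = (
                    vj2 - 2 * a_ * cross + a_**2 * vp2
                    - 2 * al * (1 - a_) * (vj - a_ * vp)
                    + n_k * al**2 * (1 - a_) ** 2
                )
                first = s12[y] - 2 * al * s1[y] + n1[y] * al**2
                return (1 - r_**2) * first + (c_ * res).sum()

            # tau | alpha, rho
            p.tau[y] = rng.gamma(
                priors.gamma_shape + 0.5 * ntot,
                1.0 / (priors.gamma_rate + 0.5 * ssq(r, a, c)),
            )

            # rho | alpha, tau (reflecting random-walk Metropolis)
            def logtarget(r_):
                a_ = np.power(r_, k)
                c_ = (1.0 - r_**2) / (1.0 - a_**2)
                norm = 0.5 * n1[y] * np.log1p(-r_**2) + 0.5 * (n_k * np.log(c_)).sum()
                return norm - 0.5 * p.tau[y] * ssq(r_, a_, c_)

            prop = _reflect(r + self.rho_step[y] * rng.standard_normal())
            acc = np.log(rng.uniform()) < logtarget(prop) - logtarget(r)
            if acc:
                p.rho[y] = prop
            if adapt:
                self.rho_step[y] *= np.exp(0.05 * ((1.0 if acc else 0.0) - 0.44))

    def chain_loglik(self) -> float:
        """Current complete-data log density of the block (diagnostics)."""
        p, v = self.params, self.values
        a = np.power(p.rho[self.year_of_trans], self.k)
        var = (1 - a**2) / (p.tau[self.year_of_trans] * (1 - p.rho[self.year_of_trans] ** 2))
        al = p.alpha[self.year_of_trans]
        resid = v[self.cur_idx] - al - a * (v[self.prev_idx] - al)
        ll = -0.5 * (np.log(2 * np.pi * var) + resid**2 / var).sum()
        sv = 1.0 / (p.tau[self.year_of_first] * (1 - p.rho[self.year_of_first] ** 2))
        d1 = v[self.first_idx] - p.alpha[self.year_of_first]
        ll += -0.5 * (np.log(2 * np.pi * sv) + d1**2 / sv).sum()
        return float(ll)


def _reflect(x):
    while x <= -1.0 or x >= 1.0:
        if x >= 1.0:
            x = 2.0 - x
        if x <= -1.0:
            x = -2.0 - x
    return x


class OccupancyBlock(_GridBlock):
    """Binary metric (presence or >q90) with dynamic-occupancy dynamics."""

    kind = "occupancy"

    def __init__(self, series: CovariateSeries, design: SurvivalDesign):
        super().__init__(series, design)
        self.params = OccupancyParams(
            phi=np.full(self.n_years, 0.5), gamma=np.full(self.n_years, 0.5)
        )
        self.step = np.full(self.n_years, 0.4)

    def initialize(self, rng: np.random.Generator) -> None:
        for y in range(self.n_years):
            nests = np.flatnonzero(self.nest_year == y)
            sel = np.concatenate(
                [np.arange(self.offsets[i], self.offsets[i + 1]) for i in nests]
            ) if nests.size else np.zeros(0, dtype=int)
            ov = self.values[sel][self.obs[sel]] if sel.size else np.zeros(0)
            freq = float(ov.mean()) if ov.size else 0.5
            freq = min(max(freq, 0.05), 0.95)
            self.params.phi[y] = freq
            self.params.gamma[y] = freq
            miss = sel[~self.obs[sel]] if sel.size else sel
            self.values[miss] = (rng.uniform(size=miss.size) < freq).astype(float)

    def impute(self, wbeta, eta, trans_gap, gap_ptr, gapG, zact_row, rng) -> None:
        p = self.params
        lam_pow = np.power((p.phi - p.gamma)[:, None], np.arange(self.kmax + 1)[None, :])
        psi = stationary_occupancy(p.phi, p.gamma)
        p11 = np.clip(psi[:, None] + (1 - psi[:, None]) * lam_pow, 1e-12, 1 - 1e-12)
        p01 = np.clip(psi[:, None] * (1 - lam_pow), 1e-12, 1 - 1e-12)
        _kernels.occ_impute_metric(
            self.values, self.days, self.act_ptr,
            self.lat_idx, self.lat_prev, self.lat_next, self.lat_year,
            np.log(psi), np.log1p(-psi),
            np.log(p11), np.log1p(-p11), np.log(p01), np.log1p(-p01),
            float(wbeta),
            eta, trans_gap, gapG, zact_row,
            rng.uniform(size=self.n_latent),
        )

    def _tables(self):
        v = self.values
        raw = _kernels.occ_counts(v, self.prev_idx, self.cur_idx, self._key, self._klen)
        # raw rows are (prev*2 + cur); rearrange to [year, k, prev, cur]
        counts = raw.reshape(2, 2, self.n_years, self.kmax + 1).transpose(2, 3, 0, 1)
        f1 = np.bincount(self.year_of_first, weights=v[self.first_idx], minlength=self.n_years)
        ntot = np.bincount(self.year_of_first, minlength=self.n_years).astype(float)
        return counts, f1, ntot - f1

    def update_params(self, rng: np.random.Generator, priors: PriorConfig, adapt=False) -> None:
        """Joint logit-scale Metropolis on (phi, gamma) per year from the
        k-step transition-count tables under Uniform(0,1) priors."""
        counts, f1, f0 = self._tables()
        ks = np.arange(self.kmax + 1)
        p = self.params
        for y in range(self.n_years):
            ck = counts[y]
            present = ck.sum(axis=(1, 2)) > 0
            k = ks[present]
            c = ck[present]

            def logtarget(lphi, lgam):
                phi = 1.0 / (1.0 + np.exp(-lphi))
                gam = 1.0 / (1.0 + np.exp(-lgam))
                psi = gam / (gam + 1 - phi)
                lamk = np.power(phi - gam, k)
                p11 = psi + (1 - psi) * lamk
                p01 = psi * (1 - lamk)
                eps = 1e-12
                ll = (
                    c[:, 1, 1] * np.log(p11 + eps) + c[:, 1, 0] * np.log(1 - p11 + eps)
                    + c[:, 0, 1] * np.log(p01 + eps) + c[:, 0, 0] * np.log(1 - p01 + eps)
                ).sum()
                ll += f1[y] * np.log(psi) + f0[y] * np.log1p(-psi)
                # Jacobian of the logit transform (Uniform(0,1) priors)
                ll += np.log(phi * (1 - phi)) + np.log(gam * (1 - gam))
                return ll

            lphi = np.log(p.phi[y]) - np.log1p(-p.phi[y])
            lgam = np.log(p.gamma[y]) - np.log1p(-p.gamma[y])
            s = self.step[y]
            lphi_p = lphi + s * rng.standard_normal()
            lgam_p = lgam + s * rng.standard_normal()
            acc = np.log(rng.uniform()) < logtarget(lphi_p, lgam_p) - logtarget(lphi, lgam)
            if acc:
                p.phi[y] = 1.0 / (1.0 + np.exp(-lphi_p))
                p.gamma[y] = 1.0 / (1.0 + np.exp(-lgam_p))
            if adapt:
                self.step[y] *= np.exp(0.05 * ((1.0 if acc else 0.0) - 0.3))

    def chain_loglik(self) -> float:
        counts, f1, f0 = self._tables()
        p = self.params
        ll = 0.0
        ks = np.arange(self.kmax + 1)
        for y in range(self.n_years):
            phi, gam = p.phi[y], p.gamma[y]
            psi = gam / (gam + 1 - phi)
            lamk = np.power(phi - gam, ks)
            p11 = psi + (1 - psi) * lamk
            p01 = psi * (1 - lamk)
            eps = 1e-12
            c = counts[y]
            ll += (
                c[:, 1, 1] * np.log(p11 + eps) + c[:, 1, 0] * np.log(1 - p11 + eps)
                + c[:, 0, 1] * np.log(p01 + eps) + c[:, 0, 0] * np.log(1 - p01 + eps)
            ).sum()
            ll += f1[y] * np.log(psi) + f0[y] * np.log1p(-psi)
        return float(ll)


def build_blocks(series_list: list[CovariateSeries], design: SurvivalDesign):
    """One latent block per covariate series, AR(1) for log_count metrics
    and dynamic occupancy for the binary ones."""
    blocks = []
    for s in series_list:
        if s.metric == "log_count":
            blocks.append(AR1Block(s, design))
        else:
            blocks.append(OccupancyBlock(s, design))
    return blocks
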