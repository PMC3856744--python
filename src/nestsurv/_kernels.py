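"""Compiled inner loops of the Metropolis-within-Gibbs sweep.

The survival likelihood is evaluated on a flattened transition layout: the
first ``n_alive`` entries of ``eta`` are transitions whose destination state
is certainly alive (each contributes log S); the remainder are terminal
death-gap transitions grouped contiguously per gap, where a gap whose
transitions have survival probabilities S_1..S_g contributes
log(1 - prod S) — the failure day is marginalized analytically, which
telescopes to one minus the probability of surviving the whole gap.

Latent covariate days live on reduced per-nest grids (observed trapping
days plus the nest's survival-relevant days); consecutive grid points k
days apart are tied by exact k-step transition densities.  The imputation
kernels update latent sites one at a time in a fixed sweep order: a pure
chain draw where the site feeds no observed survival transition, and a
Metropolis step proposing from the chain conditional (so the acceptance
ratio is the survival-likelihood ratio alone) where it does.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NOPT = dict(cache=True, fastmath=True)


@njit(inline="always", **_NOPT)
def _logsig(x):
    """log of the logistic function, numerically safe."""
    if x >= 0.0:
        return -np.log1p(np.exp(-x))
    return x - np.log1p(np.exp(x))


@njit(inline="always", **_NOPT)
def _log1mexp(x):
    """log(1 - exp(x)) for x < 0."""
    if x > -0.6931471805599453:
        return np.log(-np.expm1(x))
    return np.log1p(-np.exp(x))


@njit(**_NOPT)
def survival_ll(eta, n_alive, gap_ptr):
    """Survival log likelihood from the flattened transition layout."""
    ll = 0.0
    for j in range(n_alive):
        ll += _logsig(eta[j])
    for g in range(gap_ptr.size - 1):
        G = 0.0
        for j in range(n_alive + gap_ptr[g], n_alive + gap_ptr[g + 1]):
            G += _logsig(eta[j])
        ll += _log1mexp(G)
    return ll


@njit(**_NOPT)
def survival_ll_terms(eta, n_alive, gap_ptr, out):
    """Per-transition contributions; a gap's term sits on its first entry."""
    for j in range(n_alive):
        out[j] = _logsig(eta[j])
    for g in range(gap_ptr.size - 1):
        lo = n_alive + gap_ptr[g]
        hi = n_alive + gap_ptr[g + 1]
        G = 0.0
        for j in range(lo, hi):
            G += _logsig(eta[j])
            out[j] = 0.0
        out[lo] = _log1mexp(G)
    return out


@njit(**_NOPT)
def gap_logsums(eta, n_alive, gap_ptr, out):
    """Current sum of log S over each death gap (for incremental updates)."""
    for g in range(gap_ptr.size - 1):
        G = 0.0
        for j in range(n_alive + gap_ptr[g], n_alive + gap_ptr[g + 1]):
            G += _logsig(eta[j])
        out[g] = G
    return out


@njit(**_NOPT)
def ar1_impute_metric(
    values,      # flat covariate values over all nests' grids (mutated)
    days,        # 1-based day of season per grid point
    act_ptr,     # transition index fed by this point, -1 if none
    lat_idx,     # flat indices of latent (unobserved) points, sweep order
    lat_prev,    # has a left neighbour within the nest's grid
    lat_next,    # has a right neighbour
    lat_year,    # year index per latent point
    alpha,       # (Y,) AR(1) mean per year
    svar,        # (Y,) stationary variance per year
    rho_pow,     # (Y, kmax+1) table of rho^k per year
    wbeta,       # w_m * beta_m, survival effect of this metric
    eta,         # flattened transition logits (mutated on accept)
    trans_gap,   # gap index per transition, -1 = certain-alive transition
    gapG,        # per-gap running sum of log S (mutated)
    zact,        # this metric's value at each transition (mutated)
    randn,       # pre-drawn standard normals, one per latent site
    logu,        # pre-drawn log uniforms, one per latent site
):
    for r in range(lat_idx.size):
        j = lat_idx[r]
        y = lat_year[r]
        al = alpha[y]
        sv = svar[y]
        if lat_prev[r]:
            k1 = days[j] - days[j - 1]
            a1 = rho_pow[y, k1]
            v1 = sv * (1.0 - a1 * a1)
            p = 1.0 / v1
            num = a1 * (values[j - 1] - al) / v1
        else:
            p = 1.0 / sv
            num = 0.0
        if lat_next[r]:
            k2 = days[j + 1] - days[j]
            a2 = rho_pow[y, k2]
            v2 = sv * (1.0 - a2 * a2)
            p += a2 * a2 / v2
            num += a2 * (values[j + 1] - al) / v2
        prop = al + num / p + randn[r] / np.sqrt(p)
        a = act_ptr[j]
        if a < 0 or wbeta == 0.0:
            values[j] = prop
            if a >= 0:
                zact[a] = prop
        else:
            deta = wbeta * (prop - values[j])
            enew = eta[a] + deta
            g = trans_gap[a]
            if g < 0:
                lr = _logsig(enew) - _logsig(eta[a])
                if logu[r] < lr:
                    values[j] = prop
                    eta[a] = enew
                    zact[a] = prop
            else:
                lsold = _logsig(eta[a])
                lsnew = _logsig(enew)
                Gnew = gapG[g] - lsold + lsnew
                lr = _log1mexp(Gnew) - _log1mexp(gapG[g])
                if logu[r] < lr:
                    values[j] = prop
                    eta[a] = enew
                    zact[a] = prop
                    gapG[g] = Gnew
    return lat_idx.size


@njit(**_NOPT)
def occ_impute_metric(
    values,
    days,
    act_ptr,
    lat_idx,
    lat_prev,
    lat_next,
    lat_year,
    lpsi1,       # (Y,) log psi
    lpsi0,       # (Y,) log(1 - psi)
    lp11,        # (Y, kmax+1) log p11(k)
    lq11,        # (Y, kmax+1) log(1 - p11(k))
    lp01,        # (Y, kmax+1) log p01(k)
    lq01,        # (Y, kmax+1) log(1 - p01(k))
    wbeta,
    eta,
    trans_gap,
    gapG,
    zact,
    u,           # pre-drawn uniforms, one per latent site
):
    for r in range(lat_idx.size):
        j = lat_idx[r]
        y = lat_year[r]
        if lat_prev[r]:
            k1 = days[j] - days[j - 1]
            if values[j - 1] == 1.0:
                l1 = lp11[y, k1]
                l0 = lq11[y, k1]
            else:
                l1 = lp01[y, k1]
                l0 = lq01[y, k1]
        else:
            l1 = lpsi1[y]
            l0 = lpsi0[y]
        if lat_next[r]:
            k2 = days[j + 1] - days[j]
            if values[j + 1] == 1.0:
                l1 += lp11[y, k2]
                l0 += lp01[y, k2]
            else:
                l1 += lq11[y, k2]
                l0 += lq01[y, k2]
        a = act_ptr[j]
        use_surv = a >= 0 and wbeta != 0.0
        e1 = 0.0
        e0 = 0.0
        G1 = 0.0
        G0 = 0.0
        g = -1
        if use_surv:
            zj = values[j]
            e1 = eta[a] + wbeta * (1.0 - zj)
            e0 = eta[a] - wbeta * zj
            g = trans_gap[a]
            if g < 0:
                l1 += _logsig(e1)
                l0 += _logsig(e0)
            else:
                lsold = _logsig(eta[a])
                G1 = gapG[g] - lsold + _logsig(e1)
                G0 = gapG[g] - lsold + _logsig(e0)
                l1 += _log1mexp(G1)
                l0 += _log1mexp(G0)
        p1 = 1.0 / (1.0 + np.exp(l0 - l1))
        new = 1.0 if u[r] < p1 else 0.0
        if new != values[j]:
            values[j] = new
            if a >= 0:
                zact[a] = new
                if use_surv:
                    eta[a] = e1 if new == 1.0 else e0
                    if g >= 0:
                        gapG[g] = G1 if new == 1.0 else G0
    return lat_idx.size


@njit(**_NOPT)
def elementwise_logsig(eta, out):
    """Per-transition log S cache used by the incremental delta updates."""
    for j in range(eta.size):
        out[j] = _logsig(eta[j])


@njit(**_NOPT)
def propose_delta(eta, terms, gapG, n_alive, gap_ptr, z, d, cand, gnew):
    """Log-likelihood change of the shift eta -> eta + d*z.

    Transitions with z == 0 are untouched, so only the nonzero entries are
    revisited against the cached per-transition log S values in ``terms``.
    Candidate terms land in ``cand`` and candidate per-gap log-S sums in
    ``gnew`` so an accepted move can be applied without recomputation.
    """
    dll = 0.0
    for j in range(n_alive):
        if z[j] != 0.0:
            c = _logsig(eta[j] + d * z[j])
            cand[j] = c
            dll += c - terms[j]
    for g in range(gap_ptr.size - 1):
        G = gapG[g]
        changed = False
        for j in range(n_alive + gap_ptr[g], n_alive + gap_ptr[g + 1]):
            if z[j] != 0.0:
                c = _logsig(eta[j] + d * z[j])
                cand[j] = c
                G += c - terms[j]
                changed = True
        gnew[g] = G
        if changed:
            dll += _log1mexp(G) - _log1mexp(gapG[g])
    return dll


@njit(**_NOPT)
def apply_delta(eta, terms, gapG, z, d, cand, gnew):
    """Commit a proposed shift: update eta, the log-S cache and gap sums."""
    for j in range(eta.size):
        if z[j] != 0.0:
            eta[j] += d * z[j]
            terms[j] = cand[j]
    for g in range(gapG.size):
        gapG[g] = gnew[g]


@njit(**_NOPT)
def ar1_stats(values, prev_idx, cur_idx, key, klen):
    """Per (year, step-length) sufficient statistics of the AR(1) pairs:
    count, sum v_t, sum v_{t-k}, sum v_t^2, sum v_{t-k}^2, cross sum."""
    out = np.zeros((6, klen))
    for i in range(prev_idx.size):
        k = key[i]
        vp = values[prev_idx[i]]
        vj = values[cur_idx[i]]
        out[0, k] += 1.0
        out[1, k] += vj
        out[2, k] += vp
        out[3, k] += vj * vj
        out[4, k] += vp * vp
        out[5, k] += vj * vp
    return out


@njit(**_NOPT)
def occ_counts(values, prev_idx, cur_idx, key, klen):
    """Per (year, step-length) transition counts n00, n01, n10, n11."""
    out = np.zeros((4, klen))
    for i in range(prev_idx.size):
        k = key[i]
        c = 0
        if values[prev_idx[i]] == 1.0:
            c += 2
        if values[cur_idx[i]] == 1.0:
            c += 1
        out[c, k] += 1.0
    return out


@njit(**_NOPT)
def pair_block_update(
    eta, n_alive, gap_ptr, pair_of_trans, b0, mu, sig2, prop_step, randn, logu, accepted
):
    """Metropolis update of all pair intercepts in one pass.

    Each pair's intercept shifts only its own transitions, so per-pair
    log-likelihood deltas are accumulated in a single sweep over the
    transitions and every pair then accepts or rejects independently
    against its Normal(mu, sig2) prior.  ``eta`` and ``b0`` are updated in
    place for accepted pairs.
    """
    P = b0.size
    delta = np.empty(P)
    dll = np.zeros(P)
    for p in range(P):
        delta[p] = prop_step[p] * randn[p]
        new = b0[p] + delta[p]
        dll[p] = -((new - mu) ** 2 - (b0[p] - mu) ** 2) / (2.0 * sig2)
    for j in range(n_alive):
        p = pair_of_trans[j]
        dll[p] += _logsig(eta[j] + delta[p]) - _logsig(eta[j])
    for g in range(gap_ptr.size - 1):
        lo = n_alive + gap_ptr[g]
        hi = n_alive + gap_ptr[g + 1]
        p = pair_of_trans[lo]
        Gold = 0.0
        Gnew = 0.0
        for j in range(lo, hi):
            Gold += _logsig(eta[j])
            Gnew += _logsig(eta[j] + delta[p])
        dll[p] += _log1mexp(Gnew) - _log1mexp(Gold)
    for p in range(P):
        if logu[p] < dll[p]:
            accepted[p] = True
            b0[p] += delta[p]
        else:
            accepted[p] = False
            delta[p] = 0.0
    for j in range(eta.size):
        eta[j] += delta[pair_of_trans[j]]
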