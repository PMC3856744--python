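import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from nestsurv import _kernels
from nestsurv.selection import (
    bayes_factor,
    marginal_survival_prior_quantiles,
    summarize_selection,
    update_indicators,
)
from nestsurv.survival_model import (
    LikCache,
    PriorConfig,
    SurvivalDesign,
    SurvivalParams,
    compute_eta,
)

from conftest import history


class TestBayesFactor:
    def test_even_odds(self):
        assert bayes_factor(0.5, 0.5) == pytest.approx(1.0)

    def test_monotone_in_inclusion(self):
        ps = np.linspace(0.05, 0.95, 19)
        bfs = [bayes_factor(p, 0.5) for p in ps]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.01, 0.99))
    def test_odds_symmetry(self, p):
        assert bayes_factor(p, 0.5) * bayes_factor(1 - p, 0.5) == pytest.approx(1.0)

    def test_boundary_reports_bound(self):
        assert bayes_factor(1.0, 0.5, n_draws=1000).startswith(">")
        assert bayes_factor(0.0, 0.5, n_draws=1000).startswith("<")
        with pytest.raises(ValueError):
            bayes_factor(1.0, 0.5)


class TestSummarize:
    def test_hand_built_chain(self):
        w = np.array([[1], [1], [1], [0]])
        beta = np.array([[-1.0], [-2.0], [-3.0], [9.9]])
        s = summarize_selection(w, beta, ["v"])
        assert s.inclusion[0] == pytest.approx(0.75)
        assert s.bayes_factors[0] == pytest.approx(3.0)
        assert s.top_model.tolist() == [1]
        # conditional summary uses only the three included draws
        assert s.conditional_beta["mean"].iloc[0] == pytest.approx(-2.0)

    def test_degenerate_chain_has_single_model(self):
        w = np.tile([1, 0, 1], (50, 1))
        s = summarize_selection(w, np.zeros((50, 3)), list("abc"))
        assert len(s.visited) == 1 and s.visited["count"].iloc[0] == 50

    def test_visit_counts_conserved_for_known_mixture(self):
        w = np.vstack([np.tile([1, 1], (30, 1)), np.tile([0, 1], (20, 1))])
        s = summarize_selection(w, np.zeros((50, 2)), list("ab"))
        assert dict(zip(s.visited["model"], s.visited["count"])) == {"11": 30, "01": 20}
        assert s.visited["count"].sum() == 50


def _tiny_state(betas, w, V=1.0, zvals=None, n_days=6):
    """Three fully observed nests with fixed binary covariates."""
    hs = [
        history(nest="a", pair="p1", days=[1, 2, 3, 4], codes=[1, 1, 1, 0]),
        history(nest="b", pair="p2", days=[1, 2, 3, 4, 5], codes=[1, 1, 1, 1, 1]),
        history(nest="c", pair="p1", days=[2, 3, 4], codes=[1, 1, 0]),
    ]
    d = SurvivalDesign(hs, n_days)
    M = len(betas)
    if zvals is None:
        rng = np.random.default_rng(1)
        Z = (rng.uniform(size=(M, 3, n_days)) < 0.5).astype(float)
    else:
        Z = zvals
    zact = d.gather_covariates(Z)
    p = SurvivalParams(b0=np.array([1.2, 0.8]), mu_pair=1.0, sigma_pair=1.0,
                       beta_renest=0.0, beta=np.array(betas, dtype=float),
                       w=np.array(w, dtype=int), V=V)
    eta = compute_eta(d, p, zact)
    return d, p, zact, eta


class TestUpdateIndicators:
    def test_zero_covariate_at_prior_mode_gives_half(self, rng):
        # a single candidate with all-zero values and beta = 0: likelihood
        # ratio 1 and K' = 1 either way, so Pr(w = 1) = 0.5 exactly
        d, p, zact, eta = _tiny_state([0.0], [1], zvals=np.zeros((1, 3, 6)))
        pri = PriorConfig()
        draws = []
        for _ in range(4000):
            update_indicators(d, zact, p, eta, rng, pri)
            draws.append(int(p.w[0]))
        assert np.mean(draws) == pytest.approx(0.5, abs=0.025)

    def test_matches_exact_enumeration_over_models(self, rng):
        # hold beta and V fixed; the w-chain must visit the 4 models of a
        # 2-variable problem with exactly enumerable posterior probabilities
        d, p, zact, eta = _tiny_state([-1.2, 0.8], [1, 1], V=0.9)
        pri = PriorConfig()

        def log_post(wvec):
            q = SurvivalParams(b0=p.b0, mu_pair=p.mu_pair, sigma_pair=p.sigma_pair,
                               beta_renest=0.0, beta=p.beta.copy(),
                               w=np.array(wvec), V=p.V)
            e = compute_eta(d, q, zact)
            ll = _kernels.survival_ll(e, d.n_alive, d.gap_ptr)
            ke = max(sum(wvec), 1)
            var = p.V / ke
            lp = -0.5 * (2 * np.log(2 * np.pi * var) + (p.beta**2).sum() / var)
            return ll + lp

        models = [(0, 0), (0, 1), (1, 0), (1, 1)]
        lps = np.array([log_post(m) for m in models])
        exact = np.exp(lps - lps.max())
        exact /= exact.sum()

        counts = {m: 0 for m in models}
        for _ in range(20000):
            update_indicators(d, zact, p, eta, rng, pri, scales_logV=0.0)
            counts[tuple(p.w.tolist())] += 1
        freq = np.array([counts[m] / 20000 for m in models])
        assert np.abs(freq - exact).max() < 0.02

    def test_eta_stays_consistent_after_flips(self, rng):
        d, p, zact, eta = _tiny_state([-0.7, 0.4, 0.1], [1, 0, 1])
        pri = PriorConfig()
        cache = LikCache(d)
        cache.refresh(d, eta)
        for _ in range(200):
            update_indicators(d, zact, p, eta, rng, pri, cache=cache)
        assert np.allclose(eta, compute_eta(d, p, zact))


def test_marginal_survival_prior_is_roughly_flat():
    q5, q95 = marginal_survival_prior_quantiles(n_draws=200_000, seed=1)
    assert 0.03 < q5 < 0.5 < q95 < 0.97
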