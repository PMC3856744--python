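import numpy as np
import pytest
from scipy import integrate, stats

from nestsurv.covariate_models import (
    AR1Params,
    OccupancyParams,
    ar1_kstep,
    ar1_loglik,
    impute_ar1,
    impute_occupancy,
    occupancy_kstep,
    occupancy_loglik,
    stationary_occupancy,
    update_ar1_params,
    update_occupancy_params,
)


class TestAR1Loglik:
    def test_series_at_mean(self):
        p = AR1Params(alpha=[2.0], rho=[0.5], tau=[4.0])
        vals = np.array([[2.0, 2.0]])
        expected = (
            stats.norm.logpdf(2.0, 2.0, np.sqrt(1 / (4 * (1 - 0.25))))
            + stats.norm.logpdf(2.0, 2.0, np.sqrt(1 / 4))
        )
        assert ar1_loglik(vals, [0], p) == pytest.approx(expected, abs=1e-12)

    def test_rho_zero_reduces_to_iid(self, rng):
        vals = rng.normal(1.0, 0.7, size=(3, 20))
        p = AR1Params(alpha=[1.0], rho=[0.0], tau=[2.0])
        iid = stats.norm.logpdf(vals, 1.0, np.sqrt(0.5)).sum()
        assert ar1_loglik(vals, [0, 0, 0], p) == pytest.approx(iid, rel=1e-12)

    def test_single_standard_observation(self):
        p = AR1Params(alpha=[0.0], rho=[0.0], tau=[1.0])
        assert ar1_loglik(np.array([[0.0]]), [0], p) == pytest.approx(-0.5 * np.log(2 * np.pi))

    def test_rejects_incomplete_series(self):
        p = AR1Params(alpha=[0.0], rho=[0.0], tau=[1.0])
        with pytest.raises(ValueError, match="complete"):
            ar1_loglik(np.array([[0.0, np.nan]]), [0], p)

    def test_invalid_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            AR1Params(alpha=[0.0], rho=[1.0], tau=[1.0])


class TestKStep:
    def test_ar1_two_step_matches_composition(self):
        # integrating out the middle day of a 2-step transition must give
        # the same Gaussian as the closed-form k=2 law
        alpha, rho, tau = 1.5, 0.7, 3.0
        a1, v1 = ar1_kstep(alpha, rho, tau, 1)
        a2, v2 = ar1_kstep(alpha, rho, tau, 2)
        assert a2 == pytest.approx(a1**2)
        assert v2 == pytest.approx(v1 + a1**2 * v1)

    @pytest.mark.parametrize("k", [1, 2, 3, 7])
    def test_occupancy_kstep_matches_matrix_power(self, k):
        phi, gam = 0.83, 0.21
        P = np.array([[1 - gam, gam], [1 - phi, phi]])
        Pk = np.linalg.matrix_power(P, k)
        p11, p01 = occupancy_kstep(phi, gam, k)
        assert p11 == pytest.approx(Pk[1, 1], abs=1e-12)
        assert p01 == pytest.approx(Pk[0, 1], abs=1e-12)


class TestImputeAR1:
    def test_interior_bridge_centres_at_mean(self, rng):
        p = AR1Params(alpha=[2.0], rho=[0.6], tau=[4.0])
        vals = np.array([[2.0, np.nan, 2.0]])
        obs = np.array([[True, False, True]])
        draws = [impute_ar1(vals, obs, [0], p, rng)[0, 1] for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(2.0, abs=0.02)
        # conditional variance of the interior bridge is 1/(tau (1 + rho^2))
        assert np.var(draws) == pytest.approx(1 / (4 * (1 + 0.36)), rel=0.1)

    def test_rho_zero_draws_are_iid_normal(self, rng):
        # with rho = 0 the full conditional of every latent day is the
        # marginal Normal(alpha, 1/tau), independent of its neighbours
        p = AR1Params(alpha=[1.0], rho=[0.0], tau=[4.0])
        vals = np.full((1, 400), 1.0)  # initialized latent state
        obs = np.zeros((1, 400), dtype=bool)
        out = impute_ar1(vals, obs, [0], p, rng)
        assert stats.kstest(out.ravel(), stats.norm(1.0, 0.5).cdf).pvalue > 0.01

    def test_survival_weighting_shifts_posterior(self, rng):
        # one latent day feeding an alive transition with a negative effect:
        # compare the Metropolis chain with a quadrature oracle
        p = AR1Params(alpha=[1.0], rho=[0.5], tau=[4.0])
        beta, eta0 = -1.5, 2.0

        def loglik(i, t, z):
            return -np.log1p(np.exp(-(eta0 + beta * z)))

        vals = np.array([[1.0, 1.0, 1.0]])
        obs = np.array([[True, False, True]])
        draws = np.empty(6000)
        for i in range(6000):
            vals = impute_ar1(vals, obs, [0], p, rng, survival_logcontrib=loglik)
            draws[i] = vals[0, 1]
        m = 1.0  # both neighbours at the mean
        prec = 4.0 * (1 + 0.25)
        grid_pdf = lambda z: np.exp(-0.5 * prec * (z - m) ** 2 + loglik(0, 1, z))
        norm, _ = integrate.quad(grid_pdf, -5, 6)
        mean_oracle, _ = integrate.quad(lambda z: z * grid_pdf(z) / norm, -5, 6)
        assert mean_oracle < m  # survival of the nest argues for fewer insects
        assert draws[100:].mean() == pytest.approx(mean_oracle, abs=0.03)


class TestUpdateAR1Params:
    def test_parameter_recovery_long_series(self, rng):
        alpha, rho, tau = 2.0, 0.6, 4.0
        n = 5000
        x = np.empty(n)
        x[0] = alpha + rng.standard_normal() / np.sqrt(tau * (1 - rho**2))
        for t in range(1, n):
            x[t] = alpha + rho * (x[t - 1] - alpha) + rng.standard_normal() / np.sqrt(tau)
        vals = x.reshape(1, -1)
        p = AR1Params(alpha=[0.0], rho=[0.0], tau=[1.0])
        draws = {"alpha": [], "rho": [], "tau": []}
        for i in range(400):
            p = update_ar1_params(vals, [0], p, rng)
            if i >= 100:
                draws["alpha"].append(p.alpha[0])
                draws["rho"].append(p.rho[0])
                draws["tau"].append(p.tau[0])
        for name, truth in (("alpha", alpha), ("rho", rho), ("tau", tau)):
            d = np.asarray(draws[name])
            assert abs(d.mean() - truth) < 3 * d.std() + 1e-9, name

    def test_conjugate_tau_with_vanishing_residuals(self, rng):
        # constant series at alpha: the residual sum of squares vanishes as
        # the chain settles, so tau | rest approaches Gamma(0.1 + n/2, 0.1)
        n = 40
        vals = np.full((1, n), 1.7)
        p = AR1Params(alpha=[1.7], rho=[0.0], tau=[1.0])
        taus = []
        for i in range(3000):
            p = update_ar1_params(vals, [0], p, rng)
            if i >= 200:
                taus.append(p.tau[0])
        taus = np.asarray(taus)
        g = stats.gamma(a=0.1 + n / 2, scale=1 / 0.1)
        assert taus.mean() == pytest.approx(g.mean(), rel=0.05)
        assert taus.std() == pytest.approx(g.std(), rel=0.15)

    def test_rho_chain_stays_in_support(self, rng):
        vals = rng.normal(size=(1, 30))
        p = AR1Params(alpha=[0.0], rho=[0.97], tau=[1.0])
        for _ in range(200):
            p = update_ar1_params(vals, [0], p, rng, rho_step=0.5)
            assert -1 < p.rho[0] < 1


class TestOccupancyLoglik:
    def test_iid_degenerate_chain(self):
        p = OccupancyParams(phi=[0.3], gamma=[0.3])
        vals = np.array([[1.0, 0.0, 1.0, 1.0]])
        expected = 3 * np.log(0.3) + np.log(0.7)
        assert occupancy_loglik(vals, [0], p) == pytest.approx(expected)

    def test_persisting_pair(self):
        p = OccupancyParams(phi=[0.8], gamma=[0.2])
        # psi = 0.2 / (0.2 + 0.2) = 0.5
        assert occupancy_loglik(np.array([[1.0, 1.0]]), [0], p) == pytest.approx(
            np.log(0.5) + np.log(0.8)
        )

    def test_symmetric_chain(self):
        p = OccupancyParams(phi=[0.5], gamma=[0.5])
        assert occupancy_loglik(np.array([[0.0, 1.0, 0.0]]), [0], p) == pytest.approx(
            3 * np.log(0.5)
        )

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            OccupancyParams(phi=[1.0], gamma=[0.5])


class TestImputeOccupancy:
    def test_uninformative_chain_is_fair_coin(self, rng):
        p = OccupancyParams(phi=[0.5], gamma=[0.5])
        vals = np.array([[1.0, np.nan, 0.0]])
        obs = np.array([[True, False, True]])
        draws = [impute_occupancy(vals, obs, [0], p, rng)[0, 1] for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.03)

    def test_interior_full_conditional_enumeration(self, rng):
        # neighbours both occupied, phi=0.9, gamma=0.1:
        # Pr(1) = 0.9*0.9 / (0.9*0.9 + 0.1*0.1)
        p = OccupancyParams(phi=[0.9], gamma=[0.1])
        vals = np.array([[1.0, np.nan, 1.0]])
        obs = np.array([[True, False, True]])
        draws = [impute_occupancy(vals, obs, [0], p, rng)[0, 1] for _ in range(6000)]
        assert np.mean(draws) == pytest.approx(0.81 / 0.82, abs=0.015)

    def test_long_chain_reaches_stationary_occupancy(self, rng):
        # Gibbs sweeps over a fully latent series must reproduce the
        # stationary occupancy psi in the long-run marginal
        p = OccupancyParams(phi=[0.85], gamma=[0.25])
        obs = np.zeros((1, 300), dtype=bool)
        vals = (rng.uniform(size=(1, 300)) < 0.5).astype(float)
        for _ in range(50):
            vals = impute_occupancy(vals, obs, [0], p, rng)
        means = []
        for _ in range(60):
            vals = impute_occupancy(vals, obs, [0], p, rng)
            means.append(vals.mean())
        psi = stationary_occupancy(0.85, 0.25)
        assert np.mean(means) == pytest.approx(psi, abs=0.05)


class TestUpdateOccupancyParams:
    def test_recovery_from_simulated_chain(self, rng):
        phi, gam = 0.8, 0.3
        psi = stationary_occupancy(phi, gam)
        n, T = 20, 101
        vals = np.zeros((n, T))
        vals[:, 0] = rng.uniform(size=n) < psi
        for t in range(1, T):
            pr = np.where(vals[:, t - 1] == 1, phi, gam)
            vals[:, t] = rng.uniform(size=n) < pr
        p = OccupancyParams(phi=[0.5], gamma=[0.5])
        phis, gams = [], []
        for i in range(600):
            p = update_occupancy_params(vals, [0] * n, p, rng)
            if i >= 100:
                phis.append(p.phi[0])
                gams.append(p.gamma[0])
        assert abs(np.mean(phis) - phi) < 3 * np.std(phis) + 1e-9
        assert abs(np.mean(gams) - gam) < 3 * np.std(gams) + 1e-9

    def test_no_information_keeps_prior(self, rng):
        # all-occupied series: no transitions out of the unoccupied state,
        # so gamma's conditional stays near its Uniform(0,1) prior
        vals = np.ones((2, 30))
        p = OccupancyParams(phi=[0.5], gamma=[0.5])
        gams = []
        for _ in range(3000):
            p = update_occupancy_params(vals, [0, 0], p, rng)
            gams.append(p.gamma[0])
        gams = np.asarray(gams)
        # day-1 terms pull psi up, hence mildly favour larger gamma, but the
        # spread must remain prior-like rather than data-concentrated
        assert gams.std() > 0.2
        assert gams.mean() == pytest.approx(0.5, abs=0.25)
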