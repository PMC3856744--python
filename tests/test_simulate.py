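import numpy as np
import pytest

import nestsurv as ns
from nestsurv.simulate import (
    InsectTruth,
    NestTruth,
    make_default_fixture,
    simulate_insects,
    simulate_nests,
)


class TestSimulateInsects:
    def test_no_missing_days_when_all_sampled(self, rng):
        truth = InsectTruth.default()
        out = simulate_insects(rng, truth, trap_dropout=0.0)
        assert (out.table.table["active"] == 1).all()

    def test_default_sparsity_matches_design(self):
        fix = make_default_fixture(3)
        t = fix.traps.table
        days09 = t[(t["year"] == 2009) & (t["active"] == 1)]["day"].nunique()
        days10 = t[(t["year"] == 2010) & (t["active"] == 1)]["day"].nunique()
        assert days09 == 50 and days10 == 5
        assert t[t["year"] == 2009]["trap_id"].nunique() == 7
        assert t[t["year"] == 2010]["trap_id"].nunique() == 3

    def test_high_precision_flat_wave_gives_poisson_counts(self, rng):
        # tau -> inf, rho = 0, no peak: constant latent intensity,
        # counts are iid Poisson(exp(alpha))
        truth = InsectTruth(
            alpha={"a": (1.0, 1.0)}, rho={"a": (0.0, 0.0)}, tau={"a": (1e12, 1e12)},
            trap_sd=0.0,
        )
        out = simulate_insects(rng, truth, trap_dropout=0.0,
                               season_days={1: 600, 2: 5})
        c = out.full_table.table.query("year == 1")["count"]
        lam = np.exp(1.0)
        assert c.mean() == pytest.approx(lam, rel=0.05)
        assert c.var() == pytest.approx(lam, rel=0.15)

    def test_latent_lag1_autocorrelation_recovers_rho(self, rng):
        truth = InsectTruth(
            alpha={"a": (0.5, 0.5)}, rho={"a": (0.6, 0.6)}, tau={"a": (4.0, 4.0)},
            trap_sd=0.0,
        )
        out = simulate_insects(rng, truth, trap_dropout=0.0,
                               season_days={1: 5000, 2: 5})
        x = out.latent[("a", 1)][0]
        r = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r == pytest.approx(0.6, abs=0.05)


def _flat_covariates(name, x, y, year, day):
    return 0.0


class TestSimulateNests:
    SEASON = {2009: 72, 2010: 75}

    def _pairs(self, n=30):
        return [(f"P{i}", 2009, 5.0, 5.0) for i in range(n)]

    def test_indestructible_nests_run_full_incubation(self, rng):
        truth = NestTruth(mu_pair=50.0, sigma_pair=1e-6, effects={})
        hs, _ = simulate_nests(rng, self._pairs(), _flat_covariates, truth, self.SEASON)
        assert all(not h.failed for h in hs)
        assert all(h.days[-1] - h.days[0] == 30 for h in hs)
        assert all(h.renest == 0 for h in hs)

    def test_doomed_nests_fail_immediately(self, rng):
        truth = NestTruth(mu_pair=-50.0, sigma_pair=1e-6, effects={})
        hs, _ = simulate_nests(rng, self._pairs(), _flat_covariates, truth, self.SEASON)
        firsts = [h for h in hs if h.renest == 0]
        assert all(h.failed and h.failure_day == h.detection_day + 1 for h in firsts)

    def test_empirical_daily_survival_rate(self, rng):
        s_true = 0.9
        truth = NestTruth(mu_pair=float(np.log(s_true / (1 - s_true))),
                          sigma_pair=1e-9, beta_renest=0.0, effects={})
        hs, _ = simulate_nests(
            rng, self._pairs(500), _flat_covariates, truth, self.SEASON,
            gap_probs=(1.0, 0.0, 0.0), renest_prob=0.0,
        )
        alive, dead = 0, 0
        for h in hs:
            dead += int(h.failed)
            alive += len(h.days) - 1 - int(h.failed)
        s_hat = alive / (alive + dead)
        assert s_hat == pytest.approx(s_true, abs=0.01)


class TestDefaultFixture:
    def test_deterministic_given_seed(self):
        a = make_default_fixture(5)
        b = make_default_fixture(5)
        assert [h.nest_id for h in a.histories] == [h.nest_id for h in b.histories]
        assert all(np.array_equal(x.days, y.days) for x, y in zip(a.histories, b.histories))
        assert a.traps.table.equals(b.traps.table)

    def test_paper_shaped_bookkeeping(self):
        fix = make_default_fixture(9)
        years = {h.year for h in fix.histories}
        assert years == {2009, 2010}
        pairs = {h.pair_id for h in fix.histories}
        assert len(pairs) == 24  # 12 pairs per year
        n_nests = len(fix.histories)
        assert 24 <= n_nests <= 24 + 24  # each pair renests at most once
        for h in fix.histories:
            assert (h.renest == 1) == h.nest_id.endswith("N2")

    def test_failure_fraction_calibrated(self):
        fracs = [
            np.mean([h.failed for h in make_default_fixture(seed).histories])
            for seed in range(1, 31)
        ]
        assert all(0.5 < f < 0.95 for f in fracs)

    def test_dataset_pipeline_alignment(self, small_fixture, small_dataset):
        assert len(small_dataset.series) == 12
        ids = [h.nest_id for h in small_dataset.histories]
        for s in small_dataset.series:
            assert list(s.nest_ids) == ids
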