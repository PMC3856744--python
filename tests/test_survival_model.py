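import numpy as np
import pytest
from scipy.special import expit

from nestsurv.survival_model import (
    SurvivalDesign,
    SurvivalParams,
    daily_survival,
    survival_loglik,
)
from nestsurv.io_data import ValidationError

from conftest import history


def params(M=0, **kw):
    base = dict(b0=np.zeros(kw.pop("n_pairs", 1)), mu_pair=0.0, sigma_pair=1.0,
                beta_renest=0.0, beta=np.zeros(M), w=np.ones(M, dtype=int), V=1.0)
    base.update(kw)
    return SurvivalParams(**base)


class TestDailySurvival:
    def test_null_predictor_is_half(self):
        assert daily_survival(params(), [], renest=0) == pytest.approx(0.5)

    def test_intercept_only(self):
        p = params(b0=np.array([3.0]))
        assert daily_survival(p, [], renest=0, pair=0) == pytest.approx(expit(3.0), abs=1e-4)
        assert daily_survival(p, [], renest=0, pair=0) == pytest.approx(0.9526, abs=1e-4)

    def test_excluded_covariate_has_no_effect(self):
        p = params(M=2, beta=np.array([5.0, -0.4]), w=np.array([0, 1]))
        s1 = daily_survival(p, [10.0, 1.0], renest=0)
        s2 = daily_survival(p, [-10.0, 1.0], renest=0)
        assert s1 == s2 == pytest.approx(expit(-0.4))

    def test_missing_covariate_rejected(self):
        p = params(M=1, beta=np.array([1.0]), w=np.array([1]))
        with pytest.raises(ValidationError, match="missing covariate"):
            daily_survival(p, [np.nan], renest=0)


def brute_force_loglik(histories, S):
    """Independent oracle: day-by-day product over fully observed records.

    ``S[i][t]`` is the survival probability of nest i over day t -> t+1
    (1-based t).  Only valid when every day from detection to the record
    end is coded.
    """
    ll = 0.0
    for i, h in enumerate(histories):
        for a, b, ca, cb in zip(h.days[:-1], h.days[1:], h.codes[:-1], h.codes[1:]):
            assert b == a + 1
            ll += np.log(S[i][a]) if cb == 1.0 else np.log(1 - S[i][a])
    return ll


class TestSurvivalLoglik:
    def test_matches_bernoulli_product_oracle(self, rng):
        histories = []
        T = 12
        Smat = {}
        for i in range(8):
            days = list(range(1, T + 1))
            codes = [1.0] * T
            died = rng.uniform() < 0.6
            if died:
                dday = int(rng.integers(3, T))
                codes = [1.0] * (dday - 1) + [0.0]
                days = days[: dday]
            histories.append(history(nest=f"n{i}", pair=f"p{i%3}", days=days, codes=codes))
        M, n = 1, len(histories)
        Z = rng.normal(size=(M, n, T))
        p = params(M=1, n_pairs=3, b0=np.array([1.5, 2.0, 2.5]),
                   beta=np.array([-0.6]), w=np.array([1]))
        S = {}
        for i, h in enumerate(histories):
            S[i] = {t: float(expit(p.b0[i % 3] - 0.6 * Z[0, i, t])) for t in range(1, T)}
        ll = survival_loglik(histories, p, Z, n_days=T)
        assert ll == pytest.approx(brute_force_loglik(histories, S), abs=1e-10)

    def test_interior_missing_day_between_alive_checks(self):
        # alive on day 1 and day 3: day 2 is certainly alive, so the record
        # contributes log S_1 + log S_2 exactly
        h = history(days=[1, 3], codes=[1, 1])
        p = params(b0=np.array([1.0]))
        s = float(expit(1.0))
        assert survival_loglik([h], p, n_days=4) == pytest.approx(2 * np.log(s))

    def test_death_after_gap_marginalizes_failure_day(self):
        # alive day 1, dead day 3: P = (1-S1) + S1 (1-S2) = 1 - S1 S2
        h = history(days=[1, 3], codes=[1, 0])
        p = params(M=1, beta=np.array([0.5]), w=np.array([1]))
        Z = np.array([[[0.0, 0.3, -0.8, 0.0]]])
        s1 = float(expit(0.5 * 0.3))
        s2 = float(expit(0.5 * -0.8))
        enumeration = (1 - s1) + s1 * (1 - s2)
        ll = survival_loglik([h], p, Z, n_days=4)
        assert ll == pytest.approx(np.log(enumeration), abs=1e-12)
        assert ll == pytest.approx(np.log(1 - s1 * s2), abs=1e-12)

    def test_three_day_gap_agrees_with_enumeration(self):
        h = history(days=[2, 5], codes=[1, 0])
        p = params(b0=np.array([0.8]))
        s = float(expit(0.8))
        enum = sum(s**k * (1 - s) for k in range(3))
        assert survival_loglik([h], p, n_days=6) == pytest.approx(np.log(enum), abs=1e-12)

    def test_invariant_to_relabelling(self, rng):
        hs = [
            history(nest="a", pair="x", days=[1, 2, 3], codes=[1, 1, 0]),
            history(nest="b", pair="y", days=[2, 3, 4, 5], codes=[1, 1, 1, 1]),
        ]
        p = params(n_pairs=2, b0=np.array([0.5, 1.5]))
        ll1 = survival_loglik(hs, p, n_days=6)
        relabelled = [
            history(nest="zz", pair="q1", days=[1, 2, 3], codes=[1, 1, 0]),
            history(nest="aa", pair="q2", days=[2, 3, 4, 5], codes=[1, 1, 1, 1]),
        ]
        ll2 = survival_loglik(relabelled, p, n_days=6)
        assert ll1 == pytest.approx(ll2)

    def test_covariate_timing_uses_destination_day(self):
        # transition day1 -> day2 must read the covariate on day 2
        h = history(days=[1, 2], codes=[1, 1])
        p = params(M=1, beta=np.array([1.0]), w=np.array([1]))
        Z = np.array([[[99.0, 2.0]]])  # day1 value is irrelevant
        assert survival_loglik([h], p, Z, n_days=2) == pytest.approx(float(np.log(expit(2.0))))


class TestSurvivalDesign:
    def test_layout_counts(self):
        hs = [
            history(nest="a", days=[1, 2, 3], codes=[1, 1, 0]),          # 1 alive + gap(1)
            history(nest="b", days=[1, 4], codes=[1, 0]),                # gap(3)
            history(nest="c", days=[2, 3, 4], codes=[1, 1, 1]),          # 2 alive
        ]
        d = SurvivalDesign(hs, n_days=5)
        assert d.n_alive == 3 and d.n_gaps == 2
        assert list(np.diff(d.gap_ptr)) == [1, 3]
        assert d.n_trans == 7

    def test_rejects_missing_covariate_at_transition(self):
        h = history(days=[1, 2], codes=[1, 1])
        d = SurvivalDesign([h], n_days=2)
        Z = np.array([[[0.0, np.nan]]])
        with pytest.raises(ValidationError, match="missing covariate"):
            d.gather_covariates(Z)
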