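import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nestsurv.covariate_prep import (
    interpolate_counts,
    make_log_count,
    make_presence,
    make_q90,
)
from nestsurv.io_data import NestSite, TrapCountTable, ValidationError


def _table(trap_entries, year=2009):
    """trap_entries: list of (trap_id, x, y, day, count, active)."""
    rows = [
        dict(trap_id=t, x=x, y=y, year=year, day=d, taxon="a",
             count=c if a else np.nan, active=a)
        for t, x, y, d, c, a in trap_entries
    ]
    return TrapCountTable(pd.DataFrame(rows))


NEST_YEARS = {"n1": 2009}


class TestInterpolation:
    def test_hand_worked_inverse_distance_squared(self):
        # traps at distances 1 and 2 with counts 3 and 12:
        # (3/1 + 12/4) / (1/1 + 1/4) = 4.8
        t = _table([("T1", 1.0, 0.0, 1, 3.0, 1), ("T2", 2.0, 0.0, 1, 12.0, 1)])
        v, obs = interpolate_counts(t, [NestSite("n1", 0.0, 0.0)], "a", NEST_YEARS, 1)
        assert obs[0, 0]
        assert v[0, 0] == pytest.approx(4.8, abs=1e-12)

    def test_constant_counts_give_constant_value(self):
        t = _table([("T1", 1.0, 0.0, 1, 7.0, 1), ("T2", 5.0, 3.0, 1, 7.0, 1),
                    ("T3", -2.0, 8.0, 1, 7.0, 1)])
        v, _ = interpolate_counts(t, [NestSite("n1", 0.3, 0.4)], "a", NEST_YEARS, 1)
        assert v[0, 0] == pytest.approx(7.0)

    def test_single_active_trap_dominates(self):
        t = _table([("T1", 9.0, 9.0, 1, 9.0, 1), ("T2", 1.0, 1.0, 1, 5.0, 0)])
        v, _ = interpolate_counts(t, [NestSite("n1", 0.0, 0.0)], "a", NEST_YEARS, 1)
        assert v[0, 0] == pytest.approx(9.0)

    def test_day_without_active_trap_is_missing(self):
        t = _table([("T1", 1.0, 0.0, 1, 3.0, 1), ("T1", 1.0, 0.0, 2, 0.0, 0)])
        v, obs = interpolate_counts(t, [NestSite("n1", 0.0, 0.0)], "a", NEST_YEARS, 3)
        assert obs[0].tolist() == [True, False, False]
        assert np.isnan(v[0, 1]) and np.isnan(v[0, 2])

    def test_nest_at_trap_rejected(self):
        t = _table([("T1", 0.0, 0.0, 1, 3.0, 1)])
        with pytest.raises(ValidationError, match="minimum-distance"):
            interpolate_counts(t, [NestSite("n1", 0.0, 0.0)], "a", NEST_YEARS, 1)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0.5, 20)), min_size=2, max_size=6))
    def test_value_is_convex_combination_of_counts(self, traps):
        entries = [(f"T{i}", d, 0.0, 1, c, 1) for i, (c, d) in enumerate(traps)]
        t = _table(entries)
        v, _ = interpolate_counts(t, [NestSite("n1", 0.0, 0.0)], "a", NEST_YEARS, 1)
        counts = [c for c, _ in traps]
        assert min(counts) - 1e-9 <= v[0, 0] <= max(counts) + 1e-9


class TestMetrics:
    VALUES = np.array([[0.0, np.e - 1, 4.8]])
    OBS = np.ones((1, 3), dtype=bool)

    def test_log_count_examples(self):
        s = make_log_count(self.VALUES, self.OBS, "a", ["n1"])
        assert s.values[0, 0] == 0.0
        assert s.values[0, 1] == pytest.approx(1.0)
        assert s.values[0, 2] == pytest.approx(np.log(5.8), abs=1e-4)

    def test_log_count_rejects_negative(self):
        with pytest.raises(ValidationError):
            make_log_count(np.array([[-1.0]]), np.ones((1, 1), bool), "a", ["n1"])

    def test_presence_threshold_and_mask(self):
        vals = np.array([[0.0, 0.001, np.nan]])
        obs = np.array([[True, True, False]])
        s = make_presence(vals, obs, "a", ["n1"])
        assert s.values[0, 0] == 0.0 and s.values[0, 1] == 1.0
        assert np.isnan(s.values[0, 2]) and not s.observed[0, 2]

    def test_presence_all_zero(self):
        s = make_presence(np.zeros((2, 4)), np.ones((2, 4), bool), "a", ["n1", "n2"])
        assert (s.values == 0).all()

    def test_q90_linear_interpolation_rule(self):
        vals = np.arange(1.0, 101.0).reshape(4, 25)
        s = make_q90(vals, np.ones_like(vals, bool), "a", [f"n{i}" for i in range(4)])
        assert s.meta["threshold"] == pytest.approx(90.1)
        flat = s.values.ravel()
        assert flat[94] == 1.0  # value 95 > 90.1
        assert flat[89] == 0.0  # value 90 does not exceed 90.1
        # exactly at the threshold codes 0 ("exceeded" is strict)
        vals2 = np.array([[1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 10]], dtype=float)
        s2 = make_q90(vals2, np.ones_like(vals2, bool), "a", ["n1"])
        assert s2.meta["threshold"] == pytest.approx(10.0)
        assert (s2.values == 0).all()

    def test_q90_constant_matrix_all_zero(self):
        vals = np.full((2, 10), 3.3)
        s = make_q90(vals, np.ones_like(vals, bool), "a", ["n1", "n2"])
        assert (s.values == 0).all()

    def test_q90_requires_enough_observations(self):
        with pytest.raises(ValidationError, match=">=10"):
            make_q90(np.ones((1, 5)), np.ones((1, 5), bool), "a", ["n1"])

    def test_q90_exceedance_fraction_bounded(self, rng):
        vals = rng.uniform(size=(20, 50))
        obs = np.ones_like(vals, bool)
        s = make_q90(vals, obs, "a", [f"n{i}" for i in range(20)])
        assert s.values.mean() <= 0.1 + 0.01

    def test_presence_dominates_q90(self, rng):
        vals = rng.gamma(2.0, 2.0, size=(10, 30))
        obs = rng.uniform(size=vals.shape) < 0.8
        p = make_presence(vals, obs, "a", [f"n{i}" for i in range(10)])
        q = make_q90(vals, obs, "a", [f"n{i}" for i in range(10)])
        assert (p.values[obs] >= q.values[obs]).all()
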