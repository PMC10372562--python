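"""Federated Kaplan–Meier and log-rank: exact pooled equivalence."""

import numpy as np
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from fedsilo.survival import (
    EventTable,
    SurvivalRecord,
    aggregate_tables,
    km_curve,
    local_event_table,
    logrank_test,
    survival_at,
)


def _records(times, events):
    return [SurvivalRecord(float(t), int(e)) for t, e in zip(times, events)]


def _lung_like(n=228, seed=0):
    """Synthetic cohort with roughly 63% events: exponential event times
    plus independent uniform censoring."""
    rng = np.random.default_rng(seed)
    t_event = rng.exponential(300, size=n)
    t_cens = rng.uniform(0, 700, size=n)
    times = np.minimum(t_event, t_cens)
    events = (t_event <= t_cens).astype(int)
    return times, events


class TestLocalEventTable:
    def test_all_censored(self):
        t = local_event_table(_records([1, 2, 3], [0, 0, 0]))
        assert len(t.times) == 0 and t.n_total == 3

    def test_hand_enumeration(self):
        t = local_event_table(_records([1, 2, 2, 3], [1, 1, 1, 1]))
        assert list(t.times) == [1, 2, 3]
        assert list(t.d) == [1, 2, 1]
        assert list(t.n_at_risk) == [4, 3, 1]

    def test_single_event_drops_curve_to_zero(self):
        t = local_event_table(_records([5], [1]))
        _, s = km_curve(t)
        assert s[-1] == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            local_event_table(_records([-1], [1]))

    def test_censor_at_event_time_still_at_risk(self):
        # deaths precede censorings at ties
        t = local_event_table(_records([2, 2], [1, 0]))
        assert list(t.n_at_risk) == [2]


class TestAggregateTables:
    def test_single_table_identity(self):
        t = local_event_table(_records([1, 2], [1, 1]))
        agg = aggregate_tables([t])
        assert np.array_equal(agg.times, t.times)
        assert np.array_equal(agg.d, t.d)

    def test_duplicate_doubles_counts(self):
        t = local_event_table(_records([1, 2, 3], [1, 0, 1]))
        agg = aggregate_tables([t, t])
        assert np.array_equal(agg.d, 2 * t.d)
        assert agg.n_total == 2 * t.n_total

    def test_disjoint_times_interleave(self):
        a = local_event_table(_records([1, 3], [1, 1]))
        b = local_event_table(_records([2, 4], [1, 1]))
        agg = aggregate_tables([a, b])
        assert list(agg.times) == [1, 2, 3, 4]
        assert list(agg.n_at_risk) == [4, 3, 2, 1]

    @pytest.mark.parametrize("n_parts", [1, 2, 3, 5, 8])
    def test_partition_equals_pooled(self, n_parts):
        times, events = _lung_like(100, seed=n_parts)
        records = _records(times, events)
        rng = np.random.default_rng(n_parts)
        assignment = rng.integers(0, n_parts, size=len(records))
        tables = [
            local_event_table(
                [r for r, a in zip(records, assignment) if a == i]
            )
            for i in range(n_parts)
            if np.any(assignment == i)
        ]
        agg = aggregate_tables(tables)
        pooled = local_event_table(records)
        assert np.array_equal(agg.times, pooled.times)
        assert np.array_equal(agg.d, pooled.d)
        assert np.array_equal(agg.n_at_risk, pooled.n_at_risk)


class TestKMCurve:
    def test_no_events_flat_curve(self):
        t = local_event_table(_records([1, 2], [0, 0]))
        _, s = km_curve(t)
        assert len(s) == 0
        assert survival_at(t, 100.0) == 1.0

    def test_one_step_closed_form(self):
        t = local_event_table(_records([1, 2], [1, 0]))
        # d=[1], n=[2] at t=1 → S(1) = 0.5
        assert survival_at(t, 1.0) == pytest.approx(0.5)

    def test_three_party_split_matches_lifelines(self):
        times, events = _lung_like()
        records = _records(times, events)
        tables = [
            local_event_table(records[i::3]) for i in range(3)
        ]
        agg = aggregate_tables(tables)
        t_grid, s_fed = km_curve(agg)

        kmf = KaplanMeierFitter().fit(times, events)
        s_oracle = kmf.survival_function_at_times(t_grid).to_numpy()
        assert np.max(np.abs(s_fed - s_oracle)) < 1e-12


class TestLogrank:
    def test_identical_groups_null(self):
        t = local_event_table(_records([1, 2, 3, 4], [1, 1, 0, 1]))
        chi2, p = logrank_test({"A": t, "B": t})
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_separated_groups(self):
        # A: events at t=1,2; B: events at t=3,4
        ta = local_event_table(_records([1, 2], [1, 1]))
        tb = local_event_table(_records([3, 4], [1, 1]))
        chi2, _ = logrank_test({"A": ta, "B": tb})
        # manual hypergeometric sums over times 1..4:
        # t=1: nA=2 nB=2 d=1 → eA=1/2, v=(1·3/3)(2/4)(2/4)=1/4
        # t=2: nA=1 nB=2 d=1 → eA=1/3, v=(1·2/2)(1/3)(2/3)=2/9
        # t=3: nA=0 nB=2 d=1 → eA=0,  v=0
        # t=4: nA=0 nB=1 d=1 → eA=0,  v=0
        u = (1 - 0.5) + (1 - 1 / 3)
        v = 0.25 + 2 / 9
        assert chi2 == pytest.approx(u**2 / v, rel=1e-12)

    def test_single_group_rejected(self):
        t = local_event_table(_records([1], [1]))
        with pytest.raises(ValueError):
            logrank_test({"A": t})

    def test_no_events_rejected(self):
        t = local_event_table(_records([1], [0]))
        with pytest.raises(ValueError):
            logrank_test({"A": t, "B": t})

    @pytest.mark.parametrize("n_parts", [2, 4, 6])
    def test_partition_invariant_and_matches_lifelines(self, n_parts):
        times, events = _lung_like(150, seed=50 + n_parts)
        rng = np.random.default_rng(n_parts)
        groups = np.where(rng.random(150) < 0.5, "A", "B")
        assignment = rng.integers(0, n_parts, size=150)
        merged = {}
        for g in ("A", "B"):
            tables = []
            for i in range(n_parts):
                mask = (assignment == i) & (groups == g)
                if mask.any():
                    tables.append(
                        local_event_table(_records(times[mask], events[mask]))
                    )
            merged[g] = aggregate_tables(tables)
        chi2_fed, p_fed = logrank_test(merged)
        pooled = {
            g: local_event_table(
                _records(times[groups == g], events[groups == g])
            )
            for g in ("A", "B")
        }
        chi2_pool, _ = logrank_test(pooled)
        assert chi2_fed == pytest.approx(chi2_pool, abs=1e-12)

        oracle = multivariate_logrank_test(times, groups, events)
        assert chi2_fed == pytest.approx(oracle.test_statistic, rel=1e-9)
        assert p_fed == pytest.approx(oracle.p_value, rel=1e-6)
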