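"""Federated Kaplan–Meier estimation and log-rank testing.

Each party reduces its records to an event table — per-time event counts
plus censoring times — the minimal summable statistic for the product-limit
estimator.  Tables aggregate by summing counts over the union of time
points, which reproduces the event table of the pooled records *exactly*;
the survival curve and the log-rank statistic computed from the aggregate
are therefore identical to a centralized analysis, for any distribution of
records across parties.

Ties follow the standard convention: deaths precede censorings at equal
times, so a subject censored at t is still at risk for the events at t.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "EventTable",
    "local_event_table",
    "aggregate_tables",
    "km_curve",
    "logrank_test",
]


@dataclass(frozen=True)
class SurvivalRecord:
    time: float
    event: int  # 1 = event observed, 0 = right-censored
    group: str | None = None


@dataclass
class EventTable:
    """Per-time counts sufficient for KM: distinct event times with event
    counts, plus censoring times with counts and the cohort size.

    ``n_at_risk`` is derived: subjects whose event or censoring time is
    strictly before t have left the risk set (deaths-before-censorings at
    ties means a censoring at exactly t still counts as at risk at t).
    """

    times: np.ndarray  # sorted distinct event times
    d: np.ndarray  # events at each time
    n_total: int  # cohort size at t=0
    censor_times: np.ndarray = field(
        default_factory=lambda: np.empty(0)
    )
    censor_counts: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int)
    )

    @property
    def n_at_risk(self) -> np.ndarray:
        return self.at_risk_at(self.times)

    def at_risk_at(self, times: np.ndarray) -> np.ndarray:
        """Number still at risk at each query time (exits strictly before
        t are removed)."""
        times = np.asarray(times, dtype=float)
        gone_events = np.searchsorted(self.times, times, side="left")
        events_before = np.concatenate([[0], np.cumsum(self.d)])[gone_events]
        gone_cens = np.searchsorted(self.censor_times, times, side="left")
        cens_before = np.concatenate(
            [[0], np.cumsum(self.censor_counts)]
        )[gone_cens]
        return self.n_total - events_before - cens_before

    def events_at(self, times: np.ndarray) -> np.ndarray:
        """Event counts at each query time (0 where no event)."""
        times = np.asarray(times, dtype=float)
        out = np.zeros(len(times), dtype=int)
        if len(self.times) == 0:
            return out
        idx = np.searchsorted(self.times, times)
        inside = idx < len(self.times)
        ok = inside.copy()
        ok[inside] = self.times[idx[inside]] == times[inside]
        out[ok] = self.d[idx[ok]]
        return out


def local_event_table(records: list[SurvivalRecord]) -> EventTable:
    """Reduce one party's records to its event table."""
    if not records:
        raise ValueError("no survival records supplied")
    if any(r.time < 0 for r in records):
        raise ValueError("survival times must be nonnegative")
    ev = Counter(r.time for r in records if r.event)
    ce = Counter(r.time for r in records if not r.event)
    times = np.array(sorted(ev), dtype=float)
    d = np.array([ev[t] for t in sorted(ev)], dtype=int)
    ct = np.array(sorted(ce), dtype=float)
    cc = np.array([ce[t] for t in sorted(ce)], dtype=int)
    return EventTable(
        times=times, d=d, n_total=len(records),
        censor_times=ct, censor_counts=cc,
    )


def aggregate_tables(tables: list[EventTable]) -> EventTable:
    """Coordinator-side merge: counts summed over the union of times.

    Exactly equals ``local_event_table`` of the pooled records.
    """
    if not tables:
        raise ValueError("no event tables supplied")
    ev: Counter = Counter()
    ce: Counter = Counter()
    n_total = 0
    for t in tables:
        n_total += t.n_total
        for time, count in zip(t.times, t.d):
            ev[float(time)] += int(count)
        for time, count in zip(t.censor_times, t.censor_counts):
            ce[float(time)] += int(count)
    times = np.array(sorted(ev), dtype=float)
    d = np.array([ev[t] for t in sorted(ev)], dtype=int)
    ct = np.array(sorted(ce), dtype=float)
    cc = np.array([ce[t] for t in sorted(ce)], dtype=int)
    return EventTable(
        times=times, d=d, n_total=n_total,
        censor_times=ct, censor_counts=cc,
    )


def km_curve(table: EventTable) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit survival estimate S(t) = Π_{t_i ≤ t} (1 − d_i/n_i).

    Returns (event_times, S at those times); S(0) = 1 and the curve is a
    right-continuous step function between listed times.
    """
    n = table.n_at_risk
    with np.errstate(invalid="ignore"):
        factors = 1.0 - table.d / n
    return table.times.copy(), np.cumprod(factors)


def survival_at(table: EventTable, t: float) -> float:
    """Evaluate the step function S at an arbitrary time."""
    times, s = km_curve(table)
    idx = np.searchsorted(times, t, side="right")
    return 1.0 if idx == 0 else float(s[idx - 1])


def logrank_test(
    group_tables: dict[str, EventTable],
) -> tuple[float, float]:
    """k-sample log-rank test on (aggregated) per-group event tables.

    At every pooled event time, the expected events in group g are
    e_g = n_g · d / n and the covariance of observed events follows the
    multivariate hypergeometric law.  The statistic is
    U' V⁻¹ U over the first k−1 groups, chi-square with k−1 df under the
    null of equal hazards.  Identical to the centralized test because the
    group tables aggregate exactly.
    """
    if len(group_tables) < 2:
        raise ValueError("log-rank test requires at least two groups")
    groups = sorted(group_tables)
    tables = [group_tables[g] for g in groups]
    all_times = np.array(
        sorted(set(np.concatenate([t.times for t in tables]))), dtype=float
    )
    if len(all_times) == 0:
        raise ValueError("no events in any group: statistic undefined")
    k = len(groups)
    d_g = np.stack([t.events_at(all_times) for t in tables])  # k × T
    n_g = np.stack(
        [t.at_risk_at(all_times) for t in tables]
    ).astype(float)
    d_tot = d_g.sum(axis=0).astype(float)
    n_tot = n_g.sum(axis=0)

    expected = n_g * d_tot / n_tot
    U = (d_g - expected).sum(axis=1)[: k - 1]

    V = np.zeros((k - 1, k - 1))
    # hypergeometric covariance, summed over event times with n > 1
    valid = n_tot > 1
    for a in range(k - 1):
        for b in range(k - 1):
            same = 1.0 if a == b else 0.0
            terms = (
                d_tot[valid]
                * (n_tot[valid] - d_tot[valid])
                / (n_tot[valid] - 1)
                * (n_g[a, valid] / n_tot[valid])
                * (same - n_g[b, valid] / n_tot[valid])
            )
            V[a, b] = terms.sum()  # `same` carries the sign
    chi2 = float(U @ np.linalg.solve(V, U)) if k > 2 else float(
        U[0] ** 2 / V[0, 0]
    )
    p = float(stats.chi2.sf(chi2, df=k - 1))
    return chi2, p
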