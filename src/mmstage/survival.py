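"""Univariate survival analysis: 1-D K-means cutoffs, Kaplan–Meier curves,
log-rank tests, and the per-factor prognostic screen.

Numeric covariates are dichotomized by an exact two-cluster split of their
values: among all contiguous splits of the sorted values, the one minimizing
the within-cluster sum of squares is selected (exhaustive scan, which is
exact in one dimension), and the cutoff C is the largest value of the lower
cluster, giving groups ``<= C`` and ``> C``.

Kaplan–Meier estimation and log-rank testing delegate to lifelines; the
module adds the cutoff machinery, the median convention (smallest t with
S(t) <= 0.5, rendered "> max follow-up" when never reached), and the screen
table mirroring the per-factor report: n, events, median and p-value per
factor level and endpoint, with uncorrected pairwise tests for multi-level
factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .schema import VariableSchema

__all__ = [
    "CutoffResult",
    "KMCurve",
    "MedianSurvival",
    "LogRankResult",
    "kmeans_1d_cutoff",
    "km_estimate",
    "median_survival",
    "logrank_test",
    "univariate_screen",
    "ENDPOINTS",
]

ENDPOINTS = {"pfs": ("pfs_time_months", "pfs_event"), "os": ("os_time_months", "os_event")}


# ---------------------------------------------------------------------------
# 1-D K-means cutoff


@dataclass(frozen=True)
class CutoffResult:
    variable: str
    cutoff: float
    n_low: int   # values <= cutoff
    n_high: int  # values > cutoff


def _exact_split_wcss(v: np.ndarray, i: int) -> Fraction:
    """WCSS of the split v[:i] | v[i:] in exact rational arithmetic (floats
    are exact rationals, so this is free of rounding)."""
    total = Fraction(0)
    for part in (v[:i], v[i:]):
        s1 = sum((Fraction(x) for x in part), Fraction(0))
        s2 = sum((Fraction(x) * Fraction(x) for x in part), Fraction(0))
        total += s2 - s1 * s1 / len(part)
    return total


def kmeans_1d_cutoff(values, variable: str = "") -> CutoffResult:
    """Exact two-cluster split of 1-D values by exhaustive WCSS scan.

    The optimal 2-means partition of scalars is contiguous in sorted order,
    so scanning the n-1 splits between distinct neighbours is exact. Ties in
    WCSS are broken toward the more balanced split, then the lower cutoff;
    near-ties from the float scan are resolved in exact rational arithmetic
    so mathematically tied splits break deterministically.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n < 2 or v[0] == v[-1]:
        raise ValueError("need at least two distinct values to split")

    # prefix sums give each candidate split's WCSS in O(1)
    s1 = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def wcss(lo: int, hi: int) -> float:  # cluster = v[lo:hi]
        m = hi - lo
        tot, tot2 = s1[hi] - s1[lo], s2[hi] - s2[lo]
        return tot2 - tot * tot / m

    splits = [i for i in range(1, n) if v[i - 1] < v[i]]
    w = {i: wcss(0, i) + wcss(i, n) for i in splits}
    w_min = min(w.values())
    tol = 1e-9 * (1.0 + float(s2[n]))
    candidates = [i for i in splits if w[i] <= w_min + tol]
    if len(candidates) == 1:
        best_i = candidates[0]
    else:
        best_i = min(
            candidates,
            key=lambda i: (_exact_split_wcss(v, i), abs(n - 2 * i), v[i - 1]),
        )
    cutoff = float(v[best_i - 1])
    return CutoffResult(variable=variable, cutoff=cutoff, n_low=best_i, n_high=n - best_i)


# ---------------------------------------------------------------------------
# Kaplan–Meier


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: S(t) steps down at the event times."""

    event_times: np.ndarray      # distinct event times, ascending
    survival: np.ndarray         # S(t) just after each event time
    at_risk: np.ndarray          # risk-set size at each event time
    n_events: np.ndarray         # events at each event time
    censor_times: np.ndarray
    max_followup: float

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_months": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.n_events,
            }
        )


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimate. Ties between events and censorings
    at the same time are resolved events-first (the standard convention)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("survival times must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    event_times = ev.index.to_numpy(dtype=float)
    survival = np.array([kmf.predict(t) for t in event_times], dtype=float)
    return KMCurve(
        event_times=event_times,
        survival=survival,
        at_risk=ev["at_risk"].to_numpy(dtype=float),
        n_events=ev["observed"].to_numpy(dtype=float),
        censor_times=np.sort(times[~events]),
        max_followup=float(times.max()) if times.size else 0.0,
    )


@dataclass(frozen=True)
class MedianSurvival:
    """Median survival in months, or undefined ("> max follow-up") when the
    curve never reaches 0.5."""

    months: float | None
    max_followup: float

    @property
    def defined(self) -> bool:
        return self.months is not None

    def __str__(self) -> str:
        return f"{self.months:g}" if self.defined else f"> {self.max_followup:g}"

    @property
    def value_or_inf(self) -> float:
        return self.months if self.defined else float("inf")


def median_survival(curve: KMCurve) -> MedianSurvival:
    """Smallest event time with S(t) <= 0.5; undefined if never reached."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    if below.size == 0:
        return MedianSurvival(months=None, max_followup=curve.max_followup)
    return MedianSurvival(
        months=float(curve.event_times[below[0]]), max_followup=curve.max_followup
    )


# ---------------------------------------------------------------------------
# log-rank


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    group_n: tuple[int, ...]
    observed: tuple[float, ...]
    expected: tuple[float, ...]


def _observed_expected(groups) -> tuple[np.ndarray, np.ndarray]:
    """Per-group observed and expected event counts under the null (expected
    events at each time proportional to the at-risk share)."""
    k = len(groups)
    all_times = np.concatenate([np.asarray(t, dtype=float) for t, _ in groups])
    all_events = np.concatenate([np.asarray(e, dtype=bool) for _, e in groups])
    gidx = np.concatenate([np.full(len(t), i) for i, (t, _) in enumerate(groups)])
    observed = np.zeros(k)
    expected = np.zeros(k)
    for t in np.unique(all_times[all_events]):
        at_risk = all_times >= t
        n_t = at_risk.sum()
        d_t = (all_events & (all_times == t)).sum()
        for g in range(k):
            n_g = (at_risk & (gidx == g)).sum()
            d_g = (all_events & (all_times == t) & (gidx == g)).sum()
            observed[g] += d_g
            expected[g] += d_t * n_g / n_t
    return observed, expected


def logrank_test(groups) -> LogRankResult:
    """Unweighted k-sample log-rank test; p from chi-square with k-1 df."""
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least two groups")
    for t, e in groups:
        if len(t) == 0:
            raise ValueError("every group must be nonempty")
        if len(t) != len(e):
            raise ValueError("times and events must have equal length")
    times = np.concatenate([np.asarray(t, dtype=float) for t, _ in groups])
    events = np.concatenate([np.asarray(e, dtype=bool) for _, e in groups])
    labels = np.concatenate([np.full(len(t), i) for i, (t, _) in enumerate(groups)])
    res = multivariate_logrank_test(times, labels, events)
    observed, expected = _observed_expected(groups)
    return LogRankResult(
        statistic=float(res.test_statistic),
        df=len(groups) - 1,
        p_value=float(res.p_value),
        group_n=tuple(len(t) for t, _ in groups),
        observed=tuple(observed),
        expected=tuple(expected),
    )


# ---------------------------------------------------------------------------
# per-factor screen


def _screen_rows(factor, grouping, endpoint, groups, labels):
    """Rows for one factor/endpoint: per-level n, events, median; overall p."""
    rows = []
    test = logrank_test(groups) if len(groups) >= 2 else None
    for label, (t, e) in zip(labels, groups):
        med = median_survival(km_estimate(t, e))
        rows.append(
            {
                "factor": factor,
                "group": label,
                "grouping": grouping,
                "endpoint": endpoint,
                "n": len(t),
                "events": int(np.asarray(e, dtype=bool).sum()),
                "median_months": med.months if med.defined else np.nan,
                "median_display": str(med),
                "p_value": test.p_value if test else np.nan,
                "kind": "level",
            }
        )
    return rows


def univariate_screen(
    cohort: pd.DataFrame,
    schema: VariableSchema,
    endpoints=("pfs", "os"),
) -> pd.DataFrame:
    """Per-factor prognostic screen over the cohort.

    Categorical factors are grouped by level (multi-level factors also get
    uncorrected pairwise log-rank rows); numeric factors are dichotomized at
    their exact two-means cutoff into ``<= C`` / ``> C``. Returns a tidy
    table with one row per (factor, group, endpoint).
    """
    rows: list[dict] = []
    for endpoint in endpoints:
        tcol, ecol = ENDPOINTS[endpoint]
        times = cohort[tcol].to_numpy(dtype=float)
        events = cohort[ecol].to_numpy(dtype=bool)
        for var in schema.variables:
            if var.name not in cohort.columns:
                continue
            if var.kind == "numeric":
                values = cohort[var.name].to_numpy(dtype=float)
                if np.unique(values).size < 2:
                    rows.append(
                        {
                            "factor": var.name, "group": "all", "grouping": "constant",
                            "endpoint": endpoint, "n": len(values), "events": np.nan,
                            "median_months": np.nan, "median_display": "",
                            "p_value": np.nan, "kind": "not testable",
                        }
                    )
                    continue
                cut = kmeans_1d_cutoff(values, variable=var.name)
                lo = values <= cut.cutoff
                groups = [(times[lo], events[lo]), (times[~lo], events[~lo])]
                labels = [f"<= {cut.cutoff:g}", f"> {cut.cutoff:g}"]
                rows.extend(
                    _screen_rows(var.name, f"cutoff {cut.cutoff:g}", endpoint, groups, labels)
                )
            else:
                values = cohort[var.name].to_numpy(dtype=object)
                present = [lv for lv in var.levels if (values == lv).any()]
                if len(present) < 2:
                    rows.append(
                        {
                            "factor": var.name, "group": present[0] if present else "",
                            "grouping": "levels", "endpoint": endpoint,
                            "n": len(values), "events": np.nan,
                            "median_months": np.nan, "median_display": "",
                            "p_value": np.nan, "kind": "not testable",
                        }
                    )
                    continue
                groups = [
                    (times[values == lv], events[values == lv]) for lv in present
                ]
                rows.extend(_screen_rows(var.name, "levels", endpoint, groups, present))
                if len(present) > 2:  # uncorrected pairwise tests
                    for a, b in combinations(range(len(present)), 2):
                        pw = logrank_test([groups[a], groups[b]])
                        rows.append(
                            {
                                "factor": var.name,
                                "group": f"{present[a]} vs {present[b]}",
                                "grouping": "pairwise", "endpoint": endpoint,
                                "n": pw.group_n[0] + pw.group_n[1],
                                "events": int(sum(pw.observed)),
                                "median_months": np.nan, "median_display": "",
                                "p_value": pw.p_value, "kind": "pairwise",
                            }
                        )
    return pd.DataFrame(rows)
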