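import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmstage.survival import (
    km_estimate,
    kmeans_1d_cutoff,
    logrank_test,
    median_survival,
    univariate_screen,
)
from mmstage.synthetic import SyntheticConfig, generate_cohort

from .oracles import brute_force_1d_split, km_product_limit, logrank_statistic

# -- 1-D k-means cutoff ----------------------------------------------------


def test_cutoff_worked_example():
    res = kmeans_1d_cutoff(np.array([1.0, 2.0, 9.0, 10.0]))
    assert res.cutoff == 2.0
    assert (res.n_low, res.n_high) == (2, 2)


def test_cutoff_matches_brute_force_sample(rng):
    for _ in range(50):
        values = rng.normal(size=rng.integers(2, 30)).round(2)
        if len(np.unique(values)) < 2:
            continue
        res = kmeans_1d_cutoff(values)
        _, cutoff = brute_force_1d_split(values)
        assert res.cutoff == cutoff


@given(
    st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=60).filter(
        lambda v: len(set(v)) >= 2
    )
)
@settings(max_examples=100, deadline=None)
def test_cutoff_invariants(values):
    arr = np.array(values)
    res = kmeans_1d_cutoff(arr)
    assert arr.min() <= res.cutoff < arr.max()
    assert res.n_low >= 1 and res.n_high >= 1
    assert res.n_low + res.n_high == len(arr)
    assert res.n_low == int((arr <= res.cutoff).sum())


def test_cutoff_rejects_constant():
    with pytest.raises(ValueError):
        kmeans_1d_cutoff(np.array([5.0, 5.0, 5.0]))


# -- Kaplan-Meier ----------------------------------------------------------


def test_km_three_events():
    curve = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([True, True, True]))
    np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
    np.testing.assert_array_equal(curve.event_times, [1.0, 2.0, 3.0])


def test_km_with_censoring():
    curve = km_estimate(np.array([1.0, 2.0, 3.0]), np.array([True, False, True]))
    np.testing.assert_array_equal(curve.event_times, [1.0, 3.0])
    np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])
    assert curve.survival_at(2.0) == pytest.approx(2 / 3)


def test_km_basic_invariants(rng):
    for _ in range(20):
        n = int(rng.integers(3, 40))
        times = rng.exponential(20.0, size=n).round(1) + 0.1  # keep times > 0
        events = rng.random(n) < 0.7
        if not events.any():
            continue
        curve = km_estimate(times, events)
        s = curve.survival
        assert curve.survival_at(0.0) == 1.0
        assert (np.diff(s) <= 1e-12).all()
        assert (s >= -1e-12).all() and (s <= 1 + 1e-12).all()
        t_ref, s_ref = km_product_limit(times, events)
        np.testing.assert_array_equal(curve.event_times, t_ref)
        np.testing.assert_allclose(s, s_ref, atol=1e-12)


def test_km_rejects_negative_times():
    with pytest.raises(ValueError):
        km_estimate(np.array([-1.0, 2.0]), np.array([True, True]))


def test_median_exponential_calibration(rng):
    times = rng.exponential(24.0 / math.log(2.0), size=10_000)
    med = median_survival(km_estimate(times, np.ones_like(times, dtype=bool)))
    assert med.months == pytest.approx(24.0, rel=0.10)


def test_median_undefined_rendering():
    curve = km_estimate(np.array([5.0, 10.0, 12.0]), np.array([True, False, False]))
    med = median_survival(curve)
    assert med.months is None
    assert math.isinf(med.value_or_inf)
    assert str(med) == "> 12"


# -- log-rank --------------------------------------------------------------


def test_logrank_identical_groups_zero(rng):
    times = rng.exponential(20.0, size=30)
    events = rng.random(30) < 0.8
    res = logrank_test([(times, events), (times.copy(), events.copy())])
    assert res.statistic == pytest.approx(0.0, abs=1e-8)
    assert res.p_value == pytest.approx(1.0, abs=1e-6)


def test_logrank_matches_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(6, 40))
        times = rng.exponential(20.0, size=n).round(1)
        events = rng.random(n) < 0.7
        split = rng.integers(0, 2, size=n).astype(bool)
        if split.all() or not split.any() or not events.any():
            continue
        groups = [(times[split], events[split]), (times[~split], events[~split])]
        labels = np.where(split, 1, 0)
        res = logrank_test(groups)
        assert res.statistic == pytest.approx(
            logrank_statistic(times, events, labels), abs=1e-8
        )
        assert res.statistic >= 0
        assert sum(res.observed) == pytest.approx(sum(res.expected), abs=1e-9)


def test_logrank_validates_input(rng):
    t = rng.exponential(20.0, size=5)
    e = np.ones(5, dtype=bool)
    with pytest.raises(ValueError):
        logrank_test([(t, e)])
    with pytest.raises(ValueError):
        logrank_test([(t, e), (np.array([]), np.array([]))])


def test_logrank_power_hazard_ratio_three(rng):
    hits = 0
    for _ in range(50):
        n = 125
        t0 = rng.exponential(30.0, size=n)
        t1 = rng.exponential(10.0, size=n)  # hazard ratio 3
        ones = np.ones(n, dtype=bool)
        hits += logrank_test([(t0, ones), (t1, ones)]).p_value < 1e-3
    assert hits >= 45


# -- univariate screen -----------------------------------------------------


def test_screen_counts_sum_to_cohort(small_cohort, schema):
    table = univariate_screen(small_cohort, schema, endpoints=("pfs",))
    for _, rows in table[table["kind"] == "level"].groupby("factor"):
        assert rows["n"].sum() == len(small_cohort)


def test_screen_recovers_planted_albumin_effect(schema):
    hits = 0
    for seed in range(20):
        cohort = generate_cohort(
            SyntheticConfig(n_patients=253, seed=seed, missing_rate=0.0), schema
        )
        table = univariate_screen(cohort, schema, endpoints=("pfs",))
        level = table[table["kind"] == "level"].groupby("factor")["p_value"].min()
        null_p = min(level["calcium"], level["ldh"], level["bilirubin"])
        hits += level["albumin"] < null_p
    assert hits >= 18
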