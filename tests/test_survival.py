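"""Kaplan-Meier estimator and log-rank test, cross-checked with lifelines."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from progcnv import CnvCallMatrix, assign_groups, km_fit, log_rank
from progcnv.survival import ALTERED, UNALTERED


def _records(t1, e1, t0, e0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "os_months": np.concatenate([t1, t0]),
            "os_event": np.concatenate([e1, e0]).astype(bool),
            "group": [ALTERED] * len(t1) + [UNALTERED] * len(t0),
        }
    )


def test_product_limit_arithmetic():
    # 4 at risk, 1 death at t=2 -> S(2) = 0.75
    curve = km_fit([2.0, 3.0, 4.0, 5.0], [True, False, False, False])
    assert curve.survival_at(2.0) == pytest.approx(0.75)
    assert curve.survival_at(1.9) == 1.0


def test_no_events_gives_flat_curve_and_no_median():
    curve = km_fit([1.0, 2.0, 3.0], [False, False, False])
    assert curve.times.size == 0
    assert curve.survival_at(10.0) == 1.0
    assert curve.median is None


def test_km_without_censoring_equals_empirical_survival():
    rng = np.random.default_rng(0)
    times = rng.exponential(10, size=80)
    curve = km_fit(times, np.ones(80, dtype=bool))
    for t in np.unique(times):
        empirical = np.mean(times > t)
        assert curve.survival_at(t) == pytest.approx(empirical, abs=1e-12)


@pytest.mark.parametrize("seed", range(10))
def test_km_matches_lifelines(seed):
    rng = np.random.default_rng(seed)
    times = np.round(rng.exponential(20, size=50), 1) + 0.1
    events = rng.random(50) < 0.7
    curve = km_fit(times, events)
    kmf = KaplanMeierFitter().fit(times, events)
    for t, s in zip(curve.times, curve.survival):
        assert s == pytest.approx(
            float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-12
        )
    lifelines_median = kmf.median_survival_time_
    if np.isinf(lifelines_median):
        assert curve.median is None
    else:
        assert curve.median == pytest.approx(lifelines_median)


def test_identical_groups_give_null_statistic():
    t = np.array([3.0, 5.0, 8.0, 11.0])
    e = np.array([1, 1, 0, 1])
    result = log_rank(_records(t, e, t, e))
    assert result.statistic == pytest.approx(0.0, abs=1e-12)
    assert result.p_value == pytest.approx(1.0)


def test_complete_separation_is_significant():
    t1 = np.linspace(1, 5, 30)
    t0 = np.linspace(50, 90, 30)
    result = log_rank(_records(t1, np.ones(30), t0, np.ones(30)))
    assert result.p_value < 1e-6


def test_label_swap_invariance():
    rng = np.random.default_rng(4)
    rec = _records(rng.exponential(10, 25), rng.random(25) < 0.8,
                   rng.exponential(20, 25), rng.random(25) < 0.8)
    swapped = rec.copy()
    swapped["group"] = swapped["group"].map(
        {ALTERED: UNALTERED, UNALTERED: ALTERED}
    )
    a, b = log_rank(rec), log_rank(swapped)
    assert a.statistic == pytest.approx(b.statistic, abs=1e-12)
    assert a.p_value == pytest.approx(b.p_value, abs=1e-12)


@pytest.mark.parametrize("seed", range(20))
def test_log_rank_matches_lifelines(seed):
    rng = np.random.default_rng(100 + seed)
    n1, n0 = int(rng.integers(15, 40)), int(rng.integers(15, 40))
    t1 = np.round(rng.exponential(10, n1), 1) + 0.1  # rounding forces ties
    t0 = np.round(rng.exponential(25, n0), 1) + 0.1
    e1 = rng.random(n1) < 0.75
    e0 = rng.random(n0) < 0.75
    result = log_rank(_records(t1, e1, t0, e0))
    oracle = logrank_test(t1, t0, event_observed_A=e1, event_observed_B=e0)
    assert result.statistic == pytest.approx(oracle.test_statistic, abs=1e-8)
    assert result.p_value == pytest.approx(oracle.p_value, abs=1e-8)


def test_single_group_rejected():
    t = np.array([1.0, 2.0])
    with pytest.raises(ValueError, match="non-empty"):
        log_rank(_records(t, np.ones(2), [], []))


def test_assign_groups_from_cnv():
    samples = ["s1", "s2", "s3"]
    cnv = CnvCallMatrix(
        calls=pd.DataFrame(
            {"s1": ["GAIN", "NEUTRAL"], "s2": ["NEUTRAL", "NEUTRAL"],
             "s3": ["NEUTRAL", "LOSS"]},
            index=["A", "B"],
        ),
        cohorts=pd.Series("c", index=samples),
    )
    clinical = pd.DataFrame(
        {"sample": samples, "os_months": [10.0, 20.0, 30.0],
         "os_event": [1, 0, 1]}
    )
    groups = assign_groups(cnv, ["A", "B"], clinical)
    lookup = groups.set_index("sample")["group"]
    assert lookup["s1"] == ALTERED     # gain in A
    assert lookup["s2"] == UNALTERED   # all neutral
    assert lookup["s3"] == ALTERED     # loss counts as altered

    with pytest.raises(ValueError, match="no overlap"):
        assign_groups(cnv, ["A"], clinical.assign(sample=["x", "y", "z"]))


def test_groups_match_synthetic_truth(small_bundle):
    groups = assign_groups(
        small_bundle.cnv,
        small_bundle.truth.planted_genes,
        small_bundle.clinical,
    )
    # restrict alteration to gains only for the truth comparison: planted
    # genes may also carry background losses, so check gains are a subset
    altered = set(groups.loc[groups["group"] == ALTERED, "sample"])
    assert set(small_bundle.truth.altered_samples) <= altered


def test_type_one_error_near_nominal():
    """At hazard ratio 1 the log-rank test rejects at ~ the 5% level."""
    rng = np.random.default_rng(2024)
    n = 100
    rejections = 0
    reps = 1000
    for _ in range(reps):
        t = rng.exponential(30, n)
        cens = rng.uniform(20, 80, n)
        obs = np.minimum(t, cens)
        event = t <= cens
        group = np.where(np.arange(n) < n // 2, ALTERED, UNALTERED)
        rec = pd.DataFrame(
            {"os_months": obs, "os_event": event, "group": group}
        )
        rejections += log_rank(rec).p_value < 0.05
    rate = rejections / reps
    mc_err = 3 * np.sqrt(0.05 * 0.95 / reps)
    assert abs(rate - 0.05) < mc_err
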