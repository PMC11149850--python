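"""Discrimination, reclassification, calibration and interval statistics."""

import numpy as np
import pytest

from ppgsurv.metrics import (EXCLUDED, EVENT, NONEVENT, bootstrap_ci,
                             calibration, cfnri, clopper_pearson, harrell_c,
                             match_threshold, nri_at_threshold,
                             permutation_noninferiority, sens_spec,
                             subgroup_eval, ten_year_label)

from conftest import random_survival
from oracles import (c_index_bruteforce, cfnri_bruteforce,
                     clopper_pearson_tails, ols_slope_intercept)

Y10 = 3652.5


# ---------------------------------------------------------------------------
# Harrell's C
# ---------------------------------------------------------------------------

def test_c_perfect_and_antiperfect():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.ones(4)
    assert harrell_c(t, e, -t).estimate == 1.0
    assert harrell_c(t, e, t).estimate == 0.0


def test_c_toy_with_censoring_and_tie():
    t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    e = np.array([1, 1, 0, 1, 0, 1])
    s = np.array([3.0, 2.0, 2.0, 1.0, 0.5, 0.2])
    ours = harrell_c(t, e, s).estimate
    assert ours == pytest.approx(c_index_bruteforce(t, e, s))


def test_c_bootstrap_ci_brackets_estimate(rng):
    times, events, score = random_survival(rng, 300)
    res = harrell_c(times, events, score, bootstrap=200, seed=4)
    assert res.ci_low <= res.estimate <= res.ci_high
    res2 = harrell_c(times, events, score, bootstrap=200, seed=4)
    assert (res.ci_low, res.ci_high) == (res2.ci_low, res2.ci_high)


def test_c_requires_comparable_pairs():
    with pytest.raises(ValueError):
        harrell_c([1.0, 1.0], [0, 0], [0.1, 0.2])


# ---------------------------------------------------------------------------
# ten-year labels / operating points
# ---------------------------------------------------------------------------

def test_ten_year_label_rules():
    t = np.array([4.0, 8.0, 11.0, 9.5, 10.0]) * 365.25
    e = np.array([1, 0, 0, 1, 0])
    lab = ten_year_label(t, e, Y10)
    assert lab[0] == EVENT          # event in year 4
    assert lab[1] == EXCLUDED       # censored at 8y, no event
    assert lab[2] == NONEVENT       # followed past 10y
    assert lab[3] == EVENT
    assert lab[4] == NONEVENT       # censored exactly at the horizon


def test_sens_spec_separation_and_hand_count(rng):
    labels = np.array([EVENT] * 5 + [NONEVENT] * 15)
    scores = np.r_[np.linspace(0.8, 0.9, 5), np.linspace(0.1, 0.5, 15)]
    se, sp = sens_spec(labels, scores, 0.7)
    assert se.estimate == 1.0 and sp.estimate == 1.0
    se2, sp2 = sens_spec(labels, scores, 0.0)
    assert se2.estimate == 1.0 and sp2.estimate == 0.0
    # hand-counted toy: threshold 0.3 -> 6 of 15 non-events below
    sp3 = sens_spec(labels, scores, 0.3)[1]
    below = int(np.sum(scores[5:] < 0.3))
    assert sp3.estimate == pytest.approx(below / 15)
    with pytest.raises(ValueError):
        sens_spec(np.array([EVENT, EVENT]), np.array([0.1, 0.2]), 0.5)


def test_clopper_pearson_boundaries_and_tails():
    lo, hi = clopper_pearson(0, 10)
    assert lo == 0.0
    lo, hi = clopper_pearson(10, 10)
    assert hi == 1.0
    assert lo == pytest.approx(0.025 ** (1 / 10), abs=1e-9)
    lo, hi = clopper_pearson(3, 10)
    up, low = clopper_pearson_tails(3, 10, lo, hi)
    assert up == pytest.approx(0.025, abs=1e-9)
    assert low == pytest.approx(0.025, abs=1e-9)
    with pytest.raises(ValueError):
        clopper_pearson(1, 0)


# ---------------------------------------------------------------------------
# NRI
# ---------------------------------------------------------------------------

def test_cfnri_identity_and_maximum(rng):
    labels = np.array([EVENT] * 4 + [NONEVENT] * 4)
    s = rng.normal(size=8)
    assert cfnri(s, s, labels) == (0.0, 0.0, 0.0)
    new = np.r_[s[:4] + 1, s[4:] - 1]
    assert cfnri(s, new, labels) == (200.0, 100.0, 100.0)


def test_cfnri_toy_matches_enumeration(rng):
    for _ in range(30):
        labels = rng.choice([EVENT, NONEVENT], size=8)
        if (labels == EVENT).sum() in (0, 8):
            continue
        ref = rng.integers(0, 4, 8).astype(float)  # ties likely
        new = rng.integers(0, 4, 8).astype(float)
        ours = cfnri(ref, new, labels)
        oracle = cfnri_bruteforce(ref, new, labels)
        assert np.allclose(ours, oracle)
        overall, ev, ne = ours
        assert overall == pytest.approx(ev + ne)
        assert -100 <= ev <= 100 and -100 <= ne <= 100


def test_nri_at_threshold():
    labels = np.array([EVENT] * 3 + [NONEVENT] * 3)
    ref = np.array([0.05, 0.05, 0.05, 0.05, 0.05, 0.05])
    assert nri_at_threshold(ref, ref, labels, 0.1) == (0.0, 0.0, 0.0)
    new = np.array([0.2, 0.2, 0.2, 0.05, 0.05, 0.05])
    overall, ev, ne = nri_at_threshold(ref, new, labels, 0.1)
    assert ev == 100.0 and ne == 0.0


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_sanity():
    data = (np.arange(1.0, 101.0),)
    lo, hi = bootstrap_ci(lambda x: x.mean(), data, n_boot=1000, seed=1)
    assert lo < 50.5 < hi
    lo2, hi2 = bootstrap_ci(lambda x: 3.0, data, n_boot=100, seed=1)
    assert lo2 == hi2 == 3.0
    again = bootstrap_ci(lambda x: x.mean(), data, n_boot=1000, seed=1)
    assert (lo, hi) == again


# ---------------------------------------------------------------------------
# permutation non-inferiority
# ---------------------------------------------------------------------------

def test_permutation_identical_scores(rng):
    times, events, score = random_survival(rng, 2000, signal=0.8)
    res = permutation_noninferiority(score, score, times, events,
                                     n_perm=500, seed=2)
    assert res.delta == 0.0
    assert 0.5 <= res.p_superiority <= 1.0
    assert res.p_noninferiority < 0.05
    res2 = permutation_noninferiority(score, score, times, events,
                                      n_perm=500, seed=2)
    assert res2.p_superiority == res.p_superiority


def test_permutation_seed_reproducible(rng):
    times, events, score = random_survival(rng, 300)
    new = score + rng.normal(0, 0.5, 300)
    a = permutation_noninferiority(score, new, times, events, n_perm=300,
                                   seed=7)
    b = permutation_noninferiority(score, new, times, events, n_perm=300,
                                   seed=7)
    assert (a.p_superiority, a.p_noninferiority) == \
        (b.p_superiority, b.p_noninferiority)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

def _decile_cohort(rng, rates):
    """200 subjects in 10 prediction groups with exact event fractions."""
    preds, times, events = [], [], []
    for k, p in enumerate(rates):
        n_ev = int(round(p * 20))
        for i in range(20):
            preds.append(p + (k - 5) * 1e-6 + i * 1e-8)  # distinct values
            if i < n_ev:
                times.append(5 * 365.25)
                events.append(1)
            else:
                times.append(11 * 365.25)
                events.append(0)
    return (np.array(preds), np.array(times, dtype=float),
            np.array(events))


def test_calibration_perfect_slope_one(rng):
    rates = np.linspace(0.05, 0.5, 10)
    preds, times, events = _decile_cohort(rng, rates)
    cal = calibration(preds, times, events)
    assert cal.slope == pytest.approx(1.0, abs=1e-3)
    assert cal.mean_abs_error < 1e-3


def test_calibration_matches_ols_oracle_and_order_invariant(rng):
    rates = rng.uniform(0.05, 0.6, 10)
    preds, times, events = _decile_cohort(rng, rates)
    cal = calibration(preds, times, events)
    slope, intercept = ols_slope_intercept(cal.bin_pred, cal.bin_obs)
    assert cal.slope == pytest.approx(slope)
    assert cal.intercept == pytest.approx(intercept)
    perm = rng.permutation(preds.size)
    cal2 = calibration(preds[perm], times[perm], events[perm])
    assert cal2.slope == pytest.approx(cal.slope)


def test_calibration_overprediction_halves_slope(rng):
    rates = np.linspace(0.05, 0.5, 10)  # exact multiples of 1/20
    preds, times, events = _decile_cohort(rng, rates)
    cal = calibration(2 * preds, times, events)
    assert cal.slope == pytest.approx(0.5, abs=1e-3)
    assert cal.intercept == pytest.approx(0.0, abs=1e-3)


# ---------------------------------------------------------------------------
# threshold matching
# ---------------------------------------------------------------------------

def test_match_threshold_scan_oracle(rng):
    labels = rng.choice([EVENT, NONEVENT], size=60, p=[0.3, 0.7])
    scores = rng.normal(size=60)
    rule = (rng.random(60) < 0.4).astype(float)
    if (labels == EVENT).sum() == 0 or (labels == NONEVENT).sum() == 0:
        pytest.skip("degenerate draw")
    for target in ("sensitivity", "specificity"):
        thr = match_threshold(rule, labels, scores, target=target)
        # oracle: exhaustive scan over all candidate thresholds
        def metric(th):
            pos = scores >= th
            if target == "sensitivity":
                return np.mean(pos[labels == EVENT])
            return np.mean(~pos[labels == NONEVENT])
        ref = (np.mean(rule[labels == EVENT] >= 0.5)
               if target == "sensitivity"
               else np.mean(rule[labels == NONEVENT] < 0.5))
        cands = np.r_[scores.min() - 1, np.unique(scores), scores.max() + 1]
        ok = [c for c in cands if metric(c) >= ref]
        expected = max(ok) if target == "sensitivity" else min(ok)
        assert thr == expected
        assert metric(thr) >= ref


def test_match_threshold_fixed_mode():
    assert match_threshold(None, None, None, target="fixed",
                           fixed_value=0.10) == 0.10


def test_match_threshold_zero_specificity_reference():
    labels = np.array([EVENT] * 3 + [NONEVENT] * 3)
    scores = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
    rule = np.ones(6)  # flags everyone: specificity 0
    thr = match_threshold(rule, labels, scores, target="specificity")
    assert thr < scores.min()


# ---------------------------------------------------------------------------
# subgroups
# ---------------------------------------------------------------------------

def test_subgroup_whole_cohort_matches_global(rng):
    import pandas as pd
    times, events, score = random_survival(rng, 600, signal=0.8)
    df = pd.DataFrame({"time": times * 4000, "event": events,
                       "sex": rng.integers(0, 2, 600)})
    preds = 1 / (1 + np.exp(-score))
    table = subgroup_eval(df, score, preds, 0.5,
                          {"all": np.ones(600, dtype=bool),
                           "male": (df["sex"] == 1).to_numpy(),
                           "female": (df["sex"] == 0).to_numpy()})
    glob = harrell_c(df["time"], df["event"], score).estimate
    row = table.set_index("subgroup")
    assert row.loc["all", "c_statistic"] == pytest.approx(glob)
    assert (row.loc["male", "n_events"] + row.loc["female", "n_events"]
            == row.loc["all", "n_events"])
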