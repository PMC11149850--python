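"""Ridge Cox fitting, baseline hazard, KM/log-rank, registry plumbing."""

import numpy as np
import pandas as pd
import pytest

from ppgsurv.survival import (FEATURE_SETS, CoxRidge, fit_cox_ridge,
                              kaplan_meier, logrank_test,
                              resolve_feature_set, sbp140_score, tune_ridge)

from conftest import random_survival
from oracles import cox_grid_oracle, logrank_bruteforce


def _toy_binary_df(seed=3, n=20):
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < 0.5).astype(float)
    t = rng.exponential(np.exp(-0.8 * x))
    c = rng.uniform(0, np.quantile(t, 0.8), n)
    return pd.DataFrame({"x": x, "time": np.minimum(t, c),
                         "event": (t <= c).astype(int)})


def test_unpenalized_fit_matches_grid_oracle():
    df = _toy_binary_df()
    res = fit_cox_ridge(df, ["x"], penalty=0.0)
    oracle = cox_grid_oracle(df["x"].to_numpy(), df["time"].to_numpy(),
                             df["event"].to_numpy())
    assert abs(res.params.iloc[0] - oracle) < 1e-3


def test_huge_penalty_shrinks_to_zero():
    df = _toy_binary_df()
    res = fit_cox_ridge(df, ["x"], penalty=1e6)
    assert abs(res.params.iloc[0]) < 1e-3


def test_parameter_recovery_large_sample():
    """beta_hat within (0.6, 0.8) for true beta 0.7, n = 10,000."""
    rng = np.random.default_rng(2024)
    n = 10000
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-0.7 * x))
    cens = np.quantile(t, 0.2)
    df = pd.DataFrame({"x": x, "time": np.minimum(t, cens),
                       "event": (t <= cens).astype(int)})
    res = fit_cox_ridge(df, ["x"], penalty=0.0)
    assert 0.6 < res.params.iloc[0] < 0.8


def test_matches_lifelines_multivariate(rng):
    from lifelines import CoxPHFitter
    n = 400
    x = rng.normal(size=(n, 3))
    lp = x @ np.array([0.6, -0.4, 0.0])
    t = rng.exponential(np.exp(-lp))
    c = rng.uniform(0, np.quantile(t, 0.7), n)
    df = pd.DataFrame(x, columns=["a", "b", "c"])
    df["time"] = np.minimum(t, c)
    df["event"] = (t <= c).astype(int)
    ours = fit_cox_ridge(df, ["a", "b", "c"], penalty=0.0)
    theirs = CoxPHFitter().fit(df, "time", "event").params_
    sds = df[["a", "b", "c"]].std(ddof=0).to_numpy()
    assert np.allclose(ours.params.to_numpy() / sds,
                       theirs.to_numpy(), atol=1e-4)


def test_constant_column_rejected():
    df = _toy_binary_df()
    df["flat"] = 3.0
    with pytest.raises(ValueError):
        fit_cox_ridge(df, ["flat"])


def test_ridge_path_is_continuous():
    df = _toy_binary_df(seed=8, n=80)
    grid = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]
    betas = [fit_cox_ridge(df, ["x"], penalty=lam).params.iloc[0]
             for lam in grid]
    assert all(abs(b1 - b0) < 0.5 for b0, b1 in zip(betas, betas[1:]))
    assert all(np.sign(b) == np.sign(betas[0]) for b in betas if abs(b) > 1e-6)


def test_tune_ridge_selection(rng):
    n = 2500
    times, events, score = random_survival(rng, n, signal=0.8)
    df = pd.DataFrame({"x": score, "time": times, "event": events})
    train, tune = df.iloc[:1500], df.iloc[1500:]
    grid = (0.0, 1.0, 10.0, 1e5)
    lam, res, table = tune_ridge(train, tune, ["x"], grid=grid)
    # strong signal: the heaviest penalty cannot win
    assert lam != 1e5
    assert len(table) == len(grid)
    lam1, _, _ = tune_ridge(train, tune, ["x"], grid=(2.5,))
    assert lam1 == 2.5


def test_breslow_baseline_matches_km_when_null(rng):
    n = 1000
    t = rng.exponential(1.0, n)
    c = rng.uniform(0, 3, n)
    df = pd.DataFrame({"x": rng.normal(size=n) * 1e-8,
                       "time": np.minimum(t, c), "event": (t <= c).astype(int)})
    res = fit_cox_ridge(df, ["x"], penalty=1e8)  # effectively lp == 0
    h0 = res.baseline_cumhaz
    km = kaplan_meier(df["time"], df["event"])
    for q in (0.3, 0.6, 1.0, 1.5):
        assert abs((1 - np.exp(-h0(q))) - (1 - km(q))) < 0.02
    # no events before the first event time
    first_event = df.loc[df.event == 1, "time"].min()
    assert h0(first_event * 0.5) == 0.0
    grid_vals = h0(np.linspace(0, 3, 50))
    assert np.all(np.diff(grid_vals) >= 0)


def test_ten_year_risk_monotone_in_lp(rng):
    times, events, score = random_survival(rng, 500, signal=0.7)
    df = pd.DataFrame({"x": score, "time": times * 3000,
                       "event": events})
    res = fit_cox_ridge(df, ["x"], penalty=0.0)
    p = res.predict_10yr_risk(df)
    lp = res.predict_lp(df)
    order = np.argsort(lp)
    assert np.all(np.diff(p[order]) >= 0)
    assert np.all((p > 0) & (p < 1))


def test_ten_year_calibration_recovery(rng):
    """Decile calibration slope of predicted vs simulated true risk in
    (0.9, 1.1) on a correctly specified simulation."""
    from ppgsurv.metrics import calibration
    n = 8000
    x = rng.normal(size=n)
    lam0 = 0.004  # per year
    t_years = rng.exponential(1.0, n) / (lam0 * np.exp(0.8 * x))
    c_years = np.full(n, 12.0)
    df = pd.DataFrame({"x": x,
                       "time": np.minimum(t_years, c_years) * 365.25,
                       "event": (t_years <= c_years).astype(int)})
    res = fit_cox_ridge(df, ["x"], penalty=0.0)
    cal = calibration(res.predict_10yr_risk(df), df["time"].to_numpy(),
                      df["event"].to_numpy())
    assert 0.9 < cal.slope < 1.1


def test_kaplan_meier_hand_example():
    km = kaplan_meier([1.0, 2.0, 3.0], [1, 0, 1])
    assert km(1.0) == pytest.approx(2 / 3)
    assert km(3.0) == pytest.approx(0.0)
    assert km(0.5) == 1.0
    # no events: survival stays at 1
    km2 = kaplan_meier([1.0, 2.0], [0, 0])
    assert km2(5.0) == 1.0
    # distinct events, no censoring: empirical survival fraction
    km3 = kaplan_meier([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
    assert km3(2.5) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        kaplan_meier([-1.0], [1])


def test_logrank_identical_groups_zero():
    t = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    e = np.array([1, 0, 1, 1, 0, 1])
    g = np.array([0, 0, 0, 1, 1, 1])
    stat, p = logrank_test(g, t, e)
    assert stat == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_matches_hand_arithmetic(rng):
    for _ in range(20):
        n = 12
        t = np.round(rng.exponential(size=n), 1) + 0.1
        e = (rng.random(n) < 0.7).astype(int)
        g = rng.integers(0, 2, n)
        if e[g == 0].sum() == 0 or e[g == 1].sum() == 0:
            continue
        stat, _ = logrank_test(g, t, e)
        assert stat == pytest.approx(logrank_bruteforce(g, t, e), rel=1e-6)
    with pytest.raises(ValueError):
        logrank_test(np.zeros(4), np.arange(4.0), np.ones(4))


@pytest.mark.parametrize("sbp,expected", [(139.0, 0), (140.0, 0), (141.0, 1)])
def test_sbp140_boundary(sbp, expected):
    assert sbp140_score(np.array([sbp]))[0] == expected


def test_sbp140_missing_propagates():
    out = sbp140_score(np.array([np.nan, 150.0]))
    assert np.isnan(out[0]) and out[1] == 1.0


def test_registry_resolves_and_fits_on_synthetic_cohort(pipeline_result):
    """Every in-scope named model resolves against the cohort table and was
    fitted by the pipeline."""
    train = pipeline_result.tables["train"]
    for name in FEATURE_SETS:
        fs = resolve_feature_set(name, train)
        assert all(f in train.columns for f in fs.features)
    for name, (lam, res) in pipeline_result.models.items():
        if name == "sbp140":
            assert res is None
            continue
        assert np.all(np.isfinite(res.params.to_numpy()))
    with pytest.raises(KeyError):
        resolve_feature_set("nonexistent", train)


def test_latent_columns_refused(small_cohort):
    with pytest.raises(ValueError, match="latent"):
        CoxRidge(small_cohort.table, ["age", "_latent_s"])
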