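"""Evaluation statistics for paired risk-model comparison.

Discrimination (Harrell's C), reclassification (category-free and
threshold NRI with event / non-event components), operating-point metrics
with exact Clopper-Pearson intervals, decile calibration, percentile
bootstrap intervals, and a paired permutation test for non-inferiority of
the C-statistic at a pre-specified margin (2.5 percentage points by
default).

Binary ten-year outcomes follow one censoring rule throughout: an event
before the horizon counts as 1, follow-up past the horizon without an
event counts as 0, and subjects censored early are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

#: Ten years in days.
TEN_YEARS_DAYS = 3652.5

#: ten_year_label codes
EVENT, NONEVENT, EXCLUDED = 1, 0, -1


@dataclass(frozen=True)
class MetricResult:
    """A point estimate with an optional 95% confidence interval."""

    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None
    ci_method: str | None = None
    n_effective: int | None = None

    def __post_init__(self):
        if self.ci_low is not None and not (
                self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12):
            raise ValueError("estimate outside its confidence interval")


@dataclass(frozen=True)
class NoninferiorityResult:
    """Paired C-statistic comparison: new model versus reference."""

    delta: float                  # C(new) - C(ref), percentage points
    margin: float
    p_noninferiority: float
    p_superiority: float
    n_permutations: int


@dataclass
class CalibrationCurve:
    """Observed vs predicted ten-year rates over prediction deciles."""

    bin_pred: np.ndarray
    bin_obs: np.ndarray
    slope: float
    intercept: float
    mean_abs_error: float
    n_bins_merged: int = 0


# ---------------------------------------------------------------------------
# Harrell's C
# ---------------------------------------------------------------------------

def comparable_pairs(times, events):
    """Index arrays (i, j) of comparable pairs: t_i < t_j and subject i had
    the event.  (With tied times neither subject's time is shorter, so the
    pair is not comparable.)"""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    ev_idx = np.nonzero(events)[0]
    ii, jj = [], []
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    for i in ev_idx:
        # all j with t_j > t_i
        start = np.searchsorted(t_sorted, times[i], side="right")
        js = order[start:]
        ii.append(np.full(js.size, i))
        jj.append(js)
    if not ii:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    return np.concatenate(ii), np.concatenate(jj)


def _c_from_pairs(scores, ip, jp) -> float:
    si, sj = scores[ip], scores[jp]
    return float((np.sum(si > sj) + 0.5 * np.sum(si == sj)) / ip.size)


def harrell_c(times, events, scores, bootstrap: int = 0,
              seed: int = 0) -> MetricResult:
    """Harrell's concordance: fraction of comparable pairs ordered
    correctly by the score, ties counting one half.  A percentile
    bootstrap CI over subjects is attached when ``bootstrap`` > 0."""
    scores = np.asarray(scores, dtype=float)
    ip, jp = comparable_pairs(times, events)
    if ip.size == 0:
        raise ValueError("no comparable pairs")
    c = _c_from_pairs(scores, ip, jp)
    if not bootstrap:
        return MetricResult(c, n_effective=int(ip.size))
    lo, hi = bootstrap_ci(
        lambda t, e, s: harrell_c(t, e, s).estimate,
        (np.asarray(times, dtype=float), np.asarray(events), scores),
        n_boot=bootstrap, seed=seed)
    return MetricResult(c, min(lo, c), max(hi, c), "bootstrap_percentile",
                        int(ip.size))


# ---------------------------------------------------------------------------
# Ten-year labels and operating-point metrics
# ---------------------------------------------------------------------------

def ten_year_label(times, events, horizon_days: float = TEN_YEARS_DAYS):
    """1 = event within the horizon; 0 = followed past the horizon without
    an event; EXCLUDED (-1) = censored before the horizon event-free."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    out = np.full(times.shape, EXCLUDED, dtype=int)
    out[events & (times <= horizon_days)] = EVENT
    out[(~events | (times > horizon_days)) & (times >= horizon_days)] = NONEVENT
    return out


def clopper_pearson(k: int, n: int, alpha: float = 0.05):
    """Exact binomial confidence interval via beta quantiles."""
    if n == 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k outside [0, n]")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def sens_spec(labels, scores, threshold: float):
    """Sensitivity and specificity at ``score >= threshold``, computed on
    non-excluded subjects, with Clopper-Pearson 95% intervals."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    keep = labels != EXCLUDED
    labels, scores = labels[keep], scores[keep]
    pos = scores >= threshold
    n_ev = int(np.sum(labels == EVENT))
    n_ne = int(np.sum(labels == NONEVENT))
    if n_ev == 0 or n_ne == 0:
        raise ValueError("need at least one event and one non-event")
    tp = int(np.sum(pos & (labels == EVENT)))
    tn = int(np.sum(~pos & (labels == NONEVENT)))
    sens = MetricResult(tp / n_ev, *clopper_pearson(tp, n_ev),
                        "clopper_pearson", n_ev)
    spec = MetricResult(tn / n_ne, *clopper_pearson(tn, n_ne),
                        "clopper_pearson", n_ne)
    return sens, spec


# ---------------------------------------------------------------------------
# Net reclassification improvement
# ---------------------------------------------------------------------------

def cfnri(scores_ref, scores_new, labels):
    """Category-free NRI in percent: (overall, event, non-event).

    event     = 100 * [P(new > ref | event) - P(new < ref | event)]
    non-event = 100 * [P(new < ref | non-event) - P(new > ref | non-event)]
    Exact ties contribute zero; overall = event + non-event.
    """
    ref = np.asarray(scores_ref, dtype=float)
    new = np.asarray(scores_new, dtype=float)
    labels = np.asarray(labels)
    keep = labels != EXCLUDED
    ref, new, labels = ref[keep], new[keep], labels[keep]
    up, down = new > ref, new < ref
    ev, ne = labels == EVENT, labels == NONEVENT
    if ev.sum() == 0 or ne.sum() == 0:
        raise ValueError("need both events and non-events")
    event = 100.0 * (up[ev].mean() - down[ev].mean())
    nonevent = 100.0 * (down[ne].mean() - up[ne].mean())
    return event + nonevent, event, nonevent


def nri_at_threshold(scores_ref, scores_new, labels, threshold: float):
    """Two-category NRI at a risk threshold (high iff score >= threshold)."""
    ref = (np.asarray(scores_ref, dtype=float) >= threshold).astype(float)
    new = (np.asarray(scores_new, dtype=float) >= threshold).astype(float)
    return cfnri(ref, new, labels)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(statistic, data, n_boot: int = 1000, seed: int = 0,
                 alpha: float = 0.05, max_redraws: int = 100):
    """Percentile bootstrap over subjects; paired arrays are resampled with
    the same index draw.  Degenerate resamples (statistic raises or returns
    non-finite) are redrawn, up to ``max_redraws`` extra attempts total."""
    rng = np.random.default_rng(seed)
    arrays = [np.asarray(a) for a in data]
    n = arrays[0].shape[0]
    vals = np.empty(n_boot)
    redraws = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            v = statistic(*(a[idx] for a in arrays))
        except (ValueError, ZeroDivisionError):
            v = np.nan
        if not np.isfinite(v):
            redraws += 1
            if redraws > max_redraws:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        vals[b] = v
        b += 1
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# Paired permutation test for non-inferiority / superiority
# ---------------------------------------------------------------------------

def permutation_noninferiority(scores_ref, scores_new, times, events,
                               margin: float = 2.5, n_perm: int = 1000,
                               seed: int = 0) -> NoninferiorityResult:
    """Paired permutation test on Delta = C(new) - C(ref), percentage points.

    The null distribution exchanges the two scores within a subject with
    probability one half, independently per subject and permutation.  The
    superiority p-value is P(Delta_perm >= Delta_obs); non-inferiority
    (H0: Delta <= -margin) uses the shifted construction
    P(Delta_perm >= Delta_obs + margin).  Both are one-sided with the
    add-one correction.
    """
    if n_perm < 100:
        import warnings
        warnings.warn(f"n_perm={n_perm} is small; p-values will be coarse")
    ref = np.asarray(scores_ref, dtype=float)
    new = np.asarray(scores_new, dtype=float)
    if ref.shape != new.shape:
        raise ValueError("paired scores must align")
    ip, jp = comparable_pairs(times, events)
    if ip.size == 0:
        raise ValueError("no comparable pairs")
    delta_obs = 100.0 * (_c_from_pairs(new, ip, jp) -
                         _c_from_pairs(ref, ip, jp))
    rng = np.random.default_rng(seed)
    n = ref.size
    deltas = np.empty(n_perm)
    for b in range(n_perm):
        swap = rng.random(n) < 0.5
        r = np.where(swap, new, ref)
        s = np.where(swap, ref, new)
        deltas[b] = 100.0 * (_c_from_pairs(s, ip, jp) -
                             _c_from_pairs(r, ip, jp))
    p_sup = (1 + np.sum(deltas >= delta_obs)) / (n_perm + 1)
    p_noninf = (1 + np.sum(deltas >= delta_obs + margin)) / (n_perm + 1)
    return NoninferiorityResult(delta=float(delta_obs), margin=margin,
                                p_noninferiority=float(p_noninf),
                                p_superiority=float(p_sup),
                                n_permutations=n_perm)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibration(preds, times, events, bins: int = 10,
                horizon_days: float = TEN_YEARS_DAYS) -> CalibrationCurve:
    """Observed vs predicted event rate over prediction deciles.

    Subjects censored before the horizon are excluded; the slope and
    intercept come from ordinary least squares of the per-bin observed
    rate on the per-bin mean prediction.  Empty bins (tied predictions)
    are merged with their neighbour and counted.
    """
    preds = np.asarray(preds, dtype=float)
    labels = ten_year_label(times, events, horizon_days)
    keep = labels != EXCLUDED
    preds, labels = preds[keep], labels[keep]
    if preds.size < bins * 5:
        raise ValueError(f"need at least {bins * 5} non-excluded subjects")
    edges = np.unique(np.quantile(preds, np.linspace(0, 1, bins + 1)))
    n_merged = (bins + 1) - edges.size
    idx = np.clip(np.searchsorted(edges, preds, side="right") - 1,
                  0, edges.size - 2)
    bin_pred, bin_obs = [], []
    for b in range(edges.size - 1):
        m = idx == b
        if not np.any(m):
            n_merged += 1
            continue
        bin_pred.append(preds[m].mean())
        bin_obs.append((labels[m] == EVENT).mean())
    bin_pred = np.asarray(bin_pred)
    bin_obs = np.asarray(bin_obs)
    slope, intercept = np.polyfit(bin_pred, bin_obs, 1)
    return CalibrationCurve(bin_pred=bin_pred, bin_obs=bin_obs,
                            slope=float(slope), intercept=float(intercept),
                            mean_abs_error=float(
                                np.mean(np.abs(bin_obs - bin_pred))),
                            n_bins_merged=int(n_merged))


# ---------------------------------------------------------------------------
# Threshold matching
# ---------------------------------------------------------------------------

def _sens_spec_raw(labels, scores, threshold):
    pos = scores >= threshold
    ev, ne = labels == EVENT, labels == NONEVENT
    return (np.sum(pos & ev) / ev.sum(), np.sum(~pos & ne) / ne.sum())


def match_threshold(reference_rule_labels, labels, scores,
                    target: str = "sensitivity",
                    fixed_value: float | None = None) -> float:
    """Risk threshold whose sensitivity (or specificity) matches a binary
    reference rule's value on the same subjects.

    Sensitivity decreases with the threshold, so matching sensitivity
    returns the largest candidate threshold still achieving it (the most
    specific such operating point); matching specificity returns the
    smallest candidate achieving it.  ``target='fixed'`` returns
    ``fixed_value`` untouched (the 10% absolute-risk convention).
    """
    if target == "fixed":
        if fixed_value is None:
            raise ValueError("fixed mode needs fixed_value")
        return float(fixed_value)
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    keep = labels != EXCLUDED
    labels, scores = labels[keep], scores[keep]
    rule = np.asarray(reference_rule_labels, dtype=float)[keep]
    ref_sens, ref_spec = _sens_spec_raw(labels, rule, 0.5)
    candidates = np.concatenate([[scores.min() - 1.0], np.unique(scores),
                                 [scores.max() + 1.0]])
    achieved = []
    for thr in candidates:
        s, p = _sens_spec_raw(labels, scores, thr)
        achieved.append(s if target == "sensitivity" else p)
    achieved = np.asarray(achieved)
    ref = ref_sens if target == "sensitivity" else ref_spec
    ok = achieved >= ref
    if not np.any(ok):
        raise ValueError(f"target {target} {ref:.3f} unattainable")
    if target == "sensitivity":
        return float(candidates[np.nonzero(ok)[0].max()])
    return float(candidates[np.nonzero(ok)[0].min()])


# ---------------------------------------------------------------------------
# Subgroup evaluation
# ---------------------------------------------------------------------------

def subgroup_eval(df, scores, preds, threshold, subgroups: dict,
                  horizon_days: float = TEN_YEARS_DAYS,
                  small_bins: int = 5, min_size: int = 50):
    """Per-subgroup C, sensitivity/specificity at the global threshold and
    calibration slope.  ``subgroups`` maps name -> boolean mask (aligned
    with df) or callable(df) -> mask; small subgroups use quintile bins.
    Empty subgroups are skipped."""
    import pandas as pd
    scores = np.asarray(scores, dtype=float)
    preds = np.asarray(preds, dtype=float)
    times = df["time"].to_numpy(dtype=float)
    events = df["event"].to_numpy()
    rows = []
    for name, mask in subgroups.items():
        m = np.asarray(mask(df) if callable(mask) else mask, dtype=bool)
        n = int(m.sum())
        if n == 0:
            continue
        if n < min_size:
            import warnings
            warnings.warn(f"subgroup {name!r} has only {n} subjects")
        labels = ten_year_label(times[m], events[m], horizon_days)
        row = {"subgroup": name, "n": n,
               "n_events": int(np.sum(np.asarray(events)[m]))}
        try:
            row["c_statistic"] = harrell_c(times[m], events[m],
                                           scores[m]).estimate
        except ValueError:
            row["c_statistic"] = np.nan
        try:
            se, sp = sens_spec(labels, preds[m], threshold)
            row["sensitivity"], row["specificity"] = se.estimate, sp.estimate
        except ValueError:
            row["sensitivity"] = row["specificity"] = np.nan
        bins = small_bins if n < 10 * min_size else 10
        try:
            row["calibration_slope"] = calibration(
                preds[m], times[m], events[m], bins=bins,
                horizon_days=horizon_days).slope
        except ValueError:
            row["calibration_slope"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
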