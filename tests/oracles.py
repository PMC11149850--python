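"""Independent brute-force oracles used to cross-check the statistics.

These deliberately use naive enumeration / closed forms and share no code
with the package implementations they verify.
"""

from __future__ import annotations

import numpy as np


def c_index_bruteforce(times, events, scores) -> float:
    """Harrell's C by explicit double loop over all subject pairs."""
    n = len(times)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # comparable iff the earlier time is an event and times differ
            if times[i] < times[j] and events[i]:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def cfnri_bruteforce(ref, new, labels):
    """Category-free NRI by explicit counting (labels: 1/0/-1)."""
    up_e = dn_e = n_e = up_n = dn_n = n_n = 0
    for r, s, y in zip(ref, new, labels):
        if y == 1:
            n_e += 1
            up_e += s > r
            dn_e += s < r
        elif y == 0:
            n_n += 1
            up_n += s > r
            dn_n += s < r
    ev = 100.0 * (up_e - dn_e) / n_e
    ne = 100.0 * (dn_n - up_n) / n_n
    return ev + ne, ev, ne


def clopper_pearson_tails(k, n, lo, hi, alpha=0.05):
    """Check the defining binomial tail equations by direct summation.

    Returns (upper-tail prob at lo, lower-tail prob at hi); both should
    equal alpha/2 away from the k=0 / k=n boundaries.
    """
    from math import comb

    def binom_pmf(j, p):
        return comb(n, j) * p ** j * (1 - p) ** (n - j)

    upper_at_lo = sum(binom_pmf(j, lo) for j in range(k, n + 1))
    lower_at_hi = sum(binom_pmf(j, hi) for j in range(0, k + 1))
    return upper_at_lo, lower_at_hi


def spearman_bruteforce(x, y) -> float:
    """Spearman rho via average ranks and the Pearson formula on ranks."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2 + 1
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def ols_slope_intercept(x, y):
    """Closed-form simple least squares."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = x.mean(), y.mean()
    slope = ((x - xm) @ (y - ym)) / ((x - xm) @ (x - xm))
    return slope, ym - slope * xm


def logrank_bruteforce(groups, times, events):
    """Log-rank chi-square from the observed-minus-expected arithmetic."""
    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    labels = np.unique(groups)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        d = float(np.sum(events & (times == t)))
        n = float(at_risk.sum())
        n1 = float(np.sum(at_risk & (groups == labels[0])))
        d1 = float(np.sum(events & (times == t) & (groups == labels[0])))
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


def cox_grid_oracle(x, times, events, lo=-3.0, hi=3.0, n_grid=6001):
    """Single-covariate Cox partial likelihood maximized on a dense grid."""
    x = np.asarray(x, dtype=float)
    betas = np.linspace(lo, hi, n_grid)
    best_b, best_ll = None, -np.inf
    order = np.argsort(times)
    xs = x[order]
    es = np.asarray(events)[order].astype(bool)
    ts = np.asarray(times, dtype=float)[order]
    for b in betas:
        ll = 0.0
        for i in range(len(xs)):
            if not es[i]:
                continue
            risk = ts >= ts[i]
            ll += b * xs[i] - np.log(np.sum(np.exp(b * xs[risk])))
        if ll > best_ll:
            best_ll, best_b = ll, b
    return best_b


def interp_pointwise(src_t, src_v, t):
    """Scalar linear interpolation, coded independently of np.interp."""
    if t <= src_t[0]:
        return src_v[0]
    if t >= src_t[-1]:
        return src_v[-1]
    j = int(np.searchsorted(src_t, t, side="right")) - 1
    f = (t - src_t[j]) / (src_t[j + 1] - src_t[j])
    return src_v[j] * (1 - f) + src_v[j + 1] * f
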