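"""Second modelling stage: ridge-penalized Cox proportional-hazards models.

The ten-year risk score is a Cox model over a named feature set (age, sex,
smoking, optionally deep pulse features, morphology features, BMI/SBP or
labs).  Continuous covariates are standard-scaled with train-split
statistics; the coefficient vector maximizes the Breslow partial
likelihood minus a ridge penalty (lambda/2)*||beta||^2 via Newton-Raphson;
the baseline cumulative hazard is the Breslow step-function estimator, so
absolute ten-year risks are 1 - exp(-H0(10y) * exp(lp)).

The module follows the statsmodels convention: :class:`CoxRidge` is the
model (data + design), ``fit()`` returns :class:`CoxRidgeResults` carrying
estimates, the baseline hazard, predictions and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

#: Ten years expressed in days (survival times are in days).
TEN_YEARS_DAYS = 3652.5

#: Default ridge-penalty tuning grid (log-spaced).
DEFAULT_RIDGE_GRID = (0.0, 0.1, 1.0, 10.0, 100.0)


# ---------------------------------------------------------------------------
# Partial likelihood machinery (Breslow ties)
# ---------------------------------------------------------------------------

def _risk_set_sums(times, w, xw=None, xxw=None):
    """Tail (risk-set) sums of w, w*x, w*x x^T at each subject, tie-aware."""
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    first = np.searchsorted(t_sorted, t_sorted, side="left")
    out = []
    for arr in (w, xw, xxw):
        if arr is None:
            out.append(None)
            continue
        a = arr[order]
        tail = np.cumsum(a[::-1], axis=0)[::-1]
        out.append(tail[first])
    return order, out


def cox_loglik(lp, times, events) -> float:
    """Unpenalized Breslow log partial likelihood of a linear predictor."""
    lp = np.asarray(lp, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    shift = lp.max()
    w = np.exp(lp - shift)
    order, (s0, _, _) = _risk_set_sums(times, w)
    es = events[order]
    lps = lp[order]
    return float((lps[es] - (np.log(s0[es]) + shift)).sum())


def _loglik_grad_hess(beta, x, times, events, lam):
    lp = x @ beta
    shift = lp.max()
    w = np.exp(lp - shift)
    xw = x * w[:, None]
    xxw = np.einsum("ni,nj->nij", x, xw)
    order, (s0, s1, s2) = _risk_set_sums(times, w, xw, xxw)
    es = events[order].astype(bool)
    lps = lp[order]
    ll = (lps[es] - (np.log(s0[es]) + shift)).sum()
    mu = s1[es] / s0[es, None]
    grad = (x[order][es] - mu).sum(axis=0)
    v = s2[es] / s0[es, None, None] - np.einsum("ni,nj->nij", mu, mu)
    hess = -v.sum(axis=0)
    return (ll - 0.5 * lam * beta @ beta,
            grad - lam * beta,
            hess - lam * np.eye(beta.size))


# ---------------------------------------------------------------------------
# Covariate specification
# ---------------------------------------------------------------------------

@dataclass
class CovariateSpec:
    """Ordered features + optional age interactions + train-split scaling.

    Continuous features are standardized to (x - mean) / sd with statistics
    learned on the training data; binary (0/1) features pass through.
    Interaction terms are products of the transformed main effects.
    """

    features: list
    interactions: list = field(default_factory=list)  # (a, b) name pairs
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    binary: set = field(default_factory=set)

    @property
    def term_names(self) -> list:
        return list(self.features) + [f"{a}:{b}" for a, b in self.interactions]

    def fit(self, df: pd.DataFrame) -> "CovariateSpec":
        for a, b in self.interactions:
            if a not in self.features or b not in self.features:
                raise ValueError(f"interaction ({a},{b}) references "
                                 "features outside the spec")
        for f in self.features:
            if f.startswith("_latent"):
                raise ValueError(f"latent simulator column {f!r} may not be "
                                 "used as a model feature")
            col = df[f].astype(float)
            vals = set(np.unique(col.dropna()))
            if vals <= {0.0, 1.0}:
                self.binary.add(f)
                continue
            sd = float(col.std(ddof=0))
            if sd <= 0:
                raise ValueError(f"constant column {f!r}")
            self.means[f] = float(col.mean())
            self.sds[f] = sd
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        main = {}
        for f in self.features:
            col = df[f].to_numpy(dtype=float)
            if f not in self.binary:
                col = (col - self.means[f]) / self.sds[f]
            main[f] = col
            cols.append(col)
        for a, b in self.interactions:
            cols.append(main[a] * main[b])
        return np.column_stack(cols)

    def standardized_age(self, age_years: float, age_col: str = "age") -> float:
        if age_col in self.binary or age_col not in self.means:
            return float(age_years)
        return (age_years - self.means[age_col]) / self.sds[age_col]


# ---------------------------------------------------------------------------
# Model / results
# ---------------------------------------------------------------------------

class CoxRidge:
    """Ridge-penalized Cox proportional-hazards model.

    Parameters
    ----------
    df : DataFrame with feature columns plus duration and event columns.
    features : ordered feature names.
    penalty : ridge penalty lambda (>= 0) on the standardized coefficients.
    interactions : optional (a, b) feature-name pairs multiplied as terms.
    """

    def __init__(self, df: pd.DataFrame, features, duration_col="time",
                 event_col="event", penalty: float = 0.0, interactions=None):
        df = df.dropna(subset=list(features))  # complete-case per feature set
        if len(df) <= len(features):
            raise ValueError("more terms than subjects")
        self.spec = CovariateSpec(list(features),
                                  list(interactions or [])).fit(df)
        self.x = self.spec.transform(df)
        self.times = df[duration_col].to_numpy(dtype=float)
        self.events = df[event_col].to_numpy(dtype=int)
        self.penalty = float(penalty)
        self.n_events = int(self.events.sum())
        self.duration_col, self.event_col = duration_col, event_col
        if self.n_events < 10:
            import warnings
            warnings.warn(f"only {self.n_events} events; fit may be unstable")

    @classmethod
    def from_dataframe(cls, df, features, **kwargs) -> "CoxRidge":
        return cls(df, features, **kwargs)

    def fit(self, max_iter: int = 100, tol: float = 1e-7) -> "CoxRidgeResults":
        p = self.x.shape[1]
        beta = np.zeros(p)
        ll, grad, hess = _loglik_grad_hess(
            beta, self.x, self.times, self.events, self.penalty)
        for _ in range(max_iter):
            if np.max(np.abs(grad)) < tol:
                break
            step = np.linalg.solve(hess - 1e-12 * np.eye(p), -grad)
            # step halving keeps the penalized likelihood non-decreasing
            alpha = 1.0
            for _ in range(30):
                cand = beta + alpha * step
                ll_new, grad_new, hess_new = _loglik_grad_hess(
                    cand, self.x, self.times, self.events, self.penalty)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                alpha /= 2
            else:
                raise RuntimeError("Cox fit: step halving failed "
                                   f"(ll={ll:.6g}, |grad|={np.max(np.abs(grad)):.3g})")
            beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        else:
            raise RuntimeError(
                f"Cox fit did not converge in {max_iter} iterations "
                f"(max |grad| = {np.max(np.abs(grad)):.3g})")
        return CoxRidgeResults(model=self, params=pd.Series(
            beta, index=self.spec.term_names), loglik=ll)


class StepFunction:
    """Right-continuous step function (used for H0 and survival curves)."""

    def __init__(self, x: np.ndarray, y: np.ndarray, y0: float = 0.0):
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.y0 = y0

    def __call__(self, t):
        idx = np.searchsorted(self.x, np.asarray(t, dtype=float), side="right")
        return np.where(idx == 0, self.y0, self.y[np.maximum(idx - 1, 0)])


@dataclass
class CoxRidgeResults:
    """Fitted ridge Cox model: coefficients, baseline hazard, predictions."""

    model: CoxRidge
    params: pd.Series
    loglik: float
    _baseline: StepFunction | None = None

    # -- baseline hazard ----------------------------------------------------
    @property
    def baseline_cumhaz(self) -> StepFunction:
        """Breslow baseline cumulative hazard H0(t) from the training data."""
        if self._baseline is None:
            lp = self.model.x @ self.params.to_numpy()
            w = np.exp(lp - lp.max())
            order, (s0, _, _) = _risk_set_sums(self.model.times, w)
            t_s = self.model.times[order]
            e_s = self.model.events[order].astype(bool)
            # Breslow increment d_i / sum_{R(t_i)} exp(lp); tie groups pooled
            ev_t, counts = np.unique(t_s[e_s], return_counts=True)
            s0_at = s0[np.searchsorted(t_s, ev_t)] * np.exp(lp.max())
            h = np.cumsum(counts / s0_at)
            self._baseline = StepFunction(ev_t, h)
        return self._baseline

    # -- prediction ---------------------------------------------------------
    def predict_lp(self, df: pd.DataFrame) -> np.ndarray:
        """Linear predictor for new subjects (train-split standardization)."""
        missing = [f for f in self.model.spec.features if f not in df.columns]
        if missing:
            raise KeyError(f"missing required features: {missing}")
        return self.model.spec.transform(df) @ self.params.to_numpy()

    def predict_10yr_risk(self, df: pd.DataFrame,
                          horizon_days: float = TEN_YEARS_DAYS) -> np.ndarray:
        """Absolute event probability by the horizon: 1 - exp(-H0 e^lp)."""
        h0 = float(self.baseline_cumhaz(horizon_days))
        return 1.0 - np.exp(-h0 * np.exp(self.predict_lp(df)))

    # -- reporting ----------------------------------------------------------
    def hazard_ratios(self, at_age_years: float | None = None) -> pd.Series:
        """Per-term hazard ratios; with age interactions, the main-effect HR
        is evaluated at the given age (exp(beta_f + z_age * beta_age:f))."""
        beta = self.params
        if not self.model.spec.interactions or at_age_years is None:
            return np.exp(beta)
        z_age = self.model.spec.standardized_age(at_age_years)
        out = {}
        inter = {b: f"{a}:{b}" for a, b in self.model.spec.interactions}
        for term, b in beta.items():
            eff = b
            if term in inter:
                eff = b + z_age * beta[inter[term]]
            out[term] = np.exp(eff)
        return pd.Series(out)

    # -- persistence --------------------------------------------------------
    def to_dict(self) -> dict:
        """JSON-ready model: coefficients, scaling stats, penalty, H0."""
        h0 = self.baseline_cumhaz
        spec = self.model.spec
        return {
            "coefficients": self.params.to_dict(),
            "penalty": self.model.penalty,
            "features": list(spec.features),
            "interactions": [list(p) for p in spec.interactions],
            "means": spec.means, "sds": spec.sds,
            "binary": sorted(spec.binary),
            "baseline_cumhaz": {"times": h0.x.tolist(),
                                "values": h0.y.tolist()},
            "n": int(len(self.model.times)),
            "n_events": self.model.n_events,
        }

    def save_json(self, path) -> None:
        import json
        from pathlib import Path
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def summary(self) -> pd.DataFrame:
        """Coefficient table (per-sd units for standardized features)."""
        df = pd.DataFrame({"coef": self.params,
                           "hazard_ratio": np.exp(self.params)})
        df["standardized"] = [t.split(":")[0] not in self.model.spec.binary
                              for t in df.index]
        df.attrs["penalty"] = self.model.penalty
        df.attrs["n"] = len(self.model.times)
        df.attrs["n_events"] = self.model.n_events
        df.attrs["loglik"] = self.loglik
        return df


def fit_cox_ridge(df: pd.DataFrame, features, penalty: float = 0.0,
                  interactions=None, duration_col="time",
                  event_col="event") -> CoxRidgeResults:
    """Convenience wrapper: build and fit a :class:`CoxRidge`."""
    return CoxRidge(df, features, duration_col=duration_col,
                    event_col=event_col, penalty=penalty,
                    interactions=interactions).fit()


def tune_ridge(train_df: pd.DataFrame, tune_df: pd.DataFrame, features,
               grid=DEFAULT_RIDGE_GRID, interactions=None,
               duration_col="time", event_col="event"):
    """Pick the ridge penalty maximizing the tune-split partial likelihood.

    Each candidate is fitted on the train split; the selection criterion is
    the unpenalized Breslow log partial likelihood of the tune-split linear
    predictor.  Ties break toward the larger penalty.  Returns
    (best_lambda, fitted results at best_lambda, per-lambda table).
    """
    if len(grid) == 0:
        raise ValueError("empty penalty grid")
    tune_cc = tune_df.dropna(subset=list(features))
    rows, fits = [], {}
    for lam in grid:
        try:
            res = fit_cox_ridge(train_df, features, penalty=lam,
                                interactions=interactions,
                                duration_col=duration_col,
                                event_col=event_col)
        except RuntimeError:
            continue
        score = cox_loglik(res.predict_lp(tune_cc),
                           tune_cc[duration_col].to_numpy(),
                           tune_cc[event_col].to_numpy())
        rows.append({"penalty": lam, "tune_loglik": score})
        fits[lam] = res
    if not rows:
        raise RuntimeError("all candidate ridge fits failed")
    table = pd.DataFrame(rows)
    best_score = table["tune_loglik"].max()
    best = table.loc[np.isclose(table["tune_loglik"], best_score),
                     "penalty"].max()
    return float(best), fits[float(best)], table


# ---------------------------------------------------------------------------
# Kaplan-Meier, log-rank, SBP-140 rule
# ---------------------------------------------------------------------------

def kaplan_meier(times, events) -> StepFunction:
    """Product-limit survival estimate as a step function (S(0) = 1)."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, np.asarray(events))
    sf = kmf.survival_function_
    return StepFunction(sf.index.to_numpy(dtype=float),
                        sf.iloc[:, 0].to_numpy(dtype=float), y0=1.0)


def logrank_test(groups, times, events):
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError(f"need exactly two groups, got {labels.size}")
    a = groups == labels[0]
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    res = _ll_logrank(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


def sbp140_score(sbp):
    """Binary elevated-blood-pressure rule: 1 iff SBP strictly above 140."""
    sbp = np.asarray(sbp, dtype=float)
    out = np.where(sbp > 140.0, 1.0, 0.0)
    return np.where(np.isfinite(sbp), out, np.nan)


# ---------------------------------------------------------------------------
# Feature-set registry
# ---------------------------------------------------------------------------

METADATA = ["age", "sex", "smoking"]
MORPH_FEATURES = ["pulse_rate", "reflection_index", "peak_to_peak_time",
                  "peak_position", "notch_position", "shoulder_position",
                  "stiffness_index", "notch_present"]
DLS_PPG = ["ppg1", "ppg2", "ppg3", "ppg4", "ppg5", "ppg_hr"]


def _age_interactions(features):
    return [("age", f) for f in features if f != "age"]


@dataclass(frozen=True)
class FeatureSetDef:
    name: str
    features: tuple
    interactions: tuple = ()
    rule: str | None = None      # non-Cox scoring rules (SBP-140)


FEATURE_SETS: dict[str, FeatureSetDef] = {
    "metadata": FeatureSetDef("metadata", tuple(METADATA)),
    "office_refit_who": FeatureSetDef(
        "office_refit_who", tuple(METADATA + ["bmi", "sbp"])),
    "lab_refit_who": FeatureSetDef(
        "lab_refit_who", tuple(METADATA + ["total_cholesterol", "glucose"])),
    "metadata_morph": FeatureSetDef(
        "metadata_morph", tuple(METADATA + MORPH_FEATURES)),
    "dls": FeatureSetDef(
        "dls", tuple(METADATA + DLS_PPG),
        tuple(_age_interactions(METADATA + DLS_PPG))),
    "dls_plus": FeatureSetDef(
        "dls_plus", tuple(METADATA + DLS_PPG + ["bmi"]),
        tuple(_age_interactions(METADATA + DLS_PPG + ["bmi"]))),
    "dls_plus_plus": FeatureSetDef(
        "dls_plus_plus", tuple(METADATA + DLS_PPG + ["bmi", "sbp"]),
        tuple(_age_interactions(METADATA + DLS_PPG + ["bmi", "sbp"]))),
    "sbp140": FeatureSetDef("sbp140", ("sbp",), rule="sbp140"),
}


def resolve_feature_set(name: str, df: pd.DataFrame) -> FeatureSetDef:
    """Look up a named feature set and check it against a cohort table."""
    if name not in FEATURE_SETS:
        raise KeyError(f"unknown feature set {name!r}; "
                       f"known: {sorted(FEATURE_SETS)}")
    fs = FEATURE_SETS[name]
    missing = [f for f in fs.features if f not in df.columns]
    if missing:
        raise KeyError(f"feature set {name!r} needs missing columns {missing}")
    return fs
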