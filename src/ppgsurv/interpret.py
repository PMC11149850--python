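"""Interpretability analyses for the deep pulse features.

Three views link the learned features back to waveform physiology:
integrated-gradients saliency of the Cox log partial hazard with respect
to the input waveform (metadata held fixed, straight path from an
all-zeros baseline), quantile-averaged waveforms for any per-subject
quantity, and Spearman correlation tables between deep and engineered
morphology features, alongside coefficient/hazard-ratio reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .extractor import PPG_FEATURES, PcaProjection
from .nn import ResNet1D
from .survival import CoxRidgeResults


@dataclass
class SaliencyMap:
    """Per-timestep attributions on the unpadded waveform grid."""

    attributions: np.ndarray
    completeness_residual: float
    score: float            # F(x)
    baseline_score: float   # F(0)

    @property
    def normalized(self) -> np.ndarray:
        """Display normalization to max |value| = 1; raw values retained."""
        m = np.max(np.abs(self.attributions))
        return self.attributions / m if m > 0 else self.attributions


class DlsWaveformScorer:
    """Cox log partial hazard as a differentiable function of the waveform.

    Composes the trained encoder, the train-split PCA and the second-stage
    standardization and coefficients; the metadata contribution is an
    additive constant and is held fixed, so only the waveform path is
    differentiated.  With age interactions in the Cox model the effective
    per-feature coefficients are evaluated at a fixed reference age.
    """

    def __init__(self, network: ResNet1D, pca: PcaProjection,
                 ppg_means: np.ndarray, ppg_sds: np.ndarray,
                 betas: np.ndarray):
        self.network = network
        self.pca = pca
        self.ppg_means = np.asarray(ppg_means, dtype=float)
        self.ppg_sds = np.asarray(ppg_sds, dtype=float)
        self.betas = np.asarray(betas, dtype=float)
        # d(score)/d(embedding): fixed linear map
        self._demb = (self.pca.components.T @ (self.betas / self.ppg_sds))

    @classmethod
    def from_results(cls, network, pca, cox_results: CoxRidgeResults,
                     at_age_years: float | None = None):
        spec = cox_results.model.spec
        beta = cox_results.params
        z_age = (spec.standardized_age(at_age_years)
                 if at_age_years is not None else 0.0)
        inter = {b: f"{a}:{b}" for a, b in spec.interactions}
        eff, means, sds = [], [], []
        for f in PPG_FEATURES:
            b = beta[f]
            if f in inter and inter[f] in beta.index:
                b = b + z_age * beta[inter[f]]
            eff.append(b)
            means.append(spec.means.get(f, 0.0))
            sds.append(spec.sds.get(f, 1.0))
        return cls(network, pca, np.array(means), np.array(sds),
                   np.array(eff))

    def value(self, values: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        emb, _ = self.network.forward(values, lengths)
        scores = (emb - self.pca.mean) @ self.pca.components.T
        z = (scores - self.ppg_means) / self.ppg_sds
        return z @ self.betas

    def grad(self, values: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        self.network.forward(values, lengths)
        demb = np.tile(self._demb, (values.shape[0], 1))
        return self.network.backward(demb=demb)


def integrated_gradients(scorer, wave_values: np.ndarray,
                         steps: int = 64) -> SaliencyMap:
    """Path-integral attribution from the all-zeros baseline.

    IG_i = x_i * (1/m) * sum_{k=1..m} dF/dx_i evaluated at (k/m) x.
    The completeness residual sum(IG) - (F(x) - F(0)) is reported, never
    hidden; it shrinks as the number of path steps grows.
    """
    x = np.asarray(wave_values, dtype=float)
    n = x.size
    lengths = np.full(steps, n)
    alphas = (np.arange(1, steps + 1) / steps)[:, None]
    grads = scorer.grad(alphas * x[None, :], lengths)
    if not np.all(np.isfinite(grads)):
        raise ValueError("non-finite gradients along the attribution path")
    ig = x * grads.mean(axis=0)
    f_x = float(scorer.value(x[None, :], np.array([n]))[0])
    f_0 = float(scorer.value(np.zeros((1, n)), np.array([n]))[0])
    return SaliencyMap(attributions=ig,
                       completeness_residual=float(ig.sum() - (f_x - f_0)),
                       score=f_x, baseline_score=f_0)


def quantile_average_waves(values, waves_matrix: np.ndarray,
                           quantiles=(0.10, 0.50, 0.90), k: int = 100,
                           normalize: bool = True) -> dict:
    """Mean waveform of the k subjects nearest each quantile of a quantity.

    ``waves_matrix`` holds one fixed-length (display-space) wave per row.
    Ties in distance resolve toward the lower row index; each selected
    wave is min-max normalized before averaging unless disabled.
    """
    values = np.asarray(values, dtype=float)
    w = np.asarray(waves_matrix, dtype=float)
    if values.size < k:
        raise ValueError(f"need at least k={k} subjects, got {values.size}")
    out = {}
    for q in quantiles:
        target = np.quantile(values, q)
        dist = np.abs(values - target)
        sel = np.lexsort((np.arange(values.size), dist))[:k]
        chosen = w[np.sort(sel)]
        if normalize:
            lo = chosen.min(axis=1, keepdims=True)
            rng_ = chosen.max(axis=1, keepdims=True) - lo
            rng_[rng_ == 0] = 1.0
            chosen = (chosen - lo) / rng_
        out[q] = chosen.mean(axis=0)
    return out


def feature_correlation_table(dls_df: pd.DataFrame,
                              morph_df: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlations (average ranks for ties) between deep
    pulse features and engineered morphology features, complete cases."""
    merged = dls_df.merge(morph_df, on="id", suffixes=("", "_morph"))
    morph_cols = [c for c in morph_df.columns if c != "id"]
    rows = {}
    for f in PPG_FEATURES:
        rows[f] = {}
        for m in morph_cols:
            col = m if m in merged.columns else f"{m}_morph"
            pair = merged[[f, col]].astype(float).dropna()
            if len(pair) < 3:
                raise ValueError(f"fewer than 3 complete pairs for {f} vs {m}")
            rho = stats.spearmanr(pair[f], pair[col]).statistic
            rows[f][m] = float(rho)
    return pd.DataFrame(rows).T


def coefficient_report(results: dict[str, CoxRidgeResults],
                       median_event_age: float | None = None,
                       univariable_df: pd.DataFrame | None = None,
                       univariable_features=None) -> pd.DataFrame:
    """Coefficient / hazard-ratio table across fitted models.

    Multivariable coefficients come from each fitted model; hazard ratios
    are evaluated at the median event age when age interactions are
    present.  If a cohort frame is supplied, univariable Cox coefficients
    (one standardized feature at a time, unpenalized) are added.
    """
    from .survival import fit_cox_ridge

    frames = []
    for name, res in results.items():
        hr = res.hazard_ratios(at_age_years=median_event_age)
        df = pd.DataFrame({"model": name, "term": res.params.index,
                           "coef": res.params.to_numpy(),
                           "hazard_ratio": hr.reindex(res.params.index)})
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    if univariable_df is not None:
        uni = {}
        feats = univariable_features or sorted(
            {t for t in table["term"] if ":" not in t})
        for f in feats:
            try:
                fit = fit_cox_ridge(univariable_df, [f], penalty=0.0)
                uni[f] = float(fit.params.iloc[0])
            except (RuntimeError, ValueError, KeyError):
                uni[f] = np.nan
        table["univariable_coef"] = table["term"].map(uni)
    return table
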