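"""First modelling stage: deep survival feature extraction from pulses.

A 1-D residual CNN maps each (variable-length, zero-padded) pulse to an
embedding and a scalar risk score.  The network is trained by maximizing
the Cox partial likelihood of the risk score within each minibatch — the
standard deep-survival objective — with Breslow handling of tied event
times, and the checkpoint with the best tune-split partial likelihood is
kept.  Train-split embeddings are then reduced by PCA to five components
("PPG-1".."PPG-5"); together with the device-measured pulse rate
("PPG-HR") these are the waveform features entering the second-stage Cox
model.

The tape-speed augmentation is applied to training batches only;
embeddings are always computed on unaugmented pulses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .augment import augment_matrix
from .nn import Adam, ResNet1D
from .waveform import PaddedBatch


# ---------------------------------------------------------------------------
# Cox partial likelihood (training loss)
# ---------------------------------------------------------------------------

def _cox_order_groups(times: np.ndarray):
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    # first/last index of each tie group, per sorted position
    first = np.searchsorted(t_sorted, t_sorted, side="left")
    last = np.searchsorted(t_sorted, t_sorted, side="right") - 1
    return order, first, last


def cox_partial_nll(scores, times, events) -> float:
    """Mean negative Cox log partial likelihood (Breslow ties).

    loss = -(1/D) * sum over events i of [r_i - log sum_{j in R(t_i)} e^{r_j}]
    with R(t) the risk set {j : t_j >= t}.  Invariant to adding a constant
    to all scores and to subject reordering.
    """
    loss, _ = cox_partial_nll_grad(scores, times, events, need_grad=False)
    return loss


def cox_partial_nll_grad(scores, times, events, need_grad: bool = True):
    """Loss and its gradient with respect to the per-subject scores."""
    r = np.asarray(scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    n = r.size
    if n < 2:
        raise ValueError("need at least two subjects")
    d = int(np.sum(e))
    if d == 0:
        raise ValueError("no events: partial likelihood undefined")
    order, first, last = _cox_order_groups(t)
    rs = r[order]
    es = e[order].astype(bool)
    shift = rs.max()
    ex = np.exp(rs - shift)
    tail = np.cumsum(ex[::-1])[::-1]          # tail[k] = sum_{j>=k} e^{r_j}
    s_at = tail[first]                        # risk-set sum incl. tied times
    log_s = np.log(s_at) + shift
    loss = -(rs[es] - log_s[es]).sum() / d
    if not need_grad:
        return float(loss), None
    inv_s = np.where(es, 1.0 / s_at, 0.0)
    cum = np.cumsum(inv_s)
    g_sorted = (ex * cum[last] - es) / d      # events with t_i <= t_k (ties in)
    grad = np.empty(n)
    grad[order] = g_sorted
    return float(loss), grad


# ---------------------------------------------------------------------------
# Extractor model / results
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtractorConfig:
    """Architecture and training hyperparameters for the pulse encoder."""

    widths: tuple = (16, 32, 64, 128)
    blocks_per_stage: int = 2
    stem_kernel: int = 7
    stem_stride: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 12
    seed: int = 0
    augment_sigma: float = 0.05
    min_input_length: int = 8

    def __post_init__(self):
        if self.widths[-1] < 5:
            raise ValueError("embedding_dim (last width) must be >= 5")
        if min(self.widths) <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("config values must be positive")

    @property
    def embedding_dim(self) -> int:
        return int(self.widths[-1])


def build_extractor(config: ExtractorConfig) -> ResNet1D:
    """Instantiate the encoder with seeded He-initialized weights."""
    return ResNet1D(
        widths=config.widths,
        blocks_per_stage=config.blocks_per_stage,
        stem_kernel=config.stem_kernel,
        stem_stride=config.stem_stride,
        seed=config.seed,
    )


class PulseFeatureExtractor:
    """Deep survival feature extractor (model object).

    Built from a training and a tuning split of padded pulse batches with
    their survival outcomes; ``fit()`` trains the encoder and returns an
    :class:`ExtractorResults`.
    """

    def __init__(self, train: PaddedBatch, train_times, train_events,
                 tune: PaddedBatch, tune_times, tune_events,
                 config: ExtractorConfig | None = None):
        self.config = config or ExtractorConfig()
        if train.values.shape[1] < self.config.min_input_length:
            raise ValueError("input shorter than the receptive-field minimum")
        if np.sum(train_events) == 0 or np.sum(tune_events) == 0:
            raise ValueError("both splits must contain events")
        self.train, self.tune = train, tune
        self.train_times = np.asarray(train_times, dtype=float)
        self.train_events = np.asarray(train_events, dtype=int)
        self.tune_times = np.asarray(tune_times, dtype=float)
        self.tune_events = np.asarray(tune_events, dtype=int)

    def _tune_loss(self, net: ResNet1D) -> float:
        scores = _batched_scores(net, self.tune)
        return cox_partial_nll(scores, self.tune_times, self.tune_events)

    def fit(self, verbose: bool = False) -> "ExtractorResults":
        cfg = self.config
        net = build_extractor(cfg)
        opt = Adam(net.parameters(), lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)
        n = len(self.train)
        log_rows = []
        best = (np.inf, net.get_weights(), 0)
        for epoch in range(1, cfg.max_epochs + 1):
            perm = rng.permutation(n)
            batch_losses = []
            for start in range(0, n, cfg.batch_size):
                idx = perm[start:start + cfg.batch_size]
                if self.train_events[idx].sum() == 0:
                    continue  # risk sets empty: skip batch
                lens = self.train.lengths[idx]
                l_max = int(lens.max())
                vals = self.train.values[idx, :l_max]
                if cfg.augment_sigma > 0:
                    vals = augment_matrix(vals, lens, cfg.augment_sigma, rng)
                _, risk = net.forward(vals, lens)
                loss, grad = cox_partial_nll_grad(
                    risk, self.train_times[idx], self.train_events[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}; "
                        f"log so far: {log_rows}")
                net.backward(drisk=grad)
                opt.step(net.gradients())
                batch_losses.append(loss)
            tune_loss = self._tune_loss(net)
            log_rows.append({"epoch": epoch,
                             "train_loss": float(np.mean(batch_losses)),
                             "tune_loss": tune_loss})
            if verbose:
                print(f"epoch {epoch}: train {np.mean(batch_losses):.4f} "
                      f"tune {tune_loss:.4f}")
            if tune_loss < best[0]:
                best = (tune_loss, net.get_weights(), epoch)
        net.set_weights(best[1])
        log = pd.DataFrame(log_rows)
        return ExtractorResults(network=net, config=cfg, training_log=log,
                                best_epoch=best[2], best_tune_loss=best[0])


def _batched_scores(net: ResNet1D, batch: PaddedBatch,
                    chunk: int = 512) -> np.ndarray:
    out = np.empty(len(batch))
    for start in range(0, len(batch), chunk):
        sl = slice(start, min(start + chunk, len(batch)))
        lens = batch.lengths[sl]
        vals = batch.values[sl, :int(lens.max())]
        _, out[sl] = net.forward(vals, lens)
    return out


def _batched_embeddings(net: ResNet1D, batch: PaddedBatch,
                        chunk: int = 512) -> np.ndarray:
    out = np.empty((len(batch), net.embedding_dim))
    for start in range(0, len(batch), chunk):
        sl = slice(start, min(start + chunk, len(batch)))
        lens = batch.lengths[sl]
        vals = batch.values[sl, :int(lens.max())]
        out[sl], _ = net.forward(vals, lens)
    return out


@dataclass
class ExtractorResults:
    """Trained extractor: weights, training log, embedding computation."""

    network: ResNet1D
    config: ExtractorConfig
    training_log: pd.DataFrame
    best_epoch: int
    best_tune_loss: float

    def compute_embeddings(self, batch: PaddedBatch) -> np.ndarray:
        """Embedding matrix, one row per pulse, order-preserving."""
        return _batched_embeddings(self.network, batch)

    def risk_scores(self, batch: PaddedBatch) -> np.ndarray:
        return _batched_scores(self.network, batch)

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        """Weights in one .npz plus a JSON sidecar (config, seed, log)."""
        import dataclasses
        import hashlib
        import json
        from pathlib import Path

        path = Path(path)
        weights = self.network.get_weights()
        np.savez(path, **weights)
        digest = hashlib.sha256(
            b"".join(weights[k].tobytes() for k in sorted(weights))
        ).hexdigest()[:16]
        sidecar = {
            "config": dataclasses.asdict(self.config),
            "best_epoch": self.best_epoch,
            "best_tune_loss": self.best_tune_loss,
            "weights_sha256": digest,
            "training_log": self.training_log.to_dict(orient="records"),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "ExtractorResults":
        import json
        from pathlib import Path

        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg_dict = sidecar["config"]
        cfg_dict["widths"] = tuple(cfg_dict["widths"])
        cfg = ExtractorConfig(**cfg_dict)
        net = build_extractor(cfg)
        with np.load(path.with_suffix(".npz")) as data:
            net.set_weights({k: data[k] for k in data.files})
        return cls(network=net, config=cfg,
                   training_log=pd.DataFrame(sidecar["training_log"]),
                   best_epoch=sidecar["best_epoch"],
                   best_tune_loss=sidecar["best_tune_loss"])


# ---------------------------------------------------------------------------
# PCA reduction to the five deep pulse features
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PcaProjection:
    """Train-split PCA: mean, orthonormal loadings, explained variance."""

    mean: np.ndarray
    components: np.ndarray            # (k, embedding_dim)
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def fit_pca(train_embeddings: np.ndarray, k: int = 5) -> PcaProjection:
    """Fit PCA on train-split embeddings only (leakage-safe by contract)."""
    emb = np.asarray(train_embeddings, dtype=float)
    if emb.shape[0] <= emb.shape[1] and emb.shape[0] <= k:
        raise ValueError("need more rows than components")
    k_eff = min(k, emb.shape[1], emb.shape[0] - 1)
    pca = PCA(n_components=k_eff, svd_solver="full")
    pca.fit(emb)
    return PcaProjection(
        mean=pca.mean_.copy(),
        components=pca.components_.copy(),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
    )


def project(embeddings: np.ndarray, proj: PcaProjection) -> np.ndarray:
    """PCA scores (n x k) of embeddings under a fitted projection."""
    return (np.asarray(embeddings, dtype=float) - proj.mean) @ proj.components.T


PPG_FEATURES = ["ppg1", "ppg2", "ppg3", "ppg4", "ppg5"]


def dls_feature_frame(scores: np.ndarray, pulse_rates: np.ndarray,
                      ids) -> pd.DataFrame:
    """Assemble the deep feature set PPG-1..PPG-5 plus PPG-HR as a table."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape[1] != 5 or not np.all(np.isfinite(scores)):
        raise ValueError("expected five finite PCA scores per subject")
    df = pd.DataFrame(scores, columns=PPG_FEATURES)
    df["ppg_hr"] = np.asarray(pulse_rates, dtype=float)
    df.insert(0, "id", list(ids))
    return df
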