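"""Cox partial-likelihood loss, the CNN encoder, training, and PCA."""

import numpy as np
import pytest

from ppgsurv.extractor import (ExtractorConfig, PulseFeatureExtractor,
                               build_extractor, cox_partial_nll,
                               cox_partial_nll_grad, dls_feature_frame,
                               fit_pca, project)
from ppgsurv.waveform import PaddedBatch, UniformPulseWave, pad_batch


# ---------------------------------------------------------------------------
# partial likelihood
# ---------------------------------------------------------------------------

def test_equal_scores_single_event_is_log_n():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.array([1, 0, 0, 0])
    assert cox_partial_nll(np.zeros(4), t, e) == pytest.approx(np.log(4))


def test_two_subject_closed_form():
    loss = cox_partial_nll(np.array([1.0, 0.0]), np.array([1.0, 2.0]),
                           np.array([1, 0]))
    assert loss == pytest.approx(np.log(1 + np.exp(-1)))


def test_shift_and_permutation_invariance(rng):
    n = 30
    s = rng.normal(size=n)
    t = rng.exponential(size=n)
    e = (rng.random(n) < 0.5).astype(int)
    e[0] = 1
    base = cox_partial_nll(s, t, e)
    assert cox_partial_nll(s + 7.3, t, e) == pytest.approx(base)
    perm = rng.permutation(n)
    assert cox_partial_nll(s[perm], t[perm], e[perm]) == pytest.approx(base)


def test_zero_events_rejected(rng):
    with pytest.raises(ValueError):
        cox_partial_nll(rng.normal(size=5), np.arange(1.0, 6.0), np.zeros(5))


def test_gradient_matches_finite_differences(rng):
    n = 25
    s = rng.normal(size=n)
    t = np.round(rng.exponential(size=n), 1)  # induce ties
    e = (rng.random(n) < 0.6).astype(int)
    e[0] = 1
    loss, grad = cox_partial_nll_grad(s, t, e)
    eps = 1e-6
    for i in range(n):
        sp = s.copy()
        sp[i] += eps
        num = (cox_partial_nll(sp, t, e) - loss) / eps
        assert grad[i] == pytest.approx(num, abs=1e-5)


# ---------------------------------------------------------------------------
# encoder
# ---------------------------------------------------------------------------

def _toy_batch(rng, n=4, lengths=(40, 35, 30, 25)):
    waves = [UniformPulseWave(rng.normal(size=l).cumsum() / 10, 1000.0, 60.0)
             for l in lengths[:n]]
    return pad_batch(waves)


def test_identical_waves_give_identical_rows(rng):
    net = build_extractor(ExtractorConfig(widths=(8, 16), seed=2))
    w = rng.normal(size=40)
    values = np.stack([w, w])
    emb, risk = net.forward(values, np.array([40, 40]))
    assert np.array_equal(emb[0], emb[1])
    assert risk[0] == risk[1]
    assert emb.shape == (2, 16)


def test_padding_invariance(rng):
    net = build_extractor(ExtractorConfig(widths=(8, 16), seed=2))
    batch = _toy_batch(rng)
    emb1, _ = net.forward(batch.values, batch.lengths)
    padded = np.concatenate(
        [batch.values, np.zeros((len(batch), 10))], axis=1)
    emb2, _ = net.forward(padded, batch.lengths)
    assert np.max(np.abs(emb1 - emb2)) < 1e-6


def test_encoder_build_is_seed_deterministic():
    a = build_extractor(ExtractorConfig(seed=9))
    b = build_extractor(ExtractorConfig(seed=9))
    for k, v in a.parameters().items():
        assert np.array_equal(v, b.parameters()[k])


def _tiny_training_setup(seed=0, n=240):
    rng = np.random.default_rng(seed)
    lengths = rng.integers(25, 45, size=n)
    latent = rng.normal(size=n)
    waves = []
    for i in range(n):
        t = np.linspace(0, 1, lengths[i])
        w = np.exp(-0.5 * ((t - 0.25 - 0.05 * latent[i]) / 0.1) ** 2)
        waves.append(UniformPulseWave(w, 1000.0, 60.0))
    batch = pad_batch(waves)
    t_ev = rng.exponential(np.exp(-latent))
    cens = np.quantile(t_ev, 0.6)
    times = np.minimum(t_ev, cens)
    events = (t_ev <= cens).astype(int)
    return batch, times, events


def test_training_is_seed_reproducible_and_selects_best_epoch():
    batch, times, events = _tiny_training_setup()
    cfg = ExtractorConfig(widths=(4, 8), max_epochs=3, batch_size=64,
                          seed=5, augment_sigma=0.05)
    half = len(times) // 2
    tr = PaddedBatch(batch.values[:half], batch.lengths[:half])
    tu = PaddedBatch(batch.values[half:], batch.lengths[half:])
    args = (tr, times[:half], events[:half], tu, times[half:], events[half:])
    res1 = PulseFeatureExtractor(*args, config=cfg).fit()
    res2 = PulseFeatureExtractor(*args, config=cfg).fit()
    for k, v in res1.network.get_weights().items():
        assert np.array_equal(v, res2.network.get_weights()[k])
    log = res1.training_log
    assert res1.best_tune_loss <= log["tune_loss"].iloc[0]
    assert res1.best_epoch == int(log.loc[log["tune_loss"].idxmin(), "epoch"])


def test_training_requires_events():
    batch, times, events = _tiny_training_setup()
    with pytest.raises(ValueError):
        PulseFeatureExtractor(batch, times, np.zeros_like(events),
                              batch, times, events)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_orthonormal_centered_and_matches_eigendecomposition(rng):
    emb = rng.normal(size=(50, 8)) @ rng.normal(size=(8, 8))
    proj = fit_pca(emb, k=5)
    assert np.allclose(proj.components @ proj.components.T, np.eye(5),
                       atol=1e-8)
    assert np.all(np.diff(proj.explained_variance_ratio) <= 1e-12)
    scores = project(emb, proj)
    assert np.max(np.abs(scores.mean(axis=0))) < 1e-8
    # reconstruction error equals the eigendecomposition oracle's
    centered = emb - emb.mean(axis=0)
    recon = scores @ proj.components
    err = np.sum((centered - recon) ** 2)
    evals = np.sort(np.linalg.eigvalsh(centered.T @ centered))
    assert err == pytest.approx(evals[:3].sum(), abs=1e-8)


def test_dls_feature_frame_validates(rng):
    scores = rng.normal(size=(4, 5))
    df = dls_feature_frame(scores, np.full(4, 60.0), ids=range(4))
    assert list(df.columns) == ["id", "ppg1", "ppg2", "ppg3", "ppg4",
                                "ppg5", "ppg_hr"]
    with pytest.raises(ValueError):
        dls_feature_frame(rng.normal(size=(4, 4)), np.full(4, 60.0),
                          ids=range(4))
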