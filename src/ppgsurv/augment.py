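"""Brownian tape-speed augmentation for pulse waveforms.

During extractor training each pulse is re-read at a randomly varying
"tape speed": a latent log-speed follows a Brownian random walk, the
cumulative speed defines warped sample times, and the wave is linearly
interpolated at those times after pinning both endpoints.  The warp is
strictly monotone, so the order of morphological landmarks (systolic
peak, dicrotic notch, reflected peak) is preserved while their timing
jitters — emulating natural beat-to-beat timing variability.

Augmentation is applied only while training the feature extractor, never
when computing embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .waveform import UniformPulseWave


@dataclass(frozen=True)
class TapeSpeedParams:
    """Parameters of the tape-speed warp.

    sigma is the per-step standard deviation of the Brownian log-speed
    increments (dimensionless); 0 disables the warp.
    """

    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


def _warped_times(n: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Monotone warped time grid on [0, n-1] (grid-step units)."""
    # Brownian log tape speed; exp() keeps speeds positive => warp monotone.
    w = np.concatenate([[0.0], np.cumsum(rng.normal(0.0, sigma, size=n - 1))])
    speed = np.exp(w)
    tau = np.concatenate([[0.0], np.cumsum(speed[:-1])])
    # Rescale so the warp fixes both endpoints (pinned exactly).
    tau *= (n - 1) / tau[-1]
    tau[-1] = n - 1
    return tau


def brownian_tape_speed(
    wave: UniformPulseWave,
    params: TapeSpeedParams,
    rng: np.random.Generator | None = None,
) -> UniformPulseWave:
    """Apply a random monotone time-warp to a uniform-grid pulse.

    With ``sigma == 0`` the input is reproduced exactly.  Output length,
    grid step and endpoints are unchanged, and every output value lies
    within the input range (linear interpolation).
    """
    if params.sigma < 0:
        raise ValueError("sigma must be >= 0")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = len(wave)
    if params.sigma == 0 or n < 3:
        return wave
    tau = _warped_times(n, params.sigma, rng)
    out = np.interp(tau, np.arange(n, dtype=float), wave.samples)
    return UniformPulseWave(
        samples=out,
        pulse_period_ms=wave.pulse_period_ms,
        pulse_rate_bpm=wave.pulse_rate_bpm,
        dt_ms=wave.dt_ms,
    )


def augment(
    wave: UniformPulseWave,
    params: TapeSpeedParams,
    rng: np.random.Generator | None = None,
) -> UniformPulseWave:
    """Single augmentation entry point (tape-speed warp).

    Kept as a named indirection so an alternative warp formulation can be
    swapped in without touching training code.
    """
    return brownian_tape_speed(wave, params, rng)


def augment_matrix(
    values: np.ndarray,
    lengths: np.ndarray,
    sigma: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized-ish warp of a zero-padded batch matrix (training path)."""
    out = values.copy()
    if sigma == 0:
        return out
    for i in range(values.shape[0]):
        n = int(lengths[i])
        if n < 3:
            continue
        tau = _warped_times(n, sigma, rng)
        out[i, :n] = np.interp(tau, np.arange(n, dtype=float), values[i, :n])
    return out
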