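"""Single-pulse PPG waveform preprocessing.

The UK-Biobank-style pulse oximeter summarizes each recording as a single
pulse waveform stretched to 100 temporal units regardless of heart rate,
together with the pulse rate measured during the recording.  Because the
physical duration of the pulse varies with heart rate, the 100 samples sit
on a subject-specific time grid.  This module converts such records onto a
shared uniform grid (18.2 ms per step), rescales amplitudes to [0, 1], and
packs variable-length waves into zero-padded batches for the convolutional
feature extractor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

#: Uniform resampling grid step in milliseconds.
DT_MS = 18.2

#: Number of samples in a summarized device pulse.
N_DEVICE_SAMPLES = 100


class WaveformError(ValueError):
    """Raised for invalid or degenerate pulse records."""


@dataclass(frozen=True)
class RawPulseWave:
    """A device-summarized pulse: 100 amplitude samples plus the pulse rate.

    Parameters
    ----------
    samples
        Exactly 100 finite amplitude values in arbitrary device units.
    pulse_rate_bpm
        Pulse rate during the recording, beats per minute, in (20, 250).
    """

    samples: np.ndarray
    pulse_rate_bpm: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size != N_DEVICE_SAMPLES:
            raise WaveformError(
                f"expected {N_DEVICE_SAMPLES} samples, got shape {samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            raise WaveformError("non-finite sample values")
        if not (20.0 < self.pulse_rate_bpm < 250.0):
            raise WaveformError(
                f"pulse rate {self.pulse_rate_bpm} bpm outside (20, 250)"
            )
        object.__setattr__(self, "samples", samples)

    @property
    def pulse_period_ms(self) -> float:
        return 60000.0 / self.pulse_rate_bpm


@dataclass(frozen=True)
class UniformPulseWave:
    """A pulse on the uniform 18.2 ms grid.

    ``samples[k]`` is the amplitude at time ``k * dt_ms``; the grid covers
    one pulse period, so ``len(samples) == floor(period / dt) + 1``.
    """

    samples: np.ndarray
    pulse_period_ms: float
    pulse_rate_bpm: float
    dt_ms: float = DT_MS

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(len(self)) * self.dt_ms


def uniform_length(pulse_rate_bpm: float, dt_ms: float = DT_MS) -> int:
    """Length of the uniform-grid pulse for a given pulse rate."""
    period_ms = 60000.0 / pulse_rate_bpm
    return int(np.floor(period_ms / dt_ms)) + 1


def resample_to_uniform(
    raw: RawPulseWave, dt_ms: float = DT_MS, endpoint_divisor: int = 99
) -> UniformPulseWave:
    """Resample a 100-sample device pulse onto the uniform time grid.

    The 100 device samples are taken to span exactly one pulse period with
    spacing ``period / endpoint_divisor`` (both endpoints included for the
    default divisor of 99).  Values on the uniform grid ``t_k = k * dt_ms``
    are obtained by linear interpolation, so every output value lies within
    the input range and a constant wave resamples exactly.
    """
    period = raw.pulse_period_ms
    src_t = np.arange(N_DEVICE_SAMPLES) * (period / endpoint_divisor)
    dst_t = np.arange(int(np.floor(period / dt_ms)) + 1) * dt_ms
    out = np.interp(dst_t, src_t, raw.samples)
    return UniformPulseWave(
        samples=out,
        pulse_period_ms=period,
        pulse_rate_bpm=raw.pulse_rate_bpm,
        dt_ms=dt_ms,
    )


def normalize_amplitude(wave: UniformPulseWave) -> UniformPulseWave:
    """Min-max rescale a pulse to [0, 1].  Idempotent; rejects flat waves."""
    lo = float(np.min(wave.samples))
    hi = float(np.max(wave.samples))
    if hi <= lo:
        raise WaveformError("flat waveform (max == min); record rejected")
    return UniformPulseWave(
        samples=(wave.samples - lo) / (hi - lo),
        pulse_period_ms=wave.pulse_period_ms,
        pulse_rate_bpm=wave.pulse_rate_bpm,
        dt_ms=wave.dt_ms,
    )


@dataclass
class PaddedBatch:
    """Zero-padded batch of variable-length uniform pulses.

    ``values`` is ``n x L_max``; entries beyond each row's valid length are
    exactly zero.  ``lengths`` holds per-row valid lengths and ``ids``
    optional participant identifiers aligned with rows.
    """

    values: np.ndarray
    lengths: np.ndarray
    ids: np.ndarray | None = None
    dt_ms: float = DT_MS
    pulse_rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=int)

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def mask(self) -> np.ndarray:
        """Boolean n x L_max validity mask."""
        return np.arange(self.values.shape[1])[None, :] < self.lengths[:, None]

    def unpad(self) -> list[np.ndarray]:
        """Recover the original variable-length sample arrays."""
        return [self.values[i, : self.lengths[i]].copy() for i in range(len(self))]


def pad_batch(
    waves: Sequence[UniformPulseWave],
    length: int | str = "auto",
    ids: Sequence | None = None,
) -> PaddedBatch:
    """Right-pad uniform pulses with zeros into a single matrix."""
    if not waves:
        raise WaveformError("empty batch")
    lengths = np.array([len(w) for w in waves], dtype=int)
    l_max = int(lengths.max()) if length == "auto" else int(length)
    if l_max < lengths.max():
        raise WaveformError(
            f"pad length {l_max} smaller than longest wave ({lengths.max()})"
        )
    values = np.zeros((len(waves), l_max), dtype=float)
    for i, w in enumerate(waves):
        values[i, : lengths[i]] = w.samples
    rates = np.array([w.pulse_rate_bpm for w in waves], dtype=float)
    return PaddedBatch(
        values=values,
        lengths=lengths,
        ids=None if ids is None else np.asarray(ids),
        dt_ms=waves[0].dt_ms,
        pulse_rates=rates,
    )


def preprocess_waves(
    raws: Iterable[RawPulseWave],
) -> list[UniformPulseWave]:
    """Resample + normalize a sequence of raw pulses (the model input path)."""
    return [normalize_amplitude(resample_to_uniform(r)) for r in raws]


# ---------------------------------------------------------------------------
# I/O: CSV (one row per participant) and HDF5 containers
# ---------------------------------------------------------------------------

def read_waveform_csv(path) -> tuple[list[RawPulseWave], np.ndarray]:
    """Read raw pulses from CSV with columns id, pulse_rate_bpm, s000..s099."""
    df = pd.read_csv(path)
    cols = [f"s{i:03d}" for i in range(N_DEVICE_SAMPLES)]
    waves = [
        RawPulseWave(row[cols].to_numpy(dtype=float), float(row["pulse_rate_bpm"]))
        for _, row in df.iterrows()
    ]
    return waves, df["id"].to_numpy()


def write_waveform_csv(path, waves: Sequence[RawPulseWave], ids: Sequence) -> None:
    cols = [f"s{i:03d}" for i in range(N_DEVICE_SAMPLES)]
    df = pd.DataFrame([w.samples for w in waves], columns=cols)
    df.insert(0, "pulse_rate_bpm", [w.pulse_rate_bpm for w in waves])
    df.insert(0, "id", list(ids))
    df.to_csv(path, index=False)


def write_waveform_h5(path, waves: Sequence[RawPulseWave], ids: Sequence) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=np.stack([w.samples for w in waves]))
        f.create_dataset(
            "pulse_rate", data=np.array([w.pulse_rate_bpm for w in waves])
        )
        f.create_dataset("ids", data=np.asarray(ids))


def read_waveform_h5(path) -> tuple[list[RawPulseWave], np.ndarray]:
    with h5py.File(path, "r") as f:
        samples = f["samples"][...]
        rates = f["pulse_rate"][...]
        ids = f["ids"][...]
    waves = [RawPulseWave(s, float(r)) for s, r in zip(samples, rates)]
    return waves, ids


def write_batch_h5(path, batch: PaddedBatch) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=batch.values)
        f.create_dataset("lengths", data=batch.lengths)
        if batch.ids is not None:
            f.create_dataset("ids", data=batch.ids)


def read_batch_h5(path) -> PaddedBatch:
    with h5py.File(path, "r") as f:
        values = f["values"][...]
        lengths = f["lengths"][...]
        ids = f["ids"][...] if "ids" in f else None
    return PaddedBatch(values=values, lengths=lengths, ids=ids)
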