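"""Engineered pulse-waveform morphology features.

A finger-pulse waveform superimposes the direct systolic ejection wave and
a wave reflected from the periphery.  Classical vascular-ageing features
summarize that geometry:

* reflection index — reflected-peak over direct-peak amplitude ratio (%),
  a measure of peripheral reflection;
* peak-to-peak time — transit delay between direct and reflected peaks;
* stiffness index — subject height divided by the peak-to-peak time (m/s),
  a surrogate for large-artery pulse-wave velocity;
* positions of the systolic peak, dicrotic notch and the "shoulder"
  (inflection on the systolic downstroke), plus notch presence.

These features drive the metadata+morphology comparison model and the
correlation tables used to interpret the learned deep features.  All times
are reported in milliseconds on the uniform grid, never in sample indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .waveform import UniformPulseWave

#: Fraction of the pulse searched for the direct (systolic) peak.  The
#: reflected peak in stiff-vessel morphologies can rival the direct peak
#: in amplitude, so the search is restricted to the early pulse.
PEAK_SEARCH_FRACTION = 0.6


@dataclass
class PulseLandmarks:
    """Detected pulse landmarks; absent landmarks are None, never guessed."""

    peak_time_ms: float
    peak_amp: float
    notch_time_ms: float | None = None
    notch_amp: float | None = None
    reflected_peak_time_ms: float | None = None
    reflected_amp: float | None = None
    shoulder_time_ms: float | None = None
    notch_confident: bool = True


@dataclass
class MorphFeatures:
    """Per-subject engineered morphology feature vector."""

    pulse_rate_bpm: float
    peak_position_ms: float
    notch_present: bool
    reflection_index_pct: float | None = None
    peak_to_peak_time_ms: float | None = None
    notch_position_ms: float | None = None
    shoulder_position_ms: float | None = None
    stiffness_index_m_per_s: float | None = None

    def as_dict(self) -> dict:
        return {
            "pulse_rate": self.pulse_rate_bpm,
            "reflection_index": self.reflection_index_pct,
            "peak_to_peak_time": self.peak_to_peak_time_ms,
            "peak_position": self.peak_position_ms,
            "notch_position": self.notch_position_ms,
            "shoulder_position": self.shoulder_position_ms,
            "stiffness_index": self.stiffness_index_m_per_s,
            "notch_present": self.notch_present,
        }


def _local_minima(x: np.ndarray) -> np.ndarray:
    """Indices of strict interior local minima."""
    idx = np.nonzero((x[1:-1] < x[:-2]) & (x[1:-1] <= x[2:]))[0] + 1
    return idx


def _local_maxima(x: np.ndarray) -> np.ndarray:
    idx = np.nonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:]))[0] + 1
    return idx


def detect_landmarks(
    wave: UniformPulseWave,
    peak_fraction: float = PEAK_SEARCH_FRACTION,
    smooth: bool = True,
) -> PulseLandmarks:
    """Detect systolic peak, dicrotic notch, reflected peak and shoulder.

    The systolic peak is the global maximum within the first
    ``peak_fraction`` of the pulse.  The notch is the most *prominent*
    strict local minimum after the peak — the one with the largest
    rebound to a later maximum; prominence rather than depth is used
    because on a decaying pulse the deepest post-systolic minimum sits in
    the near-zero diastolic tail, not at the notch.  When no local
    minimum exists, the maximum of the second difference after the peak
    serves as a lower-confidence fallback only if it marks a genuine
    concavity change.  The reflected peak is the largest local maximum
    after the notch, and the shoulder is the first sign change of the
    second difference on the downstroke between peak and notch.  A light
    1-2-1 smoothing pass (on by default) suppresses noise-induced
    single-sample extrema.
    """
    x = wave.samples
    n = x.size
    if n < 10:
        raise ValueError("waveform too short for landmark detection")
    if smooth:
        x = np.convolve(x, [0.25, 0.5, 0.25], mode="same")
        x[0], x[-1] = wave.samples[0], wave.samples[-1]
    dt = wave.dt_ms

    end = max(2, int(np.ceil(n * peak_fraction)))
    peak_idx = int(np.argmax(x[:end]))
    lm = PulseLandmarks(peak_time_ms=peak_idx * dt, peak_amp=float(x[peak_idx]))

    after = x[peak_idx:]
    minima = _local_minima(after)
    notch_idx = None
    if minima.size:
        # running max of the segment after each candidate minimum
        rebound = np.array(
            [after[m:].max() - after[m] for m in minima])
        best = int(np.argmax(rebound))
        notch_idx = peak_idx + int(minima[best])
        lm.notch_confident = True
    else:
        # Shallow-notch fallback: strongest upward concavity after the peak.
        if after.size >= 5:
            d2 = np.diff(after, 2)
            j = int(np.argmax(d2))
            if d2[j] > 0:
                notch_idx = peak_idx + j + 1
                lm.notch_confident = False
    if notch_idx is not None and notch_idx < n - 1:
        lm.notch_time_ms = notch_idx * dt
        lm.notch_amp = float(x[notch_idx])
        tail = x[notch_idx:]
        maxima = _local_maxima(tail)
        if maxima.size:
            r = notch_idx + int(maxima[np.argmax(tail[maxima])])
            lm.reflected_peak_time_ms = r * dt
            lm.reflected_amp = float(x[r])
        # Shoulder: first inflection (second-difference sign change) on the
        # downstroke between peak and notch.
        seg = x[peak_idx : notch_idx + 1]
        if seg.size >= 4:
            d2 = np.diff(seg, 2)
            sign = np.sign(d2)
            flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
            if flips.size:
                lm.shoulder_time_ms = (peak_idx + flips[0] + 1) * dt
    return lm


def reflection_index(lm: PulseLandmarks) -> float | None:
    """Reflected-to-direct peak amplitude ratio in percent."""
    if lm.reflected_amp is None:
        return None
    if lm.peak_amp <= 0:
        raise ValueError("direct peak amplitude must be positive")
    return 100.0 * lm.reflected_amp / lm.peak_amp


def peak_to_peak_time(lm: PulseLandmarks) -> float | None:
    """Transit time between direct and reflected peaks (ms)."""
    if lm.reflected_peak_time_ms is None:
        return None
    dt = lm.reflected_peak_time_ms - lm.peak_time_ms
    if dt <= 0:
        raise ValueError("reflected peak must follow the direct peak")
    return dt


def stiffness_index(lm: PulseLandmarks, height_m: float) -> float | None:
    """Height / peak-to-peak transit time, in m/s."""
    if not (1.2 < height_m < 2.2):
        raise ValueError(f"implausible height {height_m} m")
    ptp = peak_to_peak_time(lm)
    if ptp is None:
        return None
    return height_m / (ptp / 1000.0)


def morphology_features(
    wave: UniformPulseWave,
    pulse_rate_bpm: float | None = None,
    height_m: float | None = None,
) -> MorphFeatures:
    """All engineered morphology features for one pulse.

    Absent optional landmarks propagate as missing values; the function
    never raises for missing notch/reflected peak.
    """
    lm = detect_landmarks(wave)
    notch_present = lm.notch_time_ms is not None and lm.notch_confident
    si = None
    if height_m is not None and lm.reflected_peak_time_ms is not None:
        si = stiffness_index(lm, height_m)
    return MorphFeatures(
        pulse_rate_bpm=(
            pulse_rate_bpm if pulse_rate_bpm is not None else wave.pulse_rate_bpm
        ),
        peak_position_ms=lm.peak_time_ms,
        notch_present=notch_present,
        reflection_index_pct=reflection_index(lm),
        peak_to_peak_time_ms=peak_to_peak_time(lm),
        notch_position_ms=lm.notch_time_ms,
        shoulder_position_ms=lm.shoulder_time_ms,
        stiffness_index_m_per_s=si,
    )


def morphology_table(
    waves: Sequence[UniformPulseWave],
    ids: Sequence,
    heights_m: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Feature table (one row per participant) for a batch of pulses."""
    rows = []
    for i, w in enumerate(waves):
        h = None if heights_m is None else float(heights_m[i])
        rows.append(morphology_features(w, height_m=h).as_dict())
    df = pd.DataFrame(rows)
    df.insert(0, "id", list(ids))
    return df
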