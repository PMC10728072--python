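"""Respiratory phase extraction.

Three steps, each exposed separately:

1. :func:`respiratory_peak_frequency` - per-participant breathing peak
   frequency as the maximum of Welch power in a 0.1-0.5 Hz search band;
2. :func:`detect_inhalation_peaks` - inhalation peak times from the
   smoothed trace (z-score, moving-mean smoothing, positive-going zero
   crossing -> local maximum, refractory half a breathing period);
3. :func:`respiration_phase` - instantaneous phase from a zero-phase
   Butterworth band-pass around the peak frequency (+/- 0.05 Hz) followed
   by a Hilbert transform. Phase is 0 at inhalation peaks and wraps in
   (-pi, pi].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .filters import filter_band_butter, hilbert_envelope, hilbert_phase

logger = logging.getLogger(__name__)

__all__ = [
    "RespirationPhase",
    "FlatSignalError",
    "detect_inhalation_peaks",
    "respiratory_peak_frequency",
    "respiration_phase",
]


class FlatSignalError(ValueError):
    """Respiration trace has no usable variance."""


@dataclass
class RespirationPhase:
    """Instantaneous respiratory phase and its provenance."""

    phase: np.ndarray            # radians in (-pi, pi], 0 = inhalation peak
    envelope: np.ndarray         # instantaneous amplitude (a.u.)
    peak_freq: float             # Hz
    band: tuple[float, float]    # filter band actually used
    inhalation_peaks: np.ndarray  # seconds
    fs: float

    def at(self, times: np.ndarray) -> np.ndarray:
        """Phase at arbitrary times (nearest sample)."""
        idx = np.clip(np.round(np.asarray(times) * self.fs).astype(int), 0, self.phase.size - 1)
        return self.phase[idx]


def respiratory_peak_frequency(
    resp: np.ndarray,
    fs: float,
    search_band: tuple[float, float] = (0.1, 0.5),
    min_duration_s: float = 300.0,
) -> float:
    """Frequency of maximal Welch power within ``search_band``."""
    resp = np.asarray(resp, dtype=float)
    if resp.size / fs < min_duration_s:
        raise ValueError(f"need at least {min_duration_s:.0f} s of respiration signal")
    nperseg = min(resp.size, int(round(120.0 * fs)))
    freqs, power = signal.welch(resp - resp.mean(), fs=fs, nperseg=nperseg)
    in_band = (freqs >= search_band[0]) & (freqs <= search_band[1])
    if not in_band.any():
        raise ValueError(f"search band {search_band} empty at fs={fs}")
    peak = float(freqs[in_band][np.argmax(power[in_band])])
    logger.info("respiratory peak frequency %.3f Hz", peak)
    return peak


def detect_inhalation_peaks(
    resp: np.ndarray,
    fs: float,
    peak_freq: float | None = None,
) -> np.ndarray:
    """Inhalation peak times (s), strictly increasing.

    The trace is z-scored, smoothed with a moving mean of width a quarter
    of the breathing period, and each positive-going zero crossing opens a
    candidate breath: the peak is the maximum of the smoothed trace before
    the next negative-going crossing. A refractory period of half a
    breathing period suppresses double detections (the larger peak wins).
    """
    resp = np.asarray(resp, dtype=float)
    if resp.size < 60 * fs:
        raise ValueError("need at least 60 s of respiration signal")
    sd = resp.std()
    if sd < 1e-12:
        raise FlatSignalError("respiration signal is flat")
    if peak_freq is None:
        peak_freq = respiratory_peak_frequency(resp, fs, min_duration_s=min(300.0, resp.size / fs))
    z = (resp - resp.mean()) / sd
    win = max(int(round(0.25 / peak_freq * fs)), 1)
    kernel = np.full(win, 1.0 / win)
    smooth = np.convolve(np.pad(z, (win // 2, win - 1 - win // 2), mode="edge"), kernel, mode="valid")

    pos = smooth > 0
    up = np.flatnonzero(~pos[:-1] & pos[1:]) + 1
    down = np.flatnonzero(pos[:-1] & ~pos[1:]) + 1
    peaks = []
    for onset in up:
        following = down[down > onset]
        end = following[0] if following.size else smooth.size
        peaks.append(onset + int(np.argmax(smooth[onset:end])))

    refractory = 0.5 / peak_freq * fs
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < refractory:
            if smooth[p] > smooth[kept[-1]]:
                kept[-1] = p
        else:
            kept.append(p)
    times = np.asarray(kept, dtype=float) / fs
    logger.info("detected %d inhalation peaks (peak freq %.3f Hz)", times.size, peak_freq)
    return times


def respiration_phase(
    resp: np.ndarray,
    fs: float,
    peak_freq: float,
    halfband: float = 0.05,
    inhalation_peaks: np.ndarray | None = None,
) -> RespirationPhase:
    """Instantaneous respiratory phase around the peak frequency.

    Band-pass ``peak_freq +/- halfband`` (zero-phase Butterworth), then
    Hilbert transform. By construction the analytic-signal phase is ~0 at
    maxima of the filtered trace, matching the inhalation-peak convention.
    """
    if peak_freq - halfband <= 0:
        raise ValueError(f"band ({peak_freq - halfband:.3f}, {peak_freq + halfband:.3f}) Hz "
                         "has a non-positive low edge")
    band = (peak_freq - halfband, peak_freq + halfband)
    filtered = filter_band_butter(np.asarray(resp, dtype=float), fs, band)
    phase = hilbert_phase(filtered)
    envelope = hilbert_envelope(filtered)
    if inhalation_peaks is None:
        inhalation_peaks = detect_inhalation_peaks(resp, fs, peak_freq=peak_freq)
    return RespirationPhase(
        phase=phase, envelope=envelope, peak_freq=float(peak_freq),
        band=band, inhalation_peaks=np.asarray(inhalation_peaks, dtype=float), fs=float(fs),
    )
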