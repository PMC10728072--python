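"""Zero-phase filtering primitives shared across the pipeline.

Two filter families are used throughout:

* wide detection bands (slow oscillations 0.3-1.25 Hz, spindles 12-18 Hz,
  narrow 1-Hz amplitude bins) use a windowed-sinc FIR whose length is
  ``3 / f_low`` seconds of taps ("three cycles of the low-frequency
  cutoff"), applied forward and backward;
* the very narrow respiration band (peak frequency +/- 0.05 Hz) uses a
  3rd-order Butterworth applied forward-backward (``sosfiltfilt``), which
  stays numerically stable where an equally narrow FIR would need
  impractically many taps.

Both are zero-phase, which matters: any phase lag introduced by filtering
would bias every phase-coupling estimate downstream.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = [
    "fir_bandpass_taps",
    "filter_bandpass_fir",
    "filter_band_butter",
    "moving_rms",
    "hilbert_phase",
    "hilbert_envelope",
]


def fir_bandpass_taps(
    band: tuple[float, float],
    fs: float,
    cycles: float = 3.0,
    max_taps: int | None = None,
) -> np.ndarray:
    """Design linear-phase band-pass taps with length ``cycles / band[0]`` s.

    The filter length convention follows the common practice of sizing a
    band-pass FIR by a number of cycles of its low cutoff, so very low
    bands get proportionally longer filters.
    """
    low, high = band
    if not 0 < low < high:
        raise ValueError(f"invalid band {band!r}")
    if high >= fs / 2:
        raise ValueError(f"band {band!r} exceeds Nyquist ({fs / 2} Hz)")
    n_taps = int(round(cycles / low * fs))
    if max_taps is not None:
        n_taps = min(n_taps, int(max_taps))
    n_taps = max(n_taps, int(0.05 * fs))
    if n_taps % 2 == 0:
        n_taps += 1
    return signal.firwin(n_taps, [low, high], pass_zero=False, fs=fs)


def _reflect_pad(x: np.ndarray, n_pad: int) -> np.ndarray:
    n_pad = min(n_pad, x.shape[-1] - 1)
    left = 2 * x[..., :1] - x[..., 1 : n_pad + 1][..., ::-1]
    right = 2 * x[..., -1:] - x[..., -n_pad - 1 : -1][..., ::-1]
    return np.concatenate([left, x, right], axis=-1), n_pad


def filter_bandpass_fir(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float],
    cycles: float = 3.0,
    max_taps: int | None = None,
) -> np.ndarray:
    """Two-pass (zero-phase) FIR band-pass along the last axis.

    The symmetric kernel is applied twice via FFT convolution (forward and
    backward passes of a linear-phase FIR are identical), with odd-symmetric
    edge padding as in :func:`scipy.signal.filtfilt`, so the magnitude
    response is squared and the phase response is identically zero.
    """
    x = np.asarray(x, dtype=float)
    if max_taps is None:
        max_taps = max(x.shape[-1] // 3, 11)
    taps = fir_bandpass_taps(band, fs, cycles=cycles, max_taps=max_taps)
    half = len(taps) // 2
    padded, n_pad = _reflect_pad(x, 2 * half)
    for _ in range(2):
        padded = signal.fftconvolve(padded, taps[np.newaxis, :] if padded.ndim == 2 else taps, mode="same", axes=-1)
    return padded[..., n_pad : n_pad + x.shape[-1]]


def filter_band_butter(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float],
    order: int = 3,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (``sosfiltfilt``) along the last axis."""
    low, high = band
    if low <= 0:
        raise ValueError(f"band {band!r}: low edge must be positive")
    if high >= fs / 2:
        raise ValueError(f"band {band!r} exceeds Nyquist ({fs / 2} Hz)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    try:
        return signal.sosfiltfilt(sos, x, axis=-1)
    except ValueError as exc:  # pragma: no cover - pathological inputs
        raise ValueError(f"Butterworth band {band!r} unstable or input too short: {exc}") from exc


def moving_rms(x: np.ndarray, fs: float, window_s: float = 0.2) -> np.ndarray:
    """Root-mean-square of ``x`` in a centred moving window of ``window_s``."""
    n = max(int(round(window_s * fs)), 1)
    kernel = np.full(n, 1.0 / n)
    # centred moving average of the squared signal; edges use shrinking
    # effective windows through edge-value padding
    sq = np.pad(np.asarray(x, dtype=float) ** 2, (n // 2, n - 1 - n // 2), mode="edge")
    return np.sqrt(np.convolve(sq, kernel, mode="valid"))


def hilbert_phase(x: np.ndarray) -> np.ndarray:
    """Instantaneous phase of the analytic signal, in (-pi, pi]."""
    return np.angle(signal.hilbert(np.asarray(x, dtype=float)))


def hilbert_envelope(x: np.ndarray) -> np.ndarray:
    """Instantaneous amplitude (analytic-signal modulus)."""
    return np.abs(signal.hilbert(np.asarray(x, dtype=float)))
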