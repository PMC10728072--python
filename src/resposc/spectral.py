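"""Inhalation-locked time-frequency analysis, respiration-phase ->
EEG-amplitude modulation index, and phase-slope-index directionality.

TFR: sliding Hanning-tapered Fourier power, window length five cycles of
each frequency (1-25 Hz in 1-Hz steps), 50-ms steps, averaged over
inhalation-locked segments, z-scored across time per frequency within
[-2, 2] s.

Modulation index (MI): the respiratory phase series is split into 20
bins; the mean EEG amplitude per bin, normalized to sum 1, is compared to
the uniform distribution by Kullback-Leibler divergence, normalized by
log(n_bins) so MI lies in [0, 1]. Significance comes from a surrogate
z-score: the phase series is circularly shifted by 200 random offsets of
at least 10 s, destroying phase-amplitude alignment while preserving both
marginals.

Phase-slope index (PSI): directionality between respiration and the slow
amplitude dynamics of band-limited EEG. Because respiration (~0.25 Hz)
and, e.g., spindle activity (12-18 Hz) share no Fourier frequencies, the
coherency is computed between the narrowband-filtered respiration and the
Hilbert amplitude envelope of the band-filtered EEG, and the phase slope
is evaluated across the respiration band. Positive PSI = respiration
leads (drives) the EEG envelope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .filters import filter_band_butter, filter_bandpass_fir, hilbert_envelope
from .respiration import RespirationPhase

logger = logging.getLogger(__name__)

__all__ = [
    "tfr_power_timeseries",
    "tfr_locked",
    "tfr_contrast",
    "modulation_index",
    "MIResult",
    "mi_z",
    "cross_psi",
    "psi_resp_eeg",
    "psi_group",
]


# ---------------------------------------------------------------------------
# time-frequency


def tfr_power_timeseries(
    x: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    cycles: float = 5.0,
) -> np.ndarray:
    """Instantaneous Hanning-tapered Fourier power of ``x`` per frequency.

    For each frequency the signal is convolved with a complex exponential
    under a Hann taper of length ``cycles / f`` seconds (amplitude-
    normalized); returns (n_freqs, n_samples) power.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty((len(freqs), x.size))
    for i, f in enumerate(freqs):
        n_win = int(round(cycles / f * fs))
        if n_win < 3:
            raise ValueError(f"window too short at {f} Hz")
        if n_win > x.size:
            raise ValueError(
                f"signal too short for {cycles} cycles at {f} Hz "
                f"(needs {n_win / fs:.1f} s)"
            )
        taper = np.hanning(n_win)
        t = np.arange(n_win) / fs
        kernel = taper * np.exp(-2j * np.pi * f * t)
        kernel /= taper.sum() / 2.0  # amplitude normalization
        analytic = sp_signal.fftconvolve(x, kernel[::-1].conj(), mode="same")
        out[i] = np.abs(analytic) ** 2
    return out


def tfr_locked(
    x: np.ndarray,
    fs: float,
    anchor_times: np.ndarray,
    freqs: np.ndarray | None = None,
    window_s: float = 2.0,
    step_s: float = 0.05,
    cycles: float = 5.0,
    z_score: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Event-locked average TFR, z-scored across time per frequency.

    Power is computed on the continuous signal, sampled on a
    [-window_s, window_s] grid of ``step_s`` around each anchor (anchors
    too close to the edges for the longest analysis window are dropped),
    averaged over anchors, then z-scored across the time axis per
    frequency (``z_score=False`` returns the raw averaged power instead;
    note that per-frequency z-scoring expresses temporal modulation, not
    absolute power, so comparisons *across* frequencies need the raw
    map). Returns ``(tfr, time_grid)`` with tfr of shape
    (n_freqs, n_times).
    """
    if freqs is None:
        freqs = np.arange(1.0, 26.0)
    freqs = np.asarray(freqs, dtype=float)
    power = tfr_power_timeseries(x, fs, freqs, cycles=cycles)
    margin = window_s + cycles / freqs.min() / 2.0
    anchors = np.asarray(anchor_times, dtype=float)
    anchors = anchors[(anchors >= margin) & (anchors <= x.size / fs - margin)]
    if anchors.size == 0:
        raise ValueError("no anchors far enough from the signal edges")
    grid = np.arange(-window_s, window_s + step_s / 2, step_s)
    idx = np.round((anchors[:, None] + grid[None, :]) * fs).astype(int)
    avg = power[:, idx].mean(axis=1)  # (n_freqs, n_times)
    if not z_score:
        return avg, grid
    mean = avg.mean(axis=1, keepdims=True)
    sd = avg.std(axis=1, keepdims=True)
    z = (avg - mean) / np.where(sd > 0, sd, 1.0)
    return z, grid


def tfr_contrast(
    event_tfrs: np.ndarray,
    random_tfrs: np.ndarray,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = 0,
):
    """Cluster-permutation contrast of per-participant event-locked vs
    randomly-centred TFR stacks (time x frequency lattice adjacency)."""
    from .stats import cluster_test

    return cluster_test(event_tfrs, random_tfrs, n_permutations=n_permutations,
                        alpha=alpha, seed=seed)


# ---------------------------------------------------------------------------
# modulation index


def modulation_index(
    phase: np.ndarray,
    amplitude: np.ndarray,
    n_bins: int = 20,
) -> float:
    """Normalized Kullback-Leibler modulation index in [0, 1].

    The phase series is split into ``n_bins`` bins over (-pi, pi]; the
    per-bin mean amplitude, normalized to sum 1, is compared with the
    uniform distribution: MI = KL(P || U) / log(n_bins). MI is 0 iff the
    binned amplitude profile is flat and 1 when all amplitude concentrates
    in a single bin.
    """
    phase = np.asarray(phase, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if phase.shape != amplitude.shape:
        raise ValueError("phase and amplitude series must have equal length")
    bins = np.clip(((phase + np.pi) / (2 * np.pi) * n_bins).astype(int), 0, n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins)
    if (counts == 0).any():
        raise ValueError("empty phase bin: provide a longer input series")
    mean_amp = np.bincount(bins, weights=amplitude, minlength=n_bins) / counts
    total = mean_amp.sum()
    if total <= 0:
        return 0.0
    p = mean_amp / total
    nonzero = p > 0
    kl = np.sum(p[nonzero] * np.log(p[nonzero] * n_bins))
    return float(kl / np.log(n_bins))


@dataclass
class MIResult:
    """Modulation index across frequency bins with surrogate statistics."""

    freqs: np.ndarray            # bin centers, Hz
    mi_raw: np.ndarray
    surrogate_mean: np.ndarray
    surrogate_sd: np.ndarray
    z: np.ndarray
    p: np.ndarray
    significant: np.ndarray      # |z| > 1.96


def mi_z(
    resp_phase: RespirationPhase | np.ndarray,
    eeg: np.ndarray,
    fs: float,
    freq_centers: np.ndarray | None = None,
    bandwidth_hz: float = 1.0,
    n_bins: int = 20,
    n_surrogates: int = 200,
    min_shift_s: float = 10.0,
    seed: int | np.random.Generator | None = 0,
) -> MIResult:
    """Surrogate-normalized modulation index across EEG frequency bins.

    For each center frequency the EEG is band-passed (two-pass FIR, length
    three cycles of the low edge; the low edge is floored at 0.25 Hz for
    the lowest bin) and its Hilbert envelope provides the amplitude. The
    raw MI is z-scored against ``n_surrogates`` circular shifts of the
    phase series by uniform offsets in [min_shift_s, T - min_shift_s].
    Bins whose surrogate SD vanishes get NaN z (flagged non-significant).
    """
    phase = resp_phase.phase if isinstance(resp_phase, RespirationPhase) else np.asarray(resp_phase)
    eeg = np.asarray(eeg, dtype=float)
    if phase.size != eeg.size:
        raise ValueError("phase and EEG series must have equal length")
    if freq_centers is None:
        freq_centers = np.arange(0.5, 25.0, 1.0)
    freq_centers = np.asarray(freq_centers, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = phase.size
    lo_shift = int(min_shift_s * fs)
    if n <= 2 * lo_shift:
        raise ValueError("signal too short for the requested surrogate shifts")
    shifts = rng.integers(lo_shift, n - lo_shift, size=n_surrogates)

    bins = np.clip(((phase + np.pi) / (2 * np.pi) * n_bins).astype(int), 0, n_bins - 1)
    log_nb = np.log(n_bins)

    def mi_from_bins(b: np.ndarray, amp: np.ndarray) -> float:
        counts = np.bincount(b, minlength=n_bins)
        if (counts == 0).any():
            raise ValueError("empty phase bin: provide a longer input series")
        mean_amp = np.bincount(b, weights=amp, minlength=n_bins) / counts
        p = mean_amp / mean_amp.sum()
        nz = p > 0
        return float(np.sum(p[nz] * np.log(p[nz] * n_bins)) / log_nb)

    mi_raw = np.empty(freq_centers.size)
    surr_mean = np.empty(freq_centers.size)
    surr_sd = np.empty(freq_centers.size)
    z = np.full(freq_centers.size, np.nan)
    for i, fc in enumerate(freq_centers):
        low = max(fc - bandwidth_hz / 2.0, 0.25)
        band = (low, fc + bandwidth_hz / 2.0)
        amp = hilbert_envelope(filter_bandpass_fir(eeg, fs, band, max_taps=n // 3))
        mi_raw[i] = mi_from_bins(bins, amp)
        surr = np.empty(n_surrogates)
        for s, shift in enumerate(shifts):
            surr[s] = mi_from_bins(np.roll(bins, shift), amp)
        surr_mean[i], surr_sd[i] = surr.mean(), surr.std(ddof=1)
        if surr_sd[i] > 0:
            z[i] = (mi_raw[i] - surr_mean[i]) / surr_sd[i]
        else:
            logger.warning("surrogate SD = 0 at %.1f Hz: z undefined", fc)
    p = 2 * sp_stats.norm.sf(np.abs(z))
    significant = np.abs(z) > 1.96
    significant[~np.isfinite(z)] = False
    return MIResult(freq_centers, mi_raw, surr_mean, surr_sd, z, p, significant)


# ---------------------------------------------------------------------------
# phase-slope index


def cross_psi(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: tuple[float, float],
    nperseg: int | None = None,
) -> float:
    """Phase-slope index between two same-domain signals over ``band``.

    PSI = -Im sum_f conj(C(f)) C(f + df) over Welch frequencies in the
    band, with C the complex coherency; the sign convention makes PSI
    positive when ``x`` leads (drives) ``y``. Antisymmetric under argument
    exchange by construction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("signals must have equal length")
    if nperseg is None:
        nperseg = int(16.0 * fs)
    if x.size < 2 * nperseg:
        raise ValueError("too few segments for coherency estimation "
                         f"(need at least {2 * nperseg} samples)")
    noverlap = nperseg // 2
    f, pxy = sp_signal.csd(x, y, fs=fs, nperseg=nperseg, noverlap=noverlap)
    _, pxx = sp_signal.welch(x, fs=fs, nperseg=nperseg, noverlap=noverlap)
    _, pyy = sp_signal.welch(y, fs=fs, nperseg=nperseg, noverlap=noverlap)
    denom = np.sqrt(pxx * pyy)
    coh = np.where(denom > 0, pxy / np.where(denom > 0, denom, 1.0), 0.0)
    sel = np.flatnonzero((f >= band[0]) & (f <= band[1]))
    if sel.size < 1 or sel[-1] + 1 >= f.size:
        raise ValueError(f"band {band} too narrow for the spectral resolution {f[1] - f[0]:.4f} Hz")
    psi = -np.imag(np.sum(np.conj(coh[sel]) * coh[sel + 1]))
    return float(psi)


def psi_resp_eeg(
    resp: np.ndarray,
    eeg: np.ndarray,
    fs: float,
    eeg_band: tuple[float, float],
    resp_peak_freq: float = 0.25,
    resp_halfband: float = 0.05,
    cycles_per_segment: float = 4.0,
) -> float:
    """Directionality between respiration and band-limited EEG activity.

    The respiration trace is filtered around its peak frequency
    (+/- ``resp_halfband``); the EEG is filtered to ``eeg_band`` and
    reduced to its Hilbert amplitude envelope; the PSI is evaluated across
    the respiration band with Welch segments of ``cycles_per_segment``
    breathing cycles (50% overlap, Hann). Positive = respiration drives
    the EEG band.
    """
    resp_band = (resp_peak_freq - resp_halfband, resp_peak_freq + resp_halfband)
    resp_f = filter_band_butter(np.asarray(resp, dtype=float), fs, resp_band)
    envelope = hilbert_envelope(filter_bandpass_fir(np.asarray(eeg, dtype=float), fs, eeg_band))
    nperseg = int(round(cycles_per_segment / resp_peak_freq * fs))
    return cross_psi(resp_f, envelope - envelope.mean(), fs, resp_band, nperseg=nperseg)


def psi_group(psi_values: np.ndarray) -> tuple[float, float]:
    """One-sample two-sided t test of per-participant PSI values against 0.

    Returns ``(t, p)``; degenerate zero-variance input yields NaN t with a
    warning-level log entry.
    """
    values = np.asarray(psi_values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 participants")
    if np.ptp(values) == 0:
        if np.allclose(values, 0):
            return 0.0, 1.0
        logger.warning("zero-variance PSI values: t undefined")
        return float("nan"), float("nan")
    t, p = sp_stats.ttest_1samp(values, 0.0)
    return float(t), float(p)
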