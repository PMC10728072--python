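"""Synthetic nap cohorts with known ground truth.

Each synthetic participant consists of

* a quasi-periodic respiration trace (~0.25 Hz) built from cycles whose
  periods jitter around the nominal period; the waveform is an asymmetric
  phase-warped cosine (inhalation shorter than exhalation), so inhalation
  peaks are not trivially equispaced maxima;
* 1/f background EEG per channel;
* embedded slow oscillations (SO), sleep spindles, and coupled
  SO_spindle complexes whose occurrence phases relative to respiration
  follow von Mises distributions with configurable preferred phase and
  concentration. Respiration is made genuinely *causal*: an event placed
  at preferred phase mu is triggered by the phase the respiratory
  oscillator held ``event_delay_s`` earlier, so directionality measures
  see respiration leading the EEG;
* a per-participant memory-reactivation score linearly linked (with
  Gaussian noise) to the true respiration-SO_spindle coupling strength
  (resultant vector length) at the representative frontal channel.

True event times, true phases, true coupling summaries and all seeds are
recorded in :class:`GroundTruth`, so every downstream stage can be
validated without recorded data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from .config import SimulationConfig
from .io import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruth",
    "generate_respiration",
    "generate_background",
    "make_so_waveform",
    "make_spindle_waveform",
    "generate_participant",
    "generate_cohort",
    "noise_sd_for_r2",
]

_PLACEMENT_MARGIN_S = 6.0


@dataclass
class GroundTruth:
    """True structure of one synthetic participant.

    ``events`` has one row per embedded event: channel, kind (SO, SPINDLE,
    SO_SPINDLE), time_s (SO downstate / spindle onset; for SO_SPINDLE the
    SO downstate), resp_phase (true respiratory phase at that time),
    coupled flag, and spindle_time_s for SO_SPINDLE rows.
    """

    participant: str
    events: pd.DataFrame
    inhalation_peaks: np.ndarray
    true_phase: np.ndarray
    coupling: pd.DataFrame          # channel, kind, mean_angle, vector_length, n
    reactivation_score: float
    seed: int
    shortfall: dict = field(default_factory=dict)

    def times(self, kind: str, channel: str) -> np.ndarray:
        sel = self.events[(self.events["kind"] == kind) & (self.events["channel"] == channel)]
        return sel["time_s"].to_numpy()

    def phases(self, kind: str, channel: str) -> np.ndarray:
        sel = self.events[(self.events["kind"] == kind) & (self.events["channel"] == channel)]
        return sel["resp_phase"].to_numpy()


# ---------------------------------------------------------------------------
# elementary generators


def generate_respiration(
    duration_s: float,
    resp_freq: float = 0.25,
    jitter: float = 0.08,
    seed: int | np.random.Generator | None = 0,
    fs: float = 200.0,
    asymmetry: float = 0.47,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quasi-periodic respiration trace with ground-truth phase.

    Returns ``(trace, inhalation_peak_times, phase_series)``. Cycle
    periods are drawn from a normal distribution with SD ``jitter`` times
    the nominal period (clipped to 0.4-1.6 of nominal). Within a cycle the
    trace is a phase-warped cosine: the inhalation peak sits a fraction
    ``asymmetry`` into the cycle (measured trough to trough), so the true
    phase - linear in cycle fraction on each flank, 0 at the inhalation
    peak, +/-pi at the troughs - wraps in (-pi, pi].
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if resp_freq <= 0:
        raise ValueError("resp_freq must be positive")
    if not 0 <= jitter < 0.5:
        raise ValueError("jitter must be in [0, 0.5)")
    if not 0.1 < asymmetry < 0.9:
        raise ValueError("asymmetry must be in (0.1, 0.9)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    period = 1.0 / resp_freq

    n_cycles = int(np.ceil(duration_s / period * 1.3)) + 4
    periods = rng.normal(period, jitter * period, size=n_cycles)
    periods = np.clip(periods, 0.4 * period, 1.6 * period)
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])  # trough times

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    cycle = np.searchsorted(boundaries, t, side="right") - 1
    u = (t - boundaries[cycle]) / periods[cycle]  # fraction of cycle, 0 at trough
    phase = np.where(
        u <= asymmetry,
        -np.pi * (1.0 - u / asymmetry),
        np.pi * (u - asymmetry) / (1.0 - asymmetry),
    )
    trace = np.cos(phase)
    peak_times = boundaries[:-1] + asymmetry * periods
    peak_times = peak_times[(peak_times > 0) & (peak_times < duration_s)]
    return trace, peak_times, phase


def generate_background(
    duration_s: float,
    fs: float = 200.0,
    noise_exponent: float = 1.0,
    seed: int | np.random.Generator | None = 0,
    sd: float = 1.0,
) -> np.ndarray:
    """Zero-mean 1/f^exponent noise of SD ``sd``, generated by spectral shaping."""
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nonzero = freqs > 0
    shaping[nonzero] = freqs[nonzero] ** (-noise_exponent / 2.0)
    shaping[0] = 0.0
    trace = np.fft.irfft(spectrum * shaping, n=n)
    trace -= trace.mean()
    scale = trace.std()
    return trace * (sd / scale) if scale > 0 else trace


def make_so_waveform(amplitude_uv: float, duration_s: float, fs: float = 200.0) -> np.ndarray:
    """Biphasic SO template: one full sine cycle, trough first.

    Positive-to-negative zero crossings sit exactly at the two ends (spacing
    ``duration_s``); the downstate trough is at a quarter of the duration.
    """
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    return -amplitude_uv * np.sin(2 * np.pi * t / duration_s)


SO_TROUGH_FRACTION = 0.25  # trough position within the SO template


def make_spindle_waveform(
    freq_hz: float, duration_s: float, amplitude_uv: float, fs: float = 200.0
) -> np.ndarray:
    """Spindle template: sinusoid under a Hann envelope, zero at both ends."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    return amplitude_uv * np.sin(2 * np.pi * freq_hz * t) * np.hanning(n)


# ---------------------------------------------------------------------------
# event placement


def _phase_to_cycle_fraction(theta: np.ndarray, asymmetry: float) -> np.ndarray:
    """Invert the asymmetric phase warp: phase -> fraction of cycle (0 = trough)."""
    theta = np.asarray(theta, dtype=float)
    return np.where(
        theta <= 0,
        asymmetry * (1.0 + theta / np.pi),
        asymmetry + (1.0 - asymmetry) * theta / np.pi,
    )


def _cycle_fraction_to_phase(u: np.ndarray, asymmetry: float) -> np.ndarray:
    u = np.mod(u, 1.0)
    return np.where(
        u <= asymmetry,
        -np.pi * (1.0 - u / asymmetry),
        np.pi * (u - asymmetry) / (1.0 - asymmetry),
    )


def _phase_to_times(
    target_phases: np.ndarray,
    phase: np.ndarray,
    fs: float,
    delay_s: float,
    resp_freq: float,
    allowed: np.ndarray,
    rng: np.random.Generator,
    asymmetry: float = 0.47,
    margin_s: float = _PLACEMENT_MARGIN_S,
) -> np.ndarray:
    """Map target phases to event times via the unwrapped true phase.

    For each target phase theta the oscillator's *trigger* phase is the
    phase held ``delay_s`` earlier in a nominal cycle (the asymmetric
    warp makes the phase rate non-uniform, so the back-shift is done in
    cycle-fraction space); the event occurs ``delay_s`` after the
    oscillator crossed the trigger phase in a randomly chosen breath cycle.
    Returns one candidate time per target (NaN when no allowed cycle fits).
    """
    unwrapped = np.unwrap(phase)
    t = np.arange(phase.size) / fs
    lo, hi = unwrapped[0], unwrapped[-1]
    times = np.full(target_phases.size, np.nan)
    u_pre = _phase_to_cycle_fraction(target_phases, asymmetry) - delay_s * resp_freq
    triggers = _cycle_fraction_to_phase(u_pre, asymmetry)
    for i, trigger in enumerate(triggers):
        k_min = int(np.ceil((lo - trigger) / (2 * np.pi)))
        k_max = int(np.floor((hi - trigger) / (2 * np.pi)))
        if k_max < k_min:
            continue
        for k in rng.permutation(np.arange(k_min, k_max + 1))[:20]:
            level = trigger + 2 * np.pi * k
            idx = np.searchsorted(unwrapped, level)
            if idx <= 0 or idx >= unwrapped.size:
                continue
            frac = (level - unwrapped[idx - 1]) / max(unwrapped[idx] - unwrapped[idx - 1], 1e-12)
            t_event = t[idx - 1] + frac / fs + delay_s
            sample = int(round(t_event * fs))
            if margin_s <= t_event <= t[-1] - margin_s and allowed[min(sample, allowed.size - 1)]:
                times[i] = t_event
                break
    return times


def _place_events(
    n_events: int,
    mu: float,
    kappa: float,
    phase: np.ndarray,
    fs: float,
    delay_s: float,
    resp_freq: float,
    allowed: np.ndarray,
    occupied: list[float],
    min_gap_s: float,
    rng: np.random.Generator,
    asymmetry: float = 0.47,
    max_rounds: int = 6,
) -> np.ndarray:
    """Draw von Mises phases and place events with a same-kind minimum gap."""
    accepted: list[float] = list(occupied)
    placed: list[float] = []
    for _ in range(max_rounds):
        need = n_events - len(placed)
        if need <= 0:
            break
        thetas = rng.vonmises(mu, kappa, size=need) if kappa > 0 else rng.uniform(-np.pi, np.pi, need)
        candidates = _phase_to_times(thetas, phase, fs, delay_s, resp_freq, allowed, rng,
                                     asymmetry=asymmetry)
        for t_event in candidates:
            if np.isnan(t_event):
                continue
            if accepted and np.min(np.abs(np.asarray(accepted) - t_event)) < min_gap_s:
                continue
            accepted.append(t_event)
            placed.append(t_event)
            if len(placed) >= n_events:
                break
    return np.sort(np.asarray(placed))


def _phase_at(phase: np.ndarray, fs: float, times: np.ndarray) -> np.ndarray:
    idx = np.clip(np.round(np.asarray(times) * fs).astype(int), 0, phase.size - 1)
    return phase[idx]


def _add_waveform(channel_data: np.ndarray, waveform: np.ndarray, start_s: float, fs: float) -> None:
    start = int(round(start_s * fs))
    stop = min(start + waveform.size, channel_data.size)
    if start >= 0 and stop > start:
        channel_data[start:stop] += waveform[: stop - start]


def _circ_stats(phases: np.ndarray) -> tuple[float, float]:
    if phases.size == 0:
        return np.nan, np.nan
    m = np.exp(1j * phases).mean()
    return float(np.angle(m)), float(np.abs(m))


# ---------------------------------------------------------------------------
# participant / cohort


def _default_hypnogram(config: SimulationConfig) -> list[str]:
    n_epochs = int(np.ceil(config.duration_s / config.epoch_len_s))
    # N2 with an N3 block in the middle third, as in a typical nap
    hypnogram = ["N2"] * n_epochs
    for i in range(n_epochs // 3, 2 * n_epochs // 3):
        hypnogram[i] = "N3"
    for i in config.wake_epochs:
        if 0 <= i < n_epochs:
            hypnogram[i] = "W"
    return hypnogram


def generate_participant(
    config: SimulationConfig,
    participant_seed: int,
    participant: str = "p00",
    kappa_sospindle: float | None = None,
) -> tuple[Recording, GroundTruth]:
    """Generate one synthetic participant (recording + ground truth).

    ``kappa_sospindle`` overrides the config value (used by
    :func:`generate_cohort` to spread coupling strength across the cohort).
    Event rates that cannot be placed without violating spacing are reduced
    with a warning; the shortfall is recorded in the ground truth.
    """
    rng = np.random.default_rng(participant_seed)
    fs = config.fs
    kappa_cfg = config.kappa_sospindle if kappa_sospindle is None else kappa_sospindle

    resp, peaks, phase = generate_respiration(
        config.duration_s, config.resp_freq, config.resp_jitter, rng,
        fs=fs, asymmetry=config.resp_asymmetry,
    )
    hypnogram = _default_hypnogram(config)
    allowed = np.ones(resp.size, dtype=bool)
    for i, stage in enumerate(hypnogram):
        if stage not in ("N2", "N3"):
            a = int(i * config.epoch_len_s * fs)
            b = min(int((i + 1) * config.epoch_len_s * fs), resp.size)
            allowed[a:b] = False

    n_minutes = config.duration_s / 60.0
    eeg = np.empty((len(config.channels), resp.size))
    rows: list[dict] = []
    shortfall: dict = {}

    for ch_idx, label in enumerate(config.channels):
        eeg[ch_idx] = generate_background(
            config.duration_s, fs, config.noise_exponent, rng, sd=config.noise_sd_uv
        )
        scale = config.channel_kappa_scale.get(label, 1.0)

        n_so = rng.poisson(config.so_rate * n_minutes)
        n_coupled = rng.binomial(n_so, config.coupled_fraction) if n_so else 0
        n_plain_so = n_so - n_coupled
        n_spindle = rng.poisson(config.spindle_rate * n_minutes)

        so_anchors = np.array([])
        coupled_anchors = _place_events(
            n_coupled, config.mu_sospindle, kappa_cfg * scale, phase, fs,
            config.event_delay_s, config.resp_freq, allowed, [],
            config.min_event_gap_s, rng, asymmetry=config.resp_asymmetry,
        )
        so_anchors = _place_events(
            n_plain_so, config.mu_so, config.kappa_so * scale, phase, fs,
            config.event_delay_s, config.resp_freq, allowed, list(coupled_anchors),
            config.min_event_gap_s, rng, asymmetry=config.resp_asymmetry,
        )
        coupled_spindle_onsets = coupled_anchors + rng.uniform(0.3, 0.9, size=coupled_anchors.size)
        spindle_onsets = _place_events(
            n_spindle, config.mu_spindle, config.kappa_spindle * scale, phase, fs,
            config.event_delay_s, config.resp_freq, allowed, list(coupled_spindle_onsets),
            config.min_event_gap_s, rng, asymmetry=config.resp_asymmetry,
        )
        deficits = {
            "SO": n_so - (so_anchors.size + coupled_anchors.size),
            "SPINDLE": n_spindle - spindle_onsets.size,
        }
        if any(v > 0 for v in deficits.values()):
            shortfall[label] = deficits
            warnings.warn(
                f"{participant}/{label}: reduced event counts {deficits} "
                "(placement constraints)", stacklevel=2,
            )

        so_wave = make_so_waveform(config.so_amplitude_uv, config.so_duration_s, fs)
        trough_offset = SO_TROUGH_FRACTION * config.so_duration_s
        for anchor in np.concatenate([so_anchors, coupled_anchors]):
            _add_waveform(eeg[ch_idx], so_wave, anchor - trough_offset, fs)
        for onset in np.concatenate([spindle_onsets, coupled_spindle_onsets]):
            freq = rng.uniform(config.spindle_freq_hz - 1.0, config.spindle_freq_hz + 1.0)
            dur = rng.uniform(0.8 * config.spindle_duration_s, 1.3 * config.spindle_duration_s)
            _add_waveform(
                eeg[ch_idx],
                make_spindle_waveform(freq, dur, config.spindle_amplitude_uv, fs),
                onset, fs,
            )

        for anchor in so_anchors:
            rows.append(dict(channel=label, kind="SO", time_s=anchor,
                             resp_phase=_phase_at(phase, fs, anchor), coupled=False,
                             spindle_time_s=np.nan))
        for anchor, sp_onset in zip(coupled_anchors, coupled_spindle_onsets):
            rows.append(dict(channel=label, kind="SO", time_s=anchor,
                             resp_phase=_phase_at(phase, fs, anchor), coupled=True,
                             spindle_time_s=sp_onset))
            rows.append(dict(channel=label, kind="SO_SPINDLE", time_s=anchor,
                             resp_phase=_phase_at(phase, fs, anchor), coupled=True,
                             spindle_time_s=sp_onset))
        for onset in np.concatenate([spindle_onsets, coupled_spindle_onsets]):
            rows.append(dict(channel=label, kind="SPINDLE", time_s=onset,
                             resp_phase=_phase_at(phase, fs, onset),
                             coupled=bool(onset in coupled_spindle_onsets),
                             spindle_time_s=np.nan))

    events = pd.DataFrame(
        rows, columns=["channel", "kind", "time_s", "resp_phase", "coupled", "spindle_time_s"]
    ).sort_values(["channel", "kind", "time_s"], ignore_index=True)

    coupling_rows = []
    for label in config.channels:
        for kind in ("SO", "SPINDLE", "SO_SPINDLE"):
            ph = events.loc[(events["channel"] == label) & (events["kind"] == kind), "resp_phase"]
            ang, r = _circ_stats(ph.to_numpy())
            coupling_rows.append(dict(channel=label, kind=kind, mean_angle=ang,
                                      vector_length=r, n=len(ph)))
    coupling = pd.DataFrame(coupling_rows)

    recording = Recording(
        labels=list(config.channels), eeg=eeg, resp=resp, fs=fs,
        hypnogram=hypnogram, participant=participant,
    )
    truth = GroundTruth(
        participant=participant, events=events, inhalation_peaks=peaks,
        true_phase=phase, coupling=coupling, reactivation_score=np.nan,
        seed=participant_seed, shortfall=shortfall,
    )
    logger.info("generated %s: %d true events", participant, len(events))
    return recording, truth


def noise_sd_for_r2(true_r: np.ndarray, slope: float, r2: float) -> float:
    """Score-noise SD giving a target true R^2 for the coupling->score link."""
    if not 0 < r2 < 1:
        raise ValueError("r2 must be in (0, 1)")
    signal_var = slope**2 * np.var(np.asarray(true_r, dtype=float))
    return float(np.sqrt(signal_var * (1 - r2) / r2))


def generate_cohort(
    config: SimulationConfig,
) -> tuple[list[tuple[Recording, GroundTruth]], pd.DataFrame]:
    """Generate a cohort plus the reactivation score table.

    Per-participant SO_spindle concentration is spread evenly over
    ``config.kappa_sospindle_range`` (if set) so coupling strength varies
    across the cohort; the reactivation score is
    ``intercept + slope * true_vector_length + N(0, noise_sd)`` with the
    vector length taken from the true SO_spindle phases at the frontal
    representative channel. Fully reproducible from ``config.seed``.
    """
    if config.n_participants < 2:
        raise ValueError("a cohort needs at least 2 participants")
    root = np.random.SeedSequence(config.seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(config.n_participants + 1)]
    score_rng = np.random.default_rng(child_seeds[-1])

    if config.kappa_sospindle_range is not None:
        kappas = np.linspace(*config.kappa_sospindle_range, config.n_participants)
    else:
        kappas = np.full(config.n_participants, config.kappa_sospindle)

    cohort = []
    score_rows = []
    ref_channel = config.channels[0]
    for i in range(config.n_participants):
        pid = f"p{i:02d}"
        rec, truth = generate_participant(config, child_seeds[i], participant=pid,
                                          kappa_sospindle=float(kappas[i]))
        sel = truth.coupling[(truth.coupling["channel"] == ref_channel)
                             & (truth.coupling["kind"] == "SO_SPINDLE")]
        true_r = float(sel["vector_length"].iloc[0])
        score = (config.regression_intercept + config.regression_slope * true_r
                 + score_rng.normal(0.0, config.regression_noise_sd))
        truth.reactivation_score = score
        score_rows.append(dict(participant=pid, score=score, true_vector_length=true_r,
                               kappa_sospindle=float(kappas[i]), seed=child_seeds[i]))
        cohort.append((rec, truth))
    scores = pd.DataFrame(score_rows)
    return cohort, scores
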