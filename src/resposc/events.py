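"""Detection of slow oscillations, spindles, SO_spindle complexes, and
matched event-free control segments in stage-masked NREM EEG.

Slow oscillations (SO): the channel is band-passed 0.3-1.25 Hz (two-pass
FIR, length three cycles of the low cutoff); every pair of successive
positive-to-negative zero crossings whose spacing lies in [0.8, 2] s is an
SO, anchored at the filtered-signal trough (the downstate). No amplitude
criterion is applied by default; an optional absolute trough-depth
criterion is available for validation work on synthetic data.

Spindles: band-pass 12-18 Hz (slow variant 9-12 Hz), moving RMS of 200 ms,
threshold = 75th percentile of RMS over stage-masked samples; contiguous
strictly-supra-threshold runs lasting more than 0.5 and less than 3 s are
events, anchored at onset.

SO_spindle complexes: an SO whose downstate is followed by a spindle onset
within 1.5 s (closed window; the earliest qualifying spindle is paired).

All detection is per channel; events touching stage-masked-out or artifact
samples are dropped.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .filters import filter_bandpass_fir, moving_rms
from .io import Recording, empty_events

logger = logging.getLogger(__name__)

__all__ = [
    "stage_mask",
    "detect_so",
    "detect_spindles",
    "detect_so_spindles",
    "sample_event_free",
    "detect_all",
]


class NoSleepError(RuntimeError):
    """No N2/N3 epochs present in the hypnogram."""


def stage_mask(
    recording: Recording,
    stages: set[str] = frozenset({"N2", "N3"}),
    epoch_len_s: float = 30.0,
) -> np.ndarray:
    """Boolean per-sample mask: requested stages minus artifact intervals."""
    n = recording.n_samples
    fs = recording.fs
    mask = np.zeros(n, dtype=bool)
    any_stage = False
    for i, stage in enumerate(recording.hypnogram):
        if stage in stages:
            any_stage = True
            a = int(round(i * epoch_len_s * fs))
            b = min(int(round((i + 1) * epoch_len_s * fs)), n)
            mask[a:b] = True
    if not any_stage:
        raise NoSleepError(f"no epochs in stages {sorted(stages)}")
    for start_s, end_s in recording.artifacts:
        a = max(int(np.floor(start_s * fs)), 0)
        b = min(int(np.ceil(end_s * fs)), n)
        mask[a:b] = False
    return mask


def _rows_to_frame(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return empty_events()
    return pd.DataFrame(rows)


def detect_so(
    eeg: np.ndarray,
    fs: float,
    mask: np.ndarray | None = None,
    band: tuple[float, float] = (0.3, 1.25),
    duration_s: tuple[float, float] = (0.8, 2.0),
    min_trough_uv: float | None = None,
    channel: str = "",
    participant: str = "",
) -> pd.DataFrame:
    """Detect slow oscillations on one channel.

    Returns an event table with kind ``SO``; ``anchor_s`` is the downstate
    trough, ``onset_s``/``offset_s`` the bounding positive-to-negative zero
    crossings. ``min_trough_uv``, if given, additionally requires the
    trough to reach below ``-min_trough_uv`` microvolts.
    """
    eeg = np.asarray(eeg, dtype=float)
    if mask is None:
        mask = np.ones(eeg.size, dtype=bool)
    if mask.sum() < 60 * fs:
        raise ValueError("stage mask must cover at least 60 s")
    filtered = filter_bandpass_fir(eeg, fs, band)
    positive = filtered > 0
    crossings = np.flatnonzero(positive[:-1] & ~positive[1:]) + 1  # first non-positive sample
    rows = []
    for c0, c1 in zip(crossings[:-1], crossings[1:]):
        dur = (c1 - c0) / fs
        if not duration_s[0] <= dur <= duration_s[1]:
            continue
        if not mask[c0 : c1 + 1].all():
            continue
        trough = c0 + int(np.argmin(filtered[c0 : c1 + 1]))
        if min_trough_uv is not None and filtered[trough] > -min_trough_uv:
            continue
        rows.append(dict(
            participant=participant, channel=channel, kind="SO",
            anchor_s=trough / fs, onset_s=c0 / fs, offset_s=c1 / fs,
            duration_s=dur, resp_phase_rad=np.nan,
        ))
    logger.info("%s/%s: %d SOs", participant, channel, len(rows))
    return _rows_to_frame(rows)


def detect_spindles(
    eeg: np.ndarray,
    fs: float,
    mask: np.ndarray | None = None,
    band: tuple[float, float] = (12.0, 18.0),
    rms_window_s: float = 0.2,
    percentile: float = 75.0,
    duration_s: tuple[float, float] = (0.5, 3.0),
    min_peak_rms_uv: float | None = None,
    kind: str = "SPINDLE",
    channel: str = "",
    participant: str = "",
) -> pd.DataFrame:
    """Detect sleep spindles on one channel (set ``band=(9, 12)`` and
    ``kind='SLOW_SPINDLE'`` for the slow variant).

    The amplitude threshold is the ``percentile`` of moving-RMS values over
    stage-masked samples only; runs must *exceed* the threshold strictly,
    last more than ``duration_s[0]`` and less than ``duration_s[1]``
    seconds (both bounds exclusive), and lie fully inside the mask.

    ``min_peak_rms_uv``, if given, additionally requires the run's peak
    RMS to exceed that absolute level (off by default; a percentile-only
    threshold necessarily passes a fraction of background fluctuations,
    so validation against known embedded events uses this floor).
    """
    eeg = np.asarray(eeg, dtype=float)
    if mask is None:
        mask = np.ones(eeg.size, dtype=bool)
    if mask.sum() < 60 * fs:
        raise ValueError("stage mask must cover at least 60 s")
    filtered = filter_bandpass_fir(eeg, fs, band)
    rms = moving_rms(filtered, fs, rms_window_s)
    threshold = np.percentile(rms[mask], percentile)
    above = (rms > threshold) & mask
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        stops = np.concatenate([stops, [above.size]])
    rows = []
    for a, b in zip(starts, stops):
        dur = (b - a) / fs
        if not duration_s[0] < dur < duration_s[1]:
            continue
        if min_peak_rms_uv is not None and rms[a:b].max() <= min_peak_rms_uv:
            continue
        rows.append(dict(
            participant=participant, channel=channel, kind=kind,
            anchor_s=a / fs, onset_s=a / fs, offset_s=b / fs,
            duration_s=dur, resp_phase_rad=np.nan,
        ))
    logger.info("%s/%s: %d %ss (threshold %.3g uV)", participant, channel, len(rows), kind, threshold)
    return _rows_to_frame(rows)


def detect_so_spindles(
    so_events: pd.DataFrame,
    spindle_events: pd.DataFrame,
    window_s: float = 1.5,
) -> pd.DataFrame:
    """Pair SOs with the first spindle whose onset falls within
    [SO downstate, SO downstate + window_s] (closed at both ends).

    Returns kind ``SO_SPINDLE`` rows anchored at the SO downstate, with
    ``so_anchor_s`` and ``spindle_onset_s`` reference columns.
    """
    if len(so_events) == 0 or len(spindle_events) == 0:
        return empty_events()
    spindle_onsets = np.sort(spindle_events["onset_s"].to_numpy())
    rows = []
    for _, so in so_events.iterrows():
        anchor = so["anchor_s"]
        i = np.searchsorted(spindle_onsets, anchor, side="left")
        if i < spindle_onsets.size and spindle_onsets[i] <= anchor + window_s:
            sp_onset = spindle_onsets[i]
            sp = spindle_events.loc[spindle_events["onset_s"] == sp_onset].iloc[0]
            rows.append(dict(
                participant=so["participant"], channel=so["channel"], kind="SO_SPINDLE",
                anchor_s=anchor, onset_s=so["onset_s"],
                offset_s=max(so["offset_s"], sp["offset_s"]),
                duration_s=max(so["offset_s"], sp["offset_s"]) - so["onset_s"],
                resp_phase_rad=np.nan,
                so_anchor_s=anchor, spindle_onset_s=sp_onset,
            ))
    return _rows_to_frame(rows)


def sample_event_free(
    mask: np.ndarray,
    events: pd.DataFrame,
    fs: float,
    n_segments: int | None = None,
    segment_s: float = 4.0,
    context_s: float = 300.0,
    seed: int | np.random.Generator | None = 0,
    participant: str = "",
    channel: str = "",
) -> pd.DataFrame:
    """Sample event-free control segments matched to detected events.

    Each control is ``segment_s`` long, fully stage-masked-in, overlaps no
    detected event of any kind (and no other control), and starts within
    +/-``context_s`` of its matched event's anchor. Sampling is without
    replacement and seeded. When fewer than requested can be placed, a
    warning reports the shortfall.
    """
    if len(events) == 0:
        raise ValueError("control sampling requires detected events")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = mask.size
    seg_len = int(round(segment_s * fs))
    occupancy = mask.copy()
    for _, ev in events.iterrows():
        a = max(int(np.floor(ev["onset_s"] * fs)), 0)
        b = min(int(np.ceil(ev["offset_s"] * fs)) + 1, n)
        occupancy[a:b] = False
    # valid start: the whole window is free
    free = occupancy.astype(np.int32)
    csum = np.concatenate([[0], np.cumsum(free)])
    window_free = (csum[seg_len:] - csum[:-seg_len]) == seg_len
    valid_starts = np.flatnonzero(window_free)

    anchors = events["anchor_s"].to_numpy()
    if n_segments is None:
        n_segments = anchors.size
    order = rng.permutation(anchors.size)
    chosen: list[int] = []
    for k in range(n_segments):
        idx = order[k % anchors.size]
        lo = int(max((anchors[idx] - context_s) * fs, 0))
        hi = int(min((anchors[idx] + context_s) * fs - seg_len, n - seg_len))
        a, b = np.searchsorted(valid_starts, [lo, hi])
        candidates = valid_starts[a:b]
        if candidates.size == 0:
            continue
        for _ in range(50):
            start = int(rng.choice(candidates))
            if all(abs(start - c) >= seg_len for c in chosen):
                chosen.append(start)
                break
    if len(chosen) < n_segments:
        warnings.warn(
            f"{participant}/{channel}: only {len(chosen)}/{n_segments} event-free "
            "segments could be placed", stacklevel=2,
        )
    rows = [dict(
        participant=participant, channel=channel, kind="CONTROL",
        anchor_s=(s + seg_len / 2) / fs, onset_s=s / fs,
        offset_s=(s + seg_len) / fs, duration_s=segment_s, resp_phase_rad=np.nan,
    ) for s in sorted(chosen)]
    logger.info("%s/%s: %d control segments", participant, channel, len(rows))
    return _rows_to_frame(rows)


def detect_all(
    recording: Recording,
    config=None,
    channels: list[str] | None = None,
) -> pd.DataFrame:
    """Run SO, spindle and SO_spindle detection on the given channels.

    Convenience wrapper used by the cohort-level pipeline; returns a single
    concatenated event table.
    """
    from .config import AnalysisConfig

    cfg = config or AnalysisConfig()
    mask = stage_mask(recording)
    tables = []
    for label in channels or recording.labels:
        x = recording.channel(label)
        so = detect_so(x, recording.fs, mask, cfg.so_band, cfg.so_duration_s,
                       min_trough_uv=cfg.so_min_trough_uv,
                       channel=label, participant=recording.participant)
        sp = detect_spindles(x, recording.fs, mask, cfg.spindle_band,
                             cfg.spindle_rms_window_s, cfg.spindle_percentile,
                             cfg.spindle_duration_s,
                             min_peak_rms_uv=cfg.spindle_min_peak_rms_uv,
                             channel=label, participant=recording.participant)
        sosp = detect_so_spindles(so, sp, cfg.so_spindle_window_s)
        tables.extend([so, sp, sosp])
    out = pd.concat(tables, ignore_index=True) if tables else empty_events()
    return out
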