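"""End-to-end orchestration for single participants and cohorts.

These wrappers wire the modules together the way a full analysis runs:
respiratory phase extraction -> stage-masked event detection -> circular
coupling summaries -> group statistics. They also provide the
ground-truth matching used to validate detectors on synthetic data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .coupling import participant_coupling
from .events import detect_all
from .io import Recording
from .respiration import RespirationPhase, detect_inhalation_peaks, respiration_phase, respiratory_peak_frequency

logger = logging.getLogger(__name__)

__all__ = [
    "ParticipantResult",
    "analyze_participant",
    "match_events",
    "detection_scores",
]


@dataclass
class ParticipantResult:
    participant: str
    resp_phase: RespirationPhase
    events: pd.DataFrame
    coupling: pd.DataFrame


def analyze_participant(
    recording: Recording,
    config: AnalysisConfig | None = None,
    channels: list[str] | None = None,
) -> ParticipantResult:
    """Run respiration-phase extraction, event detection and coupling
    summaries for one recording."""
    cfg = config or AnalysisConfig()
    peak_freq = respiratory_peak_frequency(
        recording.resp, recording.fs, cfg.resp_search_band,
        min_duration_s=min(300.0, recording.duration_s),
    )
    peaks = detect_inhalation_peaks(recording.resp, recording.fs, peak_freq)
    phase = respiration_phase(recording.resp, recording.fs, peak_freq,
                              cfg.resp_halfband_hz, inhalation_peaks=peaks)
    events = detect_all(recording, cfg, channels=channels)
    coupling = participant_coupling(events, phase, alpha=cfg.alpha)
    events = coupling.attrs.get("events", events)
    return ParticipantResult(recording.participant, phase, events, coupling)


def match_events(
    true_times: np.ndarray,
    detected_times: np.ndarray,
    tolerance_s: float = 0.5,
) -> int:
    """Greedy one-to-one matching of detected to true event times.

    Pairs are formed in order of increasing |time difference|; each true
    and each detected event is used at most once. Returns the number of
    matched pairs.
    """
    true_times = np.asarray(true_times, dtype=float)
    det = np.asarray(detected_times, dtype=float)
    if true_times.size == 0 or det.size == 0:
        return 0
    diffs = np.abs(true_times[:, None] - det[None, :])
    pairs = np.argwhere(diffs <= tolerance_s)
    order = np.argsort(diffs[pairs[:, 0], pairs[:, 1]])
    used_true: set[int] = set()
    used_det: set[int] = set()
    matched = 0
    for ti, di in pairs[order]:
        if ti in used_true or di in used_det:
            continue
        used_true.add(int(ti))
        used_det.add(int(di))
        matched += 1
    return matched


def detection_scores(
    true_times: np.ndarray,
    detected_times: np.ndarray,
    tolerance_s: float = 0.5,
) -> tuple[float, float]:
    """(recall, precision) of detected against true event times."""
    n_match = match_events(true_times, detected_times, tolerance_s)
    n_true = len(np.asarray(true_times))
    n_det = len(np.asarray(detected_times))
    recall = n_match / n_true if n_true else np.nan
    precision = n_match / n_det if n_det else np.nan
    return recall, precision
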