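"""Recording container and file formats.

The pipeline's on-disk interchange is deliberately plain:

* EDF for signals (EEG in microvolts plus one respiration channel),
* a text hypnogram with one stage label (W, N1, N2, N3, R) per 30-s epoch,
* tab-separated event tables and score tables.

EDF is read through :mod:`mne`; writing uses a small built-in EDF writer
(16-bit, one data record per second, per-channel physical ranges in the
header). The respiration trace is in arbitrary units but is stored under a
microvolt dimension label so that readers apply a uniform scaling; values
round-trip unchanged.

Time convention: 0-based seconds from recording start; intervals are
half-open [onset, offset) unless stated otherwise.
"""

from __future__ import annotations

import logging
import math
import re

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "EVENT_KINDS",
    "EVENT_COLUMNS",
    "empty_events",
    "validate_events",
    "write_events",
    "read_events",
    "write_hypnogram",
    "read_hypnogram",
    "write_edf",
    "read_recording",
    "read_scores",
    "write_scores",
]

STAGES = ("W", "N1", "N2", "N3", "R")
EVENT_KINDS = ("SO", "SPINDLE", "SLOW_SPINDLE", "SO_SPINDLE", "CONTROL")
EVENT_COLUMNS = [
    "participant",
    "channel",
    "kind",
    "anchor_s",
    "onset_s",
    "offset_s",
    "duration_s",
    "resp_phase_rad",
]
EPOCH_LEN_S = 30.0


@dataclass
class Recording:
    """Synchronized multichannel EEG + respiration with staging metadata.

    ``eeg`` is (n_channels, n_samples) in microvolts, ``resp`` is
    (n_samples,) in arbitrary units, both at sampling rate ``fs``.
    ``hypnogram`` holds one stage label per 30-s epoch. ``artifacts`` are
    (start_s, end_s) intervals to exclude from analysis.
    """

    labels: list[str]
    eeg: np.ndarray
    resp: np.ndarray
    fs: float
    hypnogram: list[str]
    artifacts: list[tuple[float, float]] = field(default_factory=list)
    participant: str = "p00"

    def __post_init__(self) -> None:
        self.eeg = np.atleast_2d(np.asarray(self.eeg, dtype=float))
        self.resp = np.asarray(self.resp, dtype=float)
        if self.eeg.shape[0] != len(self.labels):
            raise ValueError("number of labels must match EEG channels")
        if self.eeg.shape[1] != self.resp.shape[0]:
            raise ValueError("EEG and respiration must share one length")
        n_epochs_needed = self.duration_s / EPOCH_LEN_S
        if abs(len(self.hypnogram) - n_epochs_needed) > 1.0:
            raise ValueError(
                f"hypnogram has {len(self.hypnogram)} epochs but the signal spans "
                f"{n_epochs_needed:.2f} epochs of {EPOCH_LEN_S:.0f} s"
            )
        bad = set(self.hypnogram) - set(STAGES)
        if bad:
            raise ValueError(f"unknown sleep stages in hypnogram: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.eeg.shape[1] / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one EEG channel by label."""
        try:
            idx = self.labels.index(label)
        except ValueError as exc:
            raise KeyError(f"channel {label!r} not in recording ({self.labels})") from exc
        return self.eeg[idx]


class MissingRespirationError(RuntimeError):
    """Raised when no respiration channel can be identified in an EDF file."""


# ---------------------------------------------------------------------------
# event tables


def empty_events() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=(object if c in ("participant", "channel", "kind") else float))
                         for c in EVENT_COLUMNS})


def validate_events(events: pd.DataFrame, origin: str = "<events>") -> pd.DataFrame:
    """Check column set, kinds, and interval sanity; raise with row context."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"{origin}: missing event columns {missing}")
    for row_pos, (_, row) in enumerate(events.iterrows()):
        line = row_pos + 2  # header is line 1
        if row["kind"] not in EVENT_KINDS:
            raise ValueError(f"{origin}, line {line}: unknown event kind {row['kind']!r}")
        if not (row["onset_s"] <= row["anchor_s"] <= row["offset_s"]):
            raise ValueError(f"{origin}, line {line}: anchor outside [onset, offset]")
        if row["duration_s"] < 0:
            raise ValueError(f"{origin}, line {line}: negative duration")
    return events


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write an event table as TSV (full float precision, round-trip exact)."""
    out = events.loc[:, [c for c in EVENT_COLUMNS if c in events.columns]
                    + [c for c in events.columns if c not in EVENT_COLUMNS]]
    out.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    """Read and validate a TSV event table."""
    events = pd.read_csv(path, sep="\t", dtype={"participant": str, "channel": str, "kind": str})
    if len(events) == 0:
        return empty_events()
    return validate_events(events, origin=str(path))


# ---------------------------------------------------------------------------
# hypnogram and scores


def write_hypnogram(hypnogram: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(hypnogram) + "\n")


def read_hypnogram(path: str | Path) -> list[str]:
    stages = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    bad = set(stages) - set(STAGES)
    if bad:
        raise ValueError(f"{path}: unknown sleep stages {sorted(bad)}")
    return stages


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write a per-participant score table (columns: participant, score)."""
    scores.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    scores = pd.read_csv(path, sep="\t", dtype={"participant": str})
    if "participant" not in scores.columns or "score" not in scores.columns:
        raise ValueError(f"{path}: score table needs 'participant' and 'score' columns")
    return scores


def read_artifacts(path: str | Path) -> list[tuple[float, float]]:
    table = pd.read_csv(path, sep="\t")
    return [(float(a), float(b)) for a, b in zip(table.iloc[:, 0], table.iloc[:, 1])]


# ---------------------------------------------------------------------------
# EDF


def _edf_field(value, width: int) -> bytes:
    text = f"{value}"
    if len(text) > width:
        raise ValueError(f"EDF header field {text!r} exceeds {width} bytes")
    return text.ljust(width).encode("ascii")


def _phys_range(x: np.ndarray) -> float:
    """Symmetric physical range rounded up to 4 significant digits (short header field)."""
    peak = float(np.max(np.abs(x))) if x.size else 1.0
    if peak == 0:
        return 1.0
    exponent = math.floor(math.log10(peak))
    scale = 10.0 ** (exponent - 3)
    return math.ceil(peak / scale) * scale


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write the recording as 16-bit EDF, one 1-s data record per second.

    Each channel gets a symmetric physical range in the header; digital
    range is -32767..32767, so zero maps to zero and quantization error is
    bounded by range/32767. The signal is zero-padded to a whole number of
    records.
    """
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    signals = [recording.eeg[i] for i in range(len(recording.labels))] + [recording.resp]
    labels = list(recording.labels) + ["Resp"]
    ns = len(signals)
    n_records = int(math.ceil(recording.n_samples / fs))

    header = b"".join([
        _edf_field("0", 8),
        _edf_field(recording.participant, 80),
        _edf_field("synthetic nap", 80),
        _edf_field("01.01.00", 8),
        _edf_field("12.00.00", 8),
        _edf_field(256 * (ns + 1), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field("1", 8),
        _edf_field(ns, 4),
    ])
    ranges = [_phys_range(sig) for sig in signals]
    header += b"".join(_edf_field(lab, 16) for lab in labels)
    header += b"".join(_edf_field("", 80) for _ in labels)
    header += b"".join(_edf_field("uV", 8) for _ in labels)
    header += b"".join(_edf_field(f"{-r:g}", 8) for r in ranges)
    header += b"".join(_edf_field(f"{r:g}", 8) for r in ranges)
    header += b"".join(_edf_field(-32767, 8) for _ in labels)
    header += b"".join(_edf_field(32767, 8) for _ in labels)
    header += b"".join(_edf_field("", 80) for _ in labels)
    header += b"".join(_edf_field(fs, 8) for _ in labels)
    header += b"".join(_edf_field("", 32) for _ in labels)

    digital = []
    for sig, rng in zip(signals, ranges):
        padded = np.zeros(n_records * fs)
        padded[: sig.size] = sig
        digital.append(np.clip(np.round(padded / rng * 32767), -32767, 32767).astype("<i2"))

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for dig in digital:
                fh.write(dig[rec * fs : (rec + 1) * fs].tobytes())
    logger.info("wrote EDF %s: %d channels, %d records", path, ns, n_records)


def read_recording(
    edf_path: str | Path,
    hypnogram_path: str | Path,
    artifact_path: str | Path | None = None,
    resp_pattern: str = r"(?i)resp|airflow|thermistor",
    participant: str | None = None,
) -> Recording:
    """Load an EDF + hypnogram (+ optional artifact table) into a Recording.

    The respiration channel is identified by label pattern. Channels with
    differing sampling rates are resampled by mne to the slowest rate on
    load. Raises :class:`MissingRespirationError` if no respiration channel
    matches, and ``ValueError`` if the hypnogram does not cover the signal
    (beyond one epoch of slack).
    """
    import mne

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne scales microvolt channels to volts
    labels = list(raw.ch_names)
    resp_idx = [i for i, lab in enumerate(labels) if re.search(resp_pattern, lab)]
    if not resp_idx:
        raise MissingRespirationError(
            f"{edf_path}: no channel matching {resp_pattern!r} among {labels}"
        )
    eeg_idx = [i for i in range(len(labels)) if i not in resp_idx]
    hypnogram = read_hypnogram(hypnogram_path)
    artifacts = read_artifacts(artifact_path) if artifact_path else []
    rec = Recording(
        labels=[labels[i] for i in eeg_idx],
        eeg=data[eeg_idx],
        resp=data[resp_idx[0]],
        fs=float(raw.info["sfreq"]),
        hypnogram=hypnogram,
        artifacts=artifacts,
        participant=participant or Path(edf_path).stem,
    )
    logger.info(
        "read %s: %d EEG channels + respiration, %.0f s at %.0f Hz",
        edf_path, len(rec.labels), rec.duration_s, rec.fs,
    )
    return rec
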