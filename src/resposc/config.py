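"""Configuration dataclasses for simulation and analysis.

``SimulationConfig`` defines the statistical structure of a synthetic nap
cohort (event rates, respiratory coupling, the coupling-strength to
reactivation link); ``AnalysisConfig`` collects every tunable of the
analysis pipeline with the published defaults (detection bands, duration
criteria, RMS percentile, statistics settings). Both can be loaded from a
TOML file via :func:`load_simulation_config` / :func:`load_analysis_config`.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "SimulationConfig",
    "AnalysisConfig",
    "load_simulation_config",
    "load_analysis_config",
]

DEG = math.pi / 180.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Angles are radians with 0 = inhalation peak; negative angles are late
    exhalation (just *before* the inhalation peak). Defaults emulate a
    20-participant nap study: ~0.25-Hz breathing, slow oscillations (SO)
    and spindles embedded in 1/f background EEG, event occurrence phases
    von Mises distributed around kind-specific preferred phases, and
    per-participant memory-reactivation scores linearly tied (with noise)
    to the true respiration-SO_spindle coupling strength.
    """

    n_participants: int = 20
    duration_s: float = 1800.0
    fs: float = 200.0

    # respiration
    resp_freq: float = 0.25
    resp_jitter: float = 0.08          # SD of cycle period as fraction of the mean period
    resp_asymmetry: float = 0.47       # fraction of the cycle spent inhaling (< 0.5: inhalation shorter)

    # background EEG
    noise_exponent: float = 1.0        # PSD ~ f^-exponent
    noise_sd_uv: float = 15.0

    # events
    so_rate: float = 4.0               # SOs per minute (coupled + uncoupled)
    spindle_rate: float = 3.0          # uncoupled spindles per minute
    coupled_fraction: float = 0.5      # fraction of SOs followed by a spindle
    so_amplitude_uv: float = 75.0
    so_duration_s: float = 1.25
    spindle_freq_hz: float = 14.0
    spindle_amplitude_uv: float = 20.0
    spindle_duration_s: float = 1.0
    min_event_gap_s: float = 2.0       # same-kind minimum inter-event spacing

    # respiratory coupling of event occurrence
    mu_so: float = -21.0 * DEG
    mu_spindle: float = 14.0 * DEG
    mu_sospindle: float = -10.0 * DEG
    kappa_so: float = 1.2
    kappa_spindle: float = 1.0
    kappa_sospindle: float = 5.0
    kappa_sospindle_range: tuple[float, float] | None = (1.0, 8.0)
    event_delay_s: float = 0.5         # conduction delay: respiration drives events after this lag

    # channel layout; kappa scale shapes the coupling topography
    channels: tuple[str, ...] = ("F2", "C3", "P1", "O2")
    channel_kappa_scale: dict[str, float] = field(
        default_factory=lambda: {"F2": 1.0, "C3": 0.35, "P1": 1.0, "O2": 0.35}
    )

    # coupling-strength -> reactivation-score link
    regression_slope: float = 0.2
    regression_intercept: float = 0.55
    regression_noise_sd: float = 0.04

    # hypnogram
    epoch_len_s: float = 30.0
    wake_epochs: tuple[int, ...] = ()  # indices of epochs to mark as wake (stage masking tests)

    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs <= 2 * max(self.spindle_freq_hz, 1.0):
            raise ValueError("fs must exceed twice the highest embedded oscillation frequency")
        if self.resp_freq <= 0:
            raise ValueError("resp_freq must be positive")
        if not 0 <= self.resp_jitter < 0.5:
            raise ValueError("resp_jitter must be in [0, 0.5)")
        if not 0 <= self.coupled_fraction <= 1:
            raise ValueError("coupled_fraction must be in [0, 1]")
        for name in ("kappa_so", "kappa_spindle", "kappa_sospindle", "so_rate", "spindle_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class AnalysisConfig:
    """Analysis-pipeline settings. Every default is the published value.

    * SO detection: 0.3-1.25 Hz two-pass FIR, duration between successive
      positive-to-negative zero crossings in [0.8, 2] s.
    * Spindle detection: 12-18 Hz (slow variant 9-12 Hz), 200-ms moving
      RMS, threshold = 75th percentile of RMS, duration in (0.5, 3) s.
    * SO_spindle pairing: spindle onset within 1.5 s after the SO downstate.
    * Respiration: band = peak frequency +/- 0.05 Hz, zero-phase Butterworth.
    * Statistics: 1000 permutations, sample threshold p=0.05, cluster
      alpha=0.05 two-tailed, FDR q=0.05.
    """

    target_fs: float = 200.0
    so_channel: str = "F2"             # representative channel for SO / SO_spindle analyses
    spindle_channel: str = "P1"        # representative channel for spindle analyses

    so_band: tuple[float, float] = (0.3, 1.25)
    so_duration_s: tuple[float, float] = (0.8, 2.0)
    so_min_trough_uv: float | None = None   # optional amplitude criterion, off by default

    spindle_band: tuple[float, float] = (12.0, 18.0)
    slow_spindle_band: tuple[float, float] = (9.0, 12.0)
    spindle_rms_window_s: float = 0.2
    spindle_percentile: float = 75.0
    spindle_duration_s: tuple[float, float] = (0.5, 3.0)
    spindle_min_peak_rms_uv: float | None = None  # optional absolute RMS floor, off by default

    so_spindle_window_s: float = 1.5
    control_segment_s: float = 4.0
    control_context_s: float = 300.0

    resp_halfband_hz: float = 0.05
    resp_search_band: tuple[float, float] = (0.1, 0.5)

    peth_window_s: float = 1.5
    peth_bin_s: float = 0.05
    n_phase_bins: int = 20

    tfr_freqs: tuple[float, float, float] = (1.0, 25.0, 1.0)   # start, stop, step
    tfr_step_s: float = 0.05
    tfr_cycles: float = 5.0
    tfr_window_s: float = 2.0

    mi_freq_centers: tuple[float, float, float] = (0.5, 24.5, 1.0)
    mi_bandwidth_hz: float = 1.0
    mi_n_surrogates: int = 200
    mi_min_shift_s: float = 10.0

    n_permutations: int = 1000
    cluster_threshold_p: float = 0.05
    alpha: float = 0.05
    fdr_q: float = 0.05

    @classmethod
    def for_synthetic_validation(cls, **overrides) -> "AnalysisConfig":
        """Detection settings for ground-truth validation on synthetic data.

        Identical to the defaults except that the optional amplitude
        criteria are enabled (SO trough below -40 uV, spindle peak RMS
        above 7 uV). Duration-only and percentile-only criteria pass
        background fluctuations at an irreducible rate, so recovering
        *embedded* events cleanly requires an amplitude margin; the
        published detection criteria themselves remain the defaults.
        """
        return cls(so_min_trough_uv=40.0, spindle_min_peak_rms_uv=7.0, **overrides)


def _coerce(cls, raw: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in raw.items():
        if key not in fields:
            raise KeyError(f"unknown {cls.__name__} option: {key!r}")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def load_simulation_config(path: str | Path) -> SimulationConfig:
    """Load a ``SimulationConfig`` from a TOML file (section [simulation] or flat)."""
    raw = tomllib.loads(Path(path).read_text())
    return _coerce(SimulationConfig, raw.get("simulation", raw))


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Load an ``AnalysisConfig`` from a TOML file (section [analysis] or flat)."""
    raw = tomllib.loads(Path(path).read_text())
    return _coerce(AnalysisConfig, raw.get("analysis", raw))
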