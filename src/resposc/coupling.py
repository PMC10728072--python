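"""Circular coupling between respiratory phase and detected sleep events.

Per participant: the respiratory phase at each event anchor (SO downstate,
spindle onset), summarised by circular mean and resultant vector length R.
Group level: V-test of participants' preferred phases against the
inhalation peak (0 rad) per channel, Benjamini-Hochberg FDR across
channels. Also: peri-event time histograms around inhalation peaks with a
cluster-permutation contrast against event-free control segments, and the
phase-binned SO_spindle rate (SO_spindles per SO per phase bin, x100) with
a per-participant uniformity test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from . import circular
from .respiration import RespirationPhase
from .stats import ClusterTestResult, cluster_test, fdr_bh

logger = logging.getLogger(__name__)

__all__ = [
    "phase_at_events",
    "participant_coupling",
    "group_coupling",
    "peri_event_histogram",
    "peth_contrast",
    "PhaseBinnedRate",
    "so_spindle_rate_by_phase",
    "phase_bin_edges",
]


def phase_at_events(
    resp_phase: RespirationPhase | np.ndarray,
    event_times: np.ndarray,
    fs: float | None = None,
) -> np.ndarray:
    """Respiratory phase at each event time (nearest sample), in (-pi, pi].

    Events outside the phase-series extent are dropped with a warning.
    """
    if isinstance(resp_phase, RespirationPhase):
        phase, fs = resp_phase.phase, resp_phase.fs
    else:
        phase = np.asarray(resp_phase, dtype=float)
        if fs is None:
            raise ValueError("fs required when passing a bare phase array")
    times = np.asarray(event_times, dtype=float)
    if times.size == 0:
        return np.array([])
    idx = np.round(times * fs).astype(int)
    inside = (idx >= 0) & (idx < phase.size)
    if not inside.all():
        warnings.warn(f"dropped {int((~inside).sum())} events outside the phase series",
                      stacklevel=2)
    return phase[idx[inside]]


def participant_coupling(
    events: pd.DataFrame,
    resp_phase: RespirationPhase,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per (channel, kind) circular summary of event phases.

    Returns mean_angle (rad), vector_length, n, v_stat, v_p (V-test
    against the inhalation peak) and a per-participant significance flag
    at ``alpha``. Also fills the ``resp_phase_rad`` column of a copy of
    the event table (available as attribute ``events`` on the result).
    """
    rows = []
    events = events.copy()
    for (channel, kind), group in events.groupby(["channel", "kind"], sort=True):
        phases = phase_at_events(resp_phase, group["anchor_s"].to_numpy())
        events.loc[group.index, "resp_phase_rad"] = (
            phases if len(phases) == len(group) else np.nan
        )
        if phases.size == 0:
            continue
        mean, r = circular.circ_summary(phases)
        if phases.size >= 2:
            v, p = circular.v_test(phases, mu0=0.0)
        else:
            v, p = np.nan, np.nan
        rows.append(dict(channel=channel, kind=kind, mean_angle=mean, vector_length=r,
                         n=int(phases.size), v_stat=v, v_p=p,
                         significant=bool(p < alpha) if np.isfinite(p) else False))
    table = pd.DataFrame(rows)
    table.attrs["events"] = events
    return table


def group_coupling(
    mean_angles: pd.DataFrame,
    mu0: float = 0.0,
    q: float = 0.05,
) -> pd.DataFrame:
    """Group-level V-test of participants' preferred phases per channel.

    ``mean_angles``: columns participant, channel, mean_angle (one row per
    participant x channel). Returns per channel: n, group mean angle and
    vector length, V, p, and the FDR mask across channels; the mean angle
    and vector length of the FDR-significant channel set are stored in
    ``attrs['significant_summary']``.
    """
    if mean_angles["participant"].nunique() < 2:
        raise ValueError("group coupling needs at least 2 participants")
    rows = []
    for channel, group in mean_angles.groupby("channel", sort=True):
        angles = group["mean_angle"].to_numpy()
        mean, r = circular.circ_summary(angles)
        v, p = circular.v_test(angles, mu0=mu0)
        rows.append(dict(channel=channel, n=angles.size, mean_angle=mean,
                         vector_length=r, v_stat=v, v_p=p))
    table = pd.DataFrame(rows)
    table["significant"] = fdr_bh(table["v_p"].to_numpy(), q=q)
    sig = mean_angles[mean_angles["channel"].isin(table.loc[table["significant"], "channel"])]
    if len(sig):
        ang, r = circular.circ_summary(sig["mean_angle"].to_numpy())
        table.attrs["significant_summary"] = {"mean_angle": ang, "vector_length": r}
    else:
        table.attrs["significant_summary"] = None
    return table


def peri_event_histogram(
    seed_times: np.ndarray,
    target_times: np.ndarray,
    window_s: float = 1.5,
    bin_s: float = 0.05,
) -> np.ndarray:
    """Normalized peri-event time histogram of targets around seeds.

    Bins cover [-window_s, window_s) in steps of ``bin_s`` (60 bins at the
    defaults); counts are normalized to sum to 100 over the window. With
    no target in any window an all-zero histogram is returned with a
    warning.
    """
    seeds = np.sort(np.asarray(seed_times, dtype=float))
    targets = np.sort(np.asarray(target_times, dtype=float))
    if seeds.size == 0 or targets.size == 0:
        raise ValueError("seed and target event sets must be non-empty")
    n_bins = int(round(2 * window_s / bin_s))
    counts = np.zeros(n_bins)
    for s in seeds:
        rel = targets[(targets >= s - window_s) & (targets < s + window_s)] - s
        if rel.size:
            idx = np.floor((rel + window_s) / bin_s).astype(int)
            np.add.at(counts, np.clip(idx, 0, n_bins - 1), 1)
    total = counts.sum()
    if total == 0:
        warnings.warn("no target events within any seed window", stacklevel=2)
        return counts
    return counts / total * 100.0


def peth_contrast(
    event_histograms: np.ndarray,
    control_histograms: np.ndarray,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = 0,
) -> ClusterTestResult:
    """Cluster-permutation contrast of per-participant peri-event
    histograms against event-free control histograms (time bins only)."""
    return cluster_test(event_histograms, control_histograms,
                        n_permutations=n_permutations, alpha=alpha, seed=seed)


def phase_bin_edges(n_bins: int = 20) -> np.ndarray:
    """Evenly spaced phase-bin edges from -pi to pi (2*pi/n_bins wide)."""
    return np.linspace(-np.pi, np.pi, n_bins + 1)


@dataclass
class PhaseBinnedRate:
    """SO_spindle rate across the respiration cycle for one participant."""

    edges: np.ndarray            # n_bins + 1 edges over (-pi, pi]
    so_counts: np.ndarray
    so_spindle_counts: np.ndarray
    rate: np.ndarray             # 100 * SO_spindles / SOs per bin; NaN where no SO
    ks_stat: float
    ks_p: float


def so_spindle_rate_by_phase(
    so_phases: np.ndarray,
    so_spindle_phases: np.ndarray,
    n_bins: int = 20,
) -> PhaseBinnedRate:
    """Phase-binned SO_spindle rate with a uniformity test.

    The respiration cycle is split into ``n_bins`` evenly spaced phase
    bins; the rate per bin is 100 x (SO_spindle count / SO count). Bins
    without SOs are flagged NaN and excluded. Uniformity of the rate
    profile is tested with a one-sample Kolmogorov-Smirnov statistic on
    the cumulative normalized rate across the ordered bins against the
    uniform cumulative line, with effective sample size = number of
    SO_spindles.
    """
    so_phases = np.asarray(so_phases, dtype=float)
    sosp_phases = np.asarray(so_spindle_phases, dtype=float)
    if so_phases.size == 0:
        raise ValueError("SO phase set must be non-empty")
    edges = phase_bin_edges(n_bins)
    so_counts, _ = np.histogram(so_phases, bins=edges)
    sosp_counts, _ = np.histogram(sosp_phases, bins=edges)
    if not so_counts.any():
        raise ValueError("all phase bins are empty of SOs")
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(so_counts > 0, 100.0 * sosp_counts / np.maximum(so_counts, 1), np.nan)
    if (so_counts == 0).any():
        logger.info("%d phase bins without SOs excluded from the uniformity test",
                    int((so_counts == 0).sum()))
    valid = so_counts > 0
    weights = rate[valid]
    total = weights.sum()
    if total <= 0 or valid.sum() < 2:
        return PhaseBinnedRate(edges, so_counts, sosp_counts, rate, np.nan, np.nan)
    w = weights / total
    cum = np.cumsum(w)
    uniform = np.arange(1, valid.sum() + 1) / valid.sum()
    d = float(np.max(np.abs(cum - uniform)))
    n_eff = int(sosp_counts[valid].sum())
    ks_p = float(sp_stats.kstwo.sf(d, max(n_eff, 1)))
    return PhaseBinnedRate(edges, so_counts, sosp_counts, rate, d, ks_p)
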