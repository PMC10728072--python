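"""Respiratory phase of sleep events and group-level circular statistics.

Generates a small cohort in which SO_spindle complexes prefer a
respiratory phase just before the inhalation peak (mu = -10 deg,
kappa = 5), runs the full pipeline per participant (respiratory peak
frequency -> inhalation peaks -> Hilbert phase -> event detection ->
phase at event anchors), and prints the per-participant preferred phases
plus the group V-test against the inhalation peak (0 deg). A small
negative group mean angle with a short confidence spread reproduces the
planted coupling; V-test p << 0.05 says the distribution of preferred
phases is nonuniform toward 0 deg.
"""

import warnings

import numpy as np
import pandas as pd

from resposc import AnalysisConfig, SimulationConfig, generate_cohort, group_coupling
from resposc.coupling import so_spindle_rate_by_phase
from resposc.pipeline import analyze_participant
from resposc.stats import fdr_bh

warnings.filterwarnings("ignore")

config = SimulationConfig(n_participants=8, duration_s=900.0,
                          kappa_sospindle_range=None, seed=1)
cohort, _ = generate_cohort(config)
analysis = AnalysisConfig.for_synthetic_validation()

rows, ks_p = [], []
for recording, truth in cohort:
    result = analyze_participant(recording, analysis, channels=["F2"])
    summary = result.coupling.query("channel == 'F2' and kind == 'SO_SPINDLE'")
    angle = float(summary["mean_angle"].iloc[0])
    rows.append(dict(participant=recording.participant, channel="F2", mean_angle=angle))
    print(f"{recording.participant}: preferred phase {np.degrees(angle):7.1f} deg, "
          f"R = {float(summary['vector_length'].iloc[0]):.2f}, "
          f"n = {int(summary['n'].iloc[0])}")
    ev = result.events
    so = ev.query("kind == 'SO' and channel == 'F2'")["resp_phase_rad"].to_numpy()
    sosp = ev.query("kind == 'SO_SPINDLE' and channel == 'F2'")["resp_phase_rad"].to_numpy()
    ks_p.append(so_spindle_rate_by_phase(so, sosp).ks_p)

group = group_coupling(pd.DataFrame(rows))
print(f"\ngroup: mean angle {np.degrees(group['mean_angle'].iloc[0]):.1f} deg "
      f"(planted -10 deg), R = {group['vector_length'].iloc[0]:.2f}, "
      f"V = {group['v_stat'].iloc[0]:.2f}, p = {group['v_p'].iloc[0]:.2g}")
n_nonuniform = int(fdr_bh(np.array(ks_p)).sum())
print(f"phase-binned SO_spindle rate nonuniform (KS, FDR) in "
      f"{n_nonuniform}/{len(ks_p)} participants")
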