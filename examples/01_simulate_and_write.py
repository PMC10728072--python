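"""Generate a small synthetic nap participant and write it to disk.

Builds a 10-minute recording (4 EEG channels + respiration at 200 Hz)
with embedded slow oscillations, spindles and coupled SO_spindle
complexes, then writes the EDF, the text hypnogram, and the ground-truth
event table. The printed counts are the true embedded events per kind at
the frontal channel F2.
"""

from pathlib import Path

from resposc import SimulationConfig, generate_participant, write_edf
from resposc.io import write_events, write_hypnogram

out = Path("scratch/example_out")
out.mkdir(parents=True, exist_ok=True)

config = SimulationConfig(duration_s=600.0, n_participants=2, seed=0)
recording, truth = generate_participant(config, participant_seed=42, participant="p00")

write_edf(recording, out / "p00.edf")
write_hypnogram(recording.hypnogram, out / "p00.hyp")
truth.events.to_csv(out / "p00_truth.tsv", sep="\t", index=False)

print(f"wrote {out}/p00.edf ({recording.duration_s:.0f} s, "
      f"{len(recording.labels)} EEG channels at {recording.fs:.0f} Hz)")
for kind in ("SO", "SPINDLE", "SO_SPINDLE"):
    n = len(truth.events.query("channel == 'F2' and kind == @kind"))
    print(f"embedded {kind:>10} events at F2: {n}")
print("inhalation peaks:", len(truth.inhalation_peaks))
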