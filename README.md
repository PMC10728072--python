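# resposc

Respiration-locked analysis of NREM sleep oscillations — and a
synthetic-cohort generator that makes the whole pipeline testable end to
end.

During non-REM sleep, slow oscillations (SO, ~0.3–1.25 Hz), sleep
spindles (12–18 Hz) and their coupled SO_spindle complexes orchestrate
memory consolidation. `resposc` implements the analysis chain used to ask
whether the *respiratory cycle* acts as a pacemaker for these rhythms:

- **Event detection** — SOs as pairs of successive positive-to-negative
  zero crossings of the 0.3–1.25-Hz filtered EEG with duration ∈ [0.8, 2] s
  (anchor = downstate trough); spindles as >0.5 s and <3 s runs of the
  200-ms moving RMS of the 12–18-Hz filtered EEG above its 75th
  percentile; SO_spindle complexes as SOs followed by a spindle onset
  within 1.5 s; plus matched 4-s event-free control segments. Detection is
  restricted to artifact-free N2/N3 sleep.
- **Respiratory phase** — per-participant peak frequency from Welch power
  (0.1–0.5 Hz), inhalation-peak detection on the smoothed trace, and the
  instantaneous phase φ(t) from a zero-phase Butterworth band-pass (peak
  ± 0.05 Hz) followed by a Hilbert transform; φ = 0° at the inhalation peak.
- **Circular coupling statistics** — per participant the preferred phase
  θ̄ and resultant vector length R of event phases; at the group level the
  V-test against the inhalation peak, V = n·R·cos(θ̄ − μ₀) with
  p from u = V·√(2/n), Benjamini–Hochberg FDR across channels; Watson's
  U² against a fitted von Mises for unimodality; the phase-binned
  SO_spindle rate, 100 × (SO_spindles per SO) in 20 phase bins, with a
  per-participant Kolmogorov–Smirnov uniformity test.
- **Cross-frequency measures** — inhalation-locked time–frequency maps
  (Hanning taper, five cycles per frequency, z-scored over ±2 s); the
  modulation index MI = KL(P‖U)/log 20 between respiratory phase and EEG
  amplitude in 1-Hz bins (0.5–24.5 Hz) with a 200-shift surrogate z-score;
  and a cross-frequency phase-slope index (PSI) between narrowband
  respiration and the amplitude envelope of band-limited EEG — positive
  PSI means respiration leads.
- **Group inference** — dependent-sample cluster-based permutation tests
  (sum-t cluster statistic, sign-flipping null), BH-FDR, and robust
  (bisquare IRLS) regression linking respiration–SO_spindle coupling
  strength to per-participant memory-reactivation scores.
- **Synthetic cohorts** — `resposc.simulate` builds nap recordings with a
  quasi-periodic asymmetric respiration trace, 1/f background EEG, and
  embedded events whose occurrence phases follow von Mises distributions
  with configurable preferred phase and concentration; respiration drives
  the events through a conduction delay, and reactivation scores are
  linearly tied (with noise) to the true coupling strength. Every ground
  truth (times, phases, vector lengths, seeds) is recorded.

Recordings round-trip through EDF (built-in writer, `mne` reader), text
hypnograms (one stage per 30-s epoch), and TSV event/score tables.

## Worked example

```bash
python examples/03_respiratory_phase_coupling.py
```

generates an 8-participant cohort whose SO_spindle complexes prefer a
respiratory phase of −10° (κ = 5), runs the full pipeline, and prints:

```
p00: preferred phase   -11.9 deg, R = 0.86, n = 28
p01: preferred phase   -27.1 deg, R = 0.92, n = 28
...
p07: preferred phase   -20.1 deg, R = 0.86, n = 38

group: mean angle -18.3 deg (planted -10 deg), R = 1.00, V = 7.57, p = 7.7e-05
phase-binned SO_spindle rate nonuniform (KS, FDR) in 5/8 participants
```

Each line is one participant's preferred respiratory phase at the
SO downstate of detected SO_spindle complexes (negative = just before
the inhalation peak) and its vector length R (0 = uniform phases,
1 = perfectly concentrated). The group V-test says the participants'
preferred phases cluster toward the inhalation peak far beyond chance.
The other scripts in `examples/` cover simulation + EDF output, event
detection against ground truth, the modulation index, PSI
directionality, and the coupling→reactivation regression.

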