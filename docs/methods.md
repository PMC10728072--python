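# Methods

This note documents the models, algorithms and numerical choices behind
`resposc`, in the order data flows through the pipeline, plus the design
decisions taken where the problem left genuine freedom.

## Signals and conventions

Time is 0-based seconds from recording start; intervals are half-open
[onset, offset). EEG is in microvolts, respiration in arbitrary units.
Respiratory phase is radians in (−π, π], 0 at the inhalation peak,
counterclockwise-increasing (so negative phases are late exhalation,
just before the next inhalation peak); user-facing reports use degrees.
Staging is a text hypnogram with one label in {W, N1, N2, N3, R} per
30-s epoch; all detection and coupling analyses are restricted to
artifact-free N2/N3 samples.

Two zero-phase filter families are used. Detection bands (0.3–1.25 Hz,
12–18 Hz, and the 1-Hz amplitude bins) use a windowed-sinc FIR whose
length is three cycles of the low band edge, applied forward and
backward (`filters.filter_bandpass_fir`); this deliberately short design
has wide transition bands at high frequencies — e.g. the 1-Hz amplitude
bins around 15 Hz leak over a few Hz — which is accepted as part of the
method's definition. The very narrow respiration band (peak ± 0.05 Hz)
uses a 3rd-order Butterworth with `sosfiltfilt`, which is stable where
an equally narrow FIR would need tens of seconds of taps. Zero-phase
filtering matters because any filter lag would bias every phase-coupling
estimate; the test suite asserts time-reversal symmetry to 10⁻⁶.

## Synthetic cohort generator

The generator's job is to produce nap recordings whose ground truth is
known exactly, with statistical structure matching the phenomenon the
pipeline measures.

**Respiration.** Breathing is modelled as a chain of cycles whose
periods are normal around 1/f₀ (f₀ = 0.25 Hz by default) with SD
`resp_jitter` = 8% of the period, clipped to 0.4–1.6×. Within a cycle
the trace is a phase-warped cosine: the inhalation peak sits a fraction
`resp_asymmetry` = 0.47 into the trough-to-trough cycle, so inhalation
is slightly shorter than exhalation, as in real airflow traces, and
inhalation peaks are not trivially equidistant. True phase is linear in
cycle fraction on each flank (±π at the troughs, 0 at the peak). The
asymmetry is kept mild on purpose: the analysis pipeline measures phase
by narrowband filtering + Hilbert transform, which tracks the waveform's
fundamental; stronger asymmetry shifts the Hilbert phase at the true
peak away from 0 (≈ −0.09 rad at 0.47, growing with asymmetry), and the
convention "phase ≈ 0 at inhalation peaks" should hold within ±0.2 rad.

**Background EEG** is 1/f^α noise (α = 1 by default, SD 15 µV),
generated by spectral shaping of white noise, independently per channel.

**Events.** SO templates are one full sine cycle (trough first,
amplitude 75 µV, duration 1.25 s), so the positive-to-negative zero
crossings bound the event exactly and the downstate trough sits a
quarter period in. Spindles are Hann-windowed sinusoids (13–15 Hz,
0.8–1.3 s, 20 µV). Event counts are Poisson (SO 4/min of which half are
coupled; uncoupled spindles 3/min — `spindle_rate` counts uncoupled
spindles only, total spindles = uncoupled + coupled). These densities
are conventional values for N2/N3 sleep, not measured quantities.
Same-kind events keep a ≥2-s gap via rejection sampling; unplaceable
events are dropped with a warning and the shortfall recorded.

**Respiratory coupling, causally.** Each event kind draws its occurrence
phase from von Mises(μ_kind, κ_kind); defaults place SOs at −21°
(κ = 1.2), spindles at +14° (κ = 1.0) and coupled SO_spindles at −10°
(κ = 5, or spread per participant, below). Crucially, events are not
placed *at* the drawn phase: the drawn phase is back-shifted (in
cycle-fraction space, respecting the asymmetric warp) by a conduction
delay `event_delay_s` = 0.5 s, and the event occurs that delay after the
oscillator crosses the shifted phase. The measured preferred phase is
still μ, but respiration now genuinely *drives* the events: without the
delay, event times would be a pure function of instantaneous phase, the
coherency phase slope across the respiration band would be flat, and the
phase-slope index would be 0 by construction — a generator that claims
directionality must implement a lag. Coupled spindles start 0.3–0.9 s
after their SO downstate (inside the 1.5-s pairing window).

**Topography and the reactivation link.** Coupling concentrations are
scaled per channel (F2 and P1 full strength, C3/O2 at 0.35), giving a
frontal/parietal-weighted topography. In a cohort, each participant's
SO_spindle κ is spread evenly over (1, 8) so the true vector length
varies, and the memory-reactivation score is
`0.55 + 0.2 × R_true(F2) + N(0, 0.04)`. `noise_sd_for_r2` computes the
noise SD that yields a prescribed true R² for a given R spread. Because
the weakly coupled channels inherit the same participant-level κ (scaled
down), their vector lengths correlate with the score as well; channel
specificity in the strict sense would require per-channel independent
concentrations.

All randomness descends from a single seed through `SeedSequence` spawns
(children reduced mod 2³¹); cohorts regenerate bit-identically.

**What the generator does not emulate.** No biophysical head model or
channel covariance (channels are independent), no spindle frequency
gradients or amplitude asymmetries, no K-complexes, arousals, cardiac or
EMG contamination, no apneas, no stage transitions beyond an N2/N3 block
structure with optional wake insertions. Passing tests therefore show
that the *algorithms* recover planted structure under realistic noise —
not that the statistical thresholds transfer unchanged to recorded
polysomnography.

## Event detection

The SO detector emits every pair of successive positive-to-negative zero
crossings of the 0.3–1.25-Hz filtered signal spaced 0.8–2 s apart,
anchored at the trough between them. This duration-only rule has an
irreducible false-alarm rate on any noisy background — band-limited
noise completes cycles in that range constantly — so an optional
absolute trough-depth criterion (`min_trough_uv`, off by default) is
provided; ground-truth validation enables it at 40 µV, in the tradition
of fixed-amplitude SO detectors. Similarly, the spindle detector's
percentile threshold (75th of the 200-ms moving RMS over masked
samples) passes background envelope runs at a scale-invariant rate;
an optional absolute peak-RMS floor (`min_peak_rms_uv`, off by default,
7 µV in validation) separates embedded events from background runs.
With both options enabled, recall and precision on default cohorts are
≥ 0.99 for SOs and spindles. With the published criteria alone the same
events are found (recall ≈ 1) amid additional low-amplitude detections —
matching how these detectors behave on real data.

Threshold exceedance is strict (`>`), so a constant signal yields no
events. Spindle duration bounds are exclusive (more than 0.5, less than
3 s); SO duration bounds inclusive. SO–spindle pairing uses a closed
window [downstate, downstate + 1.5 s], ties broken by earliest spindle
onset; pairing is within-channel. Event-free control segments are 4-s
windows that overlap no detected event (and no other control), drawn
without replacement within ±5 min of a matched event, seeded.

## Respiratory phase

Peak frequency = argmax of Welch power (120-s segments) in 0.1–0.5 Hz.
Inhalation peaks: z-score, moving-mean smoothing over a quarter period,
positive-going zero crossing opens a breath, peak = maximum before the
next negative-going crossing, refractory of half a period (larger peak
wins). Phase: Butterworth band-pass peak ± 0.05 Hz, Hilbert transform;
the analytic phase of a narrowband signal is 0 at its maxima, matching
the inhalation-peak convention automatically. Phase at an event is read
at the nearest sample to its anchor.

On synthetic data with κ = 5, measured event phases deviate from truth
with circular RMS ≈ 0.14 rad, and per-participant preferred phases carry
a small systematic offset (≈ −5°) from the waveform-asymmetry bias noted
above — group-level recovery of a planted −10° lands near −15°.

## Circular statistics

Implemented directly (mean direction and resultant length from the first
trigonometric moment; V-test with p from u = V√(2/n) on the upper normal
tail; Rayleigh with the standard small-sample correction). Watson's U²
against a von Mises with estimated (μ, κ) uses a parametric bootstrap
for the null distribution (re-fit per replicate), since critical values
with estimated parameters depend on κ; 300 replicates by default. κ is
estimated by the standard A(κ)-inverse approximation plus two Newton
steps.

The phase-binned SO_spindle rate divides SO_spindle counts by SO counts
in 20 equal phase bins (×100, so it is a percentage and ≤ 100 by the
subset property); bins without SOs are flagged missing and excluded. Its
uniformity test computes a Kolmogorov–Smirnov statistic on the
cumulative normalized rate across the ordered bins against the uniform
line, with effective sample size = number of SO_spindles; Monte-Carlo
calibration under the null (coupled events a random subset of SOs) shows
a false-positive rate of 0.048 at nominal 0.05. The exact reference
distribution for this statistic is a modelling choice; a permutation of
coupled labels is the obvious alternative and gives near-identical
decisions.

## Cross-frequency measures

**TFR.** Power per frequency is the squared magnitude of a convolution
with a Hann-tapered complex exponential of length five cycles,
amplitude-normalized; event-locked maps sample this on a ±2-s grid in
50-ms steps around anchors (anchors too close to the edges are dropped),
average over anchors, and z-score across time per frequency. Note the
z-scored map expresses temporal modulation per frequency, not absolute
power — cross-frequency comparisons need the raw map (`z_score=False`).

**Modulation index.** Phase is divided into 20 bins; the per-bin mean
amplitude, normalized to sum 1, is compared to uniform via
KL-divergence, normalized by log 20 so MI ∈ [0, 1]; MI is invariant to
amplitude scaling. Surrogates circularly shift the phase series by
uniform offsets ≥ 10 s from either end (destroying alignment, preserving
both marginals); z = (MI − mean_surr)/sd_surr, two-sided threshold 1.96.
For the lowest bin (center 0.5 Hz) the filter's low edge is floored at
0.25 Hz; filter lengths are capped at a third of the signal.

**Phase-slope index.** Respiration (~0.25 Hz) and spindle-band EEG share
no Fourier frequencies, so the PSI is computed between the narrowband
respiration and the *Hilbert amplitude envelope* of the band-filtered
EEG — the slow dynamics that can be coherent with breathing; the same
construction is used for the SO band for symmetry. Coherency comes from
Welch estimates with segments of four breathing cycles (16 s), 50%
overlap, Hann; PSI = −Im Σ_f conj(C(f))·C(f+δf) over the respiration
band, the sign fixed so that a delayed second signal gives positive PSI
(first argument leads). Antisymmetry under argument exchange holds to
machine precision by construction. Group inference is a two-sided
one-sample t test; zero-variance inputs are flagged NaN.

## Group statistics

**Cluster permutation.** Paired grids (time, time × frequency,
optionally × channel) are reduced to a dependent-sample t map,
thresholded at the two-sided p = 0.05 t quantile; suprathreshold cells
are clustered under lattice adjacency (channels through an explicit
neighbour matrix merged by union-find), cluster statistic = sum of t;
the null is the maximum |cluster sum| over both polarities across
sign-flips of participants' difference grids; cluster
p = (1 + #{max ≥ |obs|})/(n_perm + 1). Type-I error calibrates to
0.05 ± 0.01 in simulation, and results agree with
`mne.stats.permutation_cluster_1samp_test` on shared cases.

**Robust regression** wraps statsmodels RLM (Tukey bisquare, c = 4.685,
convergence on coefficients at 10⁻⁸, ≤ 50 iterations; scale = MAD about
zero); R² is computed on the weighted fit and F = R²/(1−R²)·(n−2) with
(1, n−2) df. An exact fit returns unit weights. The test suite holds the
wrapper to ≤ 10⁻⁶ against an independently coded IRLS.
The coupling→reactivation analysis regresses scores on per-channel
vector lengths with BH-FDR across channels; participants without scores
are dropped with a warning.

FDR is Benjamini–Hochberg (statsmodels `multipletests`).

## Problem sizes and known limitations

Validation runs use 20 participants × 30 min at 200 Hz (≈ 120 SOs and
≈ 120 spindles per participant at F2) — a deliberate desk-scale choice;
a recorded nap study would have several-fold more events per
participant. Two statistical consequences are documented rather than
hidden: (i) at ~60 SO_spindles per participant the phase-binned-rate KS
test flags 17–20 of 20 participants depending on the seed, so "≥ 18/20"
is not guaranteed; (ii) recovering a planted coupling→reactivation slope
with true R² = 0.3 at n = 20 has ≈ 0.78 power at α = 0.05 (noncentral t,
ncp ≈ 2.93, df 18), and FDR across channels cannot raise it to 0.9 —
larger cohorts or effects would be needed. The F statistic is reported
with (1, n−2) df throughout.

Other limitations: the respiration model has a single dominant rhythm
(no sighs or apneas); phase measurement inherits a small
waveform-asymmetry bias (quantified above); the per-channel kappa
scaling ties channel coupling strengths together within participant; and
the EDF writer quantizes to 16 bits over a per-channel symmetric range
(error ≤ range/32767, verified on round trip through an independent
reader).
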