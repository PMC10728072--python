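"""SO / spindle / SO_spindle detectors and event-free control sampling."""

import warnings

import numpy as np
import pandas as pd
import pytest

from resposc.config import SimulationConfig
from resposc.events import (
    NoSleepError,
    detect_so,
    detect_so_spindles,
    detect_spindles,
    sample_event_free,
    stage_mask,
)
from resposc.filters import filter_bandpass_fir, moving_rms
from resposc.io import Recording, empty_events
from resposc.simulate import generate_background, generate_participant, make_so_waveform, make_spindle_waveform

FS = 200.0


def _recording(n_samples=120000, hypnogram=None, artifacts=()):
    hypnogram = hypnogram or ["N2"] * 20
    return Recording(["F2"], np.zeros((1, n_samples)), np.zeros(n_samples), FS,
                     hypnogram=hypnogram, artifacts=list(artifacts))


class TestStageMask:
    def test_all_n2_all_true(self):
        assert stage_mask(_recording()).all()

    def test_wake_epoch_excluded(self):
        hyp = ["N2"] * 10
        hyp[3] = "W"
        mask = stage_mask(_recording(60000, hyp))
        assert (~mask).sum() == 6000  # 30 s x 200 Hz
        assert not mask[int(90 * FS) : int(120 * FS)].any()

    def test_artifact_subtracted(self):
        mask = stage_mask(_recording(artifacts=[(100.0, 101.0)]))
        assert not mask[int(100 * FS) : int(101 * FS)].any()
        assert mask.sum() == 120000 - 200

    def test_no_sleep_error(self):
        with pytest.raises(NoSleepError):
            stage_mask(_recording(60000, ["W"] * 10))


def brute_force_so_scan(filtered, fs, dur=(0.8, 2.0)):
    """Exhaustive sample-by-sample crossing scan (independent oracle)."""
    events = []
    prev = None
    for i in range(1, len(filtered)):
        if filtered[i - 1] > 0 >= filtered[i]:
            if prev is not None:
                d = (i - prev) / fs
                if dur[0] <= d <= dur[1]:
                    trough = prev + int(np.argmin(filtered[prev : i + 1]))
                    events.append((prev, i, trough))
            prev = i
    return events


class TestDetectSO:
    def test_all_zero_signal_no_events(self):
        assert len(detect_so(np.zeros(int(120 * FS)), FS)) == 0

    def test_single_template_recovered(self, rng):
        x = generate_background(120, FS, 1.0, rng, sd=3.0)
        wave = make_so_waveform(120, 1.25, FS)
        trough_true = 60.0
        start = int((trough_true - 0.25 * 1.25) * FS)
        x[start : start + wave.size] += wave
        events = detect_so(x, FS, min_trough_uv=40.0)
        assert len(events) == 1
        assert abs(events["anchor_s"].iloc[0] - trough_true) <= 0.05

    @pytest.mark.parametrize("period,expected", [(0.7, 0), (1.25, "some"), (2.1, 0)])
    def test_duration_criterion_bounds(self, period, expected):
        # a sine of that period produces crossing pairs spaced exactly one
        # period; mask out the edges where filter transients live
        t = np.arange(int(120 * FS)) / FS
        x = 50 * np.sin(2 * np.pi * t / period)
        mask = np.ones(x.size, bool)
        mask[: int(10 * FS)] = mask[-int(10 * FS):] = False
        events = detect_so(x, FS, mask)
        if expected == 0:
            assert len(events) == 0
        else:
            assert len(events) > 0
            assert np.allclose(events["duration_s"], period, atol=0.02)

    def test_matches_exhaustive_scan(self, rng):
        # crossing/pairing logic vs brute-force oracle, exact, random inputs
        for _ in range(20):
            x = rng.standard_normal(int(90 * FS)).cumsum()  # random walk: slow content
            filtered = filter_bandpass_fir(x, FS, (0.3, 1.25))
            events = detect_so(x, FS)
            oracle = brute_force_so_scan(filtered, FS)
            assert len(events) == len(oracle)
            np.testing.assert_array_equal(
                np.round(events["onset_s"].to_numpy() * FS).astype(int),
                [o[0] for o in oracle])
            np.testing.assert_array_equal(
                np.round(events["anchor_s"].to_numpy() * FS).astype(int),
                [o[2] for o in oracle])

    def test_masked_candidates_dropped(self, rng):
        x = generate_background(120, FS, 1.0, rng, sd=10.0)
        full = detect_so(x, FS)
        mask = np.ones(x.size, bool)
        mask[: x.size // 2] = False
        half = detect_so(x, FS, mask)
        assert len(half) < len(full)
        assert (half["onset_s"] >= 60.0).all()


def independent_spindle_oracle(x, fs, band=(12.0, 18.0), win=0.2, pct=75.0,
                               dur=(0.5, 3.0)):
    """Recompute RMS, percentile and runs with loop-based code."""
    filtered = filter_bandpass_fir(x, fs, band)
    n = max(int(round(win * fs)), 1)
    half_lo, half_hi = n // 2, n - 1 - n // 2
    sq = np.concatenate([np.full(half_lo, filtered[0] ** 2), filtered**2,
                         np.full(half_hi, filtered[-1] ** 2)])
    rms = np.empty(filtered.size)
    c = np.concatenate([[0.0], np.cumsum(sq)])
    for i in range(filtered.size):
        rms[i] = np.sqrt((c[i + n] - c[i]) / n)
    threshold = np.percentile(rms, pct)
    events, start = [], None
    for i, v in enumerate(rms):
        if v > threshold and start is None:
            start = i
        elif v <= threshold and start is not None:
            if dur[0] < (i - start) / fs < dur[1]:
                events.append((start, i))
            start = None
    return events, threshold


class TestDetectSpindles:
    def test_constant_signal_no_events(self):
        x = np.full(int(120 * FS), 5.0)
        assert len(detect_spindles(x, FS)) == 0

    def test_single_burst_recovered(self, rng):
        x = generate_background(120, FS, 1.0, rng, sd=5.0)
        wave = make_spindle_waveform(14, 1.0, 60, FS)
        onset_true = 60.0
        x[int(onset_true * FS) : int(onset_true * FS) + wave.size] += wave
        events = detect_spindles(x, FS, min_peak_rms_uv=15.0)
        assert len(events) == 1
        assert abs(events["onset_s"].iloc[0] - onset_true) <= 0.15

    def test_short_run_rejected(self, rng):
        # a 0.2-s tapered burst yields a supra-threshold RMS run shorter
        # than 0.5 s (the 200-ms RMS window stretches a strong burst by up
        # to its own width, so the burst must be well under the criterion)
        x = generate_background(120, FS, 1.0, rng, sd=5.0)
        wave = make_spindle_waveform(14, 0.2, 60, FS)
        x[12000 : 12000 + wave.size] += wave
        filtered = filter_bandpass_fir(x, FS, (12.0, 18.0))
        rms = moving_rms(filtered, FS, 0.2)
        threshold = np.percentile(rms, 75)
        above = rms > threshold
        center = 12000 + wave.size // 2
        lo = hi = center
        while lo > 0 and above[lo - 1]:
            lo -= 1
        while hi < above.size and above[hi]:
            hi += 1
        assert (hi - lo) / FS < 0.5  # premise: the run really is sub-criterion
        events = detect_spindles(x, FS, min_peak_rms_uv=15.0)
        assert len(events) == 0

    def test_matches_independent_oracle(self, rng):
        for seed in range(5):
            x = generate_background(90, FS, 1.0, np.random.default_rng(seed), sd=5.0)
            wave = make_spindle_waveform(13.5, 1.2, 30, FS)
            x[6000 : 6000 + wave.size] += wave
            events = detect_spindles(x, FS)
            oracle, thr = independent_spindle_oracle(x, FS)
            assert len(events) == len(oracle)
            np.testing.assert_allclose(events["onset_s"].to_numpy() * FS,
                                       [o[0] for o in oracle])

    def test_threshold_percentile_monotonicity(self, rng):
        x = generate_background(300, FS, 1.0, rng, sd=10.0)
        counts = [len(detect_spindles(x, FS, percentile=p)) for p in (70, 75, 80, 90)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_slow_spindle_band(self, rng):
        x = generate_background(120, FS, 1.0, rng, sd=5.0)
        wave = make_spindle_waveform(10.5, 1.0, 60, FS)
        x[12000 : 12000 + wave.size] += wave
        events = detect_spindles(x, FS, band=(9.0, 12.0), kind="SLOW_SPINDLE",
                                 min_peak_rms_uv=15.0)
        assert len(events) == 1
        assert events["kind"].iloc[0] == "SLOW_SPINDLE"


def _so_row(anchor, participant="p", channel="F2"):
    return dict(participant=participant, channel=channel, kind="SO",
                anchor_s=anchor, onset_s=anchor - 0.3, offset_s=anchor + 0.8,
                duration_s=1.1, resp_phase_rad=np.nan)


def _sp_row(onset, participant="p", channel="F2"):
    return dict(participant=participant, channel=channel, kind="SPINDLE",
                anchor_s=onset, onset_s=onset, offset_s=onset + 1.0,
                duration_s=1.0, resp_phase_rad=np.nan)


class TestSOSpindlePairing:
    def test_boundary_inclusive(self):
        so = pd.DataFrame([_so_row(10.0)])
        sp = pd.DataFrame([_sp_row(11.5)])
        pairs = detect_so_spindles(so, sp)
        assert len(pairs) == 1

    def test_outside_window_excluded(self):
        so = pd.DataFrame([_so_row(10.0)])
        sp = pd.DataFrame([_sp_row(11.6)])
        assert len(detect_so_spindles(so, sp)) == 0

    def test_no_spindles_empty(self):
        assert len(detect_so_spindles(pd.DataFrame([_so_row(10.0)]), empty_events())) == 0

    def test_earliest_of_two_spindles_used(self):
        so = pd.DataFrame([_so_row(10.0)])
        sp = pd.DataFrame([_sp_row(11.2), _sp_row(10.6)])
        pairs = detect_so_spindles(so, sp)
        assert len(pairs) == 1
        assert pairs["spindle_onset_s"].iloc[0] == 10.6

    def test_matches_exhaustive_pairing(self, rng):
        so = pd.DataFrame([_so_row(a) for a in np.sort(rng.uniform(0, 300, 40))])
        sp = pd.DataFrame([_sp_row(a) for a in np.sort(rng.uniform(0, 300, 40))])
        pairs = detect_so_spindles(so, sp)
        expected = []
        for a in so["anchor_s"]:
            qualifying = [o for o in sp["onset_s"] if a <= o <= a + 1.5]
            if qualifying:
                expected.append((a, min(qualifying)))
        assert len(pairs) == len(expected)
        np.testing.assert_allclose(pairs["spindle_onset_s"].to_numpy(),
                                   [e[1] for e in expected])


class TestEventFreeControls:
    def test_window_arithmetic(self):
        mask = np.ones(int(1200 * FS), bool)
        events = pd.DataFrame([_so_row(600.0)])
        ctrl = sample_event_free(mask, events, FS, n_segments=30, seed=0)
        assert (ctrl["onset_s"] >= 300.0 - 1e-9).all()
        assert (ctrl["offset_s"] <= 900.0 + 1e-9).all()

    def test_controls_never_overlap_events(self, small_participant, validation_config):
        from resposc.events import detect_all

        _, rec, _ = small_participant
        mask = stage_mask(rec)
        events = detect_all(rec, validation_config, channels=["F2"])
        ctrl = sample_event_free(mask, events, rec.fs, seed=1)
        for _, c in ctrl.iterrows():
            overlap = ((events["onset_s"] < c["offset_s"])
                       & (c["onset_s"] < events["offset_s"]))
            assert not overlap.any()
        # controls pairwise disjoint, 4 s long, fully masked-in
        starts = np.sort(ctrl["onset_s"].to_numpy())
        assert np.all(np.diff(starts) >= 4.0 - 1e-9)
        np.testing.assert_allclose(ctrl["duration_s"], 4.0)

    def test_saturated_recording_yields_warning(self):
        mask = np.ones(int(300 * FS), bool)
        events = pd.DataFrame([_so_row(a) for a in np.arange(2.0, 298.0, 2.0)])
        events["onset_s"] = events["anchor_s"] - 1.0
        events["offset_s"] = events["anchor_s"] + 1.0
        with pytest.warns(UserWarning, match="event-free"):
            ctrl = sample_event_free(mask, events, FS, n_segments=10, seed=0)
        assert len(ctrl) == 0

    def test_reproducible_by_seed(self):
        mask = np.ones(int(1200 * FS), bool)
        events = pd.DataFrame([_so_row(a) for a in (100.0, 400.0, 800.0)])
        a = sample_event_free(mask, events, FS, seed=5)
        b = sample_event_free(mask, events, FS, seed=5)
        assert a.equals(b)


def test_so_duration_widening_never_decreases_count(rng):
    x = generate_background(300, FS, 1.0, rng, sd=10.0)
    narrow = detect_so(x, FS, duration_s=(0.9, 1.8))
    wide = detect_so(x, FS, duration_s=(0.8, 2.0))
    assert len(wide) >= len(narrow)


def test_detection_reproducible(small_participant, validation_config):
    from resposc.events import detect_all

    _, rec, _ = small_participant
    a = detect_all(rec, validation_config, channels=["F2"])
    b = detect_all(rec, validation_config, channels=["F2"])
    assert a.equals(b)
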