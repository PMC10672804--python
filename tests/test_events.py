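"""Spindle and slow oscillation detectors with individual thresholds."""

import numpy as np
import pytest

from sospin import (
    GeneratorConfig,
    SpindlePeak,
    detect_sos,
    detect_spindles,
    generate_recording,
    individual_band,
    summarize_features,
)
from sospin.synth import _so_waveform, _spindle_waveform


class TestIndividualBand:
    @pytest.mark.parametrize("peak,expected", [(11.2, (9.7, 12.7)), (13.0, (11.5, 14.5))])
    def test_band_arithmetic(self, peak, expected):
        band = individual_band(SpindlePeak(peak, 1.0, "cp"))
        assert band.lo == pytest.approx(expected[0])
        assert band.hi == pytest.approx(expected[1])
        assert not band.below_canonical

    def test_low_peak_flags_sub9_edge(self):
        with pytest.warns(UserWarning, match="below 9"):
            band = individual_band(SpindlePeak(9.0, 1.0, "cp"))
        assert (band.lo, band.hi) == (7.5, 10.5)
        assert band.below_canonical


def make_signal_with_bursts(duration=300.0, fs=256.0, bursts=(), noise_uv=0.5, freq=13.0, seed=0):
    """Tiny noise floor + constant-amplitude 13 Hz bursts at given (start, stop, amp)."""
    rng = np.random.default_rng(seed)
    n = int(duration * fs)
    t = np.arange(n) / fs
    x = rng.standard_normal(n) * noise_uv
    for start, stop, amp in bursts:
        sel = (t >= start) & (t < stop)
        x[sel] += amp * np.sin(2 * np.pi * freq * t[sel])
    return x


class TestDetectSpindles:
    def test_pure_sine_never_crosses_threshold(self, quiet_recording):
        # analytic null: for a pure sine, mean RMS = SD = c/sqrt(2), so the
        # threshold is 2.5 c/sqrt(2), above the c/sqrt(2) envelope
        fs = 256.0
        t = np.arange(int(300 * fs)) / fs
        rec = quiet_recording(20.0 * np.sin(2 * np.pi * 13.0 * t), fs=fs)
        assert detect_spindles(rec, "centro-parietal", (12.5, 16.0)) == []

    def test_single_burst_recovered_within_100ms(self, quiet_recording):
        x = make_signal_with_bursts(bursts=[(100.0, 101.0, 20.0)])
        rec = quiet_recording(x)
        events = detect_spindles(rec, "centro-parietal", (12.5, 16.0))
        assert len(events) == 1
        assert abs(events[0].center_s - 100.5) <= 0.1

    def test_close_bursts_merge_into_one_event(self, quiet_recording):
        x = make_signal_with_bursts(bursts=[(10.0, 10.6, 20.0), (10.7, 11.3, 20.0)])
        rec = quiet_recording(x)
        events = detect_spindles(rec, "centro-parietal", (12.5, 16.0))
        assert len(events) == 1
        # envelope smoothing smears edges outward, so bound rather than pin
        assert events[0].onset_s <= 10.05
        assert events[0].offset_s >= 11.25

    def test_merge_rule_on_run_intervals(self):
        from sospin.events import merge_intervals

        assert merge_intervals([(10.0, 10.6), (10.7, 11.3)]) == [(10.0, 11.3)]
        # 1.6 s runs with 0.1 s gap would merge to 3.3 s > 3 s: refused
        assert merge_intervals([(10.0, 11.6), (11.7, 13.3)]) == [(10.0, 11.6), (11.7, 13.3)]

    def test_event_durations_within_bounds(self, default_recording):
        _, rec, _ = default_recording
        events = detect_spindles(rec, "centro-parietal", (11.5, 14.5))
        assert events, "expected spindles in the default synthetic recording"
        for e in events:
            assert 0.5 <= e.duration_s <= 3.0
            assert e.center_s == pytest.approx((e.onset_s + e.offset_s) / 2)

    def test_no_event_overlaps_artifact_second(self, quiet_recording):
        x = make_signal_with_bursts(bursts=[(100.0, 101.0, 20.0), (200.0, 201.0, 20.0)])
        rec = quiet_recording(x, artifact_sec=[200])
        events = detect_spindles(rec, "centro-parietal", (12.5, 16.0))
        assert len(events) == 1
        assert abs(events[0].center_s - 100.5) < 0.2

    def test_amplitude_scaling_equivariance(self, quiet_recording):
        x = make_signal_with_bursts(bursts=[(50.0, 51.2, 15.0), (120.0, 121.0, 25.0)])
        e1 = detect_spindles(quiet_recording(x), "centro-parietal", (12.5, 16.0))
        e2 = detect_spindles(quiet_recording(3.0 * x), "centro-parietal", (12.5, 16.0))
        assert [e.onset_s for e in e1] == [e.onset_s for e in e2]
        for a, b in zip(e1, e2):
            assert b.p2p_amp_uv == pytest.approx(3.0 * a.p2p_amp_uv, rel=1e-9)

    def test_band_outside_nyquist_raises(self, quiet_recording):
        rec = quiet_recording(np.zeros(int(70 * 256)))
        with pytest.raises(ValueError, match="band"):
            detect_spindles(rec, "centro-parietal", (12.5, 200.0))


def so_cycle_signal(duration=300.0, fs=256.0, events=(), freq=0.75):
    """Isolated noiseless SO cycles at (start_s, p2p_amp)."""
    x = np.zeros(int(duration * fs))
    wf = _so_waveform(1.0 / freq, 1.0, fs)
    for start, p2p in events:
        i0 = int(start * fs)
        x[i0 : i0 + len(wf)] += p2p * wf
    return x


class TestDetectSos:
    def test_single_candidate_fails_self_threshold(self, quiet_recording):
        # 1.25 x mean of a single candidate exceeds its own amplitude
        x = so_cycle_signal(events=[(100.0, 150.0)])
        rec = quiet_recording(x, labels=("F3", "F4"))
        assert detect_sos(rec, "frontal") == []
        candidates = detect_sos(rec, "frontal", amp_criterion_factor=0.0)
        assert len(candidates) == 1
        c = candidates[0]
        assert c.end_s - c.start_s == pytest.approx(1 / 0.75, abs=0.05)
        assert 0.5 <= c.freq_hz <= 1.0

    def test_too_fast_pair_rejected_by_frequency_gate(self, quiet_recording):
        x = so_cycle_signal(events=[(100.0, 150.0)], freq=1.25)
        rec = quiet_recording(x, labels=("F3", "F4"))
        assert detect_sos(rec, "frontal", amp_criterion_factor=0.0) == []

    def test_only_outsized_candidate_survives(self, quiet_recording):
        # 10 equal + 1 double: mean = 12/11 x, 1.25*mean = 1.364x -> only 2x passes
        events = [(20.0 + 10 * k, 100.0) for k in range(10)] + [(130.0, 200.0)]
        x = so_cycle_signal(duration=160.0, events=events)
        rec = quiet_recording(x, labels=("F3", "F4"))
        kept = detect_sos(rec, "frontal")
        assert len(kept) == 1
        assert abs(kept[0].down_peak_s - (130.0 + 1 / 3)) < 0.1

    def test_event_geometry_and_bounds(self, default_recording):
        _, rec, _ = default_recording
        sos = detect_sos(rec, "frontal")
        assert sos, "expected SOs in the default synthetic recording"
        for e in sos:
            assert e.start_s < e.down_peak_s < e.up_peak_s < e.end_s
            assert 0.5 <= e.freq_hz <= 1.0

    def test_thresholding_is_self_normalizing(self, default_recording):
        _, rec, _ = default_recording
        sos1 = detect_sos(rec, "frontal")
        scaled = type(rec)(
            signal=rec.signal * 7.0,
            sampling_rate_hz=rec.sampling_rate_hz,
            channel_labels=rec.channel_labels,
            hypnogram=rec.hypnogram,
            artifact_mask=rec.artifact_mask,
        )
        sos2 = detect_sos(scaled, "frontal")
        assert [e.down_peak_s for e in sos1] == [e.down_peak_s for e in sos2]
        for a, b in zip(sos1, sos2):
            assert b.p2p_amp_uv == pytest.approx(7.0 * a.p2p_amp_uv, rel=1e-9)


class TestSummarizeFeatures:
    def test_density_ratio(self):
        events = [
            type("E", (), dict(freq_hz=12.0, p2p_amp_uv=30.0, topography="cp", spindle_class="x"))()
            for _ in range(40)
        ]
        s = summarize_features(events, eligible_minutes=10.0)
        assert s.density_per_min == pytest.approx(4.0)

    def test_feature_means(self):
        mk = lambda f: type("E", (), dict(freq_hz=f, p2p_amp_uv=10.0, topography="cp", spindle_class="x"))()
        s = summarize_features([mk(12.0), mk(14.0)], eligible_minutes=5.0)
        assert s.frequency_hz == pytest.approx(13.0)

    def test_empty_events_marked_missing(self):
        s = summarize_features([], eligible_minutes=10.0, topography="cp")
        assert s.density_per_min == 0.0
        assert np.isnan(s.frequency_hz) and np.isnan(s.amplitude_uv)

    def test_zero_minutes_rejected(self):
        with pytest.raises(ValueError):
            summarize_features([], eligible_minutes=0.0)
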