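"""Synthetic polysomnography generator: spectra, event placement, coupling."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from sospin import (
    CohortSpec,
    GeneratorConfig,
    generate_background,
    generate_cohort,
    generate_recording,
    inject_sos,
    inject_spindles,
    simulate_events,
)
from sospin.synth import adult_like_spec, age_gradient_configs, child_like_spec, draw_cohort_configs


def welch_loglog_slope(x, fs, lo=2.0, hi=30.0):
    """Independent spectral-slope oracle: Welch PSD + least-squares fit."""
    f, p = sps.welch(x, fs=fs, nperseg=4096)
    sel = (f >= lo) & (f <= hi)
    slope, _ = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)
    return slope


class TestBackground:
    def test_spectral_slope_recovered(self):
        slopes = [welch_loglog_slope(generate_background(600, 256, 10, 2, s), 256) for s in range(5)]
        assert abs(np.mean(slopes) - (-2.0)) < 0.1

    def test_zero_scale_gives_silence(self):
        assert np.all(generate_background(10, 256, 0, 2, 1) == 0)

    def test_deterministic_given_seed(self):
        a = generate_background(10, 256, 5, 1.5, 42)
        b = generate_background(10, 256, 5, 1.5, 42)
        assert np.array_equal(a, b)

    def test_zero_mean(self):
        x = generate_background(60, 256, 50, 1.5, 0)
        assert abs(x.mean()) < 1e-9

    @pytest.mark.parametrize(
        "args",
        [(0, 256, 1.0, 1.5), (10, -1, 1.0, 1.5), (10, 256, 1.0, 0.0), (10, 256, -1.0, 1.5)],
    )
    def test_rejects_bad_inputs(self, args):
        with pytest.raises(ValueError):
            generate_background(*args, seed=0)


class TestInjectSos:
    def test_count_is_density_times_duration(self):
        cfg = GeneratorConfig(duration_s=600, so_density_per_min=5, artifact_fraction=0.0, seed=0)
        sig = np.zeros((len(cfg.channel_labels), int(600 * 256)))
        _, gt = inject_sos(sig, cfg, seed=0)
        assert len(gt) == 50

    def test_waveform_span_is_one_period(self):
        cfg = GeneratorConfig(duration_s=300, so_freq_hz=0.75, so_density_per_min=2, artifact_fraction=0.0, seed=1)
        sig = np.zeros((len(cfg.channel_labels), int(300 * 256)))
        _, gt = inject_sos(sig, cfg, seed=1)
        spans = gt["end_s"] - gt["start_s"]
        assert np.allclose(spans, 1 / 0.75, atol=1e-9)

    def test_noiseless_peak_to_peak_matches_config(self):
        cfg = GeneratorConfig(
            duration_s=300,
            so_amp_frontal_uv=300.0,
            so_amp_centroparietal_uv=150.0,
            so_density_per_min=2,
            artifact_fraction=0.0,
            seed=2,
        )
        sig = np.zeros((len(cfg.channel_labels), int(300 * 256)))
        sig, gt = inject_sos(sig, cfg, seed=2)
        i_f = cfg.channel_labels.index("F3")
        i_c = cfg.channel_labels.index("Cz")
        row = gt.iloc[0]
        lo, hi = int(row.start_s * 256), int(row.end_s * 256)
        assert sig[i_f, lo:hi].max() - sig[i_f, lo:hi].min() == pytest.approx(300.0, rel=1e-3)
        assert sig[i_c, lo:hi].max() - sig[i_c, lo:hi].min() == pytest.approx(150.0, rel=1e-3)

    def test_unplaceable_density_raises_naming_density(self):
        cfg = GeneratorConfig(duration_s=60, so_density_per_min=100, artifact_fraction=0.0, seed=0)
        sig = np.zeros((len(cfg.channel_labels), int(60 * 256)))
        with pytest.raises(ValueError, match="100"):
            inject_sos(sig, cfg, seed=0)


class TestInjectSpindles:
    def test_uniform_phase_has_small_resultant(self):
        # circular-statistics oracle on the planted phases
        cfg = GeneratorConfig(
            duration_s=1200,
            coupled_fraction=1.0,
            coupling_kappa=0.0,
            spindle_density_per_min=10,
            seed=3,
        )
        gt = simulate_events(cfg)
        phases = gt.spindle_events.query("coupled")["so_phase_rad"].to_numpy()
        assert len(phases) == 200
        assert abs(np.exp(1j * phases).mean()) < 0.15

    def test_uncoupled_centers_avoid_so_windows(self):
        cfg = GeneratorConfig(duration_s=600, coupled_fraction=0.0, seed=4)
        gt = simulate_events(cfg)
        centers = gt.spindle_events["center_s"].to_numpy()
        for _, so in gt.so_events.iterrows():
            assert not np.any((centers > so.start_s - 1.2) & (centers < so.end_s + 1.2))

    def test_tight_coupling_lands_near_up_peak(self):
        # von Mises quantile: at kappa=20 nearly all mass lies within
        # +-0.25 s of the up peak for a 0.75 Hz slow oscillation
        cfg = GeneratorConfig(
            duration_s=1200,
            coupled_fraction=1.0,
            coupling_kappa=20.0,
            coupling_phase_rad=0.0,
            so_freq_hz=0.75,
            spindle_density_per_min=6,
            seed=5,
        )
        gt = simulate_events(cfg)
        ups = gt.so_events["up_peak_s"].to_numpy()
        centers = gt.spindle_events.query("coupled")["center_s"].to_numpy()
        near = [np.abs(ups - c).min() <= 0.25 for c in centers]
        assert np.mean(near) >= 0.9

    def test_infinite_concentration_hits_configured_phase(self):
        cfg = GeneratorConfig(
            duration_s=600, coupled_fraction=1.0, coupling_kappa=1e8, seed=6
        )
        gt = simulate_events(cfg)
        ups = gt.so_events["up_peak_s"].to_numpy()
        centers = gt.spindle_events.query("coupled")["center_s"].to_numpy()
        dt = np.array([np.abs(ups - c).min() for c in centers])
        assert np.all(dt <= 1.0 / 256 + 1e-9)

    def test_coupling_without_sos_raises(self):
        cfg = GeneratorConfig(duration_s=600, coupled_fraction=0.5, so_density_per_min=0.0, seed=0)
        sig = np.zeros((len(cfg.channel_labels), int(600 * 256)))
        empty = simulate_events(
            GeneratorConfig(duration_s=600, so_density_per_min=0.0, coupled_fraction=0.0, seed=0)
        ).so_events
        with pytest.raises(ValueError, match="SO"):
            inject_spindles(sig, cfg, empty.iloc[0:0], seed=0)


class TestGroundTruthInvariants:
    def test_counts_and_bounds(self, default_recording):
        cfg, rec, gt = default_recording
        n_min = cfg.duration_s / 60
        assert len(gt.so_events) == round(cfg.so_density_per_min * n_min)
        assert len(gt.spindle_events) == round(cfg.spindle_density_per_min * n_min)
        for col in ("start_s", "down_peak_s", "up_peak_s", "end_s"):
            assert gt.so_events[col].between(0, cfg.duration_s).all()
        assert gt.spindle_events["center_s"].between(0, cfg.duration_s).all()

    def test_recording_geometry(self, default_recording):
        cfg, rec, gt = default_recording
        assert rec.n_samples == round(cfg.duration_s * cfg.sampling_rate_hz)
        assert len(rec.hypnogram) == int(np.ceil(cfg.duration_s / 30))
        assert rec.artifact_mask.shape == (rec.n_channels, int(np.ceil(cfg.duration_s)))

    def test_rendering_deterministic(self):
        cfg = GeneratorConfig(duration_s=120, seed=9)
        r1, g1 = generate_recording(cfg)
        r2, g2 = generate_recording(cfg)
        assert np.array_equal(r1.signal, r2.signal)
        pd.testing.assert_frame_equal(g1.spindle_events, g2.spindle_events)


class TestCohort:
    def test_cardinality(self):
        spec = CohortSpec(n_subjects=10, base=GeneratorConfig(duration_s=60, artifact_fraction=0.0))
        cohort, meta = generate_cohort(spec, seed=0)
        assert len(cohort) == 10
        assert len(meta) == 10

    def test_metadata_deterministic(self):
        spec = child_like_spec(4, duration_s=60.0)
        _, m1 = draw_cohort_configs(spec, seed=5)
        _, m2 = draw_cohort_configs(spec, seed=5)
        assert m1.to_csv() == m2.to_csv()

    def test_age_gradient_monotone_in_expectation(self):
        configs, meta = age_gradient_configs(10, seed=0, duration_s=60)
        assert len(configs) == 10
        assert meta["age"].is_monotonic_increasing
        # kappa and frontal SO amplitude trend upward along the axis
        assert np.corrcoef(meta["age"], meta["coupling_kappa"])[0, 1] > 0.5
        assert np.corrcoef(meta["age"], meta["so_amp_frontal_uv"])[0, 1] > 0.5

    def test_presets_have_expected_contrast(self):
        child = child_like_spec(2)
        adult = adult_like_spec(2)
        assert child.base.spindle_freq_hz < adult.base.spindle_freq_hz
        assert child.base.coupling_kappa < adult.base.coupling_kappa
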