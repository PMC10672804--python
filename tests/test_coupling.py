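"""SO-spindle coupling: trials, t-maps, PETHs, surrogates, KL divergence."""

import numpy as np
import pytest

from sospin import (
    GeneratorConfig,
    TrialSet,
    cluster_test_peth,
    co_occurrence,
    detect_sos,
    downsample_control,
    extract_trials,
    kl_divergence,
    peth,
    peth_with_surrogate,
    simulate_events,
    surrogate_peth,
    tf_contrast,
)
from sospin.coupling import mean_up_peak_latency


class TestExtractTrials:
    def test_counts_match_and_windows_disjoint(self, default_recording):
        _, rec, _ = default_recording
        sos = detect_sos(rec, "frontal")
        so_tr, non_tr = extract_trials(rec, sos, "centro-parietal", seed=0)
        assert so_tr.trials.shape == non_tr.trials.shape
        downs = np.array([e.down_peak_s for e in sos])
        dmin = np.abs(non_tr.centers_s[:, None] - downs[None, :]).min()
        assert dmin > 6.0  # non-SO windows overlap no SO window

    def test_artifact_window_excluded(self, default_recording):
        _, rec, _ = default_recording
        sos = detect_sos(rec, "frontal")
        so_tr, _ = extract_trials(rec, sos, "centro-parietal", seed=0)
        eligible = rec.eligible_seconds("centro-parietal")
        for c in so_tr.centers_s:
            assert eligible[int(c - 3) : int(np.ceil(c + 3))].all()


class TestTfContrast:
    def make_trials(self, n=12, fs=256.0, seed=0):
        rng = np.random.default_rng(seed)
        L = int(6 * fs)
        return rng.standard_normal((n, L)) * 5, (np.arange(L) - L // 2) / fs

    def test_identical_sets_give_zero_map(self):
        x, _ = self.make_trials()
        tfc = tf_contrast(TrialSet(x, "SO down peak", 256.0), TrialSet(x.copy(), "random non-SO", 256.0))
        assert np.abs(tfc.tmap).max() < 1e-9
        assert tfc.times_s[0] == pytest.approx(-1.2)
        assert tfc.times_s[-1] == pytest.approx(1.2)
        assert np.allclose(np.diff(tfc.times_s), 0.002)

    def test_label_swap_negates_map(self):
        x, _ = self.make_trials(seed=1)
        y, _ = self.make_trials(seed=2)
        a = tf_contrast(TrialSet(x, "SO down peak", 256.0), TrialSet(y, "random non-SO", 256.0))
        b = tf_contrast(TrialSet(y, "SO down peak", 256.0), TrialSet(x, "random non-SO", 256.0))
        assert np.allclose(a.tmap, -b.tmap, atol=1e-9)

    def test_planted_burst_localized(self):
        x, t = self.make_trials(n=30, seed=3)
        y, _ = self.make_trials(n=30, seed=4)
        x = x + 8.0 * np.exp(-((t - 0.4) ** 2) / (2 * 0.1**2)) * np.sin(2 * np.pi * 13 * t)
        tfc = tf_contrast(TrialSet(x, "SO down peak", 256.0), TrialSet(y, "random non-SO", 256.0))
        i, j = np.unravel_index(np.argmax(tfc.tmap), tfc.tmap.shape)
        assert abs(tfc.freqs_hz[i] - 13.0) <= 1.0
        assert abs(tfc.times_s[j] - 0.4) <= 0.15

    def test_single_trial_rejected(self):
        x, _ = self.make_trials(n=1)
        with pytest.raises(ValueError):
            tf_contrast(TrialSet(x, "SO down peak", 256.0), TrialSet(x, "random non-SO", 256.0))


class TestCoOccurrence:
    def test_simple_ratio(self):
        spindles = np.array([0.5, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0])
        sos = np.array([0.6, 10.4, 20.9])  # first three spindles within 1.2 s
        res = co_occurrence(spindles, sos)
        assert res.spindles_near_so_pct == pytest.approx(30.0)
        assert res.sos_near_spindle_pct == pytest.approx(100.0)

    def test_empty_reference_is_undefined_not_zero(self):
        res = co_occurrence(np.array([1.0, 2.0]), np.array([]))
        assert np.isnan(res.spindles_near_so_pct)
        assert np.isnan(res.sos_near_spindle_pct)

    def test_fully_coupled_cohort_near_total_co_occurrence(self):
        cfg = GeneratorConfig(duration_s=600, coupled_fraction=1.0, coupling_kappa=20.0, seed=7)
        gt = simulate_events(cfg)
        res = co_occurrence(gt.spindle_events, gt.so_events)
        assert res.spindles_near_so_pct >= 95.0


class TestPeth:
    def test_single_event_fills_its_bin(self):
        out = peth(np.array([100.45]), np.array([100.0]))
        assert out.n_spindles_in_windows == 1
        idx = np.searchsorted(out.bin_edges_s, 0.45, side="right") - 1
        assert out.observed_pct[idx] == pytest.approx(100.0)
        assert np.nansum(out.observed_pct) == pytest.approx(100.0)

    def test_center_at_window_edge_excluded(self):
        out = peth(np.array([101.2]), np.array([100.0]))
        assert out.n_spindles_in_windows == 0
        assert np.all(np.isnan(out.observed_pct))

    def test_uniform_placement_approaches_uniform_bins(self):
        rng = np.random.default_rng(0)
        centers = rng.uniform(-1.2, 1.2, size=10_000) + 500.0
        out = peth(centers, np.array([500.0]))
        assert np.all(np.abs(out.observed_pct - 100.0 / 24.0) < 1.0)

    def test_percentages_sum_to_hundred(self, default_recording):
        _, rec, gt = default_recording
        out = peth(gt.spindle_events, gt.so_events)
        assert out.observed_pct.sum() == pytest.approx(100.0)


class TestSurrogate:
    def test_expectation_is_uniform(self):
        # realistic peaked PETH: up-peak bins elevated, flanks depressed
        obs = np.full(24, 2.5)
        obs[14:18] = (12.0, 15.0, 10.0, 8.0)
        obs *= 100.0 / obs.sum()
        sur = surrogate_peth(obs, n_shuffles=1000, seed=0)
        assert np.all(np.abs(sur - 100.0 / 24.0) < 0.5)
        assert sur.sum() == pytest.approx(100.0)

    def test_uniform_observed_is_fixed_point(self):
        obs = np.full(24, 100.0 / 24.0)
        sur = surrogate_peth(obs, n_shuffles=10, seed=1)
        assert np.allclose(sur, obs)

    def test_deterministic_given_seed(self):
        obs = np.arange(24, dtype=float)
        assert np.array_equal(surrogate_peth(obs, 100, seed=3), surrogate_peth(obs, 100, seed=3))


class TestKlDivergence:
    def test_printed_formula_hand_values(self):
        assert kl_divergence([70, 30], [50, 50]) == pytest.approx(0.08228, abs=5e-5)
        assert kl_divergence([100, 0], [50, 50]) == pytest.approx(np.log(2), rel=1e-12)
        assert kl_divergence([30, 70], [30, 70]) == 0.0

    def test_scale_invariance(self):
        p, q = [0.7, 0.3], [50.0, 50.0]
        assert kl_divergence(p, q) == pytest.approx(kl_divergence([70, 30], [0.5, 0.5]), rel=1e-12)

    def test_non_negative(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.dirichlet(np.ones(24))
            q = rng.dirichlet(np.ones(24))
            assert kl_divergence(p, q) >= 0

    def test_zero_q_on_support_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            kl_divergence([50, 50], [100, 0])


class TestClusterTestPeth:
    def test_zero_effect_gives_no_clusters(self):
        obs = np.tile(np.linspace(1, 5, 24), (8, 1))
        res = cluster_test_peth(obs, obs.copy(), n_perm=100, seed=0)
        assert res.clusters == []

    def test_coupled_cohort_shows_positive_cluster_at_up_peak(self):
        observed, surrogate, up_bins = [], [], []
        for s in range(12):
            cfg = GeneratorConfig(
                duration_s=600, coupled_fraction=0.8, coupling_kappa=8.0, seed=300 + s
            )
            gt = simulate_events(cfg)
            pe = peth_with_surrogate(gt.spindle_events, gt.so_events, seed=s)
            observed.append(pe.observed_pct)
            surrogate.append(pe.surrogate_pct)
            up_bins.append(
                np.searchsorted(pe.bin_edges_s, mean_up_peak_latency(gt.so_events), side="right") - 1
            )
        res = cluster_test_peth(np.stack(observed), np.stack(surrogate), n_perm=500, seed=1)
        sig_pos = [c for c in res.significant if c.sign > 0]
        assert sig_pos
        big = max(sig_pos, key=lambda c: c.cluster_mass)
        assert big.mask[int(np.median(up_bins))]


class TestDownsampleControl:
    def test_full_fraction_is_identity(self, default_recording):
        _, _, gt = default_recording
        full = peth(gt.spindle_events, gt.so_events)
        down = downsample_control(gt.spindle_events, gt.so_events, fraction=1.0, seed=0)
        assert np.allclose(full.observed_pct, down.observed_pct)

    def test_half_sample_keeps_peak_bin(self):
        cfg = GeneratorConfig(duration_s=1200, coupled_fraction=1.0, coupling_kappa=12.0, seed=13)
        gt = simulate_events(cfg)
        full = peth(gt.spindle_events, gt.so_events)
        down = downsample_control(gt.spindle_events, gt.so_events, fraction=0.5, n_draws=100, seed=2)
        assert np.argmax(full.observed_pct) == np.argmax(down.observed_pct)

    def test_deterministic_given_seed(self, default_recording):
        _, _, gt = default_recording
        a = downsample_control(gt.spindle_events, gt.so_events, seed=5)
        b = downsample_control(gt.spindle_events, gt.so_events, seed=5)
        assert np.array_equal(a.observed_pct, b.observed_pct)


class TestKlMonotonicity:
    def test_median_kl_increases_with_concentration(self):
        medians = []
        for kappa in (0.0, 2.0, 8.0):
            kls = []
            for s in range(10):
                cfg = GeneratorConfig(
                    duration_s=600, coupled_fraction=1.0, coupling_kappa=kappa, seed=900 + s
                )
                gt = simulate_events(cfg)
                pe = peth_with_surrogate(gt.spindle_events, gt.so_events, seed=s)
                kls.append(pe.kl_divergence_nats)
            medians.append(np.median(kls))
        assert medians[0] < medians[1] < medians[2]
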