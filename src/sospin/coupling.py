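"""Slow oscillation-spindle coupling statistics.

Two complementary views of coupling:

* **Spectral**: Morlet power (12 cycles, 5-20 Hz) in SO-locked trials
  (down peak +- 3 s) contrasted with matched SO-free trials per subject
  (two-sample t map, cropped to +-1.2 s), then tested against zero across
  subjects with a cluster-based permutation test.

* **Event timing**: peri-event time histograms (PETHs) of spindle centres
  in 100-ms bins within +-1.2 s of SO down peaks, normalised to percent of
  in-window spindles; a bin-shuffled surrogate is the chance reference and
  the Kullback-Leibler divergence between observed and surrogate PETH is
  the modulation-strength index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .cluster import ClusterResult, cluster_permutation_1samp
from .recording import NREM_STAGES, Recording

TRIAL_HALF_S = 3.0
CROP_HALF_S = 1.2
TF_FREQS_HZ = np.arange(5.0, 21.0, 1.0)
TF_TIME_STEP_S = 0.002
N_CYCLES = 12
PETH_WINDOW_S = 1.2
PETH_BIN_S = 0.1
N_PETH_BINS = 24


def _center_times(events) -> np.ndarray:
    """Spindle centre times from an event list, DataFrame, or array."""
    if hasattr(events, "columns"):
        return np.asarray(events["center_s"], float)
    if len(events) and hasattr(events[0], "center_s"):
        return np.array([e.center_s for e in events], float)
    return np.asarray(events, float)


def _down_peak_times(events) -> np.ndarray:
    if hasattr(events, "columns"):
        return np.asarray(events["down_peak_s"], float)
    if len(events) and hasattr(events[0], "down_peak_s"):
        return np.array([e.down_peak_s for e in events], float)
    return np.asarray(events, float)


def _up_peak_times(events) -> np.ndarray:
    if hasattr(events, "columns"):
        return np.asarray(events["up_peak_s"], float)
    if len(events) and hasattr(events[0], "up_peak_s"):
        return np.array([e.up_peak_s for e in events], float)
    return np.asarray(events, float)


# ---------------------------------------------------------------------------
# trials and time-frequency contrast
# ---------------------------------------------------------------------------

@dataclass
class TrialSet:
    trials: np.ndarray  # (n_trials, n_samples), µV
    anchor: str  # "SO down peak" | "random non-SO"
    sampling_rate_hz: float
    centers_s: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def times_s(self) -> np.ndarray:
        n = self.trials.shape[1]
        return (np.arange(n) - n // 2) / self.sampling_rate_hz


@dataclass
class TFContrast:
    times_s: np.ndarray
    freqs_hz: np.ndarray
    tmap: np.ndarray  # (n_freqs, n_times)
    n_so_trials: int
    n_nonso_trials: int


def extract_trials(
    recording: Recording,
    so_events,
    channel_set,
    seed: int | np.random.Generator | None = None,
    stages=NREM_STAGES,
) -> tuple[TrialSet, TrialSet]:
    """SO-locked trials (down peak +- 3 s, fully artifact-free NREM) and an
    equal number of SO-free trials whose 6-s windows overlap no SO window."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = recording.sampling_rate_hz
    x = recording.averaged_signal(channel_set)
    eligible = recording.eligible_seconds(channel_set, stages)
    half = int(round(TRIAL_HALF_S * fs))
    duration = recording.duration_s

    down_peaks = _down_peak_times(so_events)

    def window_ok(center: float) -> bool:
        lo, hi = center - TRIAL_HALF_S, center + TRIAL_HALF_S
        if lo < 0 or hi > duration:
            return False
        sec = eligible[int(lo) : int(math.ceil(hi))]
        return bool(sec.size and sec.all())

    so_centers = [t for t in down_peaks if window_ok(t)]
    if not so_centers:
        raise ValueError("no artifact-free SO windows available")
    so_trials = np.stack(
        [x[int(round(t * fs)) - half : int(round(t * fs)) + half] for t in so_centers]
    )

    n_needed = len(so_centers)
    non_centers: list[float] = []
    for _try in range(200 * n_needed):
        if len(non_centers) == n_needed:
            break
        t = float(rng.uniform(TRIAL_HALF_S, duration - TRIAL_HALF_S))
        if not window_ok(t):
            continue
        if np.min(np.abs(down_peaks - t)) < 2 * TRIAL_HALF_S:
            continue
        non_centers.append(t)
    if len(non_centers) < n_needed:
        raise ValueError(
            f"could only place {len(non_centers)} of {n_needed} SO-free trials; "
            "recording too short or SO density too high"
        )
    non_trials = np.stack(
        [x[int(round(t * fs)) - half : int(round(t * fs)) + half] for t in non_centers]
    )
    return (
        TrialSet(so_trials, "SO down peak", fs, np.array(so_centers)),
        TrialSet(non_trials, "random non-SO", fs, np.array(sorted(non_centers))),
    )


def _morlet_power(trials: np.ndarray, fs: float, freqs: np.ndarray) -> np.ndarray:
    from mne.time_frequency import tfr_array_morlet

    power = tfr_array_morlet(
        trials[:, None, :], fs, freqs=freqs, n_cycles=N_CYCLES, output="power", verbose="error"
    )
    return power[:, 0]  # (n_trials, n_freqs, n_times)


def tf_contrast(
    so_trials: TrialSet,
    nonso_trials: TrialSet,
    freqs_hz: np.ndarray = TF_FREQS_HZ,
    crop_half_s: float = CROP_HALF_S,
    time_step_s: float = TF_TIME_STEP_S,
    equal_var: bool = True,
) -> TFContrast:
    """Per-subject two-sample t map (SO minus non-SO Morlet power) on the
    +-1.2 s / 0.002 s output grid (native-rate power linearly interpolated
    in time)."""
    if so_trials.trials.shape[0] < 2 or nonso_trials.trials.shape[0] < 2:
        raise ValueError("need at least 2 trials per condition")
    fs = so_trials.sampling_rate_hz
    freqs_hz = np.asarray(freqs_hz, float)
    p_so = _morlet_power(so_trials.trials, fs, freqs_hz)
    p_non = _morlet_power(nonso_trials.trials, fs, freqs_hz)

    t_native = so_trials.times_s
    keep = np.abs(t_native) <= crop_half_s + 2.0 / fs
    t_native = t_native[keep]
    p_so = p_so[:, :, keep]
    p_non = p_non[:, :, keep]

    tstat = stats.ttest_ind(p_so, p_non, axis=0, equal_var=equal_var).statistic

    out_times = np.arange(-crop_half_s, crop_half_s + time_step_s / 2.0, time_step_s)
    tmap = np.stack([np.interp(out_times, t_native, row) for row in tstat])
    return TFContrast(
        times_s=out_times,
        freqs_hz=freqs_hz,
        tmap=tmap,
        n_so_trials=so_trials.trials.shape[0],
        n_nonso_trials=nonso_trials.trials.shape[0],
    )


def cluster_test_tf(
    tmaps: Sequence[TFContrast] | np.ndarray,
    n_perm: int = 5000,
    cluster_alpha: float = 0.05,
    seed: int | None = None,
) -> ClusterResult:
    """Group-level test of subject t-maps against zero (sign-flip
    cluster-mass permutation, doubled p values)."""
    if len(tmaps) and isinstance(tmaps[0], TFContrast):
        data = np.stack([m.tmap for m in tmaps])
    else:
        data = np.asarray(tmaps, float)
    return cluster_permutation_1samp(data, n_perm=n_perm, cluster_alpha=cluster_alpha, seed=seed)


# ---------------------------------------------------------------------------
# event-timing coupling
# ---------------------------------------------------------------------------

@dataclass
class PETH:
    bin_edges_s: np.ndarray  # 25 edges, -1.2 .. +1.2
    observed_pct: np.ndarray  # 24 values summing to 100 (NaN when undefined)
    surrogate_pct: np.ndarray | None
    n_spindles_in_windows: int
    kl_divergence_nats: float | None = None

    @property
    def bin_centers_s(self) -> np.ndarray:
        return (self.bin_edges_s[:-1] + self.bin_edges_s[1:]) / 2.0


class CoOccurrence:
    """Bidirectional co-occurrence percentages; NaN marks an undefined
    direction (empty reference list), deliberately distinct from 0."""

    def __init__(self, spindles_near_so_pct: float, sos_near_spindle_pct: float):
        self.spindles_near_so_pct = spindles_near_so_pct
        self.sos_near_spindle_pct = sos_near_spindle_pct

    def __repr__(self) -> str:
        return (
            f"CoOccurrence(spindles_near_so={self.spindles_near_so_pct:.1f}%, "
            f"sos_near_spindle={self.sos_near_spindle_pct:.1f}%)"
        )


def co_occurrence(spindles, sos, window_s: float = PETH_WINDOW_S) -> CoOccurrence:
    """Percentage of spindle centres within +-window of any SO down peak,
    and of SO down peaks within +-window of any spindle centre."""
    centers = _center_times(spindles)
    downs = _down_peak_times(sos)

    def pct(a: np.ndarray, ref: np.ndarray) -> float:
        if a.size == 0 or ref.size == 0:
            return float("nan")
        hits = np.abs(a[:, None] - ref[None, :]).min(axis=1) <= window_s
        return 100.0 * float(hits.sum()) / a.size

    return CoOccurrence(pct(centers, downs), pct(downs, centers))


def _bin_counts(centers: np.ndarray, downs: np.ndarray) -> np.ndarray:
    """Pooled half-open 100-ms-bin counts of spindle centres around every
    down peak; a centre inside two overlapping windows counts in each."""
    counts = np.zeros(N_PETH_BINS)
    for d in downs:
        rel = centers - d
        rel = rel[(rel >= -PETH_WINDOW_S) & (rel < PETH_WINDOW_S)]
        idx = np.floor((rel + PETH_WINDOW_S) / PETH_BIN_S).astype(int)
        np.add.at(counts, idx, 1)
    return counts


def peth(spindles, sos, window_s: float = PETH_WINDOW_S) -> PETH:
    """Observed PETH (percent per 100-ms bin, summing to 100)."""
    centers = _center_times(spindles)
    downs = _down_peak_times(sos)
    edges = np.linspace(-window_s, window_s, N_PETH_BINS + 1)
    counts = _bin_counts(centers, downs)
    total = counts.sum()
    if total == 0:
        return PETH(edges, np.full(N_PETH_BINS, np.nan), None, 0)
    return PETH(edges, 100.0 * counts / total, None, int(total))


def surrogate_peth(
    observed: PETH | np.ndarray,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Chance reference: the observed percentage vector shuffled across
    bins ``n_shuffles`` times and averaged elementwise."""
    obs = observed.observed_pct if isinstance(observed, PETH) else np.asarray(observed, float)
    if np.any(~np.isfinite(obs)):
        raise ValueError("cannot build a surrogate for an undefined PETH")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    acc = np.zeros_like(obs)
    for _ in range(n_shuffles):
        acc += rng.permutation(obs)
    return acc / n_shuffles


def kl_divergence(p_pct: np.ndarray, q_pct: np.ndarray) -> float:
    """KL divergence (nats) between two binned distributions given on any
    common scale; both are rescaled to proportions first.  Terms with
    ``p_i = 0`` contribute zero; ``q_i = 0`` with ``p_i > 0`` is undefined."""
    p = np.asarray(p_pct, float)
    q = np.asarray(q_pct, float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("probabilities must be non-negative")
    p = p / p.sum()
    q = q / q.sum()
    support = p > 0
    if np.any(q[support] == 0):
        raise ValueError("q is zero where p > 0; KL divergence undefined")
    return float(np.sum(p[support] * np.log(p[support] / q[support])))


def peth_with_surrogate(
    spindles,
    sos,
    n_shuffles: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> PETH:
    """Observed PETH, bin-shuffled surrogate and their KL divergence."""
    out = peth(spindles, sos)
    if out.n_spindles_in_windows == 0:
        return out
    out.surrogate_pct = surrogate_peth(out, n_shuffles=n_shuffles, seed=seed)
    out.kl_divergence_nats = kl_divergence(out.observed_pct, out.surrogate_pct)
    return out


def cluster_test_peth(
    observed: np.ndarray,
    surrogate: np.ndarray,
    n_perm: int = 5000,
    cluster_alpha: float = 0.05,
    seed: int | None = None,
) -> ClusterResult:
    """Paired test of observed vs surrogate PETHs across subjects: per-bin
    dependent t on the differences, 1-D adjacency clusters, sign-flip
    (condition-swap) max-mass null, doubled p."""
    observed = np.asarray(observed, float)
    surrogate = np.asarray(surrogate, float)
    if observed.shape != surrogate.shape:
        raise ValueError("observed and surrogate must have matching subjects x bins")
    return cluster_permutation_1samp(
        observed - surrogate, n_perm=n_perm, cluster_alpha=cluster_alpha, seed=seed
    )


def downsample_control(
    spindles,
    sos,
    fraction: float = 0.5,
    n_draws: int = 100,
    seed: int | np.random.Generator | None = None,
) -> PETH:
    """PETH averaged over random subsets of the spindles — a control for
    event-count differences between spindle classes."""
    centers = _center_times(spindles)
    if centers.size < 2:
        raise ValueError("need at least 2 spindles")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = max(int(round(fraction * centers.size)), 1)
    edges = np.linspace(-PETH_WINDOW_S, PETH_WINDOW_S, N_PETH_BINS + 1)
    if k >= centers.size:
        return peth(centers, sos)
    acc = np.zeros(N_PETH_BINS)
    total = 0
    n_valid = 0
    for _ in range(n_draws):
        sub = rng.choice(centers, size=k, replace=False)
        draw = peth(sub, sos)
        if draw.n_spindles_in_windows == 0:
            continue
        acc += draw.observed_pct
        total += draw.n_spindles_in_windows
        n_valid += 1
    if n_valid == 0:
        return PETH(edges, np.full(N_PETH_BINS, np.nan), None, 0)
    return PETH(edges, acc / n_valid, None, total)


def mean_up_peak_latency(sos) -> float:
    """Mean up-peak latency relative to the down peak (s); locates the bin
    where coupled spindles should concentrate."""
    downs = _down_peak_times(sos)
    ups = _up_peak_times(sos)
    return float(np.mean(ups - downs))
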