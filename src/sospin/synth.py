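"""Synthetic polysomnography with ground-truth events.

Generates recordings whose statistical structure matches the assumptions of
the detection and coupling analyses: a 1/f (``A * f**-a``) background,
slow-oscillation (SO) half-wave pairs at 0.5-1 Hz with a configurable
frontal-vs-posterior amplitude gradient, and Hann-windowed spindle bursts
(9-16 Hz, 0.5-3 s) of which a configurable fraction is phase-locked to SOs
via a von Mises phase distribution.

Event counts are deterministic, ``round(density * duration)``, so that
cardinality checks are exact.  SO phase convention: phase 0 = up peak,
+-pi = down peak, defined on the 0.2-4 Hz waveform; a coupled spindle with
phase theta is centred at ``up_peak + theta * T / (2*pi)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .recording import CHANNEL_GROUPS, EPOCH_S, Recording

SO_GT_COLUMNS = (
    "channel_group",
    "start_s",
    "down_peak_s",
    "up_peak_s",
    "end_s",
    "neg_amp_uv",
    "p2p_amp_uv",
)
SPINDLE_GT_COLUMNS = (
    "channel_group",
    "onset_s",
    "offset_s",
    "center_s",
    "freq_hz",
    "amp_uv",
    "coupled",
    "so_phase_rad",
)

#: exclusion margin (s) around an SO inside which uncoupled spindles are
#: never placed; matches the +-1.2 s co-occurrence window downstream.
SO_EXCLUSION_MARGIN_S = 1.2


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic recording.

    Amplitudes are µV, densities events/min, durations seconds.  The
    background power spectral density is ``A * f**-a`` (µV²/Hz) between
    0.5 and 35 Hz.
    """

    duration_s: float = 600.0
    sampling_rate_hz: float = 256.0
    channel_labels: tuple[str, ...] = ("F3", "F4", "C3", "Cz", "C4", "Pz", "Oz")
    background_scale_A: float = 100.0
    background_exponent_a: float = 1.5
    so_density_per_min: float = 3.0
    so_amp_frontal_uv: float = 250.0
    so_amp_centroparietal_uv: float = 150.0
    so_freq_hz: float = 0.75
    spindle_density_per_min: float = 4.0
    spindle_freq_hz: float = 13.0
    spindle_freq_jitter_hz: float = 0.5
    spindle_amp_uv: float = 25.0
    spindle_dur_s: float = 1.5
    spindle_channel_group: str = "centro-parietal"
    coupled_fraction: float = 0.7
    coupling_phase_rad: float = 0.0
    coupling_kappa: float = 5.0
    #: margin (s) around each SO from which uncoupled spindles are barred;
    #: ``None`` places them independently of SO timing (the chance model
    #: for type-I-error simulations)
    so_exclusion_margin_s: float | None = SO_EXCLUSION_MARGIN_S
    artifact_fraction: float = 0.02
    wake_prologue_epochs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if self.background_scale_A < 0:
            raise ValueError("background_scale_A must be >= 0")
        if self.background_exponent_a <= 0:
            raise ValueError("background_exponent_a must be > 0")
        for name in (
            "so_density_per_min",
            "so_amp_frontal_uv",
            "so_amp_centroparietal_uv",
            "spindle_density_per_min",
            "spindle_amp_uv",
            "coupling_kappa",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.5 <= self.so_freq_hz <= 1.0:
            raise ValueError("so_freq_hz must lie in [0.5, 1]")
        if not 9.0 <= self.spindle_freq_hz <= 16.0:
            raise ValueError("spindle_freq_hz must lie in [9, 16]")
        if not 0.5 <= self.spindle_dur_s <= 3.0:
            raise ValueError("spindle_dur_s must lie in [0.5, 3]")
        if not 0.0 <= self.coupled_fraction <= 1.0:
            raise ValueError("coupled_fraction must lie in [0, 1]")
        if not 0.0 <= self.artifact_fraction <= 1.0:
            raise ValueError("artifact_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted events of one synthetic recording (times in s from start)."""

    so_events: pd.DataFrame
    spindle_events: pd.DataFrame

    def __post_init__(self) -> None:
        for df, cols in ((self.so_events, SO_GT_COLUMNS), (self.spindle_events, SPINDLE_GT_COLUMNS)):
            missing = set(cols) - set(df.columns)
            if missing:
                raise ValueError(f"ground-truth table missing columns {missing}")


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def band_rms(A: float, a: float, lo_hz: float, hi_hz: float) -> float:
    """RMS amplitude (µV) of the ``A*f**-a`` background inside a band.

    Closed form of ``sqrt(integral of A*f**-a df)``; used to express burst
    amplitudes as in-band signal-to-noise ratios.
    """
    lo = max(lo_hz, 0.5)
    hi = min(hi_hz, 35.0)
    if hi <= lo:
        return 0.0
    if abs(a - 1.0) < 1e-12:
        power = A * math.log(hi / lo)
    else:
        power = A * (hi ** (1.0 - a) - lo ** (1.0 - a)) / (1.0 - a)
    return math.sqrt(max(power, 0.0))


def generate_background(
    duration_s: float,
    sampling_rate_hz: float,
    A: float,
    a: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """One channel of 1/f background noise (µV), zero mean.

    White Gaussian noise is spectrally shaped so the expected one-sided
    power spectral density equals ``A * f**-a`` between 0.5 and 35 Hz and
    is zero outside, mirroring the band-passed (0.3-35 Hz) acquisition
    chain the analyses assume and avoiding the DC singularity of the
    power law.
    """
    if duration_s <= 0 or sampling_rate_hz <= 0:
        raise ValueError("duration and sampling rate must be positive")
    if A < 0:
        raise ValueError("A must be >= 0")
    if a <= 0:
        raise ValueError("a must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration_s * sampling_rate_hz))
    if A == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate_hz)
    psd = A * np.clip(freqs, 0.5, None) ** (-a)
    psd[(freqs < 0.5) | (freqs > 35.0)] = 0.0
    psd[0] = 0.0
    # E|X_k|^2 = psd * fs * n / 2 makes the periodogram an unbiased
    # estimate of psd (one-sided density convention)
    scale = np.sqrt(psd * sampling_rate_hz * n / 2.0)
    coeffs = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))) / math.sqrt(2.0)
    coeffs *= scale
    coeffs[0] = 0.0
    if n % 2 == 0:
        coeffs[-1] = coeffs[-1].real * math.sqrt(2.0)
    x = np.fft.irfft(coeffs, n=n)
    return x - x.mean()


# ---------------------------------------------------------------------------
# event placement (signal-free; reused by the fast Monte-Carlo path)
# ---------------------------------------------------------------------------

def _free_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean per-second mask, as (start, stop)."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def _place_intervals(
    n: int,
    length_s: float,
    eligible: np.ndarray,
    rng: np.random.Generator,
    min_gap_s: float = 0.25,
    max_tries: int = 200,
) -> np.ndarray:
    """Start times of ``n`` non-overlapping intervals of ``length_s`` whose
    full span lies in eligible seconds.  Raises if they cannot be placed."""
    runs = [(s, e) for s, e in _free_runs(eligible) if e - s >= length_s]
    if n == 0:
        return np.array([])
    if not runs:
        raise ValueError("no eligible stretch long enough for event placement")
    starts: list[float] = []
    weights = np.array([e - s - length_s + 1e-9 for s, e in runs], float)
    weights /= weights.sum()
    for _ in range(n):
        placed = False
        for _try in range(max_tries):
            run = runs[rng.choice(len(runs), p=weights)]
            t0 = rng.uniform(run[0], run[1] - length_s)
            if all(abs(t0 - s) >= length_s + min_gap_s for s in starts):
                starts.append(t0)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place {n} non-overlapping events of {length_s:.2f} s "
                "(density too high for the eligible data)"
            )
    return np.sort(np.array(starts))


def place_sos(config: GeneratorConfig, rng: np.random.Generator, eligible: np.ndarray) -> pd.DataFrame:
    """Ground-truth SO table (no waveform rendering)."""
    T = 1.0 / config.so_freq_hz
    n = int(round(config.so_density_per_min * config.duration_s / 60.0))
    try:
        starts = _place_intervals(n, T, eligible, rng)
    except ValueError as err:
        raise ValueError(f"SO density {config.so_density_per_min}/min: {err}") from err
    return pd.DataFrame(
        {
            "channel_group": "global",
            "start_s": starts,
            "down_peak_s": starts + T / 4.0,
            "up_peak_s": starts + 3.0 * T / 4.0,
            "end_s": starts + T,
            "neg_amp_uv": config.so_amp_frontal_uv / 2.0,
            "p2p_amp_uv": config.so_amp_frontal_uv,
        }
    )


def place_spindles(
    config: GeneratorConfig,
    so_events: pd.DataFrame,
    rng: np.random.Generator,
    eligible: np.ndarray,
) -> pd.DataFrame:
    """Ground-truth spindle table; coupled centres drawn from a von Mises
    distribution over SO phase, the rest uniform outside SO windows."""
    n = int(round(config.spindle_density_per_min * config.duration_s / 60.0))
    n_coupled = int(round(config.coupled_fraction * n))
    if n_coupled > 0 and len(so_events) == 0:
        raise ValueError("coupled_fraction > 0 requires at least one SO")
    half = config.spindle_dur_s / 2.0
    T = 1.0 / config.so_freq_hz
    duration = config.duration_s

    rows: list[dict] = []
    # coupled spindles
    for _ in range(n_coupled):
        for _try in range(500):
            i = int(rng.integers(len(so_events)))
            theta = float(rng.vonmises(config.coupling_phase_rad, config.coupling_kappa))
            center = float(so_events["up_peak_s"].iloc[i]) + theta * T / (2.0 * math.pi)
            lo, hi = center - half, center + half
            if lo < 0 or hi > duration:
                continue
            sec = eligible[int(lo) : int(math.ceil(hi))]
            if sec.size and sec.all():
                rows.append(
                    {"center_s": center, "coupled": True, "so_phase_rad": theta}
                )
                break
        else:
            raise ValueError("could not place coupled spindles in eligible data")

    # uncoupled spindles: uniform over eligible seconds, outside every
    # SO +- exclusion margin window (no exclusion when margin is None)
    excl = eligible.copy()
    if config.so_exclusion_margin_s is not None:
        margin = config.so_exclusion_margin_s
        for _, so in so_events.iterrows():
            lo = int(max(so["start_s"] - margin - half, 0))
            hi = int(math.ceil(min(so["end_s"] + margin + half, len(excl))))
            excl[lo:hi] = False
    if n - n_coupled > 0:
        try:
            starts = _place_intervals(
                n - n_coupled, config.spindle_dur_s, excl, rng, min_gap_s=1.0
            )
        except ValueError as err:
            raise ValueError(f"uncoupled spindle placement failed: {err}") from err
        for t0 in starts:
            rows.append(
                {"center_s": t0 + half, "coupled": False, "so_phase_rad": np.nan}
            )

    df = pd.DataFrame(rows, columns=["center_s", "coupled", "so_phase_rad"])
    df["channel_group"] = config.spindle_channel_group
    df["onset_s"] = df["center_s"] - half
    df["offset_s"] = df["center_s"] + half
    # event-to-event frequency spread around the subject's dominant rhythm
    if len(df) and config.spindle_freq_jitter_hz > 0:
        df["freq_hz"] = np.clip(
            rng.normal(config.spindle_freq_hz, config.spindle_freq_jitter_hz, size=len(df)),
            9.0,
            16.0,
        )
    else:
        df["freq_hz"] = config.spindle_freq_hz
    df["amp_uv"] = config.spindle_amp_uv
    return df[list(SPINDLE_GT_COLUMNS)].sort_values("center_s").reset_index(drop=True)


def simulate_events(config: GeneratorConfig, seed: int | None = None) -> GroundTruth:
    """Event placement only — the fast path for Monte-Carlo statistics on
    event timing, skipping waveform synthesis and detection."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    hyp = _make_hypnogram(config)
    mask_1ch = _make_artifact_seconds(config, rng)
    eligible = _eligibility(config, hyp, mask_1ch)
    sos = place_sos(config, rng, eligible)
    spindles = place_spindles(config, sos, rng, eligible)
    return GroundTruth(so_events=sos, spindle_events=spindles)


# ---------------------------------------------------------------------------
# waveform rendering
# ---------------------------------------------------------------------------

def _so_waveform(T: float, p2p: float, fs: float) -> np.ndarray:
    """Negative half-sine then positive half-sine, peak-to-peak ``p2p``."""
    n = int(round(T * fs))
    t = np.arange(n) / fs
    # -sin is <= 0 on the first half-period and >= 0 on the second:
    # negative half-wave (down state) first, positive (up state) second
    return -(p2p / 2.0) * np.sin(2.0 * math.pi * t / T)


def _spindle_waveform(dur: float, freq: float, amp: float, fs: float) -> np.ndarray:
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    hann = 0.5 * (1.0 - np.cos(2.0 * math.pi * np.arange(n) / max(n - 1, 1)))
    return amp * hann * np.sin(2.0 * math.pi * freq * t)


def _group_of(label: str) -> str:
    if label in CHANNEL_GROUPS["frontal"]:
        return "frontal"
    if label in CHANNEL_GROUPS["occipital"]:
        return "occipital"
    return "centro-parietal"


def inject_sos(
    signal: np.ndarray,
    config: GeneratorConfig,
    seed: int | np.random.Generator,
    channel_labels: Sequence[str] | None = None,
    eligible: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Add SO half-wave pairs to a (channels x samples) signal in place.

    Events are global (same times on every channel) with a per-group
    amplitude gradient: frontal channels receive ``so_amp_frontal_uv``
    peak-to-peak, all others ``so_amp_centroparietal_uv``.  Returns the
    signal and the ground-truth table (frontal-group amplitudes).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = tuple(channel_labels or config.channel_labels)
    if eligible is None:
        eligible = np.ones(int(math.ceil(config.duration_s)), bool)
    sos = place_sos(config, rng, eligible)
    fs = config.sampling_rate_hz
    T = 1.0 / config.so_freq_hz
    wf_frontal = _so_waveform(T, config.so_amp_frontal_uv, fs)
    wf_post = _so_waveform(T, config.so_amp_centroparietal_uv, fs)
    for start in sos["start_s"]:
        i0 = int(round(start * fs))
        for c, label in enumerate(labels):
            wf = wf_frontal if _group_of(label) == "frontal" else wf_post
            seg = signal[c, i0 : i0 + len(wf)]
            seg += wf[: len(seg)]
    return signal, sos


def inject_spindles(
    signal: np.ndarray,
    config: GeneratorConfig,
    so_ground_truth: pd.DataFrame,
    seed: int | np.random.Generator,
    channel_labels: Sequence[str] | None = None,
    eligible: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Add Hann-windowed spindle bursts on the configured channel group."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = tuple(channel_labels or config.channel_labels)
    if eligible is None:
        eligible = np.ones(int(math.ceil(config.duration_s)), bool)
    spindles = place_spindles(config, so_ground_truth, rng, eligible)
    fs = config.sampling_rate_hz
    targets = [
        c
        for c, label in enumerate(labels)
        if label in CHANNEL_GROUPS.get(config.spindle_channel_group, (config.spindle_channel_group,))
    ]
    for onset, freq in zip(spindles["onset_s"], spindles["freq_hz"]):
        wf = _spindle_waveform(config.spindle_dur_s, freq, config.spindle_amp_uv, fs)
        i0 = int(round(onset * fs))
        for c in targets:
            seg = signal[c, i0 : i0 + len(wf)]
            seg += wf[: len(seg)]
    return signal, spindles


# ---------------------------------------------------------------------------
# full recordings and cohorts
# ---------------------------------------------------------------------------

def _make_hypnogram(config: GeneratorConfig) -> np.ndarray:
    n_epochs = int(math.ceil(config.duration_s / EPOCH_S))
    hyp = np.empty(n_epochs, object)
    # alternate 10-epoch (5-min) blocks of N2 and N3 after the wake prologue
    for i in range(n_epochs):
        hyp[i] = "N2" if (i // 10) % 2 == 0 else "N3"
    hyp[: min(config.wake_prologue_epochs, n_epochs)] = "W"
    return hyp


def _make_artifact_seconds(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-second artifact flags, contiguous blocks of ~5 s, all channels."""
    n_sec = int(math.ceil(config.duration_s))
    mask = np.zeros(n_sec, bool)
    target = int(round(config.artifact_fraction * n_sec))
    block = 5
    guard = 0
    while mask.sum() < target and guard < 10_000:
        guard += 1
        start = int(rng.integers(0, max(n_sec - block, 1)))
        mask[start : start + min(block, target - mask.sum() + block)] = True
    return mask


def _eligibility(config: GeneratorConfig, hyp: np.ndarray, artifact_sec: np.ndarray) -> np.ndarray:
    n_sec = len(artifact_sec)
    stage_sec = np.repeat(hyp, int(EPOCH_S))[:n_sec]
    return np.isin(stage_sec, ("N2", "N3")) & ~artifact_sec


def generate_recording(config: GeneratorConfig, seed: int | None = None) -> tuple[Recording, GroundTruth]:
    """Render one full synthetic recording with its ground truth."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_ch = len(config.channel_labels)
    n_samples = int(round(config.duration_s * config.sampling_rate_hz))

    hyp = _make_hypnogram(config)
    artifact_sec = _make_artifact_seconds(config, rng)
    eligible = _eligibility(config, hyp, artifact_sec)

    signal = np.empty((n_ch, n_samples))
    for c in range(n_ch):
        signal[c] = generate_background(
            config.duration_s,
            config.sampling_rate_hz,
            config.background_scale_A,
            config.background_exponent_a,
            rng,
        )
    signal, sos = inject_sos(signal, config, rng, eligible=eligible)
    signal, spindles = inject_spindles(signal, config, sos, rng, eligible=eligible)

    mask = np.tile(artifact_sec, (n_ch, 1))
    rec = Recording(
        signal=signal,
        sampling_rate_hz=config.sampling_rate_hz,
        channel_labels=config.channel_labels,
        hypnogram=hyp,
        artifact_mask=mask,
        meta={"generator_config": config},
    )
    return rec, GroundTruth(so_events=sos, spindle_events=spindles)


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic cohort: a base configuration plus per-subject normal
    draws for selected parameters (clipped to each parameter's legal range)."""

    n_subjects: int
    base: GeneratorConfig = field(default_factory=GeneratorConfig)
    vary: dict = field(default_factory=dict)  # name -> (mean, sd)
    label: str = "cohort"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("cohort must have at least one subject")
        known = {f.name for f in fields(GeneratorConfig)}
        bad = set(self.vary) - known
        if bad:
            raise ValueError(f"unknown GeneratorConfig fields in vary: {bad}")


_CLIP_RANGES = {
    "spindle_freq_hz": (9.0, 16.0),
    "so_freq_hz": (0.5, 1.0),
    "spindle_dur_s": (0.5, 3.0),
    "coupled_fraction": (0.0, 1.0),
    "coupling_kappa": (0.0, np.inf),
    "spindle_amp_uv": (0.0, np.inf),
    "spindle_density_per_min": (0.0, np.inf),
    "so_density_per_min": (0.0, np.inf),
    "so_amp_frontal_uv": (0.0, np.inf),
    "so_amp_centroparietal_uv": (0.0, np.inf),
    "artifact_fraction": (0.0, 1.0),
}


def draw_cohort_configs(spec: CohortSpec, seed: int) -> tuple[list[GeneratorConfig], pd.DataFrame]:
    """Per-subject configs and the metadata table of drawn parameters."""
    rng = np.random.default_rng(seed)
    configs, meta = [], []
    for i in range(spec.n_subjects):
        draws = {}
        for name, (mu, sd) in sorted(spec.vary.items()):
            val = float(rng.normal(mu, sd))
            lo, hi = _CLIP_RANGES.get(name, (-np.inf, np.inf))
            draws[name] = float(np.clip(val, lo, hi))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        cfg = replace(spec.base, **draws, seed=sub_seed)
        configs.append(cfg)
        meta.append({"subject_id": f"{spec.label}-{i:03d}", "seed": sub_seed, **draws})
    return configs, pd.DataFrame(meta)


def generate_cohort(
    spec: CohortSpec, seed: int
) -> tuple[list[tuple[Recording, GroundTruth]], pd.DataFrame]:
    """One (Recording, GroundTruth) pair per synthetic subject."""
    configs, meta = draw_cohort_configs(spec, seed)
    out = [generate_recording(cfg) for cfg in configs]
    return out, meta


def age_gradient_configs(
    n_subjects: int,
    seed: int,
    duration_s: float = 600.0,
    base: GeneratorConfig | None = None,
) -> tuple[list[GeneratorConfig], pd.DataFrame]:
    """Configs along a latent maturity axis ``age`` in [0, 1].

    With increasing age the dominant fast-spindle frequency rises from
    ~11 Hz toward the canonical 12.5-16 Hz band, SO-phase concentration
    (kappa) and the coupled fraction grow, and the SO topography shifts
    from posterior- to frontal-dominant — the gradients the maturity
    scores are built to capture.  Subjects are evenly spaced on the axis
    with per-subject jitter.
    """
    if n_subjects < 2:
        raise ValueError("gradient cohort needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    base = base or GeneratorConfig()
    ages = np.linspace(0.0, 1.0, n_subjects)
    configs, meta = [], []
    for i, t in enumerate(ages):
        jitter = rng.normal(0.0, 0.15)
        freq = float(np.clip(12.0 + 1.8 * t + rng.normal(0, 0.2), 9.5, 15.0))
        kappa = float(np.clip(1.0 + 7.0 * (t + jitter), 0.2, 12.0))
        coupled = float(np.clip(0.5 + 0.3 * t + rng.normal(0, 0.05), 0.2, 0.95))
        front = float(np.clip(150.0 + 150.0 * t + rng.normal(0, 15.0), 50.0, None))
        post = float(np.clip(200.0 - 30.0 * t + rng.normal(0, 15.0), 50.0, None))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        configs.append(
            replace(
                base,
                duration_s=duration_s,
                spindle_freq_hz=freq,
                coupling_kappa=kappa,
                coupled_fraction=coupled,
                so_amp_frontal_uv=front,
                so_amp_centroparietal_uv=post,
                seed=sub_seed,
            )
        )
        meta.append(
            {
                "subject_id": f"dev-{i:03d}",
                "age": float(t),
                "spindle_freq_hz": freq,
                "coupling_kappa": kappa,
                "coupled_fraction": coupled,
                "so_amp_frontal_uv": front,
                "so_amp_centroparietal_uv": post,
                "seed": sub_seed,
            }
        )
    return configs, pd.DataFrame(meta)


def child_like_spec(n_subjects: int = 10, **overrides) -> CohortSpec:
    """Cohort emulating young children: slower dominant fast spindles,
    weak SO-phase concentration, posterior-dominant SOs."""
    base = GeneratorConfig(
        spindle_freq_hz=11.0,
        coupling_kappa=1.0,
        coupled_fraction=0.5,
        so_amp_frontal_uv=150.0,
        so_amp_centroparietal_uv=200.0,
        **overrides,
    )
    return CohortSpec(
        n_subjects=n_subjects,
        base=base,
        vary={"spindle_freq_hz": (11.0, 0.5), "coupling_kappa": (1.0, 0.3)},
        label="child",
    )


def adult_like_spec(n_subjects: int = 10, **overrides) -> CohortSpec:
    """Cohort emulating young adults: canonical fast spindles tightly
    locked to the SO up peak, frontal-dominant SOs."""
    base = GeneratorConfig(
        spindle_freq_hz=13.5,
        coupling_kappa=8.0,
        coupled_fraction=0.8,
        so_amp_frontal_uv=300.0,
        so_amp_centroparietal_uv=180.0,
        **overrides,
    )
    return CohortSpec(
        n_subjects=n_subjects,
        base=base,
        vary={"spindle_freq_hz": (13.5, 0.5), "coupling_kappa": (8.0, 1.5)},
        label="adult",
    )
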