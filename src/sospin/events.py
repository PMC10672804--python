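"""Sleep spindle and slow oscillation detection with individual thresholds.

Spindles: the channel-averaged signal of a topographic group is band-pass
filtered (two-pass Butterworth, order 6), its 0.2-s moving RMS is smoothed
with a 0.2-s moving average, and events are maximal runs where this
envelope exceeds ``mean(envelope) + 1.5 * SD(filtered signal)``, both
statistics taken over artifact-free N2/N3 data.  Runs of 0.5-3 s are kept;
events closer than 0.25 s are merged when the merged span stays below 3 s.

Slow oscillations: on the 0.2-4 Hz filtered average, each negative
half-wave followed by a positive half-wave whose joint span corresponds to
0.5-1 Hz is a candidate; candidates survive only if their peak-to-peak and
negative amplitudes both exceed 1.25x the respective candidate means —
an amplitude criterion that adapts to the individual recording.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .recording import NREM_STAGES, Recording
from .spectral import SpindlePeak

ADULT_LIKE_BAND = (12.5, 16.0)
SO_FILTER_BAND = (0.2, 4.0)
RMS_WINDOW_S = 0.2
SMOOTH_WINDOW_S = 0.2
THRESHOLD_SD = 1.5
MIN_SPINDLE_S, MAX_SPINDLE_S = 0.5, 3.0
MERGE_GAP_S = 0.25
SO_FREQ_RANGE = (0.5, 1.0)
SO_AMP_FACTOR = 1.25
PAD_S = 10.0


class Band(NamedTuple):
    lo: float
    hi: float
    below_canonical: bool = False


@dataclass
class SpindleEvent:
    topography: str
    band_hz: tuple[float, float]
    onset_s: float
    offset_s: float
    duration_s: float
    center_s: float
    p2p_amp_uv: float
    freq_hz: float
    spindle_class: str = "development-specific"


@dataclass
class SOEvent:
    topography: str
    start_s: float
    end_s: float
    down_peak_s: float
    up_peak_s: float
    neg_amp_uv: float
    p2p_amp_uv: float
    freq_hz: float


@dataclass
class FeatureSummary:
    """Per-recording event features: density (events per artifact-free
    NREM minute) and unweighted means of frequency and amplitude.  Means
    are NaN (missing-marked) when no events were detected."""

    topography: str
    spindle_class: str | None
    n_events: int
    density_per_min: float
    frequency_hz: float
    amplitude_uv: float


def individual_band(peak: SpindlePeak, half_width_hz: float = 1.5) -> Band:
    """Individualized detection band: spectral peak +- 1.5 Hz.  A lower
    edge below 9 Hz is legal but flagged, since it leaves the canonical
    spindle range."""
    if peak is None:
        raise ValueError("no spindle peak available; use a fallback band")
    lo = peak.peak_freq_hz - half_width_hz
    hi = peak.peak_freq_hz + half_width_hz
    flag = lo < 9.0
    if flag:
        warnings.warn(
            f"individual band lower edge {lo:.1f} Hz is below 9 Hz", stacklevel=2
        )
    return Band(lo, hi, flag)


def bandpass(x: np.ndarray, band: tuple[float, float], fs: float, order: int = 6) -> np.ndarray:
    """Zero-phase (two-pass) Butterworth band-pass with reflection padding."""
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} must lie inside (0, {fs / 2}) Hz")
    sos = sps.butter(order, [lo, hi], btype="bandpass", output="sos", fs=fs)
    padlen = min(int(PAD_S * fs), x.size - 1)
    return sps.sosfiltfilt(sos, x, padtype="odd", padlen=padlen)


def _moving_rms(x: np.ndarray, fs: float, window_s: float = RMS_WINDOW_S) -> np.ndarray:
    w = max(int(round(window_s * fs)), 1)
    return np.sqrt(uniform_filter1d(x**2, size=w, mode="nearest"))


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def _zero_crossing_count(x: np.ndarray) -> int:
    s = np.signbit(x)
    return int(np.count_nonzero(s[1:] != s[:-1]))


def _event_fully_eligible(onset_s: float, offset_s: float, eligible_sec: np.ndarray) -> bool:
    lo = int(onset_s)
    hi = min(int(math.ceil(offset_s)), len(eligible_sec))
    return bool(eligible_sec[lo:hi].all()) if hi > lo else False


def merge_intervals(
    intervals_s: Sequence[tuple[float, float]],
    gap_s: float = MERGE_GAP_S,
    max_s: float = MAX_SPINDLE_S,
) -> list[tuple[float, float]]:
    """Merge successive events whose boundary gap is within ``gap_s``, but
    only while the merged span stays below ``max_s``."""
    merged: list[list[float]] = []
    for lo, hi in sorted(intervals_s):
        if merged and lo - merged[-1][1] <= gap_s and hi - merged[-1][0] < max_s:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def detect_spindles(
    recording: Recording,
    channel_set: str | Sequence[str],
    band_hz: tuple[float, float],
    stages: Iterable[str] = NREM_STAGES,
    spindle_class: str = "development-specific",
) -> list[SpindleEvent]:
    fs = recording.sampling_rate_hz
    eligible_sec = recording.eligible_seconds(channel_set, stages)
    if eligible_sec.sum() < 60:
        raise ValueError("need at least 60 s of artifact-free data in the requested stages")
    x = recording.averaged_signal(channel_set)
    filt = bandpass(x, tuple(band_hz)[:2], fs)
    envelope = uniform_filter1d(
        _moving_rms(filt, fs), size=max(int(round(SMOOTH_WINDOW_S * fs)), 1), mode="nearest"
    )

    sample_ok = recording.eligible_sample_mask(channel_set, stages)
    threshold = envelope[sample_ok].mean() + THRESHOLD_SD * filt[sample_ok].std()

    runs = _runs_above(envelope > threshold)
    kept = [
        (i0 / fs, i1 / fs)
        for i0, i1 in runs
        if MIN_SPINDLE_S <= (i1 - i0) / fs <= MAX_SPINDLE_S
    ]
    merged = merge_intervals(kept)

    topo = channel_set if isinstance(channel_set, str) else ",".join(channel_set)
    events = []
    for onset, offset in merged:
        i0, i1 = int(round(onset * fs)), int(round(offset * fs))
        if not _event_fully_eligible(onset, offset, eligible_sec):
            continue
        seg = filt[i0:i1]
        duration = offset - onset
        events.append(
            SpindleEvent(
                topography=topo,
                band_hz=(float(band_hz[0]), float(band_hz[1])),
                onset_s=onset,
                offset_s=offset,
                duration_s=duration,
                center_s=(onset + offset) / 2.0,
                p2p_amp_uv=float(seg.max() - seg.min()),
                freq_hz=_zero_crossing_count(seg) / 2.0 / duration,
                spindle_class=spindle_class,
            )
        )
    return events


def detect_sos(
    recording: Recording,
    channel_set: str | Sequence[str],
    stages: Iterable[str] = NREM_STAGES,
    amp_criterion_factor: float = SO_AMP_FACTOR,
) -> list[SOEvent]:
    fs = recording.sampling_rate_hz
    eligible_sec = recording.eligible_seconds(channel_set, stages)
    if eligible_sec.sum() < 60:
        raise ValueError("need at least 60 s of artifact-free data in the requested stages")
    x = recording.averaged_signal(channel_set)
    filt = bandpass(x, SO_FILTER_BAND, fs)

    # negative-going zero-crossings start a candidate; the next positive-
    # going crossing ends the negative half-wave; the following negative-
    # going crossing ends the positive half-wave
    neg = filt < 0
    down_cross = np.flatnonzero(~neg[:-1] & neg[1:]) + 1
    up_cross = np.flatnonzero(neg[:-1] & ~neg[1:]) + 1

    topo = channel_set if isinstance(channel_set, str) else ",".join(channel_set)
    candidates: list[SOEvent] = []
    for k in range(len(down_cross) - 1):
        i_start = down_cross[k]
        ups = up_cross[(up_cross > i_start) & (up_cross < down_cross[k + 1])]
        if ups.size == 0:
            continue
        i_mid = ups[0]
        i_end = down_cross[k + 1]
        span = (i_end - i_start) / fs
        freq = 1.0 / span
        if not SO_FREQ_RANGE[0] <= freq <= SO_FREQ_RANGE[1]:
            continue
        neg_seg = filt[i_start:i_mid]
        pos_seg = filt[i_mid:i_end]
        if neg_seg.size == 0 or pos_seg.size == 0:
            continue
        i_down = i_start + int(np.argmin(neg_seg))
        i_up = i_mid + int(np.argmax(pos_seg))
        start_s, end_s = i_start / fs, i_end / fs
        if not _event_fully_eligible(start_s, end_s, eligible_sec):
            continue
        candidates.append(
            SOEvent(
                topography=topo,
                start_s=start_s,
                end_s=end_s,
                down_peak_s=i_down / fs,
                up_peak_s=i_up / fs,
                neg_amp_uv=float(-filt[i_down]),
                p2p_amp_uv=float(filt[i_up] - filt[i_down]),
                freq_hz=freq,
            )
        )
    if not candidates:
        return []
    mean_p2p = float(np.mean([c.p2p_amp_uv for c in candidates]))
    mean_neg = float(np.mean([c.neg_amp_uv for c in candidates]))
    return [
        c
        for c in candidates
        if c.p2p_amp_uv >= amp_criterion_factor * mean_p2p
        and c.neg_amp_uv >= amp_criterion_factor * mean_neg
    ]


def summarize_features(
    events: Sequence[SpindleEvent] | Sequence[SOEvent],
    eligible_minutes: float,
    topography: str | None = None,
    spindle_class: str | None = None,
) -> FeatureSummary:
    if eligible_minutes <= 0:
        raise ValueError("eligible_minutes must be > 0")
    n = len(events)
    if n == 0:
        freq = amp = float("nan")
    else:
        freq = float(np.mean([e.freq_hz for e in events]))
        amp = float(np.mean([e.p2p_amp_uv for e in events]))
        if topography is None:
            topography = events[0].topography
        if spindle_class is None:
            spindle_class = getattr(events[0], "spindle_class", None)
    return FeatureSummary(
        topography=topography or "",
        spindle_class=spindle_class,
        n_events=n,
        density_per_min=n / eligible_minutes,
        frequency_hz=freq,
        amplitude_uv=amp,
    )


def events_to_frame(events: Sequence) -> "pd.DataFrame":  # noqa: F821
    """Event list -> tidy table with the event dataclass fields."""
    import pandas as pd
    from dataclasses import asdict

    if not events:
        return pd.DataFrame()
    return pd.DataFrame([asdict(e) for e in events])
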