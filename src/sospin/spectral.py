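"""NREM power spectra, 1/f background removal, and spindle-peak detection.

The individual fast-spindle frequency is found by averaging Hann-tapered
periodograms of artifact-free 5-s NREM segments (0.2 Hz resolution),
removing the aperiodic ``A * f**-a`` background fitted by robust
regression in log-log space, and locating the largest local maximum of the
corrected spectrum between 9 and 16 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import signal as sps

from .recording import NREM_STAGES, Recording

SEGMENT_S = 5.0
DEFAULT_FIT_RANGE = (2.0, 30.0)
PEAK_SEARCH_RANGE = (9.0, 16.0)


@dataclass
class PowerSpectrum:
    """Averaged one-sided periodogram, µV²/Hz on a 0.2-Hz grid."""

    freqs_hz: np.ndarray
    power: np.ndarray
    n_epochs: int
    channel_set: str | Sequence[str]

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, float)
        self.power = np.asarray(self.power, float)
        if self.freqs_hz.shape != self.power.shape:
            raise ValueError("freqs and power must align")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequencies must be strictly increasing")


@dataclass
class BackgroundFit:
    """Aperiodic model ``power = A * f**-a`` fitted on log-log axes."""

    A: float
    a: float
    fit_range_hz: tuple[float, float]
    residual_scale: float

    def evaluate(self, freqs_hz: np.ndarray) -> np.ndarray:
        f = np.asarray(freqs_hz, float)
        return self.A * f ** (-self.a)


@dataclass
class SpindlePeak:
    peak_freq_hz: float
    prominence: float
    channel_set: str | Sequence[str]


def _segment_starts(recording: Recording, stages: Iterable[str]) -> np.ndarray:
    """Start seconds of non-overlapping 5-s segments aligned to 30-s
    hypnogram epochs of the requested stages."""
    stages = set(stages)
    starts = []
    for e, stage in enumerate(recording.hypnogram):
        if stage in stages:
            t0 = e * 30
            for k in range(6):
                if t0 + (k + 1) * SEGMENT_S <= recording.duration_s + 1e-9:
                    starts.append(t0 + k * SEGMENT_S)
    return np.array(starts)


def nrem_power_spectrum(
    recording: Recording,
    channel_set: str | Sequence[str],
    stages: Iterable[str] = NREM_STAGES,
) -> PowerSpectrum:
    """Mean over channels of the mean Hann periodogram of eligible 5-s
    segments (fully artifact-free on every channel of the set)."""
    fs = recording.sampling_rate_hz
    idx = recording.channel_indices(channel_set)
    clean_sec = ~recording.artifact_mask[idx].any(axis=0)

    starts = _segment_starts(recording, stages)
    if starts.size == 0:
        raise ValueError(f"no hypnogram epochs in stages {sorted(set(stages))}")
    eligible = [
        s for s in starts if clean_sec[int(s) : int(s + SEGMENT_S)].all()
    ]
    if not eligible:
        raise ValueError(
            "no artifact-free 5-s segments in the requested stages on "
            f"channel set {channel_set!r}"
        )

    nper = int(round(SEGMENT_S * fs))
    acc = None
    for s in eligible:
        i0 = int(round(s * fs))
        seg = recording.signal[idx, i0 : i0 + nper]
        freqs, pxx = sps.periodogram(
            seg, fs=fs, window="hann", detrend="constant", scaling="density", axis=-1
        )
        chan_mean = pxx.mean(axis=0)
        acc = chan_mean if acc is None else acc + chan_mean
    power = acc / len(eligible)
    return PowerSpectrum(
        freqs_hz=freqs[1:], power=power[1:], n_epochs=len(eligible), channel_set=channel_set
    )


def fit_background(
    spectrum: PowerSpectrum, fit_range_hz: tuple[float, float] = DEFAULT_FIT_RANGE
) -> BackgroundFit:
    """Robust (IRLS, Tukey bisquare c=4.685) linear fit of log power on
    log frequency; ``A = exp(intercept)``, ``a = -slope``."""
    lo, hi = fit_range_hz
    sel = (spectrum.freqs_hz >= lo) & (spectrum.freqs_hz <= hi)
    if sel.sum() < 10:
        raise ValueError(
            f"need >= 10 frequency bins in fit range {fit_range_hz}, have {int(sel.sum())}"
        )
    p = spectrum.power[sel]
    if np.any(p <= 0):
        raise ValueError("non-positive power inside the fit range; log-log fit undefined")
    x = np.log(spectrum.freqs_hz[sel])
    y = np.log(p)
    exog = sm.add_constant(x)
    model = sm.RLM(y, exog, M=sm.robust.norms.TukeyBiweight(c=4.685))
    res = model.fit(maxiter=50, tol=1e-8, conv="coefs")
    intercept, slope = res.params
    return BackgroundFit(
        A=float(np.exp(intercept)),
        a=float(-slope),
        fit_range_hz=(lo, hi),
        residual_scale=float(res.scale),
    )


def correct_spectrum(spectrum: PowerSpectrum, fit: BackgroundFit) -> np.ndarray:
    """Background-corrected power, ``power(f) - A * f**-a`` (may go negative)."""
    return spectrum.power - fit.evaluate(spectrum.freqs_hz)


def detect_peak(
    freqs_hz: np.ndarray,
    corrected: np.ndarray,
    search_range: tuple[float, float] = PEAK_SEARCH_RANGE,
    channel_set: str | Sequence[str] = "centro-parietal",
) -> SpindlePeak | None:
    """Highest local maximum (first derivative + to -) of the corrected
    spectrum strictly inside the search range; ``None`` when no local
    maximum exists.  Equal heights tie-break to the lower frequency."""
    freqs_hz = np.asarray(freqs_hz, float)
    corrected = np.asarray(corrected, float)
    lo, hi = search_range
    d = np.diff(corrected)
    best = None
    for i in range(1, len(corrected) - 1):
        if not (lo < freqs_hz[i] < hi):
            continue
        if d[i - 1] > 0 and d[i] < 0:
            cand = (corrected[i], -freqs_hz[i])
            if best is None or cand > best:
                best = cand
    if best is None:
        return None
    height, negf = best
    return SpindlePeak(peak_freq_hz=-negf, prominence=float(height), channel_set=channel_set)


def export_spectrum_table(spectrum: PowerSpectrum, fit: BackgroundFit | None = None):
    """Tidy (freq_hz, power, background, corrected) table for export."""
    import pandas as pd

    out = pd.DataFrame({"freq_hz": spectrum.freqs_hz, "power": spectrum.power})
    if fit is not None:
        out["background"] = fit.evaluate(spectrum.freqs_hz)
        out["corrected"] = out["power"] - out["background"]
    return out
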