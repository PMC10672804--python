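"""Reading and writing recordings and result tables.

Recordings travel as 16-bit EDF (physical units µV) plus plain-text
sidecars: hypnogram (epoch_index, stage), artifact mask (second_index,
channel, flag; only flagged seconds are listed) and ground-truth event
tables, all tab-separated.  EDF reading goes through ``mne.io.read_raw_edf``;
writing uses the minimal EDF encoder below (no installed library exports
EDF in this stack).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import Recording
from .synth import SO_GT_COLUMNS, SPINDLE_GT_COLUMNS, GroundTruth

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, recording: Recording) -> Path:
    """Write a recording as 16-bit EDF with 1-s data records, µV units."""
    path = Path(path)
    fs = recording.sampling_rate_hz
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_full = recording.n_samples // spr
    if n_full * spr != recording.n_samples:
        raise ValueError("EDF export requires a whole number of 1-s records")
    ns = recording.n_channels
    data = recording.signal[:, : n_full * spr]

    # one-decimal physical range, matching the ASCII header exactly so the
    # reader reconstructs with the same scale the encoder used
    phys_max = np.ceil(np.maximum(np.abs(data).max(axis=1), 1.0) * 10.0) / 10.0
    phys_min = -phys_max
    scale = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((data - phys_min[:, None]) / scale[:, None] + _DIG_MIN).astype("<i2")

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("synthetic polysomnography", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 + ns * 256, 8),
            _ascii("", 44),
            _ascii(n_full, 8),
            _ascii(1, 8),
            _ascii(ns, 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_ascii(lbl, 16) for lbl in recording.channel_labels),
            b"".join(_ascii("AgAgCl electrode", 80) for _ in range(ns)),
            b"".join(_ascii("uV", 8) for _ in range(ns)),
            b"".join(_ascii(f"{phys_min[c]:.1f}", 8) for c in range(ns)),
            b"".join(_ascii(f"{phys_max[c]:.1f}", 8) for c in range(ns)),
            b"".join(_ascii(_DIG_MIN, 8) for _ in range(ns)),
            b"".join(_ascii(_DIG_MAX, 8) for _ in range(ns)),
            b"".join(_ascii("", 80) for _ in range(ns)),
            b"".join(_ascii(spr, 8) for _ in range(ns)),
            b"".join(_ascii("", 32) for _ in range(ns)),
        ]
    )
    records = digital.reshape(ns, n_full, spr).transpose(1, 0, 2)
    path.write_bytes(header + sig + records.tobytes())
    return path


def read_edf_signal(path: str | Path) -> tuple[np.ndarray, float, tuple[str, ...]]:
    """Signal (µV), sampling rate, labels — via the mne EDF reader."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), tuple(raw.ch_names)


# ---------------------------------------------------------------------------
# sidecars
# ---------------------------------------------------------------------------

def write_hypnogram(path: str | Path, hypnogram: np.ndarray) -> Path:
    df = pd.DataFrame({"epoch_index": np.arange(len(hypnogram)), "stage": hypnogram})
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_hypnogram(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    return df.sort_values("epoch_index")["stage"].to_numpy(dtype=object)


def write_artifact_mask(path: str | Path, mask: np.ndarray, channel_labels) -> Path:
    """Only flagged (artifact) seconds are written; shape is restored from
    the recording on read."""
    ch_idx, sec_idx = np.nonzero(mask)
    df = pd.DataFrame(
        {
            "second_index": sec_idx,
            "channel": [channel_labels[c] for c in ch_idx],
            "flag": 1,
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_artifact_mask(path: str | Path, channel_labels, n_seconds: int) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    mask = np.zeros((len(channel_labels), n_seconds), bool)
    labels = list(channel_labels)
    for _, row in df.iterrows():
        if row["flag"]:
            mask[labels.index(row["channel"]), int(row["second_index"])] = True
    return mask


def write_ground_truth(directory: str | Path, gt: GroundTruth, prefix: str = "") -> tuple[Path, Path]:
    directory = Path(directory)
    so_path = directory / f"{prefix}so_events.tsv"
    sp_path = directory / f"{prefix}spindle_events.tsv"
    gt.so_events.to_csv(so_path, sep="\t", index=False)
    gt.spindle_events.to_csv(sp_path, sep="\t", index=False)
    return so_path, sp_path


def read_ground_truth(directory: str | Path, prefix: str = "") -> GroundTruth:
    directory = Path(directory)
    so = pd.read_csv(directory / f"{prefix}so_events.tsv", sep="\t")
    sp = pd.read_csv(directory / f"{prefix}spindle_events.tsv", sep="\t")
    return GroundTruth(so_events=so[list(SO_GT_COLUMNS)], spindle_events=sp[list(SPINDLE_GT_COLUMNS)])


def write_recording(directory: str | Path, recording: Recording, name: str = "recording") -> dict[str, Path]:
    """EDF + sidecars for one recording; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "edf": write_edf(directory / f"{name}.edf", recording),
        "hypnogram": write_hypnogram(directory / f"{name}_hypnogram.tsv", recording.hypnogram),
        "artifacts": write_artifact_mask(
            directory / f"{name}_artifacts.tsv", recording.artifact_mask, recording.channel_labels
        ),
    }
    return paths


def read_recording(edf_path: str | Path, hypnogram_path: str | Path, mask_path: str | Path) -> Recording:
    signal, fs, labels = read_edf_signal(edf_path)
    hyp = read_hypnogram(hypnogram_path)
    n_seconds = math.ceil(signal.shape[1] / fs)
    mask = read_artifact_mask(mask_path, labels, n_seconds)
    return Recording(
        signal=signal,
        sampling_rate_hz=fs,
        channel_labels=labels,
        hypnogram=hyp,
        artifact_mask=mask,
    )
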