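"""Core polysomnography container and channel-topography helpers.

A :class:`Recording` bundles the multichannel EEG signal (µV) with its
30-s-epoch hypnogram and a per-second, per-channel artifact mask.  All
detection and coupling analyses operate on artifact-free N2/N3 data only,
so the eligibility helpers here are the single source of truth for what
"analysable data" means throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

STAGES = ("W", "N1", "N2", "N3", "REM")
NREM_STAGES = ("N2", "N3")

EPOCH_S = 30.0

#: Named channel groups (10-20 labels).  Detection runs on the average of
#: the available channels of a group.
CHANNEL_GROUPS: dict[str, tuple[str, ...]] = {
    "frontal": ("F3", "F4"),
    "centro-parietal": ("C3", "Cz", "C4", "Pz"),
    "centro-parietal-so": ("Cz", "Pz"),
    "occipital": ("Oz", "O1", "O2"),
}


def resolve_channels(labels: Sequence[str], channel_set: str | Sequence[str]) -> list[int]:
    """Map a channel-set name or explicit label list to channel indices.

    Named groups keep only the labels present in the recording; an explicit
    list must match exactly.
    """
    if isinstance(channel_set, str):
        if channel_set not in CHANNEL_GROUPS:
            raise KeyError(
                f"unknown channel set {channel_set!r}; known: {sorted(CHANNEL_GROUPS)}"
            )
        wanted = [ch for ch in CHANNEL_GROUPS[channel_set] if ch in labels]
        if not wanted:
            raise ValueError(
                f"recording has no channels of group {channel_set!r} (labels: {list(labels)})"
            )
    else:
        missing = [ch for ch in channel_set if ch not in labels]
        if missing:
            raise ValueError(f"channels not in recording: {missing}")
        wanted = list(channel_set)
    return [list(labels).index(ch) for ch in wanted]


@dataclass
class Recording:
    """Multichannel sleep EEG with hypnogram and artifact mask.

    Parameters
    ----------
    signal
        Array (n_channels, n_samples), microvolts.
    sampling_rate_hz
        Sampling rate in Hz.
    channel_labels
        10-20 electrode names, one per signal row.
    hypnogram
        One stage label (W/N1/N2/N3/REM) per 30-s epoch.
    artifact_mask
        Boolean (n_channels, n_seconds); ``True`` marks a 1-s segment as
        artifact on that channel.
    """

    signal: np.ndarray
    sampling_rate_hz: float
    channel_labels: tuple[str, ...]
    hypnogram: np.ndarray
    artifact_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError("one label per signal row required")
        self.hypnogram = np.asarray(self.hypnogram, dtype=object)
        bad = set(self.hypnogram) - set(STAGES)
        if bad:
            raise ValueError(f"unknown sleep stages {bad}")
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != (self.n_channels, self.n_seconds):
            raise ValueError(
                "artifact mask must be (n_channels, n_seconds) = "
                f"{(self.n_channels, self.n_seconds)}, got {self.artifact_mask.shape}"
            )
        n_epochs = math.ceil(self.duration_s / EPOCH_S)
        if len(self.hypnogram) != n_epochs:
            raise ValueError(
                f"hypnogram must have {n_epochs} epochs, got {len(self.hypnogram)}"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    @property
    def n_seconds(self) -> int:
        return math.ceil(self.duration_s)

    # -- topography -----------------------------------------------------
    def channel_indices(self, channel_set: str | Sequence[str]) -> list[int]:
        return resolve_channels(self.channel_labels, channel_set)

    def averaged_signal(self, channel_set: str | Sequence[str]) -> np.ndarray:
        """Mean over the channels of a topographic group (1-D, µV)."""
        idx = self.channel_indices(channel_set)
        return self.signal[idx].mean(axis=0)

    # -- eligibility ----------------------------------------------------
    def second_stages(self) -> np.ndarray:
        """Stage label of every 1-s segment (expanded hypnogram)."""
        reps = np.repeat(self.hypnogram, int(EPOCH_S))
        return reps[: self.n_seconds]

    def eligible_seconds(
        self,
        channel_set: str | Sequence[str],
        stages: Iterable[str] = NREM_STAGES,
    ) -> np.ndarray:
        """Boolean per second: in a requested stage and artifact-free on
        every channel of the set."""
        stages = set(stages)
        idx = self.channel_indices(channel_set)
        in_stage = np.isin(self.second_stages(), list(stages))
        clean = ~self.artifact_mask[idx].any(axis=0)
        return in_stage & clean

    def eligible_minutes(
        self,
        channel_set: str | Sequence[str],
        stages: Iterable[str] = NREM_STAGES,
    ) -> float:
        return float(self.eligible_seconds(channel_set, stages).sum()) / 60.0

    def eligible_sample_mask(
        self,
        channel_set: str | Sequence[str],
        stages: Iterable[str] = NREM_STAGES,
    ) -> np.ndarray:
        """Per-sample expansion of :meth:`eligible_seconds`."""
        sec = self.eligible_seconds(channel_set, stages)
        n = int(round(self.sampling_rate_hz))
        mask = np.repeat(sec, n)
        return mask[: self.n_samples]
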