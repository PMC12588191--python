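"""Core data containers shared across the pipeline.

All signal containers hold a ``channels x samples`` float array in microvolts
together with the sampling rate and enough provenance (subject, seizure index,
window/segment index) to trace any feature row back to its source signal.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "SeizureEvent",
    "PreictalWindow",
    "Segment",
    "SegmentSet",
    "FeatureMatrix",
]


def _validate_signal(data: np.ndarray, fs: float, channel_labels: list[str]) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError(f"signal must be 2-D (channels x samples), got shape {data.shape}")
    if data.shape[0] < 1:
        raise ValueError("at least one channel required")
    if fs <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    if len(channel_labels) != data.shape[0]:
        raise ValueError(
            f"{len(channel_labels)} labels for {data.shape[0]} channels"
        )
    if len(set(channel_labels)) != len(channel_labels):
        raise ValueError("channel labels must be unique")
    return data


@dataclass
class Recording:
    """A multichannel scalp EEG recording (channels x samples, microvolts)."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = _validate_signal(self.data, self.fs, self.channel_labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SeizureEvent:
    """A clinically annotated seizure, in seconds from recording start."""

    onset_s: float
    offset_s: float
    source_file: str = ""

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset_s}")
        if self.offset_s < self.onset_s:
            raise ValueError(
                f"offset ({self.offset_s}) precedes onset ({self.onset_s})"
            )


@dataclass
class PreictalWindow:
    """A fixed-length slice of EEG immediately preceding a seizure onset."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str = ""
    seizure_index: int = 0
    start_s: float = 0.0
    end_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = _validate_signal(self.data, self.fs, self.channel_labels)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def window_id(self) -> str:
        return f"{self.subject_id}/{self.seizure_index}"


@dataclass
class Segment:
    """One fixed-length, non-overlapping piece of a pre-ictal window."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str
    window_id: str
    segment_index: int

    def __post_init__(self) -> None:
        self.data = _validate_signal(self.data, self.fs, self.channel_labels)
        if self.segment_index < 0:
            raise ValueError("segment_index must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SegmentSet:
    """Ordered segments plus per-subject bookkeeping counts."""

    segments: list[Segment]
    per_subject_counts: pd.DataFrame  # columns: subject_id, windows, segments

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_windows(self) -> int:
        return int(self.per_subject_counts["windows"].sum())

    def manifest(self) -> pd.DataFrame:
        rows = []
        for seg in self.segments:
            start = seg.segment_index * seg.n_samples
            rows.append(
                {
                    "subject_id": seg.subject_id,
                    "window_id": seg.window_id,
                    "segment_index": seg.segment_index,
                    "start_sample": start,
                    "end_sample": start + seg.n_samples,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class FeatureMatrix:
    """n_segments x n_features matrix with stable column names and row metadata."""

    values: np.ndarray
    feature_names: list[str]
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{len(self.feature_names)} names for {self.values.shape[1]} columns"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains NaN or Inf")

    @property
    def n_segments(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)
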