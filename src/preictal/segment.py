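"""Split pre-ictal windows into fixed-length, non-overlapping segments.

A 30-s window at the default 5-s segment length yields six segments per
window; a 12-subject cohort with 96 windows therefore yields 576 segments.
Sample indexing is 0-based and half-open: segment ``i`` covers samples
``[i*seg_len*fs, (i+1)*seg_len*fs)``.  A trailing partial segment is dropped
with a warning.
"""
from __future__ import annotations

import warnings

import pandas as pd

from .types import PreictalWindow, Segment, SegmentSet

__all__ = ["segment_window", "segment_dataset"]


def segment_window(window: PreictalWindow, seg_len_s: float = 5.0) -> list[Segment]:
    """Cut a window into contiguous non-overlapping segments in temporal order."""
    if seg_len_s <= 0:
        raise ValueError(f"segment length must be positive, got {seg_len_s}")
    if window.duration_s < seg_len_s:
        raise ValueError(
            f"window ({window.duration_s}s) shorter than segment length ({seg_len_s}s)"
        )
    seg_samples = int(round(seg_len_s * window.fs))
    n_full = window.n_samples // seg_samples
    remainder = window.n_samples - n_full * seg_samples
    if remainder:
        warnings.warn(
            f"window {window.window_id}: dropping trailing partial segment "
            f"({remainder} samples)",
            stacklevel=2,
        )
    return [
        Segment(
            data=window.data[:, i * seg_samples : (i + 1) * seg_samples].copy(),
            fs=window.fs,
            channel_labels=list(window.channel_labels),
            subject_id=window.subject_id,
            window_id=window.window_id,
            segment_index=i,
        )
        for i in range(n_full)
    ]


def segment_dataset(
    windows: list[PreictalWindow], seg_len_s: float = 5.0
) -> SegmentSet:
    """Segment every window and tabulate per-subject window/segment counts."""
    if not windows:
        raise ValueError("no windows to segment")
    segments: list[Segment] = []
    counts: dict[str, list[int]] = {}
    for win in windows:
        segs = segment_window(win, seg_len_s=seg_len_s)
        segments.extend(segs)
        row = counts.setdefault(win.subject_id, [0, 0])
        row[0] += 1
        row[1] += len(segs)
    table = pd.DataFrame(
        [
            {"subject_id": sid, "windows": w, "segments": s}
            for sid, (w, s) in sorted(counts.items())
        ]
    )
    return SegmentSet(segments=segments, per_subject_counts=table)
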