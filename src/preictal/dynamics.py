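"""Temporal structure of microstate labels within pre-ictal windows.

Segments within a window form an ordered label sequence; consecutive pairs
define transitions, which never span window boundaries (windows are
discontinuous slices of the source recordings).  A short moving-average
smoother suppresses single-segment flickers: labels are one-hot encoded,
averaged over a trailing window, and re-discretized by argmax with ties
resolved in favor of the previous smoothed label.  Filtered segments
(label -1) break pair adjacency rather than bridging it.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Segment

__all__ = [
    "LabelSequence",
    "TransitionMatrix",
    "build_sequences",
    "smooth_labels",
    "transition_matrix",
    "dynamics_report",
    "label_change_count",
]


@dataclass
class LabelSequence:
    """Ordered cluster labels for one window's segments (-1 = filtered)."""

    window_id: str
    labels: list[int]


@dataclass
class TransitionMatrix:
    """Transition counts and row-stochastic probabilities between states."""

    counts: np.ndarray
    probs: np.ndarray
    state_ids: list[int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("negative transition counts")
        row_sums = self.probs.sum(axis=1)
        out = self.counts.sum(axis=1)
        for i, (s, c) in enumerate(zip(row_sums, out)):
            if c > 0 and abs(s - 1.0) > 1e-9:
                raise ValueError(f"row {i} not stochastic (sum {s})")
            if c == 0 and s != 0:
                raise ValueError(f"row {i} has no transitions but nonzero probs")

    def to_frame(self, what: str = "probs") -> pd.DataFrame:
        arr = self.probs if what == "probs" else self.counts
        return pd.DataFrame(arr, index=self.state_ids, columns=self.state_ids)


def build_sequences(
    segments: list[Segment], labels: np.ndarray
) -> list[LabelSequence]:
    """Group per-segment labels into one ordered sequence per window.

    Input order is irrelevant: sequences are restored by ``segment_index``.
    Duplicate or missing segment indices within a window raise.
    """
    labels = np.asarray(labels, dtype=int)
    if len(segments) != len(labels):
        raise ValueError(
            f"{len(segments)} segments but {len(labels)} labels"
        )
    per_window: dict[str, dict[int, int]] = {}
    order: list[str] = []
    for seg, lab in zip(segments, labels):
        if seg.window_id not in per_window:
            order.append(seg.window_id)
        d = per_window.setdefault(seg.window_id, {})
        if seg.segment_index in d:
            raise ValueError(
                f"duplicate segment_index {seg.segment_index} in window "
                f"{seg.window_id}"
            )
        d[seg.segment_index] = int(lab)
    sequences = []
    for wid in order:
        d = per_window[wid]
        expected = set(range(len(d)))
        if set(d) != expected:
            raise ValueError(
                f"window {wid}: segment indices {sorted(d)} are not contiguous "
                "from 0"
            )
        sequences.append(LabelSequence(wid, [d[i] for i in sorted(d)]))
    return sequences


def smooth_labels(seq: LabelSequence, window: int = 2) -> LabelSequence:
    """Moving-average smoothing of a categorical label sequence.

    Each position's label is the argmax of the one-hot average over the
    trailing ``window`` original labels; ties go to the previous smoothed
    label, and the first element is left unchanged.  ``window=1`` is the
    identity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    labels = list(seq.labels)
    if window == 1 or len(labels) <= 1:
        return LabelSequence(seq.window_id, labels)
    out = [labels[0]]
    for t in range(1, len(labels)):
        chunk = labels[max(0, t - window + 1) : t + 1]
        vals, counts = np.unique(chunk, return_counts=True)
        best = counts.max()
        candidates = set(vals[counts == best].tolist())
        if out[-1] in candidates:
            out.append(out[-1])
        else:
            # deterministic fallback among tied labels: most recent occurrence
            for lab in reversed(chunk):
                if lab in candidates:
                    out.append(int(lab))
                    break
    return LabelSequence(seq.window_id, out)


def transition_matrix(
    sequences: list[LabelSequence],
    exclude_noise: bool = True,
    n_states: int | None = None,
) -> TransitionMatrix:
    """Count within-window consecutive label pairs and row-normalize.

    Pairs involving the noise label (-1) are skipped when ``exclude_noise``.
    ``n_states`` fixes the state set (0..n_states-1); by default it is
    inferred from the observed labels.
    """
    pairs = []
    for seq in sequences:
        for a, b in zip(seq.labels[:-1], seq.labels[1:]):
            if exclude_noise and (a < 0 or b < 0):
                continue
            pairs.append((a, b))
    if not pairs:
        raise ValueError("no transitions observed (after noise exclusion)")
    if n_states is None:
        states = sorted({s for p in pairs for s in p})
    else:
        states = list(range(n_states))
    index = {s: i for i, s in enumerate(states)}
    counts = np.zeros((len(states), len(states)), dtype=int)
    for a, b in pairs:
        counts[index[a], index[b]] += 1
    out = counts.sum(axis=1)
    probs = np.zeros_like(counts, dtype=float)
    nonzero = out > 0
    probs[nonzero] = counts[nonzero] / out[nonzero, None]
    return TransitionMatrix(counts=counts, probs=probs, state_ids=states)


def label_change_count(sequences: list[LabelSequence]) -> int:
    """Total number of within-window consecutive label changes."""
    return sum(
        int(a != b)
        for seq in sequences
        for a, b in zip(seq.labels[:-1], seq.labels[1:])
    )


def dynamics_report(
    tm: TransitionMatrix,
    sequences: list[LabelSequence] | None = None,
    smoothing_window: int = 2,
) -> dict:
    """Summarize transition structure and the effect of smoothing.

    Reports each state's top destination, the overall most and least frequent
    observed transitions, and (when sequences are given) the label-change
    count before and after smoothing — smoothing never increases it.
    """
    top = {}
    for i, s in enumerate(tm.state_ids):
        if tm.counts[i].sum() == 0:
            continue
        j = int(np.argmax(tm.probs[i]))
        top[s] = {"to": tm.state_ids[j], "prob": float(tm.probs[i, j])}

    observed = np.argwhere(tm.counts > 0)
    if observed.size:
        flat = [(tuple(ij), tm.counts[ij[0], ij[1]]) for ij in observed]
        most = max(flat, key=lambda t: t[1])
        least = min(flat, key=lambda t: t[1])
        fmt = lambda ij: (tm.state_ids[ij[0]], tm.state_ids[ij[1]])
        extremes = {
            "most_frequent": {"pair": fmt(most[0]), "count": int(most[1])},
            "least_frequent": {"pair": fmt(least[0]), "count": int(least[1])},
        }
    else:
        extremes = {}

    report: dict = {"top_destinations": top, **extremes}
    if sequences is not None:
        smoothed = [smooth_labels(s, window=smoothing_window) for s in sequences]
        before = label_change_count(sequences)
        after = label_change_count(smoothed)
        assert after <= before, "smoothing increased the label-change count"
        report["label_changes_before"] = before
        report["label_changes_after"] = after
    return report
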