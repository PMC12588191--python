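"""Reading EEG recordings, parsing seizure annotations, and cutting pre-ictal windows.

EDF files are read through MNE and restricted to a requested bipolar montage.
Seizure onsets come from the plain-text summary dialect used by the CHB-MIT
scalp EEG database (``Seizure Start Time: N seconds``).  A small 16-bit EDF
writer is included so synthetic recordings can round-trip through the same
on-disk format as clinical data.
"""
from __future__ import annotations

import datetime
import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .types import PreictalWindow, Recording, SeizureEvent

__all__ = [
    "DEFAULT_MONTAGE",
    "read_recording",
    "write_edf",
    "parse_seizure_summary",
    "extract_preictal_window",
    "extract_windows",
]

#: 18-channel longitudinal bipolar montage (double banana) used by default.
DEFAULT_MONTAGE: list[str] = [
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ",
]


def normalize_label(label: str) -> str:
    """Canonical channel-label form: uppercase, hyphen/space/underscore stripped."""
    return re.sub(r"[\s\-_]", "", label.upper())


def read_recording(
    path: str | Path,
    montage: list[str] | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Read an EDF file and return the requested channels, in order, in microvolts.

    Parameters
    ----------
    path
        EDF file path.
    montage
        Channel labels to select, matched case-insensitively and tolerant of
        hyphen/space differences.  Defaults to the 18-channel bipolar montage.
    subject_id
        Subject identifier; defaults to the file stem's leading token.

    Raises
    ------
    ValueError
        If the montage is empty, a requested label is missing, or the
        requested channels do not share one sampling rate.
    """
    import mne

    if montage is None:
        montage = list(DEFAULT_MONTAGE)
    if len(montage) == 0:
        raise ValueError("montage must name at least one channel")

    path = Path(path)
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")

    available = {normalize_label(name): name for name in raw.ch_names}
    missing = [lab for lab in montage if normalize_label(lab) not in available]
    if missing:
        raise ValueError(
            f"channel(s) {missing} not found in {path.name}; "
            f"available: {raw.ch_names}"
        )
    picks = [available[normalize_label(lab)] for lab in montage]

    # MNE silently upsamples mixed-rate EDF channels on load; detect and refuse
    # using the per-channel sample counts from the EDF header.
    extras = getattr(raw, "_raw_extras", None)
    n_samps = extras[0].get("n_samps") if extras else None
    if n_samps is not None:
        idx = [raw.ch_names.index(p) for p in picks]
        per_chan = {int(n_samps[i]) for i in idx}
        if len(per_chan) > 1:
            raise ValueError(
                f"requested channels have mixed per-record sample counts "
                f"{sorted(per_chan)} (mixed sampling rates)"
            )

    data_v = raw.get_data(picks=picks)  # volts
    if subject_id is None:
        subject_id = path.stem.split("_")[0]
    return Recording(
        data=data_v * 1e6,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(montage),
        subject_id=subject_id,
    )


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a Recording as a plain 16-bit EDF file (one 1-s data record per second).

    Physical dimension is microvolts; per-channel physical range is taken from
    the data, so re-reading reproduces the signal within 16-bit quantization.
    The recording length must be a whole number of seconds at an integer
    sampling rate.
    """
    path = Path(path)
    fs = rec.fs
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    if rec.n_samples % fs != 0:
        raise ValueError("EDF writer requires a whole number of seconds of signal")
    n_records = rec.n_samples // fs
    ns = rec.n_channels

    def pad(text: str, width: int) -> bytes:
        b = text.encode("ascii")[:width]
        return b + b" " * (width - len(b))

    now = datetime.datetime(2000, 1, 1)
    header = b"".join(
        [
            pad("0", 8),
            pad(rec.subject_id or "X", 80),
            pad("Startdate 01-JAN-2000", 80),
            pad(now.strftime("%d.%m.%y"), 8),
            pad(now.strftime("%H.%M.%S"), 8),
            pad(str(256 * (ns + 1)), 8),
            pad("", 44),
            pad(str(n_records), 8),
            pad("1", 8),
            pad(str(ns), 4),
        ]
    )

    phys_min = np.empty(ns)
    phys_max = np.empty(ns)
    for c in range(ns):
        lo, hi = float(rec.data[c].min()), float(rec.data[c].max())
        if hi <= lo:  # constant channel: give a nonzero span
            lo, hi = lo - 1.0, hi + 1.0
        phys_min[c], phys_max[c] = lo, hi

    def fmt8(v: float) -> str:
        for p in range(6, -1, -1):
            s = f"{v:.{p}f}"
            if len(s) <= 8:
                return s
        return f"{v:.0f}"[:8]

    fields = [
        b"".join(pad(lab, 16) for lab in rec.channel_labels),
        b"".join(pad("", 80) for _ in range(ns)),
        b"".join(pad("uV", 8) for _ in range(ns)),
        b"".join(pad(fmt8(phys_min[c]), 8) for c in range(ns)),
        b"".join(pad(fmt8(phys_max[c]), 8) for c in range(ns)),
        b"".join(pad("-32768", 8) for _ in range(ns)),
        b"".join(pad("32767", 8) for _ in range(ns)),
        b"".join(pad("", 80) for _ in range(ns)),
        b"".join(pad(str(fs), 8) for _ in range(ns)),
        b"".join(pad("", 32) for _ in range(ns)),
    ]
    header += b"".join(fields)

    # The stated physical range must match what fmt8 printed, or quantization
    # error exceeds one digital step on re-read.
    pmin = np.array([float(fmt8(phys_min[c])) for c in range(ns)])
    pmax = np.array([float(fmt8(phys_max[c])) for c in range(ns)])
    scale = (pmax - pmin) / (32767.0 - (-32768.0))
    digital = np.rint((rec.data - pmin[:, None]) / scale[:, None] - 32768.0)
    digital = np.clip(digital, -32768, 32767).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for rec_i in range(n_records):
            sl = slice(rec_i * fs, (rec_i + 1) * fs)
            fh.write(digital[:, sl].tobytes())
    return path


_FILE_RE = re.compile(r"^File Name:\s*(\S+)", re.IGNORECASE)
_COUNT_RE = re.compile(r"^Number of Seizures in File:\s*(\d+)", re.IGNORECASE)
_START_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+Start Time:\s*([\d.]+)\s*sec", re.IGNORECASE)
_END_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+End Time:\s*([\d.]+)\s*sec", re.IGNORECASE)


def parse_seizure_summary(text: str) -> dict[str, list[SeizureEvent]]:
    """Parse a CHB-MIT-style seizure summary into a file -> events map.

    Each ``File Name`` block declares a seizure count followed by paired
    ``Seizure Start Time`` / ``Seizure End Time`` lines in seconds from the
    start of that file.  Events are returned ordered by onset.

    Raises
    ------
    ValueError
        If an end precedes its start, a start lacks an end, or the declared
        seizure count disagrees with the number of parsed pairs.
    """
    result: dict[str, list[SeizureEvent]] = {}
    current_file: str | None = None
    declared: dict[str, int] = {}
    pending_start: float | None = None

    def close_file() -> None:
        if current_file is None:
            return
        if pending_start is not None:
            raise ValueError(
                f"{current_file}: seizure start at {pending_start}s has no end time"
            )
        got = len(result.get(current_file, []))
        want = declared.get(current_file)
        if want is not None and got != want:
            raise ValueError(
                f"{current_file}: declared {want} seizures but parsed {got}"
            )

    for line in text.splitlines():
        line = line.strip()
        m = _FILE_RE.match(line)
        if m:
            close_file()
            current_file = m.group(1)
            result.setdefault(current_file, [])
            pending_start = None
            continue
        m = _COUNT_RE.match(line)
        if m and current_file is not None:
            declared[current_file] = int(m.group(1))
            continue
        m = _START_RE.match(line)
        if m:
            if current_file is None:
                raise ValueError("seizure time before any 'File Name' line")
            if pending_start is not None:
                raise ValueError(
                    f"{current_file}: consecutive start times without an end"
                )
            pending_start = float(m.group(1))
            continue
        m = _END_RE.match(line)
        if m:
            if current_file is None or pending_start is None:
                raise ValueError("seizure end time without a preceding start")
            end = float(m.group(1))
            if end < pending_start:
                raise ValueError(
                    f"{current_file}: end {end}s precedes start {pending_start}s"
                )
            result[current_file].append(
                SeizureEvent(pending_start, end, source_file=current_file)
            )
            pending_start = None
    close_file()

    for events in result.values():
        events.sort(key=lambda ev: ev.onset_s)
    return result


def extract_preictal_window(
    rec: Recording,
    ev: SeizureEvent,
    duration_s: float = 30.0,
    gap_s: float = 0.0,
    seizure_index: int = 0,
) -> PreictalWindow | None:
    """Cut the ``duration_s`` of signal ending ``gap_s`` before seizure onset.

    The window covers ``[onset - gap - duration, onset - gap)`` and never
    includes samples at or after ``onset - gap``.  Returns None (with a
    warning) when the recording has too little pre-onset signal.
    """
    start_s = ev.onset_s - gap_s - duration_s
    end_s = ev.onset_s - gap_s
    if start_s < 0:
        warnings.warn(
            f"skipping seizure at {ev.onset_s}s for {rec.subject_id}: "
            f"needs {duration_s + gap_s}s of pre-onset signal",
            stacklevel=2,
        )
        return None
    n = int(round(duration_s * rec.fs))
    start = int(round(start_s * rec.fs))
    if start + n > rec.n_samples:
        warnings.warn(
            f"skipping seizure at {ev.onset_s}s for {rec.subject_id}: "
            "window extends past end of recording",
            stacklevel=2,
        )
        return None
    return PreictalWindow(
        data=rec.data[:, start : start + n].copy(),
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        subject_id=rec.subject_id,
        seizure_index=seizure_index,
        start_s=start_s,
        end_s=end_s,
    )


def extract_windows(
    rec: Recording,
    events: list[SeizureEvent],
    duration_s: float = 30.0,
    gap_s: float = 0.0,
) -> tuple[list[PreictalWindow], pd.DataFrame]:
    """Extract one window per seizure; return windows plus a manifest.

    The manifest lists every event with its extraction status
    (``ok`` / ``skipped``), so skipped seizures are reported, not lost.
    """
    windows: list[PreictalWindow] = []
    rows = []
    for i, ev in enumerate(events):
        win = extract_preictal_window(
            rec, ev, duration_s=duration_s, gap_s=gap_s, seizure_index=i
        )
        rows.append(
            {
                "subject_id": rec.subject_id,
                "source_file": ev.source_file,
                "seizure_index": i,
                "onset_s": ev.onset_s,
                "start_s": win.start_s if win is not None else np.nan,
                "end_s": win.end_s if win is not None else np.nan,
                "n_samples": win.n_samples if win is not None else 0,
                "status": "ok" if win is not None else "skipped",
            }
        )
        if win is not None:
            windows.append(win)
    return windows, pd.DataFrame(rows)
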