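"""Synthetic pediatric-EEG generator with planted microstates and artifacts.

Windows are built segment by segment: a Markov chain over latent spectral
states advances at 5-s segment boundaries, and each state imposes a relative
band-power profile (delta/theta/alpha/beta/gamma).  Band-limited Gaussian
sources are shared across channels with channel-specific gains, producing
the inter-channel correlation typical of scalp EEG, on top of per-channel
1/f background noise.  Artifacts are planted with known ground truth: blink
templates (300-ms raised-cosine bumps on the frontal FP1/FP2 derivations at
a Poisson rate per 30 s) and a mains-frequency sinusoid.

The line-noise amplitude parameter is specified on the *measurement* scale —
the mean single-sided DFT amplitude over the mains +/- 1 Hz band that
``preprocess.line_noise_amplitude`` reports — and the injected tone's peak
amplitude is calibrated accordingly (a pure tone concentrates in one DFT bin,
so its band-mean reads peak/n_bins).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .ingest import DEFAULT_MONTAGE, normalize_label
from .preprocess import mains_band_bin_count
from .types import PreictalWindow

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "default_spec",
    "generate_window",
    "generate_dataset",
    "simulate_state_sequence",
]

#: Band edges shared with the feature extractor.
_BANDS = [(0.5, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0), (30.0, 45.0)]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic cohort; defaults mirror the study setting."""

    n_states: int = 4
    n_channels: int = 18
    fs: float = 256.0
    window_s: float = 30.0
    seg_len_s: float = 5.0
    state_band_weights: np.ndarray = field(default_factory=lambda: _DEFAULT_WEIGHTS.copy())
    markov: np.ndarray = field(default_factory=lambda: _DEFAULT_MARKOV.copy())
    rhythm_rms_uv: float = 30.0
    background_rms_uv: float = 12.0
    background_1f_exponent: float = 1.0
    background_max_hz: float = 45.0
    blink_rate_per_30s: float = 3.4
    blink_amplitude_uv: float = 200.0
    blink_duration_s: float = 0.3
    line_freq_hz: float = 50.0
    line_amplitude_uv: float = 2.6
    subject_gain_jitter: float = 0.10
    band_gain_jitter: float = 0.05
    seed: int = 42
    channel_labels: list[str] = field(default_factory=lambda: list(DEFAULT_MONTAGE))

    def __post_init__(self) -> None:
        self.state_band_weights = np.asarray(self.state_band_weights, dtype=float)
        self.markov = np.asarray(self.markov, dtype=float)
        if self.state_band_weights.shape != (self.n_states, len(_BANDS)):
            raise ValueError("state_band_weights must be n_states x 5")
        if np.any(self.state_band_weights < 0):
            raise ValueError("band weights must be non-negative")
        if not np.allclose(self.state_band_weights.sum(axis=1), 1.0):
            raise ValueError("band-weight rows must sum to 1")
        if self.markov.shape != (self.n_states, self.n_states):
            raise ValueError("markov must be n_states x n_states")
        if np.any(self.markov < 0) or not np.allclose(self.markov.sum(axis=1), 1.0):
            raise ValueError("markov rows must be stochastic")
        for name in ("blink_rate_per_30s", "blink_amplitude_uv", "line_amplitude_uv",
                     "rhythm_rms_uv", "background_rms_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def segments_per_window(self) -> int:
        return int(self.window_s // self.seg_len_s)


# State profiles: 0 alpha-dominant, 1 theta-dominant, 2 delta+theta-dominant,
# 3 beta/gamma-dominant.  Rows are (delta, theta, alpha, beta, gamma).
_DEFAULT_WEIGHTS = np.array(
    [
        [0.05, 0.08, 0.65, 0.17, 0.05],
        [0.10, 0.70, 0.10, 0.07, 0.03],
        [0.70, 0.15, 0.07, 0.05, 0.03],
        [0.05, 0.08, 0.12, 0.45, 0.30],
    ]
)

# Self-transition 0.5; elevated flow into the slow-wave state 2 from states
# 0 and 1; direct 3 -> 0 transitions suppressed; remainder spread uniformly.
_DEFAULT_MARKOV = np.array(
    [
        [0.50, 0.10, 0.30, 0.10],
        [0.10, 0.50, 0.30, 0.10],
        [0.50 / 3, 0.50 / 3, 0.50, 0.50 / 3],
        [0.02, 0.24, 0.24, 0.50],
    ]
)


@dataclass
class GroundTruth:
    """Planted truth for one window: states, blink times, line amplitude."""

    window_id: str
    state_sequence: list[int]
    blink_times_s: list[float]
    line_amplitude_uv: float

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.state_sequence):
            raise ValueError("states must be non-negative")


def default_spec(seed: int = 42) -> SyntheticSpec:
    """The default 4-state cohort specification."""
    return SyntheticSpec(seed=seed)


def simulate_state_sequence(
    spec: SyntheticSpec, rng: np.random.Generator, n_segments: int | None = None
) -> list[int]:
    """Draw a latent-state sequence from the Markov chain (uniform start)."""
    if n_segments is None:
        n_segments = spec.segments_per_window
    state = int(rng.integers(spec.n_states))
    seq = [state]
    for _ in range(n_segments - 1):
        state = int(rng.choice(spec.n_states, p=spec.markov[state]))
        seq.append(state)
    return seq


def _band_sources(
    rng: np.random.Generator, n_rows: int, n: int, lo: float, hi: float, fs: float
) -> np.ndarray:
    """``n_rows`` independent unit-variance band-limited Gaussian noise rows."""
    white = rng.standard_normal((n_rows, n + 512))
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white, axis=1)[:, 256 : 256 + n]
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _pink_noise(
    rng: np.random.Generator,
    n_rows: int,
    n: int,
    exponent: float,
    fs: float,
    max_hz: float | None = None,
) -> np.ndarray:
    """``n_rows`` independent unit-variance 1/f^exponent noise rows.

    ``max_hz`` band-limits the background to the modeled rhythm band so the
    mains-frequency region stays clean unless line noise is planted.
    """
    freqs = np.fft.rfftfreq(n, 1 / fs)
    spectrum = rng.standard_normal((n_rows, freqs.size)) + 1j * rng.standard_normal(
        (n_rows, freqs.size)
    )
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2)
    if max_hz is not None:
        shape[freqs > max_hz] = 0.0
    x = np.fft.irfft(spectrum * shape[None, :], n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _blink_template(fs: float, duration_s: float) -> np.ndarray:
    n = int(round(duration_s * fs))
    t = np.arange(n) / (n - 1)
    return 0.5 * (1 - np.cos(2 * np.pi * t))


def generate_window(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    subject_id: str = "sim00",
    seizure_index: int = 0,
    channel_gains: np.ndarray | None = None,
) -> tuple[PreictalWindow, GroundTruth]:
    """Generate one 30-s window and its ground truth.

    ``channel_gains`` (channels x bands) carries per-subject variability;
    defaults to all ones.
    """
    n_seg = spec.segments_per_window
    seg_n = int(round(spec.seg_len_s * spec.fs))
    n = n_seg * seg_n
    n_ch = spec.n_channels
    if channel_gains is None:
        channel_gains = np.ones((n_ch, len(_BANDS)))

    states = simulate_state_sequence(spec, rng, n_seg)
    # one shared band-limited source per (band, segment), mixed into channels
    # through sqrt(band weight of the segment's state) and per-channel gains
    src = np.stack(
        [
            _band_sources(rng, n_seg, seg_n, lo, hi, spec.fs)
            for lo, hi in _BANDS
        ]
    )  # (n_bands, n_seg, seg_n)
    sqrt_w = np.sqrt(spec.state_band_weights[states])  # (n_seg, n_bands)
    data = spec.rhythm_rms_uv * np.einsum(
        "sb,cb,bst->cst", sqrt_w, channel_gains, src
    ).reshape(n_ch, n)
    data += spec.background_rms_uv * _pink_noise(
        rng, n_ch, n, spec.background_1f_exponent, spec.fs,
        max_hz=spec.background_max_hz,
    )

    # blinks on frontal channels
    frontal = [
        i for i, lab in enumerate(spec.channel_labels[:n_ch])
        if normalize_label(lab).startswith(("FP1", "FP2"))
    ]
    blink_times: list[float] = []
    if spec.blink_rate_per_30s > 0 and frontal:
        n_blinks = rng.poisson(spec.blink_rate_per_30s * spec.window_s / 30.0)
        template = spec.blink_amplitude_uv * _blink_template(
            spec.fs, spec.blink_duration_s
        )
        # keep templates clear of the window edges so they are whole blinks
        t_lo = 0.5
        t_max = spec.window_s - spec.blink_duration_s - 0.5
        for t0 in np.sort(rng.uniform(t_lo, t_max, size=n_blinks)):
            start = int(round(t0 * spec.fs))
            data[frontal, start : start + template.size] += template[None, :]
            blink_times.append(float(t0))

    # mains-frequency line noise, calibrated to the band-mean amplitude scale
    if spec.line_amplitude_uv > 0:
        n_bins = mains_band_bin_count(n, spec.fs, spec.line_freq_hz)
        peak = spec.line_amplitude_uv * n_bins
        t = np.arange(n) / spec.fs
        phase = rng.uniform(0, 2 * np.pi)
        data += peak * np.sin(2 * np.pi * spec.line_freq_hz * t + phase)[None, :]

    window = PreictalWindow(
        data=data,
        fs=spec.fs,
        channel_labels=list(spec.channel_labels[:n_ch]),
        subject_id=subject_id,
        seizure_index=seizure_index,
        start_s=0.0,
        end_s=spec.window_s,
    )
    truth = GroundTruth(
        window_id=window.window_id,
        state_sequence=states,
        blink_times_s=blink_times,
        line_amplitude_uv=spec.line_amplitude_uv,
    )
    return window, truth


def generate_dataset(
    spec: SyntheticSpec,
    n_subjects: int = 12,
    windows_per_subject: int = 8,
) -> tuple[list[PreictalWindow], list[GroundTruth]]:
    """Generate a cohort of windows with per-subject channel-gain jitter.

    Fully reproducible from ``spec.seed``; the default cohort shape
    (12 subjects x 8 windows) yields 96 windows and, downstream, 576
    segments.
    """
    if n_subjects < 1 or windows_per_subject < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(spec.seed)
    windows: list[PreictalWindow] = []
    truths: list[GroundTruth] = []
    for s in range(n_subjects):
        subject_id = f"sim{s:02d}"
        gains = (
            1.0 + spec.subject_gain_jitter * rng.standard_normal((spec.n_channels, 1))
        ) * (
            1.0 + spec.band_gain_jitter * rng.standard_normal(
                (spec.n_channels, len(_BANDS))
            )
        )
        gains = np.clip(gains, 0.2, None)
        for w in range(windows_per_subject):
            win, truth = generate_window(
                spec, rng, subject_id=subject_id, seizure_index=w,
                channel_gains=gains,
            )
            windows.append(win)
            truths.append(truth)
    return windows, truths
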