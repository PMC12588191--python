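"""Standardization, band-limiting, and ICA-based artifact removal.

The cleaning path mirrors standard clinical EEG practice: per-channel z-score
normalization, zero-phase Butterworth band-pass (0.5-45 Hz), and independent
component analysis to isolate and subtract ocular (blink) and mains-frequency
line-noise sources.  Artifact burden is quantified before and after cleaning:

* line noise -- median over channels of the mean single-sided DFT amplitude
  in a +/-1 Hz band around the mains frequency (the quantity a reader would
  report as "median line-noise amplitude (49-51 Hz)");
* blinks -- threshold events on the 0.5-5 Hz-filtered frontal-channel mean,
  expressed as a count per 30 s.

The component-selection criteria (frontal loading, kurtosis, low-frequency
power for blinks; narrowband mains power for line noise) are declared,
configurable defaults -- there is no universally agreed rule.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .ingest import normalize_label
from .types import PreictalWindow

__all__ = [
    "ArtifactReport",
    "ICADecomposition",
    "zscore_normalize",
    "bandpass",
    "fit_ica",
    "flag_artifact_components",
    "remove_components",
    "line_noise_amplitude",
    "blink_count",
    "clean_window",
]


@dataclass
class ArtifactReport:
    """Artifact burden before/after cleaning, with percent reductions."""

    line_noise_uv_pre: float
    line_noise_uv_post: float
    blink_count_per_30s_pre: float
    blink_count_per_30s_post: float
    delta_line_pct: float = field(init=False)
    delta_blink_pct: float = field(init=False)

    def __post_init__(self) -> None:
        self.delta_line_pct = percent_change(
            self.line_noise_uv_pre, self.line_noise_uv_post
        )
        self.delta_blink_pct = percent_change(
            self.blink_count_per_30s_pre, self.blink_count_per_30s_post
        )


def percent_change(pre: float, post: float) -> float:
    """Signed percent change, ``-100*(pre-post)/pre``; 0 when pre is 0."""
    if pre == 0:
        return 0.0
    return -100.0 * (pre - post) / pre


@dataclass
class ICADecomposition:
    """FastICA decomposition of one window plus artifact component flags."""

    unmixing: np.ndarray      # components x channels
    mixing: np.ndarray        # channels x components
    sources: np.ndarray       # components x samples (unit variance)
    mean: np.ndarray          # per-channel mean removed before unmixing
    channel_labels: list[str]
    fs: float
    seed: int
    flagged_blink: list[int] = field(default_factory=list)
    flagged_line: list[int] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]


def zscore_normalize(window: PreictalWindow) -> PreictalWindow:
    """Scale each channel to zero mean and unit (population) SD over the window.

    Zero-variance channels become all-zeros and are reported in a warning
    rather than producing NaNs.
    """
    data = window.data
    mean = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)  # population SD (ddof=0)
    flat = np.where(sd[:, 0] == 0)[0]
    if flat.size:
        labels = [window.channel_labels[i] for i in flat]
        warnings.warn(
            f"zero-variance channel(s) set to zeros: {labels}", stacklevel=2
        )
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (data - mean) / safe_sd
    out[flat] = 0.0
    return _replace_data(window, out)


def bandpass(
    window: PreictalWindow,
    low: float = 0.5,
    high: float | None = 45.0,
    order: int = 4,
) -> PreictalWindow:
    """Zero-phase Butterworth filter (forward-backward).

    ``high=None`` gives a pure high-pass, used before ICA when mains-frequency
    content must be kept for the ICA to isolate.
    """
    nyq = window.fs / 2
    if low <= 0:
        raise ValueError(f"low edge must be > 0, got {low}")
    if high is not None:
        if high >= nyq:
            raise ValueError(f"high edge {high} Hz >= Nyquist {nyq} Hz")
        if high <= low:
            raise ValueError("high edge must exceed low edge")
        sos = sps.butter(order, [low, high], btype="bandpass", fs=window.fs, output="sos")
    else:
        sos = sps.butter(order, low, btype="highpass", fs=window.fs, output="sos")
    out = sps.sosfiltfilt(sos, window.data, axis=1)
    return _replace_data(window, out)


def fit_ica(
    window: PreictalWindow,
    n_components: int | None = None,
    seed: int = 0,
    max_iter: int = 200,
    on_nonconvergence: str = "warn",
) -> ICADecomposition:
    """FastICA decomposition of a (high-pass filtered) window.

    Deterministic given ``seed``; sources have unit variance.  EEG routinely
    contains a near-Gaussian background subspace within which FastICA's
    rotation criterion cannot settle, while the artifact components of
    interest (spiky blinks, sinusoidal mains) separate within a few
    iterations; non-convergence at ``max_iter`` therefore warns by default.
    Set ``on_nonconvergence="raise"`` to escalate it to an error carrying the
    iteration count.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    if on_nonconvergence not in ("warn", "raise", "ignore"):
        raise ValueError(f"unknown on_nonconvergence policy {on_nonconvergence!r}")
    n_ch = window.n_channels
    if n_components is None:
        n_components = n_ch
    if n_components > n_ch:
        raise ValueError(
            f"n_components ({n_components}) exceeds channel count ({n_ch})"
        )
    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        random_state=seed,
        max_iter=max_iter,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(window.data.T)  # samples x components
    unconverged = any(issubclass(w.category, ConvergenceWarning) for w in caught)
    if unconverged and on_nonconvergence == "raise":
        raise RuntimeError(f"ICA did not converge within {max_iter} iterations")
    if unconverged and on_nonconvergence == "warn":
        warnings.warn(
            f"ICA reached the iteration limit ({max_iter}) without the "
            "rotation criterion settling; artifact components are typically "
            "already separated",
            stacklevel=2,
        )
    # fit_transform sources have unit *sample* variance (ddof=0 after scaling);
    # normalize defensively so downstream power ratios are comparable.
    sd = sources.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    sources = sources / sd
    mixing = ica.mixing_ * sd[None, :]
    return ICADecomposition(
        unmixing=ica.components_,
        mixing=mixing,
        sources=sources.T,
        mean=ica.mean_,
        channel_labels=list(window.channel_labels),
        fs=window.fs,
        seed=seed,
    )


def _source_psd_fractions(
    source: np.ndarray, fs: float, mains_hz: float
) -> tuple[float, float]:
    """(fraction of power < 5 Hz, fraction of power in mains +/- 1 Hz)."""
    freqs = np.fft.rfftfreq(source.size, 1 / fs)
    power = np.abs(np.fft.rfft(source)) ** 2
    total = power.sum()
    if total == 0:
        return 0.0, 0.0
    low = power[freqs < 5.0].sum() / total
    band = (freqs >= mains_hz - 1) & (freqs <= mains_hz + 1)
    line = power[band].sum() / total
    return float(low), float(line)


def flag_artifact_components(
    ica: ICADecomposition,
    mains_hz: float = 50.0,
    frontal_fraction_threshold: float = 0.6,
    kurtosis_threshold: float = 5.0,
    low_freq_fraction_threshold: float = 0.5,
    line_fraction_threshold: float = 0.3,
) -> tuple[list[int], list[int]]:
    """Identify blink-like and line-noise-like independent components.

    A component is flagged as a blink when its mixing-column loading
    concentrates on frontal channels (FP1*/FP2*), its source is spiky
    (excess kurtosis above threshold), and most of its power lies below 5 Hz.
    A component is flagged as line noise when the fraction of its power within
    +/-1 Hz of the mains frequency exceeds the threshold.  The flags are also
    stored on ``ica``.
    """
    frontal = np.array(
        [
            normalize_label(lab).startswith(("FP1", "FP2"))
            for lab in ica.channel_labels
        ]
    )
    blink: list[int] = []
    line: list[int] = []
    abs_mix = np.abs(ica.mixing)
    for k in range(ica.n_components):
        col = abs_mix[:, k]
        total = col.sum()
        frontal_frac = col[frontal].sum() / total if total > 0 else 0.0
        low_frac, line_frac = _source_psd_fractions(
            ica.sources[k], ica.fs, mains_hz
        )
        if line_frac > line_fraction_threshold:
            line.append(k)
            continue
        kurt = stats.kurtosis(ica.sources[k], fisher=True, bias=True)
        if (
            frontal_frac > frontal_fraction_threshold
            and kurt > kurtosis_threshold
            and low_frac > low_freq_fraction_threshold
        ):
            blink.append(k)
    ica.flagged_blink = blink
    ica.flagged_line = line
    return blink, line


def remove_components(
    ica: ICADecomposition, window: PreictalWindow, indices: list[int]
) -> PreictalWindow:
    """Reconstruct the window with the given source components zeroed.

    An empty index set reproduces the input (within numerical error of the
    decomposition); out-of-range indices raise.
    """
    for i in indices:
        if not 0 <= i < ica.n_components:
            raise IndexError(
                f"component index {i} out of range [0, {ica.n_components})"
            )
    sources = ica.sources.copy()
    sources[list(indices), :] = 0.0
    recon = ica.mixing @ sources + ica.mean[:, None]
    return _replace_data(window, recon)


def line_noise_amplitude(window: PreictalWindow, mains_hz: float = 50.0) -> float:
    """Median over channels of mean DFT amplitude within mains +/- 1 Hz (uV).

    Single-sided amplitude spectrum of the whole window (rectangular window,
    2/N normalization), averaged over the band's frequency bins.
    """
    if window.duration_s < 2.0:
        raise ValueError("window must be at least 2 s for a +/-1 Hz band")
    if mains_hz + 1 > window.fs / 2:
        raise ValueError(
            f"band {mains_hz - 1}-{mains_hz + 1} Hz exceeds Nyquist {window.fs / 2} Hz"
        )
    n = window.n_samples
    freqs = np.fft.rfftfreq(n, 1 / window.fs)
    amp = 2.0 * np.abs(np.fft.rfft(window.data, axis=1)) / n
    band = (freqs >= mains_hz - 1) & (freqs <= mains_hz + 1)
    return float(np.median(amp[:, band].mean(axis=1)))


def mains_band_bin_count(n_samples: int, fs: float, mains_hz: float = 50.0) -> int:
    """Number of DFT bins in the mains +/- 1 Hz band for a given window length."""
    freqs = np.fft.rfftfreq(n_samples, 1 / fs)
    return int(((freqs >= mains_hz - 1) & (freqs <= mains_hz + 1)).sum())


def blink_count(
    window: PreictalWindow,
    threshold_sigmas: float = 4.0,
    min_separation_s: float = 0.5,
    edge_guard_s: float = 0.5,
    block_s: float = 2.5,
) -> float:
    """Blink events per 30 s, detected on the frontal-channel mean.

    The mean of frontal channels (labels beginning FP1/FP2) is band-passed
    0.5-5 Hz; events are positive excursions beyond ``threshold_sigmas``
    times a MAD-based robust SD, with a minimum separation between events
    (blinks deflect the frontal derivations positively; the filter's negative
    undershoot must not double-count).  The robust SD is estimated per
    ``block_s`` block (floored by the whole-window MAD) so that slow
    nonstationarity of background delta power does not masquerade as blinks.
    The count is normalized to a per-30-s rate.
    """
    frontal = [
        i
        for i, lab in enumerate(window.channel_labels)
        if normalize_label(lab).startswith(("FP1", "FP2"))
    ]
    if not frontal:
        raise ValueError("no frontal (FP1*/FP2*) channels present")
    mean_sig = window.data[frontal].mean(axis=0)
    sos = sps.butter(4, [0.5, 5.0], btype="bandpass", fs=window.fs, output="sos")
    filt = sps.sosfiltfilt(sos, mean_sig)
    global_sd = 1.4826 * np.median(np.abs(filt - np.median(filt)))
    if global_sd == 0:
        return 0.0
    # blockwise robust SD, floored by the global estimate
    block = max(1, int(round(block_s * window.fs)))
    local_sd = np.empty_like(filt)
    for start in range(0, filt.size, block):
        seg = filt[start : start + block]
        sd = 1.4826 * np.median(np.abs(seg - np.median(seg)))
        local_sd[start : start + block] = max(sd, global_sd)
    peaks, _ = sps.find_peaks(
        filt,
        distance=max(1, int(round(min_separation_s * window.fs))),
    )
    peaks = peaks[filt[peaks] > threshold_sigmas * local_sd[peaks]]
    # the zero-phase filter's boundary transients are not blinks
    guard = int(round(edge_guard_s * window.fs))
    n = filt.size
    peaks = peaks[(peaks >= guard) & (peaks < n - guard)]
    return len(peaks) * 30.0 / window.duration_s


def clean_window(
    window: PreictalWindow,
    mains_hz: float = 50.0,
    seed: int = 0,
    max_iter: int = 200,
    highpass_hz: float = 0.5,
) -> tuple[PreictalWindow, ArtifactReport, ICADecomposition]:
    """High-pass, decompose, flag, and subtract artifact components.

    Artifact metrics are measured on the raw window (pre) and on the
    reconstruction with flagged components removed (post).  The low-pass edge
    is deliberately left open here so mains-frequency content survives to the
    ICA stage and is removed as a source, not by the filter.
    """
    pre_line = line_noise_amplitude(window, mains_hz=mains_hz)
    pre_blink = blink_count(window)
    hp = bandpass(window, low=highpass_hz, high=None)
    ica = fit_ica(hp, seed=seed, max_iter=max_iter)
    blink_idx, line_idx = flag_artifact_components(ica, mains_hz=mains_hz)
    cleaned = remove_components(ica, hp, sorted(set(blink_idx) | set(line_idx)))
    post_line = line_noise_amplitude(cleaned, mains_hz=mains_hz)
    post_blink = blink_count(cleaned)
    report = ArtifactReport(pre_line, post_line, pre_blink, post_blink)
    return cleaned, report, ica


def _replace_data(window: PreictalWindow, data: np.ndarray) -> PreictalWindow:
    return PreictalWindow(
        data=data,
        fs=window.fs,
        channel_labels=list(window.channel_labels),
        subject_id=window.subject_id,
        seizure_index=window.seizure_index,
        start_s=window.start_s,
        end_s=window.end_s,
    )
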