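"""Multimodal per-channel feature extraction for 5-s EEG segments.

Each channel contributes 80 features — 8 time-domain statistics, 3 Hjorth
parameters, 18 spectral quantities (absolute/relative band powers in the
canonical delta/theta/alpha/beta/gamma bands plus summary statistics and
band ratios), 3 entropy measures (sample, permutation, histogram Shannon),
and 48 discrete-wavelet subband statistics — so the default 18-channel
montage yields a 1,440-dimensional vector per segment.

Degenerate inputs never produce NaN/Inf: constant signals map skewness,
kurtosis and entropies to 0, and all-zero signals map relative powers and
ratios to 0.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from numba import njit
from scipy import signal as sps

from .types import FeatureMatrix, Segment

__all__ = [
    "FeatureConfig",
    "time_stats",
    "hjorth",
    "band_powers",
    "sample_entropy",
    "permutation_entropy",
    "hist_entropy",
    "wavelet_features",
    "per_channel_feature_names",
    "extract_features",
    "extract_feature_matrix",
]

#: Canonical EEG frequency bands (Hz), half-open [low, high).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the per-channel feature extractor."""

    fs: float = 256.0
    n_channels: int = 18
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS)
    )
    welch_window_s: float = 2.0
    welch_overlap: float = 0.5
    sampen_m: int = 2
    sampen_r_factor: float = 0.2
    perm_order: int = 3
    perm_delay: int = 1
    hist_bins: int = 10
    wavelet: str = "db4"
    wavelet_level: int = 5

    def __post_init__(self) -> None:
        edges = [e for band in self.bands.values() for e in band]
        if any(hi <= lo for lo, hi in self.bands.values()):
            raise ValueError("band edges must be strictly increasing")
        if min(edges) <= 0 or max(edges) >= self.fs / 2:
            raise ValueError("band edges must lie within (0, fs/2)")

    @property
    def total_band(self) -> tuple[float, float]:
        lows = [lo for lo, _ in self.bands.values()]
        highs = [hi for _, hi in self.bands.values()]
        return (min(lows), max(highs))

    @property
    def features_per_channel(self) -> int:
        return len(per_channel_feature_names(self))


_TIME_NAMES = [
    "mean", "variance", "skewness", "kurtosis",
    "rms", "ptp", "zcr", "line_length",
]
_HJORTH_NAMES = ["hjorth_activity", "hjorth_mobility", "hjorth_complexity"]
_SPECTRAL_SUMMARY_NAMES = [
    "total_power", "spectral_entropy", "edge95_hz", "peak_freq_hz", "median_freq_hz",
]
_RATIO_NAMES = ["ratio_theta_alpha", "ratio_delta_beta", "ratio_slow_fast"]
_ENTROPY_NAMES = ["sampen", "perm_entropy", "hist_entropy"]
_WAVELET_STAT_NAMES = [
    "mean", "sd", "mean_abs", "energy", "rel_energy", "max_abs",
    "skewness", "kurtosis",
]


def per_channel_feature_names(config: FeatureConfig) -> list[str]:
    """The ordered names of the features computed for one channel."""
    names = list(_TIME_NAMES) + list(_HJORTH_NAMES)
    names += [f"pow_{b}" for b in config.bands]
    names += [f"rel_{b}" for b in config.bands]
    names += list(_SPECTRAL_SUMMARY_NAMES) + list(_RATIO_NAMES)
    names += list(_ENTROPY_NAMES)
    subbands = [f"cA{config.wavelet_level}"] + [
        f"cD{lvl}" for lvl in range(config.wavelet_level, 0, -1)
    ]
    names += [f"wav_{sb}_{st}" for sb in subbands for st in _WAVELET_STAT_NAMES]
    return names


def _skew_kurt(x: np.ndarray) -> tuple[float, float]:
    """Population Fisher skewness and excess kurtosis; 0 for constant input."""
    sd = x.std()
    if sd == 0:
        return 0.0, 0.0
    z = (x - x.mean()) / sd
    return float(np.mean(z**3)), float(np.mean(z**4) - 3.0)


def time_stats(x: np.ndarray) -> np.ndarray:
    """Mean, population variance, skewness, excess kurtosis, RMS,
    peak-to-peak, zero-crossing rate, and line length of one channel."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    skew, kurt = _skew_kurt(x)
    signs = np.where(x >= 0, 1, -1)
    zcr = np.count_nonzero(np.diff(signs)) / (x.size - 1)
    return np.array(
        [
            x.mean(),
            x.var(),
            skew,
            kurt,
            np.sqrt(np.mean(x**2)),
            np.ptp(x),
            zcr,
            np.mean(np.abs(np.diff(x))),
        ]
    )


def hjorth(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity (variance), mobility, and complexity.

    Mobility is the RMS frequency proxy sqrt(var(dx)/var(x)); complexity is
    the mobility of the first difference divided by the mobility of the
    signal.  A constant signal maps to (0, 0, 0).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    activity = x.var()
    if activity == 0:
        return 0.0, 0.0, 0.0
    dx = np.diff(x)
    var_dx = dx.var()
    mobility = np.sqrt(var_dx / activity)
    if var_dx == 0:
        return float(activity), float(mobility), 0.0
    ddx = np.diff(dx)
    complexity = np.sqrt(ddx.var() / var_dx) / mobility
    return float(activity), float(mobility), float(complexity)


def band_powers(x: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """Welch-PSD band powers and spectral summaries for one channel.

    Returns, in order: absolute power per band, relative power per band,
    total power over the full analysis band, normalized spectral entropy,
    95 % spectral edge frequency, peak frequency, median frequency, and the
    theta/alpha, delta/beta, and (delta+theta)/(alpha+beta) ratios.
    """
    psd_f, psd = _welch(np.asarray(x, dtype=float)[None, :], config)
    return _band_powers_from_psd(psd_f, psd, config)[0]


def _welch(data: np.ndarray, config: FeatureConfig) -> tuple[np.ndarray, np.ndarray]:
    nperseg = int(round(config.welch_window_s * config.fs))
    if data.shape[-1] < nperseg:
        raise ValueError(
            f"segment shorter ({data.shape[-1]}) than one Welch window ({nperseg})"
        )
    noverlap = int(round(nperseg * config.welch_overlap))
    freqs, psd = sps.welch(
        data, fs=config.fs, window="hamming", nperseg=nperseg, noverlap=noverlap,
        axis=-1,
    )
    return freqs, psd


def _band_powers_from_psd(
    freqs: np.ndarray, psd: np.ndarray, config: FeatureConfig
) -> np.ndarray:
    """Vectorized over channels: psd is (n_channels, n_freqs)."""
    df = freqs[1] - freqs[0]
    lo, hi = config.total_band
    total_mask = (freqs >= lo) & (freqs <= hi)
    f_tot = freqs[total_mask]
    p_tot = psd[:, total_mask]
    total = p_tot.sum(axis=1) * df

    # bands are half-open [lo, hi); the topmost band closes at the upper edge
    # so the bands exactly tile the total analysis band
    abs_powers = np.stack(
        [
            psd[
                :,
                (freqs >= b_lo)
                & ((freqs <= b_hi) if b_hi == hi else (freqs < b_hi)),
            ].sum(axis=1)
            * df
            for b_lo, b_hi in config.bands.values()
        ],
        axis=1,
    )
    safe_total = np.where(total > 0, total, 1.0)
    rel = np.where(total[:, None] > 0, abs_powers / safe_total[:, None], 0.0)

    # normalized Shannon entropy of the PSD over the analysis band
    p_sum = p_tot.sum(axis=1, keepdims=True)
    prob = np.where(p_sum > 0, p_tot / np.where(p_sum > 0, p_sum, 1.0), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(prob > 0, prob * np.log(prob), 0.0)
    spec_ent = np.where(
        p_sum[:, 0] > 0, -plogp.sum(axis=1) / np.log(p_tot.shape[1]), 0.0
    )

    cum = np.cumsum(p_tot, axis=1)
    cum_total = cum[:, -1]

    def edge(fraction: float) -> np.ndarray:
        idx = np.argmax(cum >= fraction * cum_total[:, None], axis=1)
        return np.where(cum_total > 0, f_tot[idx], 0.0)

    edge95 = edge(0.95)
    median_freq = edge(0.50)
    peak = np.where(cum_total > 0, f_tot[np.argmax(p_tot, axis=1)], 0.0)

    band_names = list(config.bands)
    bd = {name: abs_powers[:, i] for i, name in enumerate(band_names)}

    def ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)

    ratios = np.stack(
        [
            ratio(bd["theta"], bd["alpha"]),
            ratio(bd["delta"], bd["beta"]),
            ratio(bd["delta"] + bd["theta"], bd["alpha"] + bd["beta"]),
        ],
        axis=1,
    )
    return np.concatenate(
        [
            abs_powers,
            rel,
            total[:, None],
            spec_ent[:, None],
            edge95[:, None],
            peak[:, None],
            median_freq[:, None],
            ratios,
        ],
        axis=1,
    )


@njit(cache=True)
def _sampen_counts(x: np.ndarray, r: float) -> tuple[int, int]:
    """Template-match counts for m=2 (B) and m=3 (A) under Chebyshev distance.

    Sorted sweep on the first template coordinate: templates are reordered by
    their first sample, so candidate pairs whose first coordinates already
    differ by more than r are skipped in bulk.  Equivalent to the O(n^2)
    pairwise count.
    """
    n = x.shape[0]
    nt = n - 2  # templates of length 3 start at 0..n-3; m-templates use same range
    order = np.argsort(x[:nt])
    # gather successor coordinates in sorted order for sequential access
    s0 = np.empty(nt)
    s1 = np.empty(nt)
    s2 = np.empty(nt)
    for a in range(nt):
        i = order[a]
        s0[a] = x[i]
        s1[a] = x[i + 1]
        s2[a] = x[i + 2]
    a_count = 0
    b_count = 0
    for a in range(nt - 1):
        xa = s0[a]
        y1 = s1[a]
        y2 = s2[a]
        for b in range(a + 1, nt):
            if s0[b] - xa > r:
                break
            if abs(s1[b] - y1) <= r:
                b_count += 1
                if abs(s2[b] - y2) <= r:
                    a_count += 1
    return a_count, b_count


def sample_entropy(
    x: np.ndarray, m: int = 2, r: float | None = None
) -> float:
    """Sample entropy -ln(A/B) with tolerance ``r`` (default 0.2 x SD).

    A and B are the counts of length-(m+1) and length-m template pairs within
    Chebyshev distance r, self-matches excluded, both evaluated over the
    n-m-1 templates that admit an (m+1)-length extension.  Returns 0 when no
    matches exist at either length (perfectly irregular or too-short input)
    or when the signal is constant.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10:
        raise ValueError("need at least 10 samples")
    if m != 2:
        a, b = _sampen_counts_generic(x, m, r if r is not None else 0.2 * x.std())
        return 0.0 if (a == 0 or b == 0) else float(-np.log(a / b))
    if r is None:
        sd = x.std()
        if sd == 0:
            return 0.0
        r = 0.2 * sd
    a, b = _sampen_counts(x, r)
    if a == 0 or b == 0:
        return 0.0
    return float(-np.log(a / b))


def _sampen_counts_generic(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Plain vectorized pairwise count for arbitrary m (not performance-critical)."""
    n = x.size
    nt = n - m
    templ_m = np.lib.stride_tricks.sliding_window_view(x, m)[:nt]
    templ_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)[:nt]
    b = a = 0
    for i in range(nt - 1):
        dm = np.max(np.abs(templ_m[i + 1 :] - templ_m[i]), axis=1)
        hit = dm <= r
        b += int(hit.sum())
        if hit.any():
            dm1 = np.max(np.abs(templ_m1[i + 1 :][hit] - templ_m1[i]), axis=1)
            a += int((dm1 <= r).sum())
    return a, b


def permutation_entropy(
    x: np.ndarray, order: int = 3, delay: int = 1
) -> float:
    """Normalized permutation entropy in [0, 1].

    Shannon entropy of the ordinal-pattern distribution divided by
    log(order!); ties are broken by first occurrence (stable sort).
    """
    x = np.asarray(x, dtype=float)
    n_patterns = x.size - (order - 1) * delay
    if n_patterns < 1:
        raise ValueError(
            f"need at least {(order - 1) * delay + 1} samples for order {order}, "
            f"delay {delay}"
        )
    idx = np.arange(n_patterns)[:, None] + np.arange(order)[None, :] * delay
    windows = x[idx]
    perms = np.argsort(windows, axis=1, kind="stable")
    codes = (perms * (order ** np.arange(order))[None, :]).sum(axis=1)
    counts = np.bincount(codes)
    probs = counts[counts > 0] / n_patterns
    h = -np.sum(probs * np.log(probs))
    import math

    return float(h / np.log(math.factorial(order)))


def hist_entropy(x: np.ndarray, bins: int = 10) -> float:
    """Normalized Shannon entropy of the equal-width amplitude histogram.

    Bins span the observed amplitude range, so the value is invariant under
    affine rescaling of the signal.  Constant input maps to 0.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return 0.0
    counts, _ = np.histogram(x, bins=bins)
    probs = counts[counts > 0] / x.size
    return float(-np.sum(probs * np.log(probs)) / np.log(bins))


def wavelet_features(
    x: np.ndarray, wavelet: str = "db4", level: int = 5
) -> np.ndarray:
    """Statistics of the DWT subbands cA_L, cD_L, ..., cD_1 (8 per subband).

    Uses periodized orthogonal DWT so subband energies sum to the signal
    energy (Parseval).  Per subband: mean, population SD, mean absolute
    coefficient, energy, relative energy, max absolute coefficient,
    skewness, kurtosis.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2**level:
        raise ValueError(
            f"segment of {x.size} samples supports at most level "
            f"{int(np.floor(np.log2(max(x.size, 1))))}, requested {level}"
        )
    coeffs = pywt.wavedec(x, wavelet, mode="periodization", level=level)
    energies = np.array([float(np.sum(c**2)) for c in coeffs])
    total = energies.sum()
    out = np.empty(8 * len(coeffs))
    for i, c in enumerate(coeffs):
        skew, kurt = _skew_kurt(c)
        out[8 * i : 8 * (i + 1)] = [
            c.mean(),
            c.std(),
            np.mean(np.abs(c)),
            energies[i],
            energies[i] / total if total > 0 else 0.0,
            np.max(np.abs(c)),
            skew,
            kurt,
        ]
    return out


def _skew_kurt_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise population skewness and excess kurtosis; 0 for constant rows."""
    sd = x.std(axis=1)
    safe = np.where(sd == 0, 1.0, sd)
    z = (x - x.mean(axis=1, keepdims=True)) / safe[:, None]
    z2 = z * z
    skew = np.where(sd > 0, np.mean(z2 * z, axis=1), 0.0)
    kurt = np.where(sd > 0, np.mean(z2 * z2, axis=1) - 3.0, 0.0)
    return skew, kurt


def _time_stats_matrix(data: np.ndarray) -> np.ndarray:
    """Vectorized time_stats over channels: (n_ch, 8)."""
    skew, kurt = _skew_kurt_matrix(data)
    pos = data >= 0
    zcr = np.count_nonzero(pos[:, 1:] ^ pos[:, :-1], axis=1) / (data.shape[1] - 1)
    dx = np.diff(data, axis=1)
    return np.column_stack(
        [
            data.mean(axis=1),
            data.var(axis=1),
            skew,
            kurt,
            np.sqrt(np.mean(data * data, axis=1)),
            np.ptp(data, axis=1),
            zcr,
            np.mean(np.abs(dx), axis=1),
        ]
    )


def _hjorth_matrix(data: np.ndarray) -> np.ndarray:
    """Vectorized Hjorth parameters over channels: (n_ch, 3)."""
    act = data.var(axis=1)
    dx = np.diff(data, axis=1)
    var_dx = dx.var(axis=1)
    safe_act = np.where(act == 0, 1.0, act)
    mob = np.where(act > 0, np.sqrt(var_dx / safe_act), 0.0)
    ddx = np.diff(dx, axis=1)
    var_ddx = ddx.var(axis=1)
    safe_vdx = np.where(var_dx == 0, 1.0, var_dx)
    mob_dx = np.where(var_dx > 0, np.sqrt(var_ddx / safe_vdx), 0.0)
    safe_mob = np.where(mob == 0, 1.0, mob)
    comp = np.where((act > 0) & (mob > 0) & (var_dx > 0), mob_dx / safe_mob, 0.0)
    return np.column_stack([act, mob, comp])


def _wavelet_matrix(data: np.ndarray, wavelet: str, level: int) -> np.ndarray:
    """Vectorized wavelet_features over channels: (n_ch, 8*(level+1))."""
    if data.shape[1] < 2**level:
        raise ValueError(
            f"segment of {data.shape[1]} samples supports at most level "
            f"{int(np.floor(np.log2(max(data.shape[1], 1))))}, requested {level}"
        )
    coeffs = pywt.wavedec(data, wavelet, mode="periodization", level=level, axis=-1)
    energies = np.stack([np.sum(c**2, axis=1) for c in coeffs], axis=1)
    total = energies.sum(axis=1)
    safe_total = np.where(total == 0, 1.0, total)
    blocks = []
    for i, c in enumerate(coeffs):
        skew, kurt = _skew_kurt_matrix(c)
        blocks.append(
            np.column_stack(
                [
                    c.mean(axis=1),
                    c.std(axis=1),
                    np.mean(np.abs(c), axis=1),
                    energies[:, i],
                    np.where(total > 0, energies[:, i] / safe_total, 0.0),
                    np.max(np.abs(c), axis=1),
                    skew,
                    kurt,
                ]
            )
        )
    return np.concatenate(blocks, axis=1)


def _perm_entropy_matrix(data: np.ndarray, order: int, delay: int) -> np.ndarray:
    """Vectorized permutation entropy over channels."""
    import math

    n_ch, n = data.shape
    n_patterns = n - (order - 1) * delay
    idx = np.arange(n_patterns)[:, None] + np.arange(order)[None, :] * delay
    windows = data[:, idx]  # (n_ch, n_patterns, order)
    perms = np.argsort(windows, axis=2, kind="stable")
    codes = (perms * (order ** np.arange(order))[None, None, :]).sum(axis=2)
    log_nperm = np.log(math.factorial(order))
    out = np.empty(n_ch)
    for c in range(n_ch):
        counts = np.bincount(codes[c])
        probs = counts[counts > 0] / n_patterns
        out[c] = -np.sum(probs * np.log(probs)) / log_nperm
    return out


def extract_features(
    segment: Segment, config: FeatureConfig | None = None
) -> tuple[np.ndarray, list[str]]:
    """Feature vector for one segment: channel-major, 80 features per channel.

    Returns the values and the stable column names ``<channel>__<feature>``.
    Deterministic: identical input yields an identical vector.
    """
    if config is None:
        config = FeatureConfig()
    if segment.n_channels != config.n_channels:
        raise ValueError(
            f"segment has {segment.n_channels} channels, config expects "
            f"{config.n_channels}"
        )
    if segment.fs != config.fs:
        raise ValueError(
            f"segment fs {segment.fs} != config fs {config.fs}"
        )
    data = segment.data
    n_ch = segment.n_channels
    per_ch = per_channel_feature_names(config)
    p = len(per_ch)

    # blocks vectorized over channels where profitable
    freqs, psd = _welch(data, config)
    spectral = _band_powers_from_psd(freqs, psd, config)
    ts = _time_stats_matrix(data)
    hj = _hjorth_matrix(data)
    wv = _wavelet_matrix(data, config.wavelet, config.wavelet_level)
    ent = np.empty((n_ch, 3))
    ent[:, 1] = _perm_entropy_matrix(data, config.perm_order, config.perm_delay)
    for c in range(n_ch):
        x = data[c]
        ent[c, 0] = sample_entropy(
            x, m=config.sampen_m, r=config.sampen_r_factor * x.std()
        )
        ent[c, 2] = hist_entropy(x, bins=config.hist_bins)
    values = np.concatenate([ts, hj, spectral, ent, wv], axis=1)
    assert values.shape == (n_ch, p)

    names = [
        f"{ch}__{feat}"
        for ch in segment.channel_labels
        for feat in per_ch
    ]
    flat = values.reshape(-1)
    if not np.all(np.isfinite(flat)):
        bad = [names[i] for i in np.where(~np.isfinite(flat))[0][:5]]
        raise AssertionError(f"non-finite features produced: {bad}")
    return flat, names


def extract_feature_matrix(
    segments: list[Segment], config: FeatureConfig | None = None
) -> FeatureMatrix:
    """Extract features for every segment and assemble the cohort matrix."""
    if config is None:
        config = FeatureConfig()
    if not segments:
        raise ValueError("no segments given")
    rows = []
    names: list[str] | None = None
    meta = []
    for seg in segments:
        vec, seg_names = extract_features(seg, config)
        if names is None:
            names = seg_names
        rows.append(vec)
        meta.append(
            {
                "subject_id": seg.subject_id,
                "window_id": seg.window_id,
                "segment_index": seg.segment_index,
            }
        )
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_names=names or [],
        metadata=pd.DataFrame(meta),
    )
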