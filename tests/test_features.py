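import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from preictal.features import (
    FeatureConfig,
    band_powers,
    extract_features,
    extract_feature_matrix,
    hist_entropy,
    hjorth,
    per_channel_feature_names,
    permutation_entropy,
    sample_entropy,
    time_stats,
    wavelet_features,
)
from preictal.types import Segment

FS = 256.0


def _segment(data, fs=FS):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return Segment(
        data=data, fs=fs,
        channel_labels=[f"CH{i}" for i in range(data.shape[0])],
        subject_id="t", window_id="t/0", segment_index=0,
    )


def _sine(freq, n=1280, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


# ---------------------------------------------------------------- oracles

def sampen_oracle(x, m=2, r=None):
    """O(n^2) reference: pairwise Chebyshev template matches, self excluded."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = 0.2 * x.std()
    nt = len(x) - m
    a = b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                    a += 1
    if a == 0 or b == 0:
        return 0.0
    return -math.log(a / b)


def perm_entropy_oracle(x, order=3, delay=1):
    """Direct ordinal-pattern tally."""
    x = np.asarray(x, dtype=float)
    patterns = {}
    n = len(x) - (order - 1) * delay
    for t in range(n):
        w = x[t : t + order * delay : delay]
        pat = tuple(sorted(range(order), key=lambda i: (w[i], i)))
        patterns[pat] = patterns.get(pat, 0) + 1
    probs = np.array(list(patterns.values())) / n
    return float(-np.sum(probs * np.log(probs)) / math.log(math.factorial(order)))


# ---------------------------------------------------------------- tests

class TestTimeStats:
    def test_alternating_signal_closed_form(self):
        mean, var, _, _, rms, ptp, zcr, _ = time_stats([1.0, -1.0, 1.0, -1.0])
        assert mean == 0 and var == 1 and rms == 1 and ptp == 2 and zcr == 1.0

    def test_constant_signal_degenerate_rules(self):
        _, var, skew, kurt, _, _, zcr, ll = time_stats([3.0] * 10)
        assert (var, skew, kurt, zcr, ll) == (0, 0, 0, 0, 0)

    def test_standard_normal_moments(self):
        rng = np.random.default_rng(0)
        _, var, skew, _, _, _, _, _ = time_stats(rng.standard_normal(1280))
        assert abs(var - 1) < 0.15
        assert abs(skew) < 0.2


class TestHjorth:
    def test_constant_is_all_zero(self):
        assert hjorth([2.0] * 100) == (0.0, 0.0, 0.0)

    def test_sine_mobility_closed_form(self):
        # mobility of a sampled sinusoid: 2*sin(pi*f/fs)
        _, mobility, _ = hjorth(_sine(10.0, n=25600))
        assert mobility == pytest.approx(2 * np.sin(np.pi * 10 / FS), rel=1e-3)

    def test_sine_complexity_is_one(self):
        _, _, complexity = hjorth(_sine(10.0, n=25600))
        assert complexity == pytest.approx(1.0, rel=0.01)


class TestBandPowers:
    def test_relative_powers_sum_to_one(self):
        rng = np.random.default_rng(1)
        out = band_powers(rng.standard_normal(1280), FeatureConfig())
        assert out[5:10].sum() == pytest.approx(1.0, abs=1e-9)

    def test_alpha_tone_dominates_alpha_band(self):
        out = band_powers(_sine(10.0), FeatureConfig())
        rel_alpha = out[7]
        assert rel_alpha >= 0.95

    def test_white_noise_has_high_spectral_entropy(self):
        rng = np.random.default_rng(2)
        out = band_powers(rng.standard_normal(1280), FeatureConfig())
        spectral_entropy = out[11]
        assert spectral_entropy >= 0.9

    def test_zero_signal_flagged_as_zeros(self):
        out = band_powers(np.zeros(1280), FeatureConfig())
        assert np.all(np.isfinite(out))
        assert out[5:10].sum() == 0  # relative powers defined as 0


class TestSampleEntropy:
    def test_alternating_sequence_is_perfectly_regular(self):
        x = np.tile([1.0, -1.0], 50)
        assert sample_entropy(x) == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for n in (50, 120, 200):
            x = rng.standard_normal(n)
            assert sample_entropy(x) == pytest.approx(sampen_oracle(x), abs=1e-12)

    def test_iid_normal_band(self):
        rng = np.random.default_rng(4)
        value = sample_entropy(rng.standard_normal(1280))
        assert 1.5 <= value <= 3.0

    def test_oracle_agreement_on_correlated_signal(self):
        rng = np.random.default_rng(5)
        x = np.cumsum(rng.standard_normal(150))
        assert sample_entropy(x) == pytest.approx(sampen_oracle(x), abs=1e-12)


class TestPermutationEntropy:
    def test_monotone_ramp_is_zero(self):
        assert permutation_entropy(np.arange(100.0)) == 0.0

    def test_uniform_noise_near_one(self):
        rng = np.random.default_rng(6)
        assert permutation_entropy(rng.uniform(size=1280)) >= 0.99

    def test_matches_pattern_count_oracle(self):
        rng = np.random.default_rng(7)
        for n in (10, 25, 50):
            x = rng.standard_normal(n)
            assert permutation_entropy(x) == pytest.approx(
                perm_entropy_oracle(x), abs=1e-12
            )

    def test_ties_broken_by_first_occurrence(self):
        x = np.array([1.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        assert permutation_entropy(x) == pytest.approx(
            perm_entropy_oracle(x), abs=1e-12
        )


class TestWaveletFeatures:
    def test_parseval_energy_conservation(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(1280)
        out = wavelet_features(x)
        energies = out[3::8]  # energy is the 4th stat of each subband
        assert energies.sum() == pytest.approx(np.sum(x**2), rel=1e-6)

    def test_relative_energies_sum_to_one(self):
        rng = np.random.default_rng(9)
        out = wavelet_features(rng.standard_normal(1280))
        assert out[4::8].sum() == pytest.approx(1.0, abs=1e-9)

    def test_slow_tone_concentrates_in_approximation_band(self):
        # cA5 covers 0..fs/2^6 = 4 Hz at fs 256
        out = wavelet_features(_sine(1.0))
        rel_cA5 = out[4]
        assert rel_cA5 > 0.9

    def test_too_short_signal_names_feasible_level(self):
        with pytest.raises(ValueError, match="at most level 4"):
            wavelet_features(np.zeros(16), level=5)


class TestExtractFeatures:
    def test_default_vector_has_1440_named_features(self, sim_segments):
        vec, names = extract_features(sim_segments[0])
        assert vec.shape == (1440,)
        assert len(names) == 1440
        assert len(set(names)) == 1440
        assert names[0].startswith("FP1-F7__")

    def test_determinism(self, sim_segments):
        v1, n1 = extract_features(sim_segments[0])
        v2, n2 = extract_features(sim_segments[0])
        assert np.array_equal(v1, v2) and n1 == n2

    def test_vector_length_scales_with_channel_count(self):
        rng = np.random.default_rng(10)
        config = FeatureConfig(n_channels=3)
        seg = _segment(rng.standard_normal((3, 1280)))
        vec, _ = extract_features(seg, config)
        assert vec.shape == (3 * 80,)
        assert len(per_channel_feature_names(config)) == 80

    def test_all_zero_segment_is_finite(self):
        config = FeatureConfig(n_channels=2)
        vec, _ = extract_features(_segment(np.zeros((2, 1280))), config)
        assert np.all(np.isfinite(vec))

    def test_channel_count_mismatch_rejected(self):
        seg = _segment(np.zeros((2, 1280)))
        with pytest.raises(ValueError, match="channels"):
            extract_features(seg, FeatureConfig(n_channels=18))

    def test_scale_invariance_and_variance_scaling(self):
        rng = np.random.default_rng(11)
        config = FeatureConfig(n_channels=1)
        x = rng.standard_normal((1, 1280))
        v1, names = extract_features(_segment(x), config)
        v2, _ = extract_features(_segment(3.7 * x), config)
        idx = {n.split("__")[1]: i for i, n in enumerate(names)}
        for feat in ["rel_delta", "rel_theta", "rel_alpha", "rel_beta",
                     "rel_gamma", "spectral_entropy", "perm_entropy", "zcr"]:
            assert v2[idx[feat]] == pytest.approx(v1[idx[feat]], rel=1e-9), feat
        assert v2[idx["variance"]] == pytest.approx(
            3.7**2 * v1[idx["variance"]], rel=1e-9
        )

    @pytest.mark.parametrize(
        "fill",
        [0.0, 1.0, 1e6, -1e-12],
        ids=["zeros", "ones", "huge", "tiny-negative"],
    )
    def test_degenerate_inputs_stay_finite(self, fill):
        config = FeatureConfig(n_channels=2)
        vec, _ = extract_features(_segment(np.full((2, 1280), fill)), config)
        assert np.all(np.isfinite(vec))

    def test_matrix_assembly_carries_metadata(self, sim_segments):
        fm = extract_feature_matrix(sim_segments[:2])
        assert fm.values.shape == (2, 1440)
        assert fm.metadata["segment_index"].tolist() == [0, 1]


@given(
    x=hnp.arrays(
        dtype=np.float64,
        shape=st.integers(32, 200),
        elements=st.floats(-1e6, 1e6, allow_nan=False, width=64),
    )
)
@settings(max_examples=40, deadline=None)
def test_scalar_features_always_finite(x):
    """Every per-channel statistic stays finite for arbitrary finite input."""
    out = [
        *time_stats(x),
        *hjorth(x),
        sample_entropy(x, r=0.2 * x.std()) if len(x) >= 10 else 0.0,
        permutation_entropy(x),
        hist_entropy(x),
        *wavelet_features(x, level=3),
    ]
    assert np.all(np.isfinite(out))
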