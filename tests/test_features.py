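"""Quality features: oracle equivalence, analytic limits, invariances."""

import math

import numpy as np
import pytest

from _oracles import (appen_bruteforce, higuchi_bruteforce, pen_bruteforce,
                      sampen_bruteforce)
from conftest import make_segment
from fecgsqa.exceptions import ConfigurationError, DegenerateSignalError
from fecgsqa.features import (FEATURE_NAMES, EntropyParams,
                              approximate_entropy, bassqi, dfa_alpha,
                              extract_features, higuchi_fd, katz_fd,
                              moment_sqis, permutation_entropy, psqi,
                              sample_entropy, spectral_entropy)


def _sine(freq, fs=1000.0, n=3000):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs)


class TestApproximateEntropy:
    def test_constant_is_zero(self):
        assert approximate_entropy(np.full(50, 3.0), 2, 0.2) == 0.0

    def test_alternating_matches_oracle(self):
        x = np.array([1.0, 2.0] * 5)
        assert approximate_entropy(x, 2, 0.2) == pytest.approx(
            appen_bruteforce(x, 2, 0.2), abs=1e-9)

    def test_matches_oracle_on_random_inputs(self, rng):
        for _ in range(10):
            x = rng.standard_normal(rng.integers(20, 120))
            assert approximate_entropy(x, 2, 0.2) == pytest.approx(
                appen_bruteforce(x, 2, 0.2), abs=1e-9)

    def test_noise_exceeds_sine(self, rng):
        noise = rng.standard_normal(1000)
        sine = _sine(2.0, n=1000)
        assert approximate_entropy(noise) > approximate_entropy(sine)

    def test_too_short_raises(self):
        with pytest.raises(ConfigurationError):
            approximate_entropy(np.arange(3), m=2)


class TestSampleEntropy:
    def test_constant_is_zero(self):
        assert sample_entropy(np.full(100, 2.0)) == 0.0

    def test_periodic_matches_oracle(self):
        x = np.array([0.0, 1.0] * 100)
        assert sample_entropy(x, 2, 0.2) == pytest.approx(
            sampen_bruteforce(x, 2, 0.2), abs=1e-9)

    def test_matches_oracle_on_random_inputs(self, rng):
        for _ in range(10):
            x = rng.standard_normal(rng.integers(20, 150))
            a = sample_entropy(x, 2, 0.2)
            b = sampen_bruteforce(x, 2, 0.2)
            if math.isinf(b):
                assert math.isinf(a)
            else:
                assert a == pytest.approx(b, abs=1e-9)

    def test_affine_rescaling_invariant(self, rng):
        x = rng.standard_normal(300)
        assert sample_entropy(3.5 * x + 2.0) == pytest.approx(
            sample_entropy(x), abs=1e-9)

    def test_no_matches_gives_inf(self):
        # a steep ramp has no template matches at tight tolerance
        assert math.isinf(sample_entropy(np.arange(30.0), 2, 0.01))


class TestSpectralEntropy:
    def test_white_noise_near_max(self, rng):
        assert spectral_entropy(rng.standard_normal(4096), 1000.0) > 0.9

    def test_pure_tone_low(self):
        assert spectral_entropy(_sine(10.0, n=4000), 1000.0) < 0.3

    def test_bounded(self, rng):
        for _ in range(5):
            v = spectral_entropy(rng.standard_normal(1024).cumsum(), 250.0)
            assert 0.0 <= v <= 1.0

    def test_constant_raises(self):
        with pytest.raises(DegenerateSignalError):
            spectral_entropy(np.ones(100), 100.0)


class TestPermutationEntropy:
    def test_monotone_ramp_is_zero(self):
        assert permutation_entropy(np.arange(100.0), 3, 1) == 0.0

    def test_iid_uniform_near_one(self, rng):
        assert permutation_entropy(rng.uniform(size=10_000), 3, 1) > 0.99

    def test_hand_enumerated_example(self):
        x = np.array([1.0, 3.0, 2.0, 4.0, 3.0, 5.0])
        # 5 ordered pairs: (1,3)up (3,2)down (2,4)up (4,3)down (3,5)up
        expected = -(0.6 * math.log(0.6) + 0.4 * math.log(0.4)) / math.log(2)
        assert permutation_entropy(x, 2, 1) == pytest.approx(expected, abs=1e-12)

    def test_matches_oracle_with_ties(self, rng):
        for _ in range(10):
            x = rng.integers(0, 4, size=60).astype(float)  # many ties
            assert permutation_entropy(x, 3, 2) == pytest.approx(
                pen_bruteforce(x, 3, 2), abs=1e-9)

    def test_too_short_raises(self):
        with pytest.raises(ConfigurationError):
            permutation_entropy(np.arange(3.0), order=4, delay=1)


class TestDFA:
    def test_white_noise_alpha_half(self, rng):
        assert 0.4 <= dfa_alpha(rng.standard_normal(3000)) <= 0.6

    def test_random_walk_alpha_three_halves(self, rng):
        assert 1.35 <= dfa_alpha(rng.standard_normal(3000).cumsum()) <= 1.65

    def test_amplitude_invariant(self, rng):
        x = rng.standard_normal(1000)
        assert dfa_alpha(17.0 * x) == pytest.approx(dfa_alpha(x), abs=1e-9)

    def test_too_short_raises(self):
        with pytest.raises(ConfigurationError):
            dfa_alpha(np.arange(10.0))


class TestFractalDimensions:
    def test_katz_line_is_one(self):
        assert katz_fd(np.linspace(0, 5, 200)) == pytest.approx(1.0, abs=1e-6)

    def test_katz_constant_is_one(self):
        assert katz_fd(np.zeros(50)) == 1.0

    def test_katz_noise_exceeds_sine(self, rng):
        noise = rng.standard_normal(1000)
        sine = _sine(2.0, n=1000) * noise.std()
        assert katz_fd(noise) > katz_fd(sine)

    def test_higuchi_line_near_one(self):
        assert 1.0 <= higuchi_fd(np.linspace(0, 1, 500), 10) <= 1.05

    def test_higuchi_white_noise_near_two(self, rng):
        assert 1.9 <= higuchi_fd(rng.standard_normal(3000), 10) <= 2.05

    def test_higuchi_matches_oracle(self, rng):
        for _ in range(10):
            x = rng.standard_normal(100)
            assert higuchi_fd(x, 8) == pytest.approx(
                higuchi_bruteforce(x, 8), abs=1e-9)


class TestMomentSQIs:
    def test_gaussian_reference_values(self):
        x = np.random.default_rng(1).standard_normal(100_000)
        k, s = moment_sqis(x)
        assert 2.9 <= k <= 3.1
        assert -0.05 <= s <= 0.05

    def test_two_point_symmetric(self):
        k, s = moment_sqis(np.array([-1.0, 1.0] * 50))
        assert s == pytest.approx(0.0, abs=1e-12)
        assert k == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(500) ** 3
        k1, s1 = moment_sqis(x)
        k2, s2 = moment_sqis(2.5 * x + 7.0)
        assert k1 == pytest.approx(k2, rel=1e-9)
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_constant_raises(self):
        with pytest.raises(DegenerateSignalError):
            moment_sqis(np.ones(100))


class TestBandPowerSQIs:
    def test_psqi_qrs_band_tone(self):
        assert psqi(_sine(10.0), 1000.0) >= 0.95

    def test_psqi_out_of_band_tone(self):
        assert psqi(_sine(30.0), 1000.0) <= 0.05

    def test_psqi_bounded(self, rng):
        for _ in range(5):
            assert 0.0 <= psqi(rng.standard_normal(3000), 1000.0) <= 1.0

    def test_bassqi_tone_above_baseline(self):
        assert bassqi(_sine(10.0), 1000.0) >= 0.95

    def test_bassqi_baseline_tone(self):
        assert bassqi(_sine(0.5, n=10_000), 1000.0) <= 0.1

    def test_low_fs_rejected(self):
        with pytest.raises(ConfigurationError):
            psqi(np.ones(100) + np.arange(100), 50.0)


class TestExtractFeatures:
    def test_twelve_named_finite_values(self, noise_segment):
        fv = extract_features(noise_segment)
        assert list(fv.names) == FEATURE_NAMES
        values = fv.as_dict()
        for name in FEATURE_NAMES[:-1]:
            assert np.isfinite(values[name]), name
        assert math.isnan(values["AE_MSE"])   # no autoencoder supplied

    def test_order_stable_across_calls(self, noise_segment):
        a = extract_features(noise_segment)
        b = extract_features(noise_segment)
        assert a.names == b.names
        np.testing.assert_array_equal(a.values[:-1], b.values[:-1])

    def test_feature_error_tagged_with_name(self):
        seg = make_segment(np.ones(3000))
        with pytest.raises(Exception, match="AppEn|SampEn|SpecEn"):
            extract_features(seg)

    def test_entropy_params_validation(self):
        with pytest.raises(ConfigurationError):
            EntropyParams(embedding_dim=0)
        with pytest.raises(ConfigurationError):
            EntropyParams(tolerance_fraction=0.0)
        with pytest.raises(ConfigurationError):
            EntropyParams(decimation_factor=0)
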