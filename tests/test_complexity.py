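"""Entropy/complexity metrics against brute-force oracles and invariants."""

import numpy as np
import pytest
from scipy import stats as sps

from sleepcrit import complexity, spectral

from oracles import (lz76_bruteforce, permen_bruteforce, sampen_bruteforce,
                     specen_bruteforce)


def _noise_spectrum(rng, n_bins=127):
    power = rng.exponential(1.0, n_bins)
    freqs = 0.5 + 0.25 * np.arange(n_bins)
    return spectral.PowerSpectrum(freqs=freqs, power=power)


class TestSampleEntropy:
    def test_alternating_sequence_is_perfectly_predictable(self):
        x = np.tile([1.0, -1.0], 32)
        assert complexity.sample_entropy(x) == 0.0
        assert sampen_bruteforce(x) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_on_noise(self, seed):
        x = np.random.default_rng(seed).standard_normal(256)
        assert np.isclose(complexity.sample_entropy(x),
                          sampen_bruteforce(x), rtol=0, atol=1e-12)

    def test_matches_bruteforce_n512(self):
        x = np.random.default_rng(99).standard_normal(512)
        assert complexity.sample_entropy(x) == pytest.approx(
            sampen_bruteforce(x), abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            complexity.sample_entropy(np.ones(64))

    def test_scale_offset_invariance(self):
        x = np.random.default_rng(3).standard_normal(300)
        ref = complexity.sample_entropy(x)
        assert complexity.sample_entropy(5.0 * x + 11.0) == pytest.approx(
            ref, rel=1e-9)

    def test_no_m_plus_1_match_returns_inf(self):
        # (1,1) templates match at length 2 but diverge at length 3
        x = np.array([1.0, 1.0, 2.0, 1.0, 1.0, 3.0])
        assert complexity.sample_entropy(x) == np.inf
        assert sampen_bruteforce(x) == np.inf


class TestSpectralEntropy:
    def test_single_bin_concentration_is_zero(self):
        f = 0.5 + 0.25 * np.arange(40)
        p = np.zeros(40)
        p[10] = 5.0
        ps = spectral.PowerSpectrum(freqs=f, power=p)
        assert complexity.spectral_entropy(ps) == 0.0

    def test_flat_spectrum_is_one(self):
        f = 0.5 + 0.25 * np.arange(40)
        ps = spectral.PowerSpectrum(freqs=f, power=np.full(40, 2.0))
        assert complexity.spectral_entropy(ps) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_summation(self, seed, rng):
        ps = _noise_spectrum(np.random.default_rng(seed))
        mask = (ps.freqs >= 0.5) & (ps.freqs <= 32.0)
        assert complexity.spectral_entropy(ps) == pytest.approx(
            specen_bruteforce(ps.power[0, mask]), abs=1e-12)

    def test_all_zero_spectrum_raises(self):
        f = 0.5 + 0.25 * np.arange(10)
        ps = spectral.PowerSpectrum(freqs=f, power=np.zeros(10))
        with pytest.raises(ValueError):
            complexity.spectral_entropy(ps)


class TestSpectralSampleEntropy:
    def test_alternating_two_level_spectrum_is_zero(self):
        f = 0.5 + 0.25 * np.arange(64)
        p = np.tile([1.0, 3.0], 32)
        ps = spectral.PowerSpectrum(freqs=f, power=p)
        assert complexity.spectral_sample_entropy(ps) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_bin_sequence(self, seed):
        ps = _noise_spectrum(np.random.default_rng(seed))
        mask = (ps.freqs >= 0.5) & (ps.freqs <= 32.0)
        assert complexity.spectral_sample_entropy(ps) == pytest.approx(
            sampen_bruteforce(ps.power[0, mask]), abs=1e-12)

    def test_flat_spectrum_raises(self):
        f = 0.5 + 0.25 * np.arange(32)
        ps = spectral.PowerSpectrum(freqs=f, power=np.full(32, 1.0))
        with pytest.raises(ValueError, match="zero variance"):
            complexity.spectral_sample_entropy(ps)


class TestLempelZiv:
    def test_phrase_count_matches_oracle_small_strings(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 33))
            bits = (rng.random(n) > rng.random()).astype(np.uint8)
            assert complexity._lz76_phrases(bits) == lz76_bruteforce(bits)

    def test_normalized_value_matches_oracle_n1024(self):
        x = np.random.default_rng(7).standard_normal(1024)
        bits = (x > np.median(x)).astype(np.uint8)
        expected = lz76_bruteforce(bits) * np.log2(1024) / 1024
        assert complexity.lempel_ziv(x) == pytest.approx(expected, abs=1e-12)

    def test_periodic_less_complex_than_random(self):
        n = 4096
        t = np.arange(n)
        periodic = np.sin(2 * np.pi * t / 64)
        random = np.random.default_rng(11).standard_normal(n)
        assert complexity.lempel_ziv(periodic) < complexity.lempel_ziv(random)

    def test_median_tie_rule_is_deterministic(self):
        # integer-quantized data with many median ties
        x = np.array([1, 2, 2, 3, 2, 1, 3, 2, 2, 1], dtype=float)
        assert complexity.lempel_ziv(x) == complexity.lempel_ziv(x.copy())

    def test_scale_offset_invariance(self):
        x = np.random.default_rng(5).standard_normal(500)
        assert complexity.lempel_ziv(x) == complexity.lempel_ziv(3.0 * x - 7.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            complexity.lempel_ziv(np.full(100, 2.0))


class TestPermutationEntropy:
    def test_monotonic_ramp_is_zero(self):
        assert complexity.permutation_entropy(np.arange(50.0)) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce(self, seed):
        x = np.random.default_rng(seed).standard_normal(400)
        assert complexity.permutation_entropy(x) == pytest.approx(
            permen_bruteforce(x), abs=1e-12)

    def test_hand_enumerated_toy(self):
        # patterns of [0, 2, 1, 3] at order 3: (0,2,1)->012 ranks 021?
        # enumerate by hand: windows (0,2,1) and (2,1,3):
        # first: ranks low-high = positions [0,2,1]; second: [1,0,2]
        # two distinct patterns, each once -> H = log 2 / log 6
        x = np.array([0.0, 2.0, 1.0, 3.0])
        expected = np.log(2) / np.log(6)
        assert complexity.permutation_entropy(x) == pytest.approx(expected)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            complexity.permutation_entropy(np.arange(3.0), order=4)


class TestRandomnessMonotonicity:
    def test_sampen_and_lzc_increase_with_noise_fraction(self):
        fs = 256.0
        t = np.arange(2048) / fs
        tone = np.sin(2 * np.pi * 10 * t)
        noise = np.random.default_rng(21).standard_normal(t.size)
        weights = np.linspace(0, 1, 11)
        sampens, lzcs = [], []
        for w in weights:
            x = (1 - w) * tone + w * noise
            sampens.append(complexity.sample_entropy(x))
            lzcs.append(complexity.lempel_ziv(x))
        assert sps.spearmanr(weights, sampens).statistic > 0.9
        assert sps.spearmanr(weights, lzcs).statistic > 0.9
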