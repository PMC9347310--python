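"""Sound-complexity metrics: spectra, bandwidth, entropy, modulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caldrift import (
    Spectrum,
    compute_power_spectrum,
    occupied_bandwidth,
    overlapping_tone_set,
    spectral_centroid,
    spectral_entropy,
    spectrotemporal_modulation_index,
)

FS = 97_600.0


def tone(freq, dur=0.5, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestPowerSpectrum:
    def test_tone_power_concentrates_at_tone_frequency(self):
        spec = compute_power_spectrum(tone(8000), FS)
        peak_freq = spec.freqs_hz[np.argmax(spec.power)]
        assert abs(peak_freq - 8000) < 5

    def test_two_equal_tones_give_two_equal_peaks(self):
        spec = compute_power_spectrum(tone(4000) + tone(16000), FS)
        w = 200  # Hz around each tone
        m4 = spec.power[np.abs(spec.freqs_hz - 4000) < w].sum()
        m16 = spec.power[np.abs(spec.freqs_hz - 16000) < w].sum()
        assert m4 == pytest.approx(m16, rel=1e-6)
        assert m4 + m16 > 0.99 * spec.total_power

    def test_white_noise_spectrum_is_flat_on_average(self, rng):
        # averaged over octave bands the periodogram of white noise is flat
        spec = compute_power_spectrum(rng.standard_normal(97_600), FS)
        edges = np.geomspace(1000, 48000, 6)
        densities = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            band = (spec.freqs_hz >= lo) & (spec.freqs_hz < hi)
            densities.append(spec.power[band].sum() / (hi - lo))
        densities = np.array(densities) / np.mean(densities)
        assert np.all(np.abs(densities - 1) < 0.15)

    def test_rejects_empty_and_nonfinite(self):
        with pytest.raises(ValueError):
            compute_power_spectrum(np.array([]), FS)
        with pytest.raises(ValueError):
            compute_power_spectrum(np.array([1.0, np.nan]), FS)


class TestOccupiedBandwidth:
    def test_single_bin_spectrum_is_zero(self):
        assert occupied_bandwidth(Spectrum(np.array([100.0]), np.array([1.0]))) == 0.0

    def test_flat_spectrum_covers_99_percent_of_band(self):
        n = 2000
        freqs = np.linspace(0, 20_000, n)
        spec = Spectrum(freqs, np.ones(n))
        bw = occupied_bandwidth(spec)
        bin_hz = freqs[1] - freqs[0]
        assert bw == pytest.approx(0.99 * 20_000, abs=2 * bin_hz)

    def test_pure_tone_bandwidth_below_100_hz(self):
        spec = compute_power_spectrum(tone(8000), FS)
        assert occupied_bandwidth(spec) < 100

    def test_zero_spectrum_rejected(self):
        with pytest.raises(ValueError):
            occupied_bandwidth(Spectrum(np.array([1.0, 2.0]), np.zeros(2)))

    def test_adding_edge_power_never_decreases_bandwidth(self, rng):
        freqs = np.linspace(0, 10_000, 64)
        for _ in range(20):
            power = rng.random(64)
            spec = Spectrum(freqs, power)
            widened = power.copy()
            widened[0] += 5.0
            widened[-1] += 5.0
            assert occupied_bandwidth(Spectrum(freqs, widened)) >= occupied_bandwidth(spec)


class TestSpectralEntropy:
    def test_flat_spectrum_reaches_log2_n(self):
        n = 256
        spec = Spectrum(np.arange(n, dtype=float), np.ones(n))
        assert spectral_entropy(spec) == pytest.approx(np.log2(n))

    def test_single_bin_and_two_equal_bins(self):
        assert spectral_entropy(Spectrum(np.array([5.0]), np.array([3.0]))) == 0.0
        two = Spectrum(np.array([1.0, 2.0]), np.array([0.5, 0.5]))
        assert spectral_entropy(two) == pytest.approx(1.0)

    def test_entropy_bounded_by_bin_count(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 100))
            spec = Spectrum(np.arange(n, dtype=float), rng.random(n) + 1e-12)
            h = spectral_entropy(spec)
            assert 0.0 <= h <= np.log2(n) + 1e-9


class TestSpectralCentroid:
    def test_tone_midpoint_and_flat_cases(self):
        assert spectral_centroid(
            compute_power_spectrum(tone(8000), FS)
        ) == pytest.approx(8000, abs=5)
        two = Spectrum(np.array([4000.0, 16000.0]), np.array([1.0, 1.0]))
        assert spectral_centroid(two) == pytest.approx(10_000)
        n = 4000
        flat = Spectrum(np.linspace(0, 20_000, n), np.ones(n))
        assert spectral_centroid(flat) == pytest.approx(10_000, rel=1e-3)


class TestModulationIndex:
    def test_stationary_tone_near_zero(self):
        mi = spectrotemporal_modulation_index(tone(8000), FS)
        assert mi == pytest.approx(0.0, abs=0.01)

    def test_disjoint_band_rotation_exceeds_one(self, rng):
        # 20 blocks of noise in 20 mutually disjoint bands, one block per
        # time bin: every pair of binned vectors anticorrelates, so the
        # mean correlation approaches its -1/19 lower bound and the
        # index approaches 1 + 1/19
        fs = FS
        n_blocks = 20
        block = int(0.2 * fs)
        x = np.zeros(n_blocks * block)
        freqs = np.fft.rfftfreq(block, 1 / fs)
        for k in range(n_blocks):
            lo, hi = k * 2400 + 100, (k + 1) * 2400
            spec = np.fft.rfft(rng.standard_normal(block))
            spec[(freqs < lo) | (freqs > hi)] = 0
            x[k * block : (k + 1) * block] = np.fft.irfft(spec, n=block)
        mi = spectrotemporal_modulation_index(x, fs)
        assert 1.0 < mi <= 1.0 + 1 / 19 + 0.01

    def test_bounds_zero_to_two(self, stimulus_set):
        for w in stimulus_set.waveforms:
            mi = spectrotemporal_modulation_index(w, stimulus_set.sample_rate_hz)
            assert -1e-9 <= mi <= 2.0 + 1e-9

    def test_too_short_waveform_rejected(self):
        with pytest.raises(ValueError):
            spectrotemporal_modulation_index(tone(8000, dur=0.02), FS)


class TestScaleInvariance:
    @pytest.mark.parametrize("scale", [0.1, 3.0, 1000.0])
    def test_all_metrics_unchanged_by_amplitude_scaling(self, scale, stimulus_set):
        w = stimulus_set.waveforms[10]
        fs = stimulus_set.sample_rate_hz
        s1 = compute_power_spectrum(w, fs)
        s2 = compute_power_spectrum(scale * w, fs)
        assert occupied_bandwidth(s1) == pytest.approx(occupied_bandwidth(s2))
        assert spectral_entropy(s1) == pytest.approx(spectral_entropy(s2))
        assert spectral_centroid(s1) == pytest.approx(spectral_centroid(s2))
        assert spectrotemporal_modulation_index(w, fs) == pytest.approx(
            spectrotemporal_modulation_index(scale * w, fs), abs=1e-9
        )


class TestSmallSpectrumOracle:
    """Brute-force cumulative-sum oracle for spectra with <= 16 bins."""

    @staticmethod
    def brute_bandwidth(freqs, power, lo=0.005, hi=0.995):
        tot = sum(power)
        def crossing(q):
            acc = 0.0
            for f, p in zip(freqs, power):
                acc += p
                if acc >= q * tot - 1e-12:
                    return f
            return freqs[-1]
        return crossing(hi) - crossing(lo)

    @given(
        power=st.lists(
            st.floats(min_value=0.01, max_value=10.0), min_size=2, max_size=16
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_bandwidth_and_centroid_match_brute_force(self, power):
        power = np.array(power)
        freqs = np.linspace(100.0, 100.0 * len(power), len(power))
        spec = Spectrum(freqs, power)
        assert occupied_bandwidth(spec) == pytest.approx(
            self.brute_bandwidth(freqs, power)
        )
        assert spectral_centroid(spec) == pytest.approx(
            float(np.sum(freqs * power) / np.sum(power))
        )


class TestOverlappingToneSet:
    def band_spectrum(self, lo, hi, n=5000, fmax=48_000.0):
        freqs = np.linspace(0, fmax, n)
        power = ((freqs >= lo) & (freqs <= hi)).astype(float)
        return Spectrum(freqs, power)

    def test_band_limited_noise_picks_overlapping_then_lowest(self):
        # flat band 3-6 kHz: only the 4 kHz tone's third-octave window
        # overlaps; the remaining all-zero candidates tie, broken to 2 kHz
        spec = self.band_spectrum(3000, 6000)
        tones = np.array([2000.0, 4000.0, 8000.0, 16_000.0])
        assert set(overlapping_tone_set(spec, tones, k=2)) == {0, 1}

    def test_k_equals_all_returns_identity(self):
        spec = self.band_spectrum(3000, 6000)
        tones = np.array([2000.0, 4000.0, 8000.0, 16_000.0])
        assert list(overlapping_tone_set(spec, tones, k=4)) == [0, 1, 2, 3]

    def test_power_above_all_tones_returns_lowest_frequencies(self):
        spec = self.band_spectrum(40_000, 45_000)
        tones = np.array([2000.0, 4000.0, 8000.0, 16_000.0])
        assert list(overlapping_tone_set(spec, tones, k=2)) == [0, 1]

    def test_invalid_k_rejected(self):
        spec = self.band_spectrum(3000, 6000)
        with pytest.raises(ValueError):
            overlapping_tone_set(spec, np.array([2000.0]), k=2)
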