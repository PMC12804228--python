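"""AE features: spectra, peak cleaning, band percentile, windowed RMS."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import skintrib as sk
from skintrib.acoustic import SpectralProfile, spectral_energy

from conftest import percentile_oracle

RATE = 2e6


def tone(freq, amplitude=1.0, duration=0.05, rate=RATE, phase=0.0):
    t = np.arange(int(duration * rate)) / rate
    return sk.AERecording(amplitude * np.sin(2 * np.pi * freq * t + phase),
                          rate=rate)


class TestSpectrum:
    def test_sinusoid_peaks_at_its_frequency(self):
        sp = sk.compute_fft_spectrum(tone(140e3))
        assert sp.freqs[np.argmax(sp.magnitudes)] == pytest.approx(140e3, abs=sp.df)
        assert sp.magnitudes.max() == pytest.approx(1.0, rel=1e-6)

    def test_zero_input_zero_spectrum(self):
        sp = sk.compute_fft_spectrum(sk.AERecording(np.zeros(1000), rate=RATE))
        assert np.all(sp.magnitudes == 0.0)

    def test_parseval_consistency(self):
        rng = np.random.default_rng(5)
        for n in (1000, 1001, 4096):
            x = rng.normal(size=n)
            rec = sk.AERecording(x, rate=RATE)
            sp = sk.compute_fft_spectrum(rec)
            assert spectral_energy(sp, n) == pytest.approx(
                float(np.sum(x**2)), rel=1e-9)

    def test_too_short_record_rejected(self):
        with pytest.raises(sk.ParameterError):
            sk.compute_fft_spectrum(sk.AERecording(np.array([1.0]), rate=RATE))


def flat_spectrum(n=200_001, baseline=0.001, f_max=1e6):
    freqs = np.linspace(0.0, f_max, n)
    return freqs, np.full(n, baseline)


class TestSmoothing:
    def test_flat_spectrum_unchanged(self):
        freqs, mags = flat_spectrum()
        mags[60_000] = 1.0  # reference peak fixing the normalization scale
        sp = SpectralProfile(freqs, mags.copy())
        out = sk.smooth_spectrum(sp)
        # the reference peak has prominence ~1, outside the removal range
        assert np.array_equal(out.magnitudes, mags)
        assert out.smoothed

    def test_singular_spike_removed_neighbors_untouched(self):
        freqs, mags = flat_spectrum()
        mags[60_000] = 1.0          # normalization reference, retained
        spike = 120_000
        mags[spike] = 0.02          # height 0.02, prominence 0.019
        sp = SpectralProfile(freqs, mags.copy())
        out = sk.smooth_spectrum(sp)
        assert out.magnitudes[spike] == pytest.approx(0.001, rel=1e-9)
        dist = max(1, int(round(1670.0 / sp.df)))
        far = np.ones(len(mags), bool)
        far[spike - dist:spike + dist + 1] = False
        far[60_000] = False
        assert np.array_equal(out.magnitudes[far], mags[far])

    def test_broad_peak_outside_prominence_range_retained(self):
        freqs, mags = flat_spectrum()
        mags[60_000] = 1.0
        bump = 0.5 * np.exp(-0.5 * ((freqs - 8e5) / 2e4) ** 2)  # prominence 0.5
        mags = np.maximum(mags, bump)
        sp = SpectralProfile(freqs, mags.copy())
        out = sk.smooth_spectrum(sp)
        assert np.array_equal(out.magnitudes, mags)

    def test_never_increases_magnitudes(self):
        rng = np.random.default_rng(8)
        freqs = np.linspace(0, 1e6, 50_001)
        mags = 0.02 * rng.random(len(freqs))
        mags[25_000] = 1.0
        sp = SpectralProfile(freqs, mags.copy())
        out = sk.smooth_spectrum(sp)
        assert np.all(out.magnitudes <= mags)

    def test_distance_longer_than_spectrum_rejected(self):
        freqs, mags = flat_spectrum(n=101)
        with pytest.raises(sk.ParameterError):
            sk.smooth_spectrum(SpectralProfile(freqs, mags),
                               min_distance_bins=500)


class TestBandPercentile:
    def test_constant_band_returns_constant(self):
        freqs = np.linspace(0, 1e6, 10_001)
        mags = np.where((freqs >= 120e3) & (freqs <= 160e3), 0.7, 0.1)
        assert sk.band_percentile(SpectralProfile(freqs, mags)) == 0.7

    def test_linear_band_matches_oracle(self):
        freqs = np.linspace(0, 1e6, 10_001)
        mags = freqs / 1e6
        sel = (freqs >= 120e3) & (freqs <= 160e3)
        expected = percentile_oracle(mags[sel], 90.0)
        assert sk.band_percentile(SpectralProfile(freqs, mags)) == pytest.approx(
            expected, rel=1e-12)

    def test_out_of_band_tone_scores_at_noise_floor(self):
        rng = np.random.default_rng(3)
        noise = 1e-3 * rng.standard_normal(int(0.2 * RATE))
        t = np.arange(len(noise)) / RATE
        in_band = noise + 0.5 * np.sin(2 * np.pi * (140e3 + 2.5) * t)
        out_band = noise + 0.5 * np.sin(2 * np.pi * (200e3 + 2.5) * t)
        v_in = sk.band_percentile(
            sk.compute_fft_spectrum(sk.AERecording(in_band, rate=RATE)))
        v_out = sk.band_percentile(
            sk.compute_fft_spectrum(sk.AERecording(out_band, rate=RATE)))
        assert v_in > 3 * v_out

    def test_band_guards(self):
        freqs = np.linspace(0, 1e6, 101)
        sp = SpectralProfile(freqs, np.ones(101))
        with pytest.raises(sk.ParameterError):
            sk.band_percentile(sp, band=(120e3, 121e3))  # too few bins
        with pytest.raises(sk.ParameterError):
            sk.band_percentile(sp, band=(9e5, 2e6))  # beyond Nyquist


class TestRMSProfile:
    def test_constant_signal(self):
        rec = sk.AERecording(np.full(100_000, -0.3), rate=RATE)
        prof = sk.compute_rms_profile(rec, 20_000)
        assert len(prof) == 5
        assert np.allclose(prof.values, 0.3)
        assert prof.window_seconds == pytest.approx(0.01)

    def test_sinusoid_integer_cycles(self):
        rec = tone(140e3, amplitude=0.8, duration=0.05)
        prof = sk.compute_rms_profile(rec, 20_000)  # 1400 cycles per window
        assert np.allclose(prof.values, 0.8 / math.sqrt(2), rtol=1e-6)

    def test_matches_direct_summation_oracle(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=4096)
        prof = sk.compute_rms_profile(sk.AERecording(x, rate=RATE), 512)
        for k, v in enumerate(prof.values):
            w = x[k * 512:(k + 1) * 512]
            oracle = math.sqrt(math.fsum(float(s) * float(s) for s in w) / 512)
            assert v == pytest.approx(oracle, rel=1e-12)

    def test_windowing_conserves_prefix(self):
        x = np.arange(1000.0)
        rec = sk.AERecording(x, rate=RATE)
        prof = sk.compute_rms_profile(rec, 300)
        n_used = len(prof) * 300
        rebuilt = x[:n_used].reshape(len(prof), 300).ravel()
        assert np.array_equal(rebuilt, x[:n_used])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(k=st.floats(0.1, 50.0))
    def test_homogeneity_under_scaling(self, k, knit_ae):
        short = sk.AERecording(knit_ae.samples[:200_000], rate=knit_ae.rate)
        scaled = sk.AERecording(short.samples * k, rate=short.rate)
        a = sk.compute_rms_profile(short, 4000)
        b = sk.compute_rms_profile(scaled, 4000)
        assert np.allclose(b.values, k * a.values, rtol=1e-9)
        pa = sk.band_percentile(sk.compute_fft_spectrum(short))
        pb = sk.band_percentile(sk.compute_fft_spectrum(scaled))
        assert pb == pytest.approx(k * pa, rel=1e-9)

    def test_window_guards(self):
        rec = sk.AERecording(np.ones(100), rate=RATE)
        with pytest.raises(sk.ParameterError):
            sk.compute_rms_profile(rec, 0)
        with pytest.raises(sk.ParameterError):
            sk.compute_rms_profile(rec, 1000)


class TestRMSStrokes:
    def test_self_mode_recovers_planted_strokes(self, knit_ae, small_plan):
        prof = sk.compute_rms_profile(knit_ae, int(small_plan.ae_rate * 0.01))
        strokes = sk.segment_rms_strokes(prof, mode="self")
        assert len(strokes) == small_plan.n_strokes

    def test_transfer_mode_matches_force_stroke_count(
            self, knit_trial, knit_ae, small_plan):
        rec, _ = knit_trial
        force_strokes = sk.segment_strokes(rec)
        prof = sk.compute_rms_profile(knit_ae, int(small_plan.ae_rate * 0.01))
        strokes = sk.segment_rms_strokes(prof, mode="transfer",
                                         strokes=force_strokes,
                                         force_rate=small_plan.force_rate)
        assert len(strokes) == len(force_strokes)
        assert [s.direction for s in strokes] == \
               [s.direction for s in force_strokes]

    def test_constant_envelope_not_segmentable(self):
        prof = sk.compute_rms_profile(
            sk.AERecording(np.ones(400_000), rate=4e5), 4000)
        with pytest.raises(sk.NotSegmentableError):
            sk.segment_rms_strokes(prof, mode="self")

    def test_planar_profile_not_segmentable(self, small_plan):
        truth = sk.generate_stroke_schedule(small_plan)
        ae = sk.synthesize_ae_recording(sk.preset("pet_film"), small_plan, truth)
        prof = sk.compute_rms_profile(ae, int(small_plan.ae_rate * 0.01))
        with pytest.raises(sk.NotSegmentableError):
            sk.segment_rms_strokes(prof, mode="self")

    def test_stroke_rms_statistics(self):
        values = np.array([0.1, 0.2, 2.0, 4.0, 3.0, 0.1])
        prof = sk.RMSProfile(values=values, time=np.arange(6) * 0.01,
                             window_samples=100, rate=10_000)
        stroke = sk.Stroke(0, 6, 1, static_span=(0, 3), dynamic_span=(2, 5))
        feat = sk.extract_stroke_rms(stroke, prof)
        assert feat.dynamic_cof == 3.0  # median of [2, 4, 3]

    def test_amplitude_scaling_doubles_stroke_stats(self, knit_ae, small_plan):
        win = int(small_plan.ae_rate * 0.01)
        doubled = sk.AERecording(2.0 * knit_ae.samples, rate=knit_ae.rate)
        fa = sk.acoustic.analyze_ae_recording(knit_ae, win, mode="self")
        fb = sk.acoustic.analyze_ae_recording(doubled, win, mode="self")
        assert np.allclose(fb.static_rms, 2 * fa.static_rms, rtol=1e-9)
        assert np.allclose(fb.dynamic_rms, 2 * fa.dynamic_rms, rtol=1e-9)
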