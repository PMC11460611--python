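"""Treatment-sound synthesis: filters, spectral shaping, mixing, WAV output."""

import math

import numpy as np
import pytest

from tinniflow.audiogram import (
    Audiogram,
    EdgeSmoothing,
    FrequencyBand,
    edge_smoothings,
    hearing_loss_band,
)
from tinniflow.synthesis import (
    NoiseSpec,
    SoundComplex,
    band_power,
    bandpass,
    generate_white_noise,
    mix_v3,
    shape_to_audiogram,
    spectrum_report,
    synthesize_treatment_sound,
    tinnitus_band,
    welch_psd,
    write_wav,
    audiogram_envelope_db,
)

SPEC = NoiseSpec(fs_hz=44100, duration_s=2.0, seed=1)


def tone(freq_hz: float, spec: NoiseSpec = SPEC) -> SoundComplex:
    t = np.arange(spec.n_samples) / spec.fs_hz
    return SoundComplex(np.sin(2 * np.pi * freq_hz * t), spec.fs_hz)


class TestWhiteNoise:
    def test_length_and_determinism(self):
        a = generate_white_noise(NoiseSpec(44100, 1.0, seed=1))
        b = generate_white_noise(NoiseSpec(44100, 1.0, seed=1))
        assert a.n_samples == 44100
        assert np.array_equal(a.samples, b.samples)

    def test_different_seed_different_noise(self):
        a = generate_white_noise(NoiseSpec(44100, 1.0, seed=1))
        b = generate_white_noise(NoiseSpec(44100, 1.0, seed=2))
        assert not np.array_equal(a.samples, b.samples)

    def test_gaussian_moments(self):
        x = generate_white_noise(NoiseSpec(44100, 10.0, seed=3)).samples
        n = x.size
        assert abs(x.mean()) < 4.0 / math.sqrt(n)
        assert x.var() == pytest.approx(1.0, rel=0.02)

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(44100, 0.0, seed=1)


class TestBandpass:
    def test_in_band_tone_passes_at_unity(self):
        band = FrequencyBand(5400, 6600)
        out = bandpass(tone(6000), band)
        assert out.rms() == pytest.approx(tone(6000).rms(), rel=1e-6)

    def test_out_of_band_tone_heavily_attenuated(self):
        band = FrequencyBand(5400, 6600)
        x = tone(1000)
        out = bandpass(x, band)
        atten_db = 20 * math.log10(max(out.rms(), 1e-300) / x.rms())
        assert atten_db <= -40

    def test_noise_psd_support_matches_band(self):
        band = FrequencyBand(1000, 8000)
        out = bandpass(generate_white_noise(SPEC), band)
        freqs, psd = welch_psd(out)
        inside = band_power(freqs, psd, band)
        outside = np.mean(psd[(freqs > 50) & (freqs < 1000 / 2**0.5)])
        assert 10 * math.log10(inside / outside) >= 40

    def test_band_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(tone(1000), FrequencyBand(22050, 23000))

    def test_passband_idempotent_within_half_db(self):
        band = FrequencyBand(1000, 8000)
        once = bandpass(generate_white_noise(SPEC), band)
        twice = bandpass(once, band)
        ratio_db = 20 * math.log10(twice.rms() / once.rms())
        assert abs(ratio_db) < 0.5

    def test_sharper_smoothing_narrower_transition(self):
        band = FrequencyBand(1000, 8000)
        x = tone(950)  # inside the gentle skirt, outside the sharp one
        gentle = bandpass(x, band, EdgeSmoothing(1000, 100), EdgeSmoothing(8000, 100))
        sharp = bandpass(x, band, EdgeSmoothing(1000, 1), EdgeSmoothing(8000, 1))
        assert gentle.rms() > 10 * sharp.rms()


class TestParseval:
    def test_psd_power_matches_waveform_variance(self):
        x = bandpass(generate_white_noise(SPEC), FrequencyBand(1000, 8000))
        freqs, psd = welch_psd(x)
        total = np.trapezoid(psd, freqs)
        assert total == pytest.approx(x.samples.var(), rel=0.01)


class TestAudiogramShaping:
    def test_flat_loss_gives_flat_in_band_spectrum(self):
        aud = Audiogram((500, 1000, 2000, 4000, 8000), (20, 40, 40, 40, 40))
        band = hearing_loss_band(aud)
        v1 = shape_to_audiogram(
            bandpass(generate_white_noise(SPEC), band), aud, band
        )
        freqs, psd = welch_psd(v1)
        low = band_power(freqs, psd, FrequencyBand(1500, 2500))
        high = band_power(freqs, psd, FrequencyBand(5000, 7000))
        assert abs(10 * math.log10(high / low)) < 1.0

    def test_rising_loss_tilts_spectrum_by_threshold_difference(self):
        # 30 dB at 1 kHz rising to 50 dB at 8 kHz: ~20 dB PSD difference
        aud = Audiogram((500, 1000, 2000, 4000, 8000), (20, 30, 37, 43, 50))
        band = hearing_loss_band(aud)
        v1 = shape_to_audiogram(
            bandpass(generate_white_noise(SPEC), band), aud, band
        )
        freqs, psd = welch_psd(v1)
        near_low = band_power(freqs, psd, FrequencyBand(1000, 1100))
        near_high = band_power(freqs, psd, FrequencyBand(7500, 8000))
        assert 10 * math.log10(near_high / near_low) == pytest.approx(20.0, abs=2.0)

    def test_envelope_passes_through_audiogram_knots(self):
        aud = Audiogram((1000, 2000, 4000, 8000), (30, 37, 43, 50))
        freqs = np.array(aud.frequencies_hz, dtype=float)
        env = audiogram_envelope_db(freqs, aud, criterion_db=25)
        assert np.allclose(env, np.array(aud.thresholds_db_hl) - 25.0)


class TestTinnitusBand:
    @pytest.mark.parametrize("pitch,lo,hi", [(6000, 5400, 6600), (1000, 900, 1100)])
    def test_band_is_ten_percent_each_side(self, pitch, lo, hi):
        v2 = tinnitus_band(pitch, SPEC)
        assert v2.band.f_low_hz == pytest.approx(lo)
        assert v2.band.f_high_hz == pytest.approx(hi)
        assert v2.provenance == "v2"

    def test_psd_peak_inside_band(self):
        v2 = tinnitus_band(6000, SPEC)
        freqs, psd = welch_psd(v2)
        peak = freqs[np.argmax(psd)]
        assert 5400 <= peak <= 6600

    def test_pitch_too_high_for_fs_rejected(self):
        with pytest.raises(ValueError):
            tinnitus_band(21000, SPEC)


class TestMixV3:
    def _v1(self, seed=5):
        aud = Audiogram((500, 1000, 2000, 4000, 8000), (20, 30, 37, 43, 50))
        band = hearing_loss_band(aud)
        sm = edge_smoothings(aud, band)
        noise = generate_white_noise(NoiseSpec(44100, 2.0, seed))
        return shape_to_audiogram(bandpass(noise, band, sm[0], sm[-1]), aud, band)

    def test_silent_v2_returns_scaled_v1(self):
        v1 = self._v1()
        v2 = SoundComplex(
            np.zeros(v1.n_samples), v1.fs_hz, "v2", FrequencyBand(5400, 6600)
        )
        v3 = mix_v3(v1, v2)
        # proportional to v1 (peak-normalized)
        scale = np.max(np.abs(v1.samples)) / 10 ** (-1 / 20)
        assert np.allclose(v3.samples * scale, v1.samples)

    def test_band_boost_is_six_db(self):
        v1 = self._v1()
        v2 = tinnitus_band(6000, NoiseSpec(44100, 2.0, 6))
        v3 = mix_v3(v1, v2, boost_db=6.0, reference="band")
        tb = v2.band
        ref = FrequencyBand(1200, 2000)  # untouched in-band reference region
        f1, p1 = welch_psd(v1)
        f3, p3 = welch_psd(v3)
        boost = 10 * math.log10(
            (band_power(f3, p3, tb) / band_power(f3, p3, ref))
            / (band_power(f1, p1, tb) / band_power(f1, p1, ref))
        )
        assert boost == pytest.approx(6.0, abs=1.0)

    def test_peak_normalized_to_minus_one_dbfs(self):
        v1 = self._v1()
        v2 = tinnitus_band(6000, NoiseSpec(44100, 2.0, 6))
        v3 = mix_v3(v1, v2)
        assert np.max(np.abs(v3.samples)) == pytest.approx(10 ** (-1 / 20))

    def test_length_mismatch_rejected(self):
        v1 = self._v1()
        v2 = SoundComplex(np.zeros(100), 44100, "v2", FrequencyBand(5400, 6600))
        with pytest.raises(ValueError):
            mix_v3(v1, v2)


class TestFullSynthesis:
    def test_spectrum_matches_loss_band_with_pitch_boost(
        self, sloping_loss_audiogram
    ):
        v3, report = synthesize_treatment_sound(sloping_loss_audiogram, 6000, SPEC)
        assert v3.provenance == "v3"
        assert report.passband.f_low_hz == 1000
        assert report.passband.f_high_hz == 8000
        assert 5400 <= report.peak_hz <= 6600
        assert report.band_attenuation_db >= 40

    def test_global_psd_maximum_in_tinnitus_band(self, sloping_loss_audiogram):
        v3, _ = synthesize_treatment_sound(sloping_loss_audiogram, 4000, SPEC)
        freqs, psd = welch_psd(v3)
        peak = freqs[np.argmax(psd)]
        assert 0.9 * 4000 <= peak <= 1.1 * 4000

    def test_excluded_audiogram_rejected(self):
        aud = Audiogram((500, 1000, 2000), (30, 95, 40))
        with pytest.raises(ValueError):
            synthesize_treatment_sound(aud, 2000, SPEC)

    def test_same_seed_bit_identical_wav(self, tmp_path, sloping_loss_audiogram):
        p1, p2 = tmp_path / "a.wav", tmp_path / "b.wav"
        for p in (p1, p2):
            v3, _ = synthesize_treatment_sound(sloping_loss_audiogram, 6000, SPEC)
            write_wav(p, v3)
        assert p1.read_bytes() == p2.read_bytes()
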