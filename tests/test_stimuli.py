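"""Stimulus synthesis: calibration, spectral content, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.io import wavfile

from sparsepitch import stimuli as stim


def spectrum(wave):
    x = wave.samples
    f = np.fft.rfftfreq(len(x), 1 / wave.rate)
    return f, np.abs(np.fft.rfft(x))


class TestCalibration:
    @pytest.mark.parametrize(
        "level_db, expected",
        [(0.0, 2.0e-5), (30.0, 6.3246e-4), (90.0, 0.6325)],
    )
    def test_db_spl_to_pascal(self, level_db, expected):
        assert stim.db_spl_to_pascal(level_db) == pytest.approx(expected, rel=1e-4)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            stim.db_spl_to_pascal(float("nan"))

    def test_tone_rms_matches_calibration(self):
        # integer number of cycles so the discrete RMS is exact
        wave = stim.make_tone(1000.0, 30.0, duration=0.1)
        rms = np.sqrt(np.mean(wave.samples**2))
        expected = stim.db_spl_to_pascal(30.0) / np.sqrt(2.0)
        assert rms == pytest.approx(expected, rel=1e-9)


class TestHarmonicComplex:
    def test_component_frequencies_with_shift(self):
        spec = stim.ComplexToneSpec(f0=200, harmonic_indices=(4, 5, 6, 7),
                                    shift=200.0, level_db=45)
        assert list(spec.component_freqs) == [1000, 1200, 1400, 1600]
        wave = stim.make_harmonic_complex(spec, duration=0.1)
        f, mag = spectrum(wave)
        peaks = f[mag > 0.5 * mag.max()]
        assert sorted(np.round(peaks)) == [1000, 1200, 1400, 1600]

    def test_single_tone_amplitude(self):
        wave = stim.make_tone(240.0, 30.0, duration=0.05)
        assert wave.samples.max() == pytest.approx(6.3246e-4, rel=1e-4)

    def test_empty_indices_gives_silence(self):
        spec = stim.ComplexToneSpec(f0=240, harmonic_indices=(), level_db=30)
        wave = stim.make_harmonic_complex(spec, duration=0.01)
        assert np.all(wave.samples == 0)

    def test_nyquist_rejected(self):
        spec = stim.ComplexToneSpec(f0=30000, harmonic_indices=(2,), level_db=30)
        with pytest.raises(ValueError):
            stim.make_harmonic_complex(spec, duration=0.01)

    @given(f0=st.sampled_from([125.0, 200.0, 250.0, 500.0]))
    @settings(max_examples=4, deadline=None, derandomize=True)
    def test_unshifted_complex_is_periodic(self, f0):
        # f0 divides the sample rate, so one period is a whole sample count
        spec = stim.ComplexToneSpec(f0=f0, harmonic_indices=(1, 2, 3), level_db=40)
        wave = stim.make_harmonic_complex(spec, duration=3.0 / f0)
        period = int(round(wave.rate / f0))
        x = wave.samples
        dev = np.max(np.abs(x[:period] - x[period:2 * period]))
        assert dev < 1e-12 * np.max(np.abs(x))


class TestTransposedTone:
    def test_energy_at_carriers_not_modulator(self):
        spec = stim.TransposedToneSpec(f0=250.0, level_db=30)
        wave = stim.make_transposed_tone(spec, duration=0.1)
        f, mag = spectrum(wave)

        def power_near(freq, width=30.0):
            sel = (f > freq - width) & (f < freq + width)
            return mag[sel].max()

        carrier_peak = max(power_near(fc) for fc in spec.carriers)
        assert power_near(250.0) < 0.01 * carrier_peak
        for fc in (4000.0, 6350.0, 10080.0):
            assert power_near(fc) > 0.3 * carrier_peak
            # rectified-modulator sidebands at fc +- f0
            assert power_near(fc + 250.0, 20.0) > 0.02 * carrier_peak

    def test_carrier_above_nyquist_rejected(self):
        spec = stim.TransposedToneSpec(f0=250.0, carriers=(60000.0,))
        with pytest.raises(ValueError):
            stim.make_transposed_tone(spec, duration=0.01)


class TestIRN:
    def test_delay_add_comb_maxima(self):
        spec = stim.IRNSpec(delay=0.005, gain=1, n_iterations=1, seed=3,
                            lowpass_hz=4000)
        wave = stim.make_irn(spec, duration=0.5)
        f, mag = spectrum(wave)
        p = mag**2

        def band_power(freq, width=10.0):
            sel = (f > freq - width) & (f < freq + width)
            return p[sel].mean()

        # comb maxima at multiples of 1/d = 200 Hz, minima in between
        assert band_power(200) > 3 * band_power(300)
        assert band_power(400) > 3 * band_power(500)

    def test_delay_subtract_shifts_comb(self):
        spec = stim.IRNSpec(delay=0.005, gain=-1, n_iterations=1, seed=3)
        wave = stim.make_irn(spec, duration=0.5)
        f, mag = spectrum(wave)
        p = mag**2
        hi = p[(f > 90) & (f < 110)].mean()  # (k+1/2)/d = 100 Hz
        lo = p[(f > 190) & (f < 210)].mean()  # k/d notched out
        assert hi > 3 * lo

    def test_seed_determinism(self):
        spec = stim.IRNSpec(delay=0.004, gain=1, n_iterations=10, seed=42)
        a = stim.make_irn(spec, duration=0.05)
        b = stim.make_irn(spec, duration=0.05)
        assert np.array_equal(a.samples, b.samples)

    def test_level_calibration(self):
        spec = stim.IRNSpec(delay=0.005, gain=1, n_iterations=2, seed=0,
                            level_db=70)
        wave = stim.make_irn(spec, duration=0.1)
        rms = np.sqrt(np.mean(wave.samples**2))
        assert rms == pytest.approx(stim.db_spl_to_pascal(70) / np.sqrt(2), rel=1e-9)


class TestLoadAudio:
    def test_wav_pure_tone_round_trip(self, tmp_path):
        rate = 44100
        t = np.arange(rate // 2) / rate
        x = (0.4 * np.sin(2 * np.pi * 880 * t) * 32767).astype(np.int16)
        p = tmp_path / "tone.wav"
        wavfile.write(p, rate, x)
        wave = stim.load_audio(p, level_db=60)
        f, mag = spectrum(wave)
        assert f[np.argmax(mag)] == pytest.approx(880, abs=5)
        assert wave.rate == 100_000

    def test_stereo_becomes_mono_average(self, tmp_path):
        rate = 8000
        left = np.full(800, 0.5, dtype=np.float32)
        right = np.full(800, -0.5, dtype=np.float32)
        p = tmp_path / "stereo.wav"
        wavfile.write(p, rate, np.column_stack([left, right]))
        wave = stim.load_audio(p, rate=8000)
        assert np.max(np.abs(wave.samples)) < 1e-6

    def test_aiff_read(self, tmp_path):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DeprecationWarning)
            import aifc
        rate = 8000
        t = np.arange(rate) / rate
        x = (0.4 * np.sin(2 * np.pi * 440 * t) * 32767).astype(">i2")
        p = tmp_path / "tone.aiff"
        with aifc.open(str(p), "wb") as f:
            f.setnchannels(1)
            f.setsampwidth(2)
            f.setframerate(rate)
            f.writeframes(x.tobytes())
        wave = stim.load_audio(p, rate=8000)
        f_, mag = spectrum(wave)
        assert f_[np.argmax(mag)] == pytest.approx(440, abs=3)

    def test_corrupted_file_raises(self, tmp_path):
        p = tmp_path / "bad.wav"
        p.write_bytes(b"RIFFgarbage-not-audio")
        with pytest.raises((ValueError, FileNotFoundError)):
            stim.load_audio(p)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            stim.load_audio(tmp_path / "nope.wav")
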