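"""Stage-level checks of the cardiac and respiratory chains."""

import numpy as np
import pytest
from scipy import signal as sps

import imuvitals as iv
from imuvitals.preprocess import Signal1D

FS = 120.0


def tone(freq, duration=10.0, fs=FS, amp=1.0):
    t = np.arange(0.0, duration, 1.0 / fs)
    return Signal1D(amp * np.cos(2 * np.pi * freq * t), fs)


def rms(x):
    return np.sqrt(np.mean(np.asarray(x, dtype=float) ** 2))


class TestSelectAxis:
    def test_defaults(self, small_recording, config):
        _, rec, _, _ = small_recording
        np.testing.assert_array_equal(iv.select_axis(rec, "acc", config).values,
                                      rec.channel("acc", "z"))
        np.testing.assert_array_equal(iv.select_axis(rec, "gyr", config).values,
                                      rec.channel("gyr", "y"))

    def test_passthrough(self, config):
        n = 1200
        rec = iv.InertialRecording(times=np.arange(n) / FS,
                                   acc=np.full((n, 3), 3.0),
                                   gyr=np.zeros((n, 3)), fs=FS)
        out = iv.select_axis(rec, "acc", config)
        np.testing.assert_array_equal(out.values, 3.0)

    def test_unknown_sensor(self, small_recording, config):
        _, rec, _, _ = small_recording
        with pytest.raises(KeyError):
            iv.select_axis(rec, "magnetometer", config)


class TestCwtBandReconstruct:
    def test_in_band_tone_preserved(self):
        sig = tone(20.0)
        out = iv.cwt_band_reconstruct(sig, (10.0, 40.0))
        assert rms(out.values) / rms(sig.values) >= 0.9
        assert len(out) == len(sig) and out.fs == sig.fs

    def test_out_of_band_tone_suppressed(self):
        sig = tone(0.25)
        out = iv.cwt_band_reconstruct(sig, (10.0, 40.0))
        assert rms(out.values) / rms(sig.values) <= 0.1

    def test_mixture_matches_brickwall_oracle(self):
        """The reconstruction of a 20 Hz + 0.25 Hz mixture tracks an ideal
        FFT brick-wall band-pass of the same mixture."""
        t = np.arange(0.0, 10.0, 1.0 / FS)
        comp = np.cos(2 * np.pi * 20.0 * t)
        mix = comp + np.cos(2 * np.pi * 0.25 * t)
        out = iv.cwt_band_reconstruct(Signal1D(mix, FS), (10.0, 40.0))
        spec = np.fft.rfft(mix)
        f = np.fft.rfftfreq(mix.size, 1.0 / FS)
        spec[(f < 10.0) | (f > 40.0)] = 0.0
        brick = np.fft.irfft(spec, mix.size)
        assert np.corrcoef(out.values, comp)[0, 1] >= 0.95
        assert np.corrcoef(out.values, brick)[0, 1] >= 0.95

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            iv.cwt_band_reconstruct(tone(20.0), (10.0, 70.0))

    def test_sharper_than_first_order_butterworth(self):
        """Out-of-band suppression exceeds the order-1 band-pass alternative."""
        sig = tone(5.0)
        cwt_ratio = rms(iv.cwt_band_reconstruct(sig, (10.0, 40.0)).values) / rms(sig.values)
        bw_ratio = rms(iv.butter_bandpass(sig, (10.0, 40.0), 1).values) / rms(sig.values)
        assert cwt_ratio < bw_ratio


class TestNormalize:
    def test_divides_by_max_abs(self):
        out = iv.normalize(Signal1D(np.array([0.0, 2.0, -4.0]), FS))
        np.testing.assert_allclose(out.values, [0.0, 0.5, -1.0])

    def test_idempotent(self):
        sig = Signal1D(np.array([0.2, -1.0, 0.7]), FS)
        once = iv.normalize(sig)
        twice = iv.normalize(once)
        np.testing.assert_allclose(twice.values, once.values)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            iv.normalize(Signal1D(np.zeros(8), FS))


class TestRmsEnvelope:
    def test_constant_signal(self):
        out = iv.rms_envelope(Signal1D(np.full(100, -3.0), FS), 40)
        np.testing.assert_allclose(out.values, 3.0)

    def test_sine_interior_is_amplitude_over_sqrt2(self):
        amp = 2.5
        sig = tone(6.0, duration=10.0, amp=amp)  # window = 2 full periods
        out = iv.rms_envelope(sig, 40)
        interior = out.values[40:-40]
        np.testing.assert_allclose(interior, amp / np.sqrt(2), rtol=0.01)

    def test_small_array_definition(self):
        out = iv.rms_envelope(Signal1D(np.array([1.0, 2, 3, 4, 5]), FS), 3)
        assert out.values[2] == pytest.approx(np.sqrt((4 + 9 + 16) / 3))

    def test_nonnegative_and_length_preserving(self):
        rng = np.random.default_rng(0)
        sig = Signal1D(rng.standard_normal(500), FS)
        out = iv.rms_envelope(sig, 40)
        assert len(out) == 500 and np.all(out.values >= 0)

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            iv.rms_envelope(tone(5.0), 0)


class TestButterBandpass:
    def test_dc_killed(self):
        sig = Signal1D(np.full(int(30 * FS), 5.0), FS)
        out = iv.butter_bandpass(sig, (0.7, 3.0), 1)
        core = out.values[int(5 * FS):-int(5 * FS)]
        assert rms(core) <= 1e-3 * 5.0

    def test_passband_centre_preserved(self):
        fc = np.sqrt(0.7 * 3.0)
        sig = tone(fc, duration=60.0)
        out = iv.butter_bandpass(sig, (0.7, 3.0), 1)
        core = slice(int(5 * FS), -int(5 * FS))
        assert rms(out.values[core]) / rms(sig.values[core]) >= 0.9

    @pytest.mark.parametrize("band", [(0.7, 3.0), (0.1, 0.7)])
    def test_analog_prototype_minus_3db_at_cutoffs(self, band):
        """Single-pass Butterworth magnitude is 1/sqrt(2) at both cutoffs."""
        b, a = sps.butter(1, [2 * np.pi * band[0], 2 * np.pi * band[1]],
                          btype="bandpass", analog=True)
        _, h = sps.freqs(b, a, worN=2 * np.pi * np.array(band))
        np.testing.assert_allclose(np.abs(h), 1 / np.sqrt(2), rtol=1e-9)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            iv.butter_bandpass(tone(1.0), (3.0, 0.7), 1)


class TestReferencePreprocess:
    def test_ecg_dominant_frequency(self, config):
        proto = iv.SubjectProtocol(
            segments=[("sitting", 60.0)],
            hr_trajectory=iv.PiecewiseLinear.constant(72.0),
            rr_trajectory=iv.PiecewiseLinear.constant(15.0),
            noise_sd_per_posture={"sitting": 0.0}, seed=5)
        ref = iv.synthesize_reference(proto)
        out = iv.reference_preprocess(ref, "cardiac", config)
        f, p = sps.periodogram(out.values, fs=out.fs, detrend="constant")
        assert f[np.argmax(p)] == pytest.approx(1.2, abs=0.02)

    def test_respiration_dominant_frequency(self, config):
        proto = iv.SubjectProtocol(
            segments=[("sitting", 60.0)],
            hr_trajectory=iv.PiecewiseLinear.constant(72.0),
            rr_trajectory=iv.PiecewiseLinear.constant(15.0),
            noise_sd_per_posture={"sitting": 0.0}, seed=5)
        out = iv.reference_preprocess(iv.synthesize_reference(proto), "respiratory", config)
        f, p = sps.periodogram(out.values, fs=out.fs, detrend="constant")
        assert f[np.argmax(p)] == pytest.approx(0.25, abs=0.01)

    def test_flat_respiration_stays_flat(self, config):
        ref = iv.ReferenceRecording(ecg=np.zeros(2500), fs_ecg=250.0,
                                    resp=np.zeros(250), fs_resp=25.0)
        out = iv.reference_preprocess(ref, "respiratory", config)
        assert rms(out.values) <= 1e-12

    def test_unknown_target(self, config):
        ref = iv.ReferenceRecording(ecg=np.zeros(10), fs_ecg=250.0,
                                    resp=np.zeros(10), fs_resp=25.0)
        with pytest.raises(ValueError):
            iv.reference_preprocess(ref, "cardio", config)


class TestChains:
    def test_length_preserved_and_finite(self, small_recording, config):
        _, rec, _, _ = small_recording
        for sensor in ("acc", "gyr"):
            card = iv.cardiac_preprocess(rec, config, sensor)
            resp = iv.respiratory_preprocess(rec, config, sensor)
            assert len(card) == len(resp) == rec.times.size
            assert np.all(np.isfinite(card.values)) and np.all(np.isfinite(resp.values))

    def test_band_power_concentration(self, constant_subject, config):
        """Cardiac chain output lives in 0.7-3 Hz, respiratory in 0.1-0.7 Hz
        (edges excluded)."""

        def band_power_fraction(x, fs, band):
            f, p = sps.periodogram(x, fs=fs, detrend="constant")
            return p[(f >= band[0]) & (f <= band[1])].sum() / p.sum()

        _, rec, _, _ = constant_subject
        edge = int(5 * rec.fs)
        card = iv.cardiac_preprocess(rec, config, "acc").values[edge:-edge]
        resp = iv.respiratory_preprocess(rec, config, "acc").values[edge:-edge]
        assert band_power_fraction(card, rec.fs, (0.7, 3.0)) >= 0.90
        assert band_power_fraction(resp, rec.fs, (0.1, 0.7)) >= 0.90

    @pytest.mark.parametrize("gain", [0.1, 7.0])
    def test_scale_equivariance_of_rates(self, small_recording, config, gain):
        """Scaling the raw channels leaves the estimated rates unchanged."""
        _, rec, _, _ = small_recording
        scaled = iv.InertialRecording(times=rec.times, acc=gain * rec.acc,
                                      gyr=gain * rec.gyr, fs=rec.fs)
        for chain, band in ((iv.cardiac_preprocess, config.cardiac_band),
                            (iv.respiratory_preprocess, config.resp_band)):
            r1 = iv.extract_rate_series(chain(rec, config, "acc"), band, 5.0, config)
            r2 = iv.extract_rate_series(chain(scaled, config, "acc"), band, 5.0, config)
            np.testing.assert_allclose(r1.rates, r2.rates, rtol=1e-9)
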