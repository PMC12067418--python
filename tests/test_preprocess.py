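import numpy as np
import pytest
from scipy import signal

from ieegflow.preprocess import (bandpass_notch, resample_to, segment_epoch,
                                 validate_recording, zscore_channels)
from ieegflow.recording import Recording, ValidationError

from conftest import make_recording


def sine_recording(freq, fs=500.0, duration_s=64.0, n_channels=2):
    t = np.arange(int(duration_s * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1))
    return Recording(data, fs, [f"c{i}" for i in range(n_channels)],
                     int(duration_s * fs // 2),
                     np.array([True] + [False] * (n_channels - 1)))


def band_power(x, fs, freq, half_width=1.0):
    f, p = signal.periodogram(x, fs)
    return p[(f >= freq - half_width) & (f <= freq + half_width)].sum()


class TestValidation:
    @pytest.mark.parametrize("fs,preictal_s,accepted,reason_part", [
        (250.0, 60.0, False, "sampling rate below 500"),
        (1000.0, 60.0, True, ""),
        (500.0, 29.0, False, "<30 s of preictal activity"),
        (500.0, 30.0, True, ""),
    ])
    def test_inclusion_rules(self, fs, preictal_s, accepted, reason_part):
        rec = make_recording(fs=fs, duration_s=preictal_s + 30,
                             onset_s=preictal_s)
        out = validate_recording(rec)
        assert bool(out) is accepted
        assert reason_part in out.reason

    def test_order_independent_over_cohort(self):
        recs = [make_recording(fs=fs, duration_s=70, onset_s=40, seed=i)
                for i, fs in enumerate([250, 500, 1000])]
        fwd = [validate_recording(r).accepted for r in recs]
        bwd = [validate_recording(r).accepted for r in reversed(recs)]
        assert fwd == bwd[::-1]


class TestBandpassNotch:
    def test_out_of_band_tone_attenuated_40db(self):
        rec = sine_recording(100.0)
        out = bandpass_notch(rec)
        before = band_power(rec.data[0], rec.fs, 100.0)
        after = band_power(out.data[0], rec.fs, 100.0)
        assert 10 * np.log10(before / after) >= 40

    def test_in_band_tone_preserved(self):
        rec = sine_recording(10.0)
        out = bandpass_notch(rec)
        ratio = band_power(out.data[0], rec.fs, 10.0) \
            / band_power(rec.data[0], rec.fs, 10.0)
        assert abs(np.sqrt(ratio) - 1) < 0.05  # amplitude within 5%

    def test_notch_removes_line_frequency(self):
        rec = sine_recording(60.0)
        out = bandpass_notch(rec, low=3, high=100, notch=60)
        assert band_power(out.data[0], rec.fs, 60.0) \
            < 0.01 * band_power(rec.data[0], rec.fs, 60.0)

    def test_zero_input_zero_output(self):
        rec = make_recording()
        rec = rec.with_data(np.zeros_like(rec.data))
        out = bandpass_notch(rec)
        np.testing.assert_allclose(out.data, 0.0)

    def test_band_above_nyquist_rejected(self):
        rec = make_recording(fs=500)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_notch(rec, high=300)


class TestResample:
    def test_integer_decimation_counts(self):
        rec = make_recording(fs=1000.0, duration_s=56.0, onset_s=40.0)
        out = resample_to(rec, 500.0)
        assert out.fs == 500.0
        assert out.n_samples == 28000
        assert out.onset_sample == 20000

    def test_identity_when_already_at_target(self):
        rec = make_recording(fs=500.0)
        out = resample_to(rec, 500.0)
        assert out is rec

    def test_tone_survives_decimation(self):
        rec = sine_recording(20.0, fs=2000.0)
        out = resample_to(rec, 500.0)
        f, p = signal.periodogram(out.data[0], out.fs)
        assert abs(f[np.argmax(p)] - 20.0) < 0.5

    def test_upsampling_refused(self):
        rec = make_recording(fs=500.0)
        with pytest.raises(ValueError, match="upsample"):
            resample_to(rec, 1000.0)


class TestZScore:
    def test_standardizes_each_channel(self):
        rec = make_recording(seed=3)
        rec = rec.with_data(rec.data * 7.0 + 4.0)
        out = zscore_channels(rec)
        np.testing.assert_allclose(out.data.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.data.std(axis=1), 1.0, atol=1e-9)

    def test_idempotent(self):
        rec = zscore_channels(make_recording(seed=4))
        again = zscore_channels(rec)
        np.testing.assert_allclose(again.data, rec.data, atol=1e-9)

    def test_constant_channel_named_in_error(self):
        rec = make_recording()
        data = rec.data.copy()
        data[2] = 5.0
        with pytest.raises(ValidationError, match="ch2"):
            zscore_channels(rec.with_data(data))


class TestSegmentation:
    def test_default_protocol_seven_4s_segments(self):
        rec = make_recording(fs=500.0, duration_s=64.0, onset_s=32.0)
        segs = segment_epoch(rec, "preictal")
        assert segs.n_segments == 7
        assert all(s.shape == (4, 2000) for s in segs.segments)

    def test_shorter_epoch(self):
        rec = make_recording(fs=500.0, duration_s=64.0, onset_s=32.0)
        assert segment_epoch(rec, "preictal", epoch_s=8).n_segments == 2

    def test_preictal_right_aligned_ictal_left_aligned(self):
        rec = make_recording(fs=500.0, duration_s=64.0, onset_s=32.0)
        pre = segment_epoch(rec, "preictal")
        ict = segment_epoch(rec, "ictal")
        on = rec.onset_sample
        np.testing.assert_array_equal(
            np.concatenate(pre.segments, axis=1),
            rec.data[:, on - 14000:on])
        np.testing.assert_array_equal(
            np.concatenate(ict.segments, axis=1),
            rec.data[:, on:on + 14000])

    def test_insufficient_preictal_rejected(self):
        rec = make_recording(fs=500.0, duration_s=64.0, onset_s=10.0)
        with pytest.raises(ValidationError, match="preictal"):
            segment_epoch(rec, "preictal")

    def test_nondivisible_epoch_rejected(self):
        rec = make_recording(fs=500.0, duration_s=64.0, onset_s=32.0)
        with pytest.raises(ValidationError, match="multiple"):
            segment_epoch(rec, "preictal", epoch_s=28, window_s=5)
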