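import numpy as np
import pytest

import beltsense as bs
from beltsense.signals import FREQ_SIGNALS, TIME_SIGNALS, _window_spectra


def _tri(x):
    """Replicate a 1-D series onto three axes."""
    return np.column_stack([x, x, x])


class TestImuRecording:
    def test_rejects_mismatched_lengths(self):
        with pytest.raises(ValueError, match="share one length"):
            bs.ImuRecording(100.0, np.zeros((5, 3)), np.zeros((6, 3)))

    def test_rejects_nonuniform_time(self):
        t = np.array([0.0, 0.01, 0.025, 0.03])
        with pytest.raises(ValueError, match="uniform"):
            bs.ImuRecording(100.0, np.zeros((4, 3)), np.zeros((4, 3)), time=t)

    def test_rejects_nonpositive_rate(self):
        with pytest.raises(ValueError, match="sample_rate"):
            bs.ImuRecording(0.0, np.zeros((4, 3)), np.zeros((4, 3)))


class TestDenoise:
    def test_constant_passes_unchanged(self):
        x = _tri(np.full(256, 0.5))
        out = bs.denoise(x, 100.0)
        assert out.shape == x.shape
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_median_stage_removes_isolated_spike(self):
        x = np.zeros(256)
        x[100] = 10.0
        out = bs.denoise(_tri(x), 100.0)
        assert abs(out[100, 0]) < 0.05  # spike suppressed, not just smeared

    def test_attenuates_above_cutoff(self):
        # 40 Hz tone is 2x the 20 Hz cutoff: third-order Butterworth gain
        # |H| = 1/sqrt(1+2^6) ~ 0.124, squared by filtfilt => RMS well under 0.2x
        t = np.arange(1024) / 100.0
        x = _tri(np.sin(2 * np.pi * 40 * t))
        out = bs.denoise(x, 100.0)
        core = slice(100, -100)
        assert np.std(out[core, 0]) < 0.2 * np.std(x[core, 0])

    def test_rejects_low_sample_rate_and_nonfinite(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bs.denoise(_tri(np.zeros(256)), 30.0)
        bad = _tri(np.zeros(256))
        bad[3, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            bs.denoise(bad, 100.0)


class TestSeparateGravity:
    def test_static_goes_to_gravity(self):
        acc = np.tile([0.0, 0.0, 1.0], (512, 1))
        gravity, body = bs.separate_gravity(acc, 100.0)
        np.testing.assert_allclose(gravity, acc, atol=1e-9)
        np.testing.assert_allclose(body, 0.0, atol=1e-9)

    def test_fast_oscillation_goes_to_body(self):
        t = np.arange(2048) / 100.0
        acc = np.zeros((2048, 3))
        acc[:, 0] = np.sin(2 * np.pi * 2.0 * t)
        gravity, body = bs.separate_gravity(acc, 100.0)
        core = slice(300, -300)
        assert np.std(gravity[core, 0]) < 0.02
        np.testing.assert_allclose(body[core, 0], acc[core, 0], atol=0.05)

    def test_sum_reconstructs_exactly(self, rng):
        acc = rng.normal(size=(400, 3))
        gravity, body = bs.separate_gravity(acc, 100.0)
        assert np.max(np.abs(gravity + body - acc)) < 1e-9

    def test_rejects_short_input(self):
        with pytest.raises(ValueError, match="at least"):
            bs.separate_gravity(np.zeros((5, 3)), 100.0)


class TestJerk:
    def test_constant_gives_zero(self):
        assert np.allclose(bs.jerk(_tri(np.full(64, 3.0)), 100.0), 0.0)

    def test_ramp_gives_slope(self):
        t = np.arange(200) / 100.0
        out = bs.jerk(_tri(t), 100.0)  # slope 1 g/s
        np.testing.assert_allclose(out[1:-1], 1.0, rtol=1e-9)

    def test_sinusoid_amplitude(self):
        f, A, fs = 3.0, 2.0, 100.0
        t = np.arange(1000) / fs
        out = bs.jerk(_tri(A * np.sin(2 * np.pi * f * t)), fs)
        # discrete derivative of a tone: amplitude A*2*pi*f*sinc correction
        interior = out[10:-10, 0]
        assert np.max(np.abs(interior)) == pytest.approx(A * 2 * np.pi * f, rel=0.02)

    def test_rejects_single_sample(self):
        with pytest.raises(ValueError):
            bs.jerk(np.zeros((1, 3)), 100.0)


class TestMagnitude:
    @pytest.mark.parametrize(
        "vec,expected",
        [((0, 0, 0), 0.0), ((3, 4, 0), 5.0), ((1, 1, 1), np.sqrt(3))],
    )
    def test_known_vectors(self, vec, expected):
        out = bs.magnitude(np.array([vec], float))
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_non_negative_and_matches_norm(self, rng):
        x = rng.normal(size=(100, 3))
        m = bs.magnitude(x)
        assert (m >= 0).all()
        np.testing.assert_allclose(m, np.sqrt((x**2).sum(axis=1)), rtol=1e-12)


class TestToFrequency:
    def test_zero_and_dc_windows(self):
        assert np.all(bs.to_frequency(np.zeros(128)) == 0)
        spec = bs.to_frequency(np.full(128, 2.0))
        assert spec[0] == pytest.approx(2.0)
        assert np.all(spec[1:] < 1e-12)

    def test_pure_tone_peaks_at_its_bin(self):
        k = 11
        t = np.arange(128)
        spec = bs.to_frequency(np.sin(2 * np.pi * k * t / 128))
        assert np.argmax(spec) == k
        assert spec[k] > 10 * np.max(np.delete(spec, k))

    def test_rejects_non_power_of_two(self):
        with pytest.raises(ValueError, match="power of two"):
            bs.to_frequency(np.zeros(100))


class TestDeriveSignals:
    def test_seventeen_channels_with_table_flags(self, walk_signals):
        assert len(walk_signals.channels) == 17
        assert sorted(walk_signals.time_names) == sorted(TIME_SIGNALS)
        assert sorted(walk_signals.freq_names) == sorted(
            "f_" + n for n in FREQ_SIGNALS
        )
        # gravity and the angular-acceleration XYZ have no frequency version
        for absent in ("f_gravity_acc", "f_gravity_acc_mag", "f_body_gyro_jerk"):
            if absent == "f_body_gyro_jerk":
                assert absent + "_mag" in walk_signals.channels
                continue
            assert absent not in walk_signals.channels

    def test_static_recording_magnitudes(self):
        n = 1024
        rec = bs.ImuRecording(
            100.0, np.tile([0.0, 0.0, 1.0], (n, 1)), np.zeros((n, 3))
        )
        sigs = bs.derive_signals(rec)
        core = slice(200, -200)
        assert np.max(sigs["body_acc_mag"].data[core]) < 1e-6
        np.testing.assert_allclose(sigs["gravity_acc_mag"].data[core], 1.0, atol=1e-6)
        assert np.max(sigs["body_gyro_jerk_mag"].data[core]) < 1e-6

    def test_deterministic(self):
        rec = bs.generate_activity("run", 4.0, seed=3)
        a = bs.derive_signals(rec)
        b = bs.derive_signals(rec)
        for name in a.channels:
            np.testing.assert_array_equal(a[name].data, b[name].data)

    def test_mag_channels_equal_magnitude_of_parents(self, walk_signals):
        for name in ("body_acc", "gravity_acc", "body_acc_jerk", "body_gyro",
                     "body_gyro_jerk"):
            np.testing.assert_array_equal(
                walk_signals[name + "_mag"].data,
                bs.magnitude(walk_signals[name].data),
            )

    def test_mag_channels_non_negative(self, walk_signals):
        for name, ch in walk_signals.channels.items():
            if name.endswith("_mag") or ch.domain == "freq":
                assert np.all(ch.data >= 0), name

    def test_freq_channels_match_to_frequency_per_window(self, walk_signals):
        start = int(walk_signals.window_starts[2])
        seg = walk_signals["body_acc"].data[start : start + 128]
        np.testing.assert_allclose(
            walk_signals["f_body_acc"].data[2], bs.to_frequency(seg), rtol=1e-12
        )

    def test_stage_errors_name_the_stage(self):
        rec = bs.ImuRecording(30.0, np.zeros((256, 3)), np.zeros((256, 3)))
        with pytest.raises(ValueError, match="denoise stage"):
            bs.derive_signals(rec)


def test_window_spectra_empty_grid():
    out = _window_spectra(np.zeros((64, 3)), np.empty(0, int), 128)
    assert out.shape == (0, 64, 3)
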