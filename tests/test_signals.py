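"""Extraction contracts: calibration, triggers, MVIC, filtering, Pt,
displacement parameters."""

import numpy as np
import pytest

from tmgkit.signals import (
    calibrate_torque,
    detect_triggers,
    displacement_params,
    extract_mvic,
    filter_twitch,
    twitch_peak_torque,
)
from tmgkit.synthetic import (
    ConfigurationError,
    TwitchRecording,
    TwitchShape,
    generate_twitch_waveform,
    shape_from_targets,
)


def _recording(torque=None, displacement=None, fs=1000.0, stim=100):
    n = len(torque) if torque is not None else len(displacement)
    return TwitchRecording(
        torque=torque if torque is not None else np.zeros(n),
        displacement=displacement if displacement is not None
        else np.zeros(n),
        trigger=np.zeros(n), sample_rate=fs, stim_index=stim)


class TestCalibration:
    def test_unit_factor_is_identity(self, rng):
        v = rng.normal(size=50)
        np.testing.assert_array_equal(calibrate_torque(v, 1.0), v)

    def test_constant_scaling(self):
        out = calibrate_torque(np.full(10, 2.0), 50.0)
        np.testing.assert_array_equal(out, np.full(10, 100.0))

    def test_matches_elementwise_product(self, rng):
        v = rng.normal(size=200)
        np.testing.assert_allclose(
            calibrate_torque(v, 3.7), np.array([x * 3.7 for x in v]))

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ConfigurationError):
            calibrate_torque(np.ones(5), 0.0)


class TestTriggers:
    def test_silent_trace_yields_nothing(self):
        assert detect_triggers(np.zeros(1000), 0.5) == []

    def test_single_pulse_located(self):
        trace = np.zeros(2000)
        trace[500] = 1.0  # 1 ms pulse at 1 kHz
        assert detect_triggers(trace, 0.5) == [500]

    def test_two_pulses_ten_seconds_apart(self):
        trace = np.zeros(25_000)
        trace[2000] = trace[12_000] = 1.0
        idx = detect_triggers(trace, 0.5)
        assert idx == [2000, 12_000]

    def test_plateau_counts_once(self):
        trace = np.zeros(100)
        trace[40:60] = 1.0
        assert detect_triggers(trace, 0.5) == [40]


class TestMvic:
    def test_constant_plateau(self):
        assert extract_mvic(np.full(1000, 100.0)) == 100.0

    def test_median_suppresses_single_sample_spike(self):
        trace = np.full(1500, 100.0)
        trace[700] = 500.0
        assert extract_mvic(trace) == 100.0

    def test_below_floor_flags_missing(self):
        assert np.isnan(extract_mvic(np.full(1000, 10.0)))

    def test_short_trace_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            extract_mvic(np.full(100, 100.0), window=501)

    def test_matches_exhaustive_window_oracle(self, rng):
        """Brute-force O(n*w) oracle: median of every full window whose
        center exceeds the floor."""
        for _ in range(20):
            n = int(rng.integers(200, 800))
            trace = np.abs(rng.normal(40, 30, n))
            w = 51
            best = -np.inf
            half = w // 2
            for c in range(half, n - half):
                if trace[c] > 20.0:
                    best = max(best, np.median(trace[c - half:c + half + 1]))
            expected = best if best > -np.inf else float("nan")
            got = extract_mvic(trace, window=w, floor=20.0)
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected)


class TestFilter:
    def test_dc_gain_is_unity(self):
        const = np.full(2000, 3.7)
        np.testing.assert_allclose(filter_twitch(const, 1000.0), const,
                                   atol=1e-9)

    def test_50hz_attenuation_bounded_by_single_pass_response(self):
        t = np.arange(5000) / 1000.0
        out = filter_twitch(np.sin(2 * np.pi * 50 * t), 1000.0)
        single_pass = 1.0 / np.sqrt(1.0 + (50.0 / 15.0) ** 8)
        assert np.abs(out[2000:3000]).max() <= single_pass

    def test_linearity(self, rng):
        a, b = rng.normal(size=1000), rng.normal(size=1000)
        lhs = filter_twitch(a + b, 1000.0)
        rhs = filter_twitch(a, 1000.0) + filter_twitch(b, 1000.0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            filter_twitch(np.zeros(100), 20.0, cutoff=15.0)


class TestPeakTorque:
    def test_flat_zero_torque(self):
        assert twitch_peak_torque(_recording(np.zeros(1000))) == 0.0

    def test_recovers_synthetic_amplitude_within_filter_attenuation(self):
        # cutoff well above the twitch bandwidth: the peak passes almost
        # untouched and Pt recovers the configured amplitude
        shape = TwitchShape(amplitude=20.0, tau_rise=25, tau_decay=75,
                            onset_delay=10)
        torque = np.zeros(1000)
        torque[100:] = generate_twitch_waveform(shape, 900, 1000.0)[:900]
        pt = twitch_peak_torque(_recording(torque), cutoff=60.0)
        assert pt == pytest.approx(20.0, rel=0.02)

    def test_constant_offset_invariance(self, rng):
        shape = TwitchShape(amplitude=12.0, tau_rise=25, tau_decay=75)
        torque = np.zeros(1000)
        torque[100:] = generate_twitch_waveform(shape, 900, 1000.0)[:900]
        pt0 = twitch_peak_torque(_recording(torque.copy()))
        pt5 = twitch_peak_torque(_recording(torque + 5.0))
        assert pt5 == pytest.approx(pt0, abs=1e-9)

    def test_window_exceeding_trace_rejected(self):
        with pytest.raises(ConfigurationError):
            twitch_peak_torque(_recording(np.zeros(300)),
                               analysis_window_ms=500.0)


class TestDisplacementParams:
    def test_linear_ramp_exact(self):
        # 0 -> 10 mm over 100 ms then plateau; stimulus at sample 0
        disp = np.concatenate([np.linspace(0, 10, 101),
                               np.full(300, 10.0)])
        dm, td, tc = displacement_params(_recording(displacement=disp,
                                                    stim=0))
        assert dm == pytest.approx(10.0)
        assert td == pytest.approx(10.0)
        assert tc == pytest.approx(80.0)

    def test_zero_displacement_flags(self):
        dm, td, tc = displacement_params(_recording(np.zeros(500),
                                                    np.zeros(500)))
        assert np.isnan(dm) and np.isnan(td) and np.isnan(tc)

    def test_matches_oversampled_oracle(self):
        """Extraction at 1 kHz agrees with a 10x-oversampled reference
        extraction of the same bi-exponential within 0.5 ms / 1%."""
        shape = shape_from_targets(amplitude=3.0, td_ms=20.0, tc_ms=22.0)
        for fs, stim in ((1000.0, 100), (10_000.0, 1000)):
            n = int(fs)
            disp = np.zeros(n)
            span = 1000.0 - 1000.0 * stim / fs
            disp[stim:] = generate_twitch_waveform(shape, span, fs)[:n - stim]
            vals = displacement_params(_recording(displacement=disp,
                                                  fs=fs, stim=stim))
            if fs == 10_000.0:
                ref = vals
            else:
                coarse = vals
        assert coarse[0] == pytest.approx(ref[0], rel=0.01)
        assert coarse[1] == pytest.approx(ref[1], abs=0.5)
        assert coarse[2] == pytest.approx(ref[2], abs=0.5)

    def test_time_shift_invariance(self):
        shape = shape_from_targets(amplitude=2.5, td_ms=18.0, tc_ms=20.0)
        wave = generate_twitch_waveform(shape, 800, 1000.0)

        def at_offset(stim):
            disp = np.zeros(1000)
            disp[stim:stim + len(wave)] = wave[:1000 - stim]
            return displacement_params(_recording(displacement=disp,
                                                  stim=stim))

        np.testing.assert_allclose(at_offset(100), at_offset(180),
                                   rtol=1e-9)

    def test_scaling_displacement_scales_dm_only(self):
        shape = shape_from_targets(amplitude=2.0, td_ms=18.0, tc_ms=20.0)
        disp = np.zeros(1000)
        disp[100:] = generate_twitch_waveform(shape, 900, 1000.0)[:900]
        dm1, td1, tc1 = displacement_params(_recording(displacement=disp))
        dm3, td3, tc3 = displacement_params(
            _recording(displacement=3.0 * disp))
        assert dm3 == pytest.approx(3.0 * dm1, rel=1e-9)
        assert td3 == pytest.approx(td1, abs=1e-9)
        assert tc3 == pytest.approx(tc1, abs=1e-9)
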