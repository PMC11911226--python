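"""Data model, I/O and signal primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ergocap import (
    ErgometerTrace,
    TraceLoadError,
    WheelGeometry,
    filter_trace,
    force_trace,
    power_trace,
    read_trace,
    rolling_mean,
    write_trace,
)
from ergocap.trace import max_rolling_mean, window_samples

from conftest import GEOMETRY, const_trace, make_trace


class TestGeometryAndProfile:
    def test_geometry_invariants(self):
        with pytest.raises(ValueError):
            WheelGeometry(wheel_radius=0.25, rim_radius=0.26)  # rim > wheel
        with pytest.raises(ValueError):
            WheelGeometry(wheel_radius=0.31, rim_radius=0.0)
        assert WheelGeometry(0.3, 0.3).rim_over_wheel == 1.0

    def test_trace_rejects_gaps_and_jitter(self):
        t = np.arange(100) / 100.0
        t[50] += 0.004  # 40% spacing jitter
        with pytest.raises(ValueError, match="non-uniform"):
            ErgometerTrace(t, np.zeros(100), np.zeros(100), np.zeros(100),
                           np.zeros(100), GEOMETRY, 100.0)


class TestTraceIO:
    def test_round_trip_is_lossless(self, tmp_path):
        rng = np.random.default_rng(0)
        trace = make_trace(rng.normal(10, 3, 40), rng.normal(10, 3, 40),
                           rng.uniform(0, 4, 40), rng.uniform(0, 4, 40))
        p1 = tmp_path / "a.csv"
        write_trace(trace, p1)
        loaded = read_trace(p1)
        for name in ("time", "torque_left", "torque_right", "velocity_left",
                     "velocity_right"):
            assert np.array_equal(getattr(loaded, name), getattr(trace, name))
        # canonical re-serialization is byte-identical
        p2 = tmp_path / "b.csv"
        write_trace(loaded, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert loaded.geometry == trace.geometry

    def test_small_well_formed_file(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "time,torque_left,torque_right,velocity_left,velocity_right\n"
            "1.00,1,1,0,0\n1.01,2,2,0,0\n1.02,3,3,0,0\n1.03,4,4,0,0\n"
        )
        trace = read_trace(path, GEOMETRY, 100.0)
        assert trace.n_samples == 4
        assert trace.time[0] == 0.0  # rebased

    def test_backwards_time_names_row(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "time,torque_left,torque_right,velocity_left,velocity_right\n"
            "0.00,1,1,0,0\n0.01,1,1,0,0\n0.005,1,1,0,0\n0.02,1,1,0,0\n"
        )
        with pytest.raises(TraceLoadError, match="row 4"):
            read_trace(path, GEOMETRY, 100.0)

    def test_missing_channel_and_missing_value(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("time,torque_left,velocity_left,velocity_right\n0,1,0,0\n")
        with pytest.raises(TraceLoadError, match="torque_right"):
            read_trace(path, GEOMETRY, 100.0)
        path.write_text(
            "time,torque_left,torque_right,velocity_left,velocity_right\n"
            "0.00,1,1,0,0\n0.01,,1,0,0\n"
        )
        with pytest.raises(TraceLoadError, match="torque_left.*row 3"):
            read_trace(path, GEOMETRY, 100.0)


class TestFilter:
    def test_constant_channel_is_preserved(self):
        trace = const_trace(5.0, torque=7.5, velocity=2.0)
        out = filter_trace(trace)
        assert out.n_samples == trace.n_samples
        assert np.allclose(out.torque_left, 7.5, atol=1e-9)
        assert np.allclose(out.velocity_right, 2.0, atol=1e-9)

    @pytest.mark.parametrize("freq,passes", [(1.0, True), (40.0, False)])
    def test_sinusoid_gain_matches_butterworth_response(self, freq, passes):
        # closed-form magnitude of an order-4 low-pass Butterworth, squared
        # because the zero-phase filter runs twice
        fs, cutoff, order = 100.0, 10.0, 4
        expected_gain = (1.0 / np.sqrt(1.0 + (freq / cutoff) ** (2 * order))) ** 2
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * freq * t)
        trace = make_trace(x, x, np.abs(x), np.abs(x), sample_rate=fs)
        out = filter_trace(trace)
        mid = slice(int(5 * fs), int(15 * fs))  # avoid edge transients
        gain = np.max(np.abs(out.torque_left[mid]))
        if passes:
            assert gain == pytest.approx(expected_gain, rel=0.01)
            assert gain == pytest.approx(1.0, abs=0.01)
        else:
            assert gain < 0.01

    def test_cutoff_must_stay_below_nyquist(self):
        trace = const_trace(2.0, 1.0, 1.0)
        with pytest.raises(ValueError, match="Nyquist"):
            filter_trace(trace, cutoff=50.0)

    def test_long_constant_mean_preserved(self):
        trace = const_trace(30.0, torque=3.0, velocity=1.0)
        out = filter_trace(trace)
        assert np.mean(out.torque_right) == pytest.approx(3.0, rel=1e-6)


class TestForceAndPower:
    def test_force_hand_arithmetic(self):
        geom = WheelGeometry(wheel_radius=0.31, rim_radius=0.26)
        trace = const_trace(2.0, torque=26.0, velocity=0.0, geometry=geom)
        f = force_trace(trace)
        assert f.left[0] == pytest.approx(100.0)
        assert f.combined[0] == pytest.approx(100.0)

    def test_zero_torque_zero_force(self):
        f = force_trace(const_trace(2.0, 0.0, 1.0))
        assert np.all(f.combined == 0.0)

    def test_doubling_rim_radius_halves_force(self):
        small = const_trace(2.0, 13.0, 0.0, geometry=WheelGeometry(0.31, 0.15))
        large = const_trace(2.0, 13.0, 0.0, geometry=WheelGeometry(0.31, 0.30))
        assert np.allclose(force_trace(small).combined,
                           2.0 * force_trace(large).combined)

    def test_power_hand_arithmetic(self):
        geom = WheelGeometry(wheel_radius=0.30, rim_radius=0.26)
        trace = const_trace(2.0, torque=15.0, velocity=2.0, geometry=geom)
        p = power_trace(trace)
        assert p.left[0] == pytest.approx(100.0)
        assert p.total[0] == pytest.approx(200.0)

    def test_zero_velocity_zero_power(self):
        p = power_trace(const_trace(2.0, torque=50.0, velocity=0.0))
        assert np.all(p.total == 0.0)

    def test_power_equals_torque_times_angular_velocity(self):
        rng = np.random.default_rng(1)
        trace = make_trace(rng.normal(10, 2, 50), rng.normal(10, 2, 50),
                           rng.uniform(0, 3, 50), rng.uniform(0, 3, 50))
        p = power_trace(trace)
        omega_l = trace.velocity_left / trace.geometry.wheel_radius
        omega_r = trace.velocity_right / trace.geometry.wheel_radius
        expected = trace.torque_left * omega_l + trace.torque_right * omega_r
        assert np.allclose(p.total, expected)

    def test_linearity_in_torque(self):
        rng = np.random.default_rng(2)
        base = make_trace(rng.normal(10, 2, 30), rng.normal(10, 2, 30),
                          rng.uniform(0, 3, 30), rng.uniform(0, 3, 30))
        scaled = make_trace(2.0 * base.torque_left, 2.0 * base.torque_right,
                            base.velocity_left, base.velocity_right)
        assert np.array_equal(force_trace(scaled).combined,
                              2.0 * force_trace(base).combined)
        assert np.array_equal(power_trace(scaled).total,
                              2.0 * power_trace(base).total)


class TestRollingMean:
    def test_window_rounding_is_half_up(self):
        assert window_samples(3.0, 100.0) == 300
        assert window_samples(0.25, 10.0) == 3  # 2.5 samples rounds up
        assert window_samples(0.5, 3.0) == 2    # 1.5 samples rounds up

    def test_constant_series(self):
        out = rolling_mean(np.full(100, 4.2), 1.0, 10.0)
        assert out.shape == (91,)
        assert np.allclose(out, 4.2)

    def test_step_series_max_inside_block(self):
        series = np.concatenate([np.zeros(50), np.ones(50)])
        value, start = max_rolling_mean(series, 2.0, 10.0)
        assert value == 1.0
        assert start >= 50

    def test_window_longer_than_series_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            rolling_mean(np.ones(10), 5.0, 10.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        data=st.lists(st.floats(-100, 100, allow_nan=False), min_size=5, max_size=200),
        window=st.integers(1, 30),
    )
    def test_matches_brute_force_oracle(self, data, window):
        series = np.asarray(data)
        w = min(window, len(series))
        out = rolling_mean(series, float(w), 1.0)
        oracle = [sum(series[i:i + w]) / w for i in range(len(series) - w + 1)]
        assert np.allclose(out, oracle, atol=1e-9)
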