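"""Trace I/O, resampling, segmentation and smoothed differentiation."""

import numpy as np
import pytest
from pvbeat.errors import ConfigurationError, DataError, FormatError
from pvbeat.signal import (
    PressureTrace,
    nth_derivative,
    read_trace,
    resample_uniform,
    segment_beats,
)
from pvbeat.simulator import write_trace_csv


# ---------------------------------------------------------------- read_trace

def test_read_trace_roundtrip_small(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("time_s,pressure_mmhg\n0,5\n0.005,6\n0.010,7\n")
    tr = read_trace(p)
    assert len(tr) == 3
    np.testing.assert_allclose(tr.time, [0, 0.005, 0.010])
    np.testing.assert_allclose(tr.pressure, [5, 6, 7])
    assert tr.sampling_rate == pytest.approx(200.0)


def test_read_trace_rejects_reversed_time(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("time_s,pressure_mmhg\n0.010,5\n0.005,6\n0,7\n")
    with pytest.raises(DataError):
        read_trace(p)


def test_read_trace_missing_column(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("time_s,foo\n0,5\n0.01,6\n")
    with pytest.raises(FormatError):
        read_trace(p)


def test_read_trace_non_numeric_cell_reports_row(tmp_path):
    p = tmp_path / "t.csv"
    p.write_text("time_s,pressure_mmhg\n0,5\n0.005,oops\n0.010,7\n")
    with pytest.raises(DataError, match="row 1"):
        read_trace(p)


def test_read_trace_simulator_roundtrip(tmp_path, sim_beat):
    path = tmp_path / "sim.csv"
    write_trace_csv(sim_beat, path)
    tr = read_trace(path)
    np.testing.assert_array_equal(tr.pressure, sim_beat.trace.pressure)
    np.testing.assert_array_equal(tr.time, sim_beat.trace.time)


# ---------------------------------------------------------- resample_uniform

def test_resample_identity_at_same_rate():
    t = np.arange(1000) / 1000.0
    p = 100 + 40 * np.sin(2 * np.pi * 1.2 * t)
    tr = PressureTrace(t, p, sampling_rate=1000.0)
    out = resample_uniform(tr, 1000.0)
    np.testing.assert_allclose(out.pressure, p, atol=1e-9)


def test_resample_linear_ramp_exact():
    rng = np.random.default_rng(0)
    t = np.sort(rng.uniform(0, 2.0, 400))
    t[0], t[-1] = 0.0, 2.0
    tr = PressureTrace(t, 100.0 * t)
    out = resample_uniform(tr, 500.0)
    np.testing.assert_allclose(out.pressure, 100.0 * out.time, atol=1e-9)
    assert out.time[0] >= t[0] and out.time[-1] <= t[-1]


def test_resample_band_limited_round_trip():
    t = np.arange(0, 2.0, 1 / 1000)
    p = 80 + 30 * np.sin(2 * np.pi * 1.1 * t) + 10 * np.sin(2 * np.pi * 7.3 * t)
    tr = PressureTrace(t, p, sampling_rate=1000.0)
    down = resample_uniform(tr, 250.0)
    back = resample_uniform(down, 1000.0)
    n = min(len(back), len(tr))
    rms = np.sqrt(np.mean((back.pressure[:n] - tr.pressure[:n]) ** 2))
    assert rms < 0.1


def test_resample_downsampled_simulator_beat_accuracy(sim_beat_clean):
    dense = sim_beat_clean.trace  # 1 kHz, noiseless
    down = resample_uniform(dense, 250.0)
    truth = np.interp(down.time, dense.time, dense.pressure)
    assert np.max(np.abs(down.pressure - truth)) < 0.5


def test_resample_rejects_low_rate(sim_beat):
    with pytest.raises(ConfigurationError):
        resample_uniform(sim_beat.trace, 50.0)


# ------------------------------------------------------------ nth_derivative

def test_fourth_derivative_exact_on_quartic():
    t = np.arange(0, 2.0, 1 / 500)
    tr = PressureTrace(t, t**4, sampling_rate=500.0)
    # pure local-polynomial differentiation (pre-smoother off): exact on quartics
    d4 = nth_derivative(tr, 4, {"cutoff_hz": None})
    mid = slice(100, len(t) - 100)
    # interior exactness up to fp amplification by the 1/dt^4 scale
    np.testing.assert_allclose(d4.values[mid], 24.0, rtol=1e-3)


def test_fourth_derivative_sine_closed_form():
    t = np.arange(0, 3.0, 1 / 2000)
    tr = PressureTrace(t, np.sin(2 * np.pi * 2 * t), sampling_rate=2000.0)
    d4 = nth_derivative(tr, 4, {"cutoff_hz": None})
    expected = (4 * np.pi) ** 4 * np.sin(2 * np.pi * 2 * t)
    mid = slice(500, len(t) - 500)
    np.testing.assert_allclose(d4.values[mid], expected[mid],
                               atol=0.01 * (4 * np.pi) ** 4)


def test_derivative_is_linear_operator():
    rng = np.random.default_rng(3)
    t = np.arange(0, 1.5, 1 / 500)
    p1 = 100 + 30 * np.sin(2 * np.pi * 1.7 * t) + rng.normal(0, 0.5, len(t))
    p2 = 50 + 20 * np.cos(2 * np.pi * 2.3 * t) + rng.normal(0, 0.5, len(t))
    a, b = 1.7, -0.6
    tr = lambda p: PressureTrace(t, p, sampling_rate=500.0)
    lhs = nth_derivative(tr(a * p1 + b * p2), 4).values
    rhs = a * nth_derivative(tr(p1), 4).values + b * nth_derivative(tr(p2), 4).values
    np.testing.assert_allclose(lhs, rhs, rtol=1e-6, atol=1e-6 * np.max(np.abs(rhs)))


def test_derivative_window_validation(trace500):
    with pytest.raises(ConfigurationError):
        nth_derivative(trace500, 4, {"window": 5})  # below order + 2
    with pytest.raises(ConfigurationError):
        nth_derivative(trace500, 4, {"window": 31, "polyorder": 3})
    with pytest.raises(ConfigurationError):
        nth_derivative(trace500, 5, None)


def test_boundary_samples_flagged(trace500):
    d4 = nth_derivative(trace500, 4)
    half = d4.smoothing_params["window"] // 2
    assert not d4.valid[:half].any()
    assert not d4.valid[-half:].any()
    assert d4.valid[half:-half].all()


# ------------------------------------------------------------- segment_beats

def test_segment_simulator_trace_counts_and_durations(trace500, beats500, sim_beat):
    hr = sim_beat.params.hr
    expected = 60.0 / hr
    # 8 tiled cycles -> at least 6 complete minimum-to-minimum beats
    assert 6 <= len(beats500) <= 8
    durations = np.array([b.duration(500.0) for b in beats500])
    # diastolic minima jitter under catheter noise; the mean cycle length
    # must still match the pacing period closely
    assert np.mean(durations) == pytest.approx(expected, abs=5 / 500.0)
    assert np.all(np.abs(durations - expected) < 0.05)


def test_segment_constant_trace_is_empty():
    t = np.arange(0, 3.0, 1 / 500)
    tr = PressureTrace(t, np.full_like(t, 40.0), sampling_rate=500.0)
    with pytest.warns(UserWarning):
        assert segment_beats(tr) == []


def test_segment_concatenated_beats_equal_lengths(sim_beat_clean):
    segs = segment_beats(resample_uniform(sim_beat_clean.trace, 500.0))
    lengths = {s.n_samples for s in segs}
    assert max(lengths) - min(lengths) <= 1


def test_segment_negative_pressure_rejected():
    t = np.arange(0, 2.0, 1 / 500)
    tr = PressureTrace(t, -10 + np.sin(2 * np.pi * t), sampling_rate=500.0)
    with pytest.raises(DataError):
        segment_beats(tr)


def test_beat_landmark_ordering(beats500):
    for b in beats500:
        assert b.start_index <= b.ed_index < b.dpdt_max_index < b.dpdt_min_index < b.end_index
        assert b.lvp_max >= b.edp
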