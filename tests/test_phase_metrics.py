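"""Offline phase conventions, circular statistics, extremum-to-pulse
delays, and high-gamma landmark recovery."""
import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as spstats

from thetaloop import (DetectorConfig, LfpGenConfig, PulseTrain, SignalTrace,
                       circular_summary, expected_detection_delay_ms, generate_lfp,
                       highgamma_landmark, offline_phase, pulse_delays,
                       pulse_phases, run_closed_loop)
from thetaloop.phase_metrics import PhaseSeries, true_extrema_times, wrap_degrees

FS = 1000.0


def _cosine_trace(freq=8.0, duration=10.0, shift_s=0.0):
    t = np.arange(0, duration, 1 / FS)
    return SignalTrace(np.cos(2 * np.pi * freq * (t - shift_s)), FS)


def test_zero_phase_at_maxima_and_180_at_minima():
    trace = _cosine_trace()
    phase = offline_phase(trace)
    maxima = np.arange(1.0, 9.0, 1 / 8.0)
    minima = maxima + 1 / 16.0
    assert np.all(np.abs(phase.at_times(maxima)) <= 1.0)
    assert np.all(np.abs(np.abs(phase.at_times(minima)) - 180.0) <= 2.0)


def test_quarter_cycle_shift_reads_minus_90():
    # peak arrives a quarter cycle after t=0, so t=0 sits on the rising phase
    trace = _cosine_trace(shift_s=1 / 32.0)
    phase = offline_phase(trace)
    assert phase.phase_deg[1000] == pytest.approx(-90.0, abs=2.0)


def test_zero_group_delay_across_band():
    """A zero-phase filter keeps 0° on the cosine maximum at any theta
    frequency, unlike the causal online filter."""
    for freq in (5.0, 8.0, 11.0):
        trace = _cosine_trace(freq=freq)
        phase = offline_phase(trace)
        maxima = np.arange(1.0, 9.0, 1 / freq)
        # half-sample quantisation alone contributes up to 0.18*freq degrees
        assert np.max(np.abs(phase.at_times(maxima))) <= 1.0 + 0.18 * freq


def test_phase_monotone_on_asymmetric_theta():
    trace = generate_lfp(LfpGenConfig(noise_amp=0, hg_amp=0, asym=1.5), 10.0)
    ph = offline_phase(trace).phase_deg[500:-500]
    d = np.diff(ph)
    assert np.all((d > 0) | (d < -180.0))


def test_pulse_phases_at_constant_angle():
    trace = _cosine_trace()
    phase = offline_phase(trace)
    # 90° = quarter cycle past each peak
    onsets = np.arange(1.0, 9.0, 1 / 8.0) + 1 / 32.0
    summary = pulse_phases(PulseTrain(onsets=onsets, mode="peak"), phase)
    assert summary.mean_deg == pytest.approx(90.0, abs=1.5)
    assert summary.sd_deg == pytest.approx(0.0, abs=1.5)
    assert summary.resultant == pytest.approx(1.0, abs=1e-3)


def test_two_angle_circular_statistics():
    s = circular_summary([0.0, 90.0])
    assert s.mean_deg == pytest.approx(45.0)
    assert s.resultant == pytest.approx(np.cos(np.pi / 4), abs=1e-12)
    assert s.sd_deg == pytest.approx(
        np.degrees(np.sqrt(-2 * np.log(np.cos(np.pi / 4)))), abs=1e-9)


def test_circular_sd_matches_scipy():
    rng = np.random.default_rng(0)
    angles = rng.uniform(-180, 180, 40)
    s = circular_summary(angles)
    assert s.sd_deg == pytest.approx(
        np.degrees(spstats.circstd(np.radians(angles))), rel=1e-9)
    assert s.mean_deg == pytest.approx(
        wrap_degrees(np.degrees(spstats.circmean(np.radians(angles)))), abs=1e-9)


@given(st.floats(-720, 720),
       st.lists(st.floats(-180, 180), min_size=2, max_size=30))
def test_rotation_equivariance(delta, angles):
    base = circular_summary(angles)
    rot = circular_summary(np.asarray(angles) + delta)
    if base.resultant > 1e-6:  # mean direction undefined at zero resultant
        diff = wrap_degrees(rot.mean_deg - base.mean_deg - delta)
        assert abs(float(diff)) < 1e-6 or abs(abs(float(diff)) - 360) < 1e-6
    assert rot.sd_deg == pytest.approx(base.sd_deg, abs=1e-6)


def test_delays_zero_when_onsets_on_peaks():
    trace = _cosine_trace()
    phase = offline_phase(trace)
    peaks = true_extrema_times(phase, "peak")
    stats = pulse_delays(PulseTrain(onsets=peaks[5:-5], mode="peak"), phase)
    assert stats.mean_ms == pytest.approx(0.0, abs=1.0)
    assert stats.sd_ms == pytest.approx(0.0, abs=1.0)


def test_delays_recover_constructed_20ms():
    trace = _cosine_trace()
    phase = offline_phase(trace)
    onsets = np.arange(1.0, 9.0, 1 / 8.0) + 0.020
    stats = pulse_delays(PulseTrain(onsets=onsets, mode="peak"), phase)
    assert stats.mean_ms == pytest.approx(20.0, abs=1.0)
    assert stats.counts.sum() == stats.n


def test_closed_loop_delay_matches_analytic_decomposition(clean_cosine):
    cfg, trace = clean_cosine
    det = DetectorConfig(mode="peak")
    train = run_closed_loop(trace, det)
    stats = pulse_delays(train, offline_phase(trace))
    assert stats.mean_ms == pytest.approx(
        expected_detection_delay_ms(det, freq=cfg.theta_freq, fs=cfg.fs), abs=2.0)


def test_landmark_parameter_recovery():
    cfg = LfpGenConfig(seed=1, hg_phase=-90.0)
    trace = generate_lfp(cfg, 30.0)
    result = highgamma_landmark(trace, offline_phase(trace))
    assert result.modulated
    err = wrap_degrees(result.landmark_deg - (-90.0))
    assert abs(float(err)) <= 15.0


def test_flat_envelope_is_flagged():
    cfg = LfpGenConfig(seed=1, hg_amp=0.0)
    trace = generate_lfp(cfg, 30.0)
    result = highgamma_landmark(trace, offline_phase(trace))
    assert not result.modulated


def test_stimulation_brackets_high_gamma_peak(default_session):
    """Peak-triggered pulses precede the high-gamma power landmark within
    the theta cycle; trough-triggered pulses follow it."""
    _, trace, phase, trains = default_session
    result = highgamma_landmark(trace, phase, pulses_by_mode=trains)
    assert result.relative_hist["peak"]["circ_mean_deg"] < 0
    assert result.relative_hist["trough"]["circ_mean_deg"] > 0


def test_errors():
    trace = _cosine_trace(duration=0.2)
    with pytest.raises(ValueError):
        offline_phase(trace)
    phase = offline_phase(_cosine_trace())
    with pytest.raises(ValueError):
        pulse_phases(PulseTrain.empty(), phase)
    # a pulse before the first matching extremum has no defined delay
    t = np.arange(0, 2.0, 1 / FS)
    ramp = PhaseSeries(phase_deg=wrap_degrees(360.0 * 8.0 * t + 1.0), fs=FS)
    with pytest.raises(ValueError):
        pulse_delays(PulseTrain(onsets=np.array([0.01]), mode="peak"), ramp)
    with pytest.raises(ValueError):
        PhaseSeries(phase_deg=np.array([200.0]), fs=FS)
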