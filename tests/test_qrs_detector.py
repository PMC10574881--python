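import numpy as np
import pytest

from splineqrs import (
    CWTConfig,
    SimConfig,
    build_spline_wavelet,
    cwt_filter,
    detect_record,
    generate_ecg,
    init_detector,
    match_detections,
    process_sample,
    rr_to_hr,
)
from splineqrs.containers import EcgRecord
from splineqrs.qrs_detector import REFRACTORY_MS, THRESHOLD_FACTOR


def _run_stream(coeffs, config, learning_s=2.0):
    state = init_detector(config, learning_s)
    events = []
    for i, c in enumerate(coeffs):
        ev = process_sample(state, float(c), i)
        if ev is not None:
            events.append(ev)
    return state, events


@pytest.mark.parametrize("rr_ms,hr", [(1000.0, 60.0), (600.0, 100.0), (750.0, 80.0)])
def test_rr_to_hr(rr_ms, hr):
    assert rr_to_hr(rr_ms) == pytest.approx(hr)


@pytest.mark.parametrize("bad", [0.0, -10.0])
def test_rr_to_hr_rejects_nonpositive(bad):
    with pytest.raises(ValueError):
        rr_to_hr(bad)


def test_learning_duration_must_be_at_least_one_second():
    with pytest.raises(ValueError):
        init_detector(CWTConfig(250.0), learning_duration_s=0.5)


def test_zero_signal_learns_floor_and_stays_silent():
    config = CWTConfig(250.0)
    k = build_spline_wavelet(config.resolved_scale)
    state, events = _run_stream(cwt_filter(np.zeros(2500), k), config)
    assert events == []
    assert state.memory_pmax > 0 > state.memory_pmin  # floor fallback


def test_detection_suppressed_during_learning():
    fs = 1000.0
    record, _ = generate_ecg(SimConfig(sampling_rate_hz=fs, duration_s=20.0, seed=3))
    k = build_spline_wavelet(8)
    coeffs = cwt_filter(record.lead("aVF"), k)
    _, events = _run_stream(coeffs, CWTConfig(fs), learning_s=2.0)
    assert events and all(ev.p1_index >= 2000 for ev in events)


def test_learning_seeds_thresholds_from_window_extremes():
    fs = 250.0
    record, _ = generate_ecg(
        SimConfig(sampling_rate_hz=fs, duration_s=10.0, mean_hr_bpm=60.0, seed=0)
    )
    k = build_spline_wavelet(2)
    coeffs = cwt_filter(record.lead("aVF"), k)
    state = init_detector(CWTConfig(fs), 2.0)
    n_learn = int(2.0 * fs)
    for i in range(n_learn + 1):
        process_sample(state, float(coeffs[i]), i)
    window = coeffs[k.delay_samples : n_learn]
    assert state.memory_pmax == pytest.approx(THRESHOLD_FACTOR * window.max(), rel=1e-9)
    assert state.memory_pmin == pytest.approx(THRESHOLD_FACTOR * window.min(), rel=1e-9)


def test_non_monotone_index_rejected():
    state = init_detector(CWTConfig(250.0))
    process_sample(state, 0.0, 0)
    with pytest.raises(ValueError):
        process_sample(state, 0.0, 0)


def test_regular_sixty_bpm_train_gives_1000ms_rr():
    fs = 1000.0
    record, truth = generate_ecg(
        SimConfig(sampling_rate_hz=fs, duration_s=30.0, mean_hr_bpm=60.0, hr_sd_bpm=0.0)
    )
    beats = detect_record(record, CWTConfig(fs))[1]  # aVF
    rr = np.array([ev.rr_ms for ev in beats if ev.rr_ms is not None])
    assert len(rr) >= 25
    np.testing.assert_allclose(rr, 1000.0, atol=2.0)
    for ev in beats:
        if ev.rr_ms is not None:
            assert ev.hr_bpm == pytest.approx(60000.0 / ev.rr_ms, rel=1e-9)


def test_detection_invariant_under_polarity_inversion(clean_minute_250):
    """Order-agnostic pairing: a sign flip leaves every P1 index unchanged."""
    record, _ = clean_minute_250
    config = CWTConfig(250.0)
    flipped = EcgRecord(
        samples=-record.samples, sampling_rate_hz=250.0, leads=record.leads
    )
    for fwd, rev in zip(detect_record(record, config), detect_record(flipped, config)):
        assert [e.p1_index for e in fwd] == [e.p1_index for e in rev]
        # the modulus order itself swaps
        assert [e.pair_order for e in fwd] != [e.pair_order for e in rev]


def test_refractory_spacing_and_threshold_bounds(detected_minute_250):
    record, _, beats = detected_minute_250
    refractory = int(REFRACTORY_MS * 250.0 / 1000.0)
    for events in beats:
        idx = np.array([e.p1_index for e in events])
        assert np.all(np.diff(idx) >= refractory)


def test_memories_bounded_by_observed_moduli(clean_minute_250):
    record, _ = clean_minute_250
    config = CWTConfig(250.0)
    k = build_spline_wavelet(config.resolved_scale)
    coeffs = cwt_filter(record.lead("V2"), k)
    state, events = _run_stream(coeffs, config)
    assert events
    assert state.floor <= state.memory_pmax <= coeffs.max()
    assert coeffs.min() <= state.memory_pmin <= -state.floor


def test_beats_align_with_ground_truth_after_delay_compensation(detected_minute_250):
    """Mean |R-peak - P1| stays below 10 ms once the group delay is removed."""
    record, truth, beats = detected_minute_250
    fs = record.sampling_rate_hz
    for events in beats:
        det = np.array([e.p1_index for e in events])
        offsets = []
        for r in truth.r_peak_indices:
            j = np.abs(det - r).argmin()
            if abs(det[j] - r) <= 0.075 * fs:
                offsets.append((det[j] - r) / fs * 1000.0)
        assert len(offsets) > 0.9 * len(truth.r_peak_indices)
        assert abs(np.mean(offsets)) <= 10.0


def test_rr_series_consistent_across_sampling_rates():
    """The same simulated rhythm yields matching RR series at 250 and 1000 Hz."""
    rr = {}
    for fs in (250.0, 1000.0):
        config = SimConfig(
            sampling_rate_hz=fs, duration_s=60.0, mean_hr_bpm=70.0, hr_sd_bpm=5.0, seed=11
        )
        record, _ = generate_ecg(config)
        events = detect_record(record, CWTConfig(fs))[2]
        rr[fs] = np.array([e.rr_ms for e in events if e.rr_ms is not None])
    n = min(len(rr[250.0]), len(rr[1000.0]))
    rms = np.sqrt(np.mean((rr[250.0][:n] - rr[1000.0][:n]) ** 2))
    assert rms <= 8.0


@pytest.mark.parametrize("fs", [250.0, 500.0, 1000.0])
def test_sensitivity_and_predictivity_on_clean_ecg(fs):
    """Se and P+ stay above 99% over >=500 clean beats at every device rate."""
    config = SimConfig(
        sampling_rate_hz=fs, duration_s=450.0, mean_hr_bpm=70.0, hr_sd_bpm=5.0,
        snr_db=20.0, seed=int(fs),
    )
    record, truth = generate_ecg(config)
    assert len(truth.r_peak_indices) >= 500
    events = detect_record(record, CWTConfig(fs))[1]
    res = match_detections(
        truth.r_peak_indices, [e.p1_index for e in events], fs, tol_ms=75.0
    )
    assert res.se_pct >= 99.0
    assert res.ppv_pct >= 99.0


def test_single_lead_record_gives_single_beat_list():
    fs = 250.0
    record, _ = generate_ecg(SimConfig(sampling_rate_hz=fs, duration_s=10.0, seed=5))
    mono = EcgRecord(samples=record.samples[:, :1], sampling_rate_hz=fs, leads=("DI",))
    beats = detect_record(mono, CWTConfig(fs))
    assert len(beats) == 1 and len(beats[0]) > 0
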