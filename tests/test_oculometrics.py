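"""Event detection and parameter extraction against generator ground truth."""

import numpy as np
import pytest

from oculomet.oculometrics import (
    DetectionParams,
    TrialMetrics,
    aggregate_subject,
    analyze_trial,
    classify_antisaccade,
    classify_memory_saccade,
    detect_saccades,
    endpoint_error,
    pursuit_metrics,
    response_latency,
)
from oculomet.protocol_io import GazeTrace, StimulusPhase, Trial, build_protocol
from oculomet.synthetic_gaze import (
    SynthesisParams,
    sample_latents,
    synthesize_saccade,
    synthesize_trial,
)


def _quiet(**kw) -> SynthesisParams:
    return SynthesisParams(noise_sd=0.0, off_axis_noise_sd=0.0, blink_rate_hz=0.0, **kw)


def _grid(duration_ms: float, fs: float = 100.0) -> np.ndarray:
    dt = 1000.0 / fs
    return np.arange(0.0, duration_ms - dt / 2, dt)


def _step_trace(t, steps, fs=100.0):
    """Noise-free positions with raised-cosine saccades at given (onset, level)."""
    from oculomet.synthetic_gaze import _compose

    return _compose(t, 0.0, steps, 20.0, 2.0)


# ---------------------------------------------------------------------------
# detect_saccades
# ---------------------------------------------------------------------------


def test_constant_trace_has_no_events():
    t = _grid(2000.0)
    pos = np.full_like(t, 2.0)
    assert detect_saccades(t, pos, np.ones_like(t, bool), 100.0) == []


def test_all_invalid_trace_yields_empty():
    t = _grid(1000.0)
    events = detect_saccades(t, np.zeros_like(t), np.zeros_like(t, bool), 100.0)
    assert events == []


def test_injected_saccade_onset_recovered_within_one_sample():
    t = _grid(2000.0)
    pos = _step_trace(t, [(300.0, 10.0)])
    events = detect_saccades(t, pos, np.ones_like(t, bool), 100.0)
    assert len(events) == 1
    assert abs(events[0].onset_ms - 300.0) <= 10.0
    assert events[0].amplitude == pytest.approx(10.0, abs=0.1)


def test_two_saccades_in_order():
    t = _grid(2500.0)
    pos = _step_trace(t, [(400.0, 8.0), (900.0, -5.0)])
    events = detect_saccades(t, pos, np.ones_like(t, bool), 100.0)
    assert len(events) == 2
    assert events[0].onset_ms < events[1].onset_ms
    assert events[0].amplitude > 0 > events[1].amplitude


def test_event_overlapping_blink_is_dropped():
    t = _grid(2000.0)
    pos = _step_trace(t, [(500.0, 10.0)])
    valid = np.ones_like(t, bool)
    valid[(t >= 480.0) & (t <= 580.0)] = False
    assert detect_saccades(t, pos, valid, 100.0) == []


def test_detection_matches_brute_force_oracle_on_clean_traces():
    """On noise-free traces, velocity-threshold detection on the smoothed
    derivative agrees with an exhaustive scan of unsmoothed finite
    differences (event count, order and onsets to within 1.5 samples)."""
    params = DetectionParams()
    rng = np.random.default_rng(42)
    for _ in range(20):
        n_sacc = rng.integers(1, 4)
        onsets = np.sort(rng.uniform(300.0, 3200.0, n_sacc))
        while np.any(np.diff(onsets) < 300.0):
            onsets = np.sort(rng.uniform(300.0, 3200.0, n_sacc))
        levels = rng.uniform(-15, 15, n_sacc)
        while np.any(np.abs(np.diff(np.concatenate([[0], levels]))) < 2.0):
            levels = rng.uniform(-15, 15, n_sacc)
        t = _grid(4000.0)
        pos = _step_trace(t, list(zip(onsets, levels)))
        events = detect_saccades(t, pos, np.ones_like(t, bool), 100.0, params)

        # oracle: threshold scan on raw one-sided differences
        v = np.diff(pos) * 100.0 / 1.0  # deg/s at 100 Hz
        above = np.abs(v) >= params.velocity_threshold
        idx = np.flatnonzero(above)
        oracle = []
        if idx.size:
            breaks = np.flatnonzero(np.diff(idx) > 1)
            starts = np.concatenate([[idx[0]], idx[breaks + 1]])
            ends = np.concatenate([idx[breaks], [idx[-1]]])
            for i0, i1 in zip(starts, ends):
                if abs(pos[i1 + 1] - pos[i0]) >= params.min_amplitude:
                    oracle.append(t[i0])
        assert len(events) == len(oracle)
        for e, t0 in zip(events, oracle):
            assert abs(e.onset_ms - t0) <= 15.0


# ---------------------------------------------------------------------------
# latency and endpoint error
# ---------------------------------------------------------------------------


def _pro_trial(ecc=10.0, steps=(), fs=100.0):
    phases = [
        StimulusPhase("fixation", 0.0, 1000.0, 0.0, 0.0),
        StimulusPhase("target", 1000.0, 2500.0, ecc, 0.0),
        StimulusPhase("return", 2500.0, 4000.0, 0.0, 0.0),
    ]
    tr = Trial("prosaccade", "h", ecc, phases)
    t = _grid(4000.0, fs)
    pos = _step_trace(t, list(steps), fs)
    tr.trace = GazeTrace(t, pos, np.zeros_like(t), np.ones_like(t, bool), fs=fs)
    return tr


def test_response_latency_recovered():
    trial = _pro_trial(steps=[(1300.0, 10.0), (2800.0, 0.0)])
    events = detect_saccades(trial.trace.t, trial.axis_position(),
                             trial.trace.valid, 100.0)
    latency, early, primary = response_latency(trial, events)
    assert early == 0
    assert latency == pytest.approx(300.0, abs=10.0)


def test_saccade_at_go_time_is_early_and_latency_absent():
    trial = _pro_trial(steps=[(1000.0, 10.0)])
    events = detect_saccades(trial.trace.t, trial.axis_position(),
                             trial.trace.valid, 100.0)
    latency, early, primary = response_latency(
        trial, events, window_end_ms=trial.phase("return").onset_ms
    )
    assert latency is None
    assert primary is None
    assert early == 1


@pytest.mark.parametrize(
    "ecc,landing,expected",
    [
        (10.0, 10.0, 0.0),
        (10.0, 8.5, -1.5),
        (-10.0, -12.0, +2.0),
    ],
)
def test_endpoint_error_sign_convention(ecc, landing, expected):
    trial = _pro_trial(ecc=ecc, steps=[(1300.0, landing)])
    events = detect_saccades(trial.trace.t, trial.axis_position(),
                             trial.trace.valid, 100.0)
    _, _, primary = response_latency(trial, events)
    err = endpoint_error(trial, events, ecc, primary)
    assert err == pytest.approx(expected, abs=0.05)


# ---------------------------------------------------------------------------
# antisaccade / memory classification (trace-level, via the generator)
# ---------------------------------------------------------------------------


def _anti_trial_with(profiles, rng, overrides):
    lat = sample_latents(profiles["control"], rng)
    lat.update(overrides)
    proto = build_protocol("antisaccade", rng_seed=9)
    spec = proto.trials[0]
    return synthesize_trial(spec, lat, rng, _quiet())


def test_antisaccade_outcomes(profiles, rng):
    det = DetectionParams()
    # single mirror-directed saccade -> correct
    trial, truth = _anti_trial_with(profiles, rng, {"anti_pct_correct": 100.0})
    m = analyze_trial(trial, det)
    assert truth["outcome"] == m.outcome == "correct"
    # target-directed saccade only -> erroneous, uncorrected
    trial, truth = _anti_trial_with(
        profiles, rng, {"anti_pct_correct": 0.0, "anti_pct_corrected": 0.0}
    )
    m = analyze_trial(trial, det)
    assert truth["outcome"] == m.outcome == "uncorrected"
    # target-directed then mirror-crossing saccade -> corrected (successful)
    trial, truth = _anti_trial_with(
        profiles, rng, {"anti_pct_correct": 0.0, "anti_pct_corrected": 100.0}
    )
    m = analyze_trial(trial, det)
    assert truth["outcome"] == m.outcome == "corrected"
    assert m.corrected_latency == pytest.approx(truth["corrected_latency"], abs=15.0)


def test_memory_classification(profiles, rng):
    det = DetectionParams()
    lat = sample_latents(profiles["control"], rng)
    proto = build_protocol("memory", rng_seed=10)
    spec = proto.trials[0]
    # response to the remembered side at ~90% eccentricity -> correct
    lat["memory_pct_correct"] = 100.0
    trial, truth = synthesize_trial(spec, lat, rng, _quiet())
    m = analyze_trial(trial, det)
    assert m.outcome == "correct"
    # response to the opposite side -> incorrect
    lat["memory_pct_correct"] = 0.0
    for _ in range(30):
        trial, truth = synthesize_trial(spec, lat, rng, _quiet())
        if truth["outcome"] == "wrong_direction":
            break
    m = analyze_trial(trial, det)
    assert m.outcome != "correct"


# ---------------------------------------------------------------------------
# pursuit closed forms
# ---------------------------------------------------------------------------


def _pursuit_trial(eye, amp=12.0, freq=0.25, fs=1000.0):
    dur = 2.0 / freq * 1000.0
    t = _grid(dur, fs)
    phases = [StimulusPhase("pursuit", 0.0, dur, 0.0, 0.0)]
    tr = Trial("pursuit", "h", 0.0, phases, pursuit_amplitude=amp, pursuit_freq_hz=freq)
    pos = eye(t)
    tr.trace = GazeTrace(t, pos, np.zeros_like(t), np.ones_like(t, bool), fs=fs)
    return tr


def test_pursuit_eye_equals_target():
    amp, freq = 12.0, 0.25
    target = lambda t: amp * np.sin(2 * np.pi * freq * t / 1000.0)
    m = pursuit_metrics(_pursuit_trial(target, amp, freq))
    assert m.gain == pytest.approx(1.0, abs=1e-6)
    assert m.pursuit_error == pytest.approx(0.0, abs=1e-6)


def test_pursuit_stationary_eye_closed_form():
    """Stationary eye against an amplitude-A sinusoid: gain 0 and mean
    absolute error (2/pi) A.  Evaluated on a fine grid over whole periods so
    the discrete mean matches the analytic value to 1e-6."""
    amp = 12.0
    m = pursuit_metrics(_pursuit_trial(lambda t: np.zeros_like(t), amp, 0.25, fs=5000.0))
    assert m.gain == pytest.approx(0.0, abs=1e-6)
    assert m.pursuit_error == pytest.approx(2.0 / np.pi * amp, abs=1e-6 * amp)


def test_pursuit_scaled_eye_closed_form():
    amp = 12.0
    eye = lambda t: 0.8 * amp * np.sin(2 * np.pi * 0.25 * t / 1000.0)
    m = pursuit_metrics(_pursuit_trial(eye, amp, 0.25, fs=5000.0))
    assert m.gain == pytest.approx(0.8, abs=1e-6)
    assert m.pursuit_error == pytest.approx(0.2 * 2.0 / np.pi * amp, abs=1e-6 * amp)


def test_pursuit_mostly_invalid_trial_excluded():
    amp = 12.0
    trial = _pursuit_trial(lambda t: np.zeros_like(t), amp, 0.25, fs=100.0)
    trial.trace.valid[: int(0.6 * len(trial.trace.valid))] = False
    m = pursuit_metrics(trial)
    assert not m.valid
    assert m.gain is None


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def _anti_metrics(outcomes):
    return [TrialMetrics("antisaccade", "h", outcome=o) for o in outcomes]


def test_aggregate_antisaccade_percentages():
    """5 correct, 12 corrected errors, 3 uncorrected out of 20 attempted:
    correct 25%, corrected 80%, successful 85%."""
    out = aggregate_subject(
        _anti_metrics(["correct"] * 5 + ["corrected"] * 12 + ["uncorrected"] * 3)
    )
    assert out["anti_pct_correct"] == 25.0
    assert out["anti_pct_corrected"] == 80.0
    assert out["anti_pct_successful"] == 85.0


def test_aggregate_all_correct_leaves_corrected_unavailable():
    out = aggregate_subject(_anti_metrics(["correct"] * 20))
    assert out["anti_pct_correct"] == 100.0
    assert out["anti_pct_successful"] == 100.0
    assert np.isnan(out["anti_pct_corrected"])


def test_aggregate_no_corrections_makes_successful_equal_correct():
    out = aggregate_subject(_anti_metrics(["correct"] * 6 + ["uncorrected"] * 14))
    assert out["anti_pct_successful"] == out["anti_pct_correct"] == 30.0


def test_aggregate_empty_denominator_is_nan_not_zero():
    out = aggregate_subject([])
    assert np.isnan(out["anti_pct_correct"])
    assert np.isnan(out["memory_pct_correct"])
    assert np.isnan(out["prosaccade_latency_h"])


def test_successful_at_least_correct_and_percentages_bounded(small_features):
    for extracted, _, _ in small_features:
        for key in ("anti_pct_correct", "anti_pct_corrected",
                    "anti_pct_successful", "memory_pct_correct"):
            v = extracted[key]
            assert np.isnan(v) or 0.0 <= v <= 100.0
        if np.isfinite(extracted["anti_pct_successful"]):
            assert extracted["anti_pct_successful"] >= extracted["anti_pct_correct"] - 1e-9


def test_extraction_matches_truth_on_small_cohort(small_features):
    """Per-subject extraction tracks the generator oracle closely."""
    for extracted, truth, _ in small_features:
        for key in ("anti_pct_correct", "memory_pct_correct", "early_saccade_total"):
            if np.isfinite(truth[key]) and np.isfinite(extracted[key]):
                assert abs(extracted[key] - truth[key]) <= 10.0
        for key in ("pursuit_gain_h", "pursuit_gain_v"):
            assert abs(extracted[key] - truth[key]) < 0.05
        for key in ("prosaccade_latency_h", "prosaccade_latency_v"):
            if np.isfinite(truth[key]) and np.isfinite(extracted[key]):
                assert abs(extracted[key] - truth[key]) < 25.0
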