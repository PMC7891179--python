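"""Oculomotor event detection and parameter extraction.

Saccades are detected on the gaze position along the trial axis with a
velocity-threshold algorithm on a Savitzky-Golay smoothed derivative
(centred window of about 50 ms).  Detected events feed the parameter
definitions of the clinical battery:

* latency — delay from the go signal (target onset; central-target offset
  for memory trials) to the onset of the first qualifying saccade; onsets
  earlier than 80 ms are anticipatory ("early") and excluded;
* signed endpoint error — |final gaze eccentricity| minus |reference
  eccentricity| along the movement axis (overshoot positive, hypometria
  negative), where the final position includes any corrective saccade
  starting within 100 ms of the primary saccade's offset;
* antisaccade outcome — correct (first saccade mirror-directed), erroneous,
  corrected (erroneous followed by a midline-crossing saccade; the
  corrected latency defaults to go-time -> corrective onset), successful =
  correct or corrected;
* memory outcome — correct iff the first response is in the remembered
  direction and lands with at least 50% of the target eccentricity;
* pursuit gain — robust median ratio of eye to target velocity where the
  target moves faster than 20% of its peak velocity, excluding saccadic
  and invalid samples; pursuit error — mean absolute eye-target positional
  difference over the same samples (RMS available as an option).

Per-subject aggregation averages time/accuracy parameters within plane and
pools success percentages over planes; unavailable features propagate as
NaN, never as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .protocol_io import FEATURE_NAMES, SubjectRecord, Trial

__all__ = [
    "DetectionParams",
    "SaccadeEvent",
    "TrialMetrics",
    "detect_saccades",
    "response_latency",
    "endpoint_error",
    "classify_antisaccade",
    "classify_memory_saccade",
    "pursuit_metrics",
    "analyze_trial",
    "aggregate_subject",
    "extract_features",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionParams:
    """Saccade-detection settings (standard oculography conventions)."""

    velocity_threshold: float = 30.0  # deg/s
    min_amplitude: float = 1.0  # deg
    min_duration_ms: float = 10.0
    smooth_window_ms: float = 50.0
    anticipatory_floor_ms: float = 80.0
    corrective_window_ms: float = 100.0
    memory_amplitude_fraction: float = 0.5
    corrected_latency_reference: str = "stimulus"  # or "error_offset"
    pursuit_error_metric: str = "mad"  # or "rms"
    min_valid_fraction: float = 0.5

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SaccadeEvent:
    """One detected saccade along the trial axis."""

    onset_ms: float
    offset_ms: float
    start_deg: float
    end_deg: float
    peak_velocity: float

    @property
    def amplitude(self) -> float:
        return self.end_deg - self.start_deg

    @property
    def direction(self) -> float:
        return float(np.sign(self.amplitude))


@dataclass
class TrialMetrics:
    """Extracted per-trial measurements (None where unavailable)."""

    paradigm: str
    plane: str
    valid: bool = True
    latency: float | None = None
    error: float | None = None
    outcome: str | None = None
    corrected_latency: float | None = None
    return_latency: float | None = None
    early_count: int = 0
    gain: float | None = None
    pursuit_error: float | None = None


def _smooth_velocity(
    pos: np.ndarray, fs: float, window_ms: float
) -> np.ndarray:
    """Centred Savitzky-Golay differentiation (deg/s)."""
    dt = 1.0 / fs
    win = int(round(window_ms / 1000.0 * fs))
    win = max(3, win | 1)  # odd, >= 3
    if win >= len(pos):
        win = max(3, (len(pos) - 1) | 1)
        if win >= len(pos):
            return np.gradient(pos, dt)
    return savgol_filter(pos, win, polyorder=2, deriv=1, delta=dt)


def _sigmoid_shape(tau: np.ndarray) -> np.ndarray:
    """Normalized saccadic displacement profile (raised-cosine velocity)."""
    tau = np.clip(tau, 0.0, 1.0)
    return tau - np.sin(2.0 * np.pi * tau) / (2.0 * np.pi)


def _plateau(filled: np.ndarray, in_run: np.ndarray, sl: slice, fallback: float) -> float:
    vals = filled[sl][~in_run[sl]]
    return float(np.median(vals)) if vals.size else fallback


def _refine_event_times(
    t: np.ndarray,
    filled: np.ndarray,
    in_run: np.ndarray,
    i0: int,
    i1: int,
    fs: float,
) -> tuple[float, float, float, float]:
    """Template-based onset/offset refinement on the unsmoothed position.

    The velocity-threshold crossing is dragged outward by the smoothing
    kernel (which is as wide as a short saccade), so event times are
    instead estimated from the raw displacement step, whose signal-to-noise
    ratio is high: the half-amplitude crossing time ``t_mid`` pins the
    saccade's temporal centre independently of any smoothing, and a
    one-parameter least-squares fit of the sigmoid displacement template
    (raised-cosine velocity) around that centre recovers the duration.
    Returns ``(onset, offset, start_level, end_level)``.
    """
    n = len(t)
    dt = 1000.0 / fs
    pre = slice(max(0, i0 - 4), i0)
    post = slice(i1 + 1, min(n, i1 + 5))
    x0 = _plateau(filled, in_run, pre, filled[i0])
    x1 = _plateau(filled, in_run, post, filled[i1])
    amp = x1 - x0
    if amp == 0:
        return float(t[i0]), float(t[i1]), x0, x1
    # sub-sample half-amplitude crossing inside the run neighbourhood
    lo, hi = max(0, i0 - 2), min(n - 1, i1 + 2)
    rel = (filled[lo : hi + 1] - x0) / amp  # monotone 0 -> 1 up to noise
    above = rel >= 0.5
    if not above.any() or above.all():
        return float(t[i0]), float(t[i1]), x0, x1
    j = lo + int(np.argmax(above))
    if j == 0:
        t_mid = float(t[0])
    else:
        r0, r1 = (filled[j - 1] - x0) / amp, (filled[j] - x0) / amp
        frac = (0.5 - r0) / (r1 - r0) if r1 != r0 else 0.0
        t_mid = float(t[j - 1] + frac * dt)

    seg = slice(max(0, i0 - 4), min(n, i1 + 5))
    ts, xs = t[seg], filled[seg]

    def sse(T: float) -> float:
        model = x0 + amp * _sigmoid_shape((ts - (t_mid - T / 2.0)) / T)
        return float(np.sum((xs - model) ** 2))

    from scipy.optimize import minimize_scalar

    span = max(2.0 * dt, (i1 - i0 + 1) * dt)
    res = minimize_scalar(
        sse, bounds=(0.5 * span, 4.0 * span + 2 * dt), method="bounded",
        options={"xatol": 0.1},
    )
    T = float(res.x)
    return t_mid - T / 2.0, t_mid + T / 2.0, x0, x1


def detect_saccades(
    t_ms: np.ndarray,
    pos: np.ndarray,
    valid: np.ndarray,
    fs: float,
    params: DetectionParams | None = None,
) -> list[SaccadeEvent]:
    """Detect saccades in a 1-D gaze signal by velocity thresholding.

    Invalid samples (blinks, pupil-detection failures) are bridged by
    linear interpolation for filtering, and any candidate event that
    overlaps an invalid span is dropped.  Events are returned sorted by
    onset.  An all-invalid trace yields an empty list with a warning.
    """
    params = params or DetectionParams()
    t_ms = np.asarray(t_ms, float)
    pos = np.asarray(pos, float)
    valid = np.asarray(valid, bool) & np.isfinite(pos)
    if valid.sum() < 3:
        log.warning("all-invalid trace: no saccades detected")
        return []
    filled = pos.copy()
    if not valid.all():
        filled[~valid] = np.interp(t_ms[~valid], t_ms[valid], pos[valid])
    v = _smooth_velocity(filled, fs, params.smooth_window_ms)
    above = np.abs(v) >= params.velocity_threshold
    if not above.any():
        return []
    # contiguous runs of supra-threshold velocity
    idx = np.flatnonzero(above)
    runs: list[tuple[int, int]] = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((run_start, prev))
            run_start = i
        prev = i
    runs.append((run_start, prev))

    events: list[SaccadeEvent] = []
    min_dur_samples = params.min_duration_ms / 1000.0 * fs
    in_run = np.zeros(len(t_ms), dtype=bool)
    for i0, i1 in runs:
        in_run[i0 : i1 + 1] = True
    for i0, i1 in runs:
        if (i1 - i0 + 1) < min_dur_samples:
            continue
        if not valid[i0 : i1 + 1].all():
            continue
        if abs(filled[i1] - filled[i0]) < params.min_amplitude:
            continue
        onset, offset, x0, x1 = _refine_event_times(
            t_ms, filled, in_run, i0, i1, fs
        )
        if abs(x1 - x0) < params.min_amplitude:
            continue
        events.append(
            SaccadeEvent(
                onset_ms=onset,
                offset_ms=offset,
                start_deg=x0,
                end_deg=x1,
                peak_velocity=float(np.max(np.abs(v[i0 : i1 + 1]))),
            )
        )
    events.sort(key=lambda e: e.onset_ms)
    return events


def _axis_events(trial: Trial, params: DetectionParams) -> list[SaccadeEvent]:
    tr = trial.trace
    if tr is None:
        raise ValueError("trial has no trace")
    return detect_saccades(
        tr.t, trial.axis_position(), tr.valid, tr.fs, params
    )


def _final_position(
    trial: Trial, events: Sequence[SaccadeEvent], primary: SaccadeEvent,
    params: DetectionParams,
) -> float:
    """Gaze at primary-saccade offset, folding in an immediate corrective
    saccade and averaging a short post-saccadic fixation window."""
    end = primary.offset_ms
    landing = primary.end_deg
    for e in events:
        if 0.0 <= e.onset_ms - end <= params.corrective_window_ms:
            end, landing = e.offset_ms, e.end_deg
            break
    tr = trial.trace
    pos = trial.axis_position()
    m = (tr.t >= end + 20.0) & (tr.t <= end + 180.0) & tr.valid
    # stop the window at the next saccade, if any
    nxt = [e.onset_ms for e in events if e.onset_ms > end + params.corrective_window_ms]
    if nxt:
        m &= tr.t < nxt[0] - 10.0
    if m.sum() >= 3:
        return float(np.nanmean(pos[m]))
    return float(landing)


def response_latency(
    trial: Trial,
    events: Sequence[SaccadeEvent],
    params: DetectionParams | None = None,
    go_time_ms: float | None = None,
    window_end_ms: float | None = None,
) -> tuple[float | None, int, SaccadeEvent | None]:
    """Latency of the first qualifying response saccade after the go event.

    Saccades starting before ``go + anticipatory floor`` count as early and
    are excluded from the latency statistic.  Returns
    ``(latency_ms or None, early_count, primary_event or None)``.
    """
    params = params or DetectionParams()
    go = trial.go_time_ms if go_time_ms is None else go_time_ms
    end = trial.duration_ms if window_end_ms is None else window_end_ms
    early = 0
    primary: SaccadeEvent | None = None
    for e in events:
        if e.onset_ms >= end:
            break
        if abs(e.amplitude) < params.min_amplitude:
            continue
        if e.onset_ms < go + params.anticipatory_floor_ms:
            if e.onset_ms >= go - params.anticipatory_floor_ms:
                early += 1
            continue
        primary = e
        break
    if primary is None:
        return None, early, None
    return primary.onset_ms - go, early, primary


def endpoint_error(
    trial: Trial,
    events: Sequence[SaccadeEvent],
    reference_deg: float,
    primary: SaccadeEvent | None,
    params: DetectionParams | None = None,
) -> float | None:
    """Signed endpoint error of the primary response saccade (deg).

    Positive = overshoot beyond the reference eccentricity, negative =
    hypometria.  The final position is the gaze at the primary saccade's
    offset plus any immediate corrective saccade (<= 100 ms later).
    """
    params = params or DetectionParams()
    if primary is None:
        return None
    final = _final_position(trial, events, primary, params)
    sign = np.sign(reference_deg) or 1.0
    return float(final * sign - abs(reference_deg))


def classify_antisaccade(
    trial: Trial,
    events: Sequence[SaccadeEvent],
    params: DetectionParams | None = None,
) -> TrialMetrics:
    """Classify an antisaccade trial and measure its latencies and error."""
    params = params or DetectionParams()
    if trial.paradigm != "antisaccade":
        raise ValueError("not an antisaccade trial")
    m = TrialMetrics("antisaccade", trial.plane)
    go = trial.go_time_ms
    mirror = -trial.eccentricity
    latency, early, primary = response_latency(trial, events, params)
    m.early_count = early
    if primary is None:
        m.valid = False  # excluded from every antisaccade denominator
        return m
    m.latency = latency
    mirror_sign = np.sign(mirror)
    if primary.direction == mirror_sign:
        if primary.start_deg * np.sign(trial.eccentricity) > 2.0:
            # mirror-directed but launched from the target side: the
            # reflexive error saccade was lost to a blink — score corrected
            m.outcome = "corrected"
            if params.corrected_latency_reference == "stimulus":
                m.corrected_latency = primary.onset_ms - go
            else:
                m.corrected_latency = None
        else:
            m.outcome = "correct"
        m.error = endpoint_error(trial, events, mirror, primary, params)
        return m
    # erroneous: look for a later saccade crossing the midline to the mirror side
    for e in events:
        if e.onset_ms <= primary.offset_ms:
            continue
        if np.sign(e.end_deg) == mirror_sign and abs(e.end_deg) >= params.min_amplitude:
            m.outcome = "corrected"
            if params.corrected_latency_reference == "stimulus":
                m.corrected_latency = e.onset_ms - go
            else:
                m.corrected_latency = e.onset_ms - primary.offset_ms
            m.error = endpoint_error(trial, events, mirror, e, params)
            return m
    # no crossing saccade detected; a correction whose saccade fell inside a
    # blink still leaves the eye resting on the mirror side at trial end
    tr = trial.trace
    pos = trial.axis_position()
    tail = (tr.t >= trial.duration_ms - 500.0) & tr.valid
    if tail.sum() >= 10:
        resting = float(np.median(pos[tail]))
        if np.sign(resting) == mirror_sign and abs(resting) >= params.min_amplitude:
            m.outcome = "corrected"  # corrective latency unavailable
            return m
    m.outcome = "uncorrected"
    return m


def classify_memory_saccade(
    trial: Trial,
    events: Sequence[SaccadeEvent],
    params: DetectionParams | None = None,
) -> TrialMetrics:
    """Score a memory-guided saccade trial.

    Correct iff the first response after the blank-phase go signal is in
    the remembered direction and lands with at least half the target
    eccentricity; a missing response counts as incorrect (denominator
    retained).
    """
    params = params or DetectionParams()
    if trial.paradigm != "memory":
        raise ValueError("not a memory trial")
    m = TrialMetrics("memory", trial.plane)
    ecc = trial.eccentricity
    latency, early, primary = response_latency(trial, events, params)
    m.early_count = early
    if primary is None:
        # no saccadic event survived validity filtering; fall back to the
        # post-go fixation position (a response eaten by a blink still
        # parks the gaze at the remembered location)
        tr = trial.trace
        pos = trial.axis_position()
        tail = (tr.t >= trial.go_time_ms + 800.0) & tr.valid
        if tail.sum() >= 20:
            resting = float(np.median(pos[tail]))
            if np.sign(resting) == np.sign(ecc) and abs(
                resting
            ) >= params.memory_amplitude_fraction * abs(ecc):
                m.outcome = "correct"  # latency unavailable
                return m
        m.outcome = "omission"
        log.debug("memory trial without response scored incorrect")
        return m
    m.latency = latency
    final = _final_position(trial, events, primary, params)
    right_direction = np.sign(final) == np.sign(ecc) and primary.direction == np.sign(ecc)
    if right_direction:
        m.error = float(abs(final) - abs(ecc))
        amp_ok = abs(final) >= params.memory_amplitude_fraction * abs(ecc)
        m.outcome = "correct" if amp_ok else "hypometric"
    else:
        m.outcome = "wrong_direction"
    return m


def pursuit_metrics(
    trial: Trial,
    params: DetectionParams | None = None,
) -> TrialMetrics:
    """Pursuit gain and positional error for a sinusoidal pursuit trial.

    Saccadic samples (detected on the eye-minus-target residual) and
    invalid samples are removed; gain is the median ratio of eye to target
    velocity where the target is faster than 20% of its peak; the
    positional error is the mean absolute eye-target difference (or RMS if
    configured).  Trials with under 50% valid samples are excluded.
    """
    params = params or DetectionParams()
    if trial.paradigm != "pursuit":
        raise ValueError("not a pursuit trial")
    m = TrialMetrics("pursuit", trial.plane)
    tr = trial.trace
    if tr is None:
        raise ValueError("trial has no trace")
    pos = trial.axis_position()
    target = trial.target_position()
    valid = tr.valid & np.isfinite(pos)
    if valid.mean() < params.min_valid_fraction:
        m.valid = False
        return m
    residual = np.where(valid, pos - target, np.nan)
    sacc = detect_saccades(tr.t, residual, valid, tr.fs, params)
    keep = valid.copy()
    for e in sacc:
        keep &= ~((tr.t >= e.onset_ms - 10.0) & (tr.t <= e.offset_ms + 10.0))
    filled = pos.copy()
    if not valid.all():
        filled[~valid] = np.interp(tr.t[~valid], tr.t[valid], pos[valid])
    v_eye = _smooth_velocity(filled, tr.fs, params.smooth_window_ms)
    v_tgt = _smooth_velocity(target, tr.fs, params.smooth_window_ms)
    peak = np.max(np.abs(v_tgt))
    sel = keep & (np.abs(v_tgt) > 0.2 * peak)
    if sel.sum() < 10:
        m.valid = False
        return m
    m.gain = float(np.median(v_eye[sel] / v_tgt[sel]))
    diff = pos[keep] - target[keep]
    if params.pursuit_error_metric == "rms":
        m.pursuit_error = float(np.sqrt(np.mean(diff**2)))
    else:
        m.pursuit_error = float(np.mean(np.abs(diff)))
    return m


def analyze_trial(
    trial: Trial, params: DetectionParams | None = None
) -> TrialMetrics:
    """Extract every applicable metric from one trial."""
    params = params or DetectionParams()
    if trial.paradigm == "pursuit":
        return pursuit_metrics(trial, params)
    events = _axis_events(trial, params)
    if trial.paradigm == "antisaccade":
        return classify_antisaccade(trial, events, params)
    if trial.paradigm == "memory":
        mm = classify_memory_saccade(trial, events, params)
        return mm
    # prosaccade: response latency/error plus return-saccade latency
    m = TrialMetrics("prosaccade", trial.plane)
    go = trial.go_time_ms
    ret = trial.phase("return")
    latency, early, primary = response_latency(
        trial, events, params, go_time_ms=go, window_end_ms=ret.onset_ms
    )
    m.early_count = early
    if primary is None:
        m.valid = False
        return m
    m.latency = latency
    m.error = endpoint_error(trial, events, trial.eccentricity, primary, params)
    ret_latency, _, ret_primary = response_latency(
        trial,
        [e for e in events if e.onset_ms > primary.offset_ms],
        params,
        go_time_ms=ret.onset_ms,
        window_end_ms=trial.duration_ms,
    )
    if ret_primary is not None and ret_primary.direction == -np.sign(
        trial.eccentricity
    ):
        m.return_latency = ret_latency
    return m


def aggregate_subject(metrics: Iterable[TrialMetrics]) -> dict[str, float]:
    """Aggregate per-trial metrics into the subject feature vector.

    Time and accuracy parameters are averaged within plane; antisaccade and
    memory success percentages are pooled over planes (% corrected uses
    erroneous trials as its denominator); positive and negative endpoint
    errors are averaged separately over the trials of each sign.  Features
    with an empty denominator are NaN.
    """
    metrics = list(metrics)
    out: dict[str, float] = {name: np.nan for name in FEATURE_NAMES}

    def _mean(vals: list[float]) -> float:
        return float(np.mean(vals)) if vals else np.nan

    for plane in ("h", "v"):
        pro = [m for m in metrics if m.paradigm == "prosaccade" and m.plane == plane]
        out[f"prosaccade_latency_{plane}"] = _mean(
            [m.latency for m in pro if m.latency is not None]
        )
        out[f"return_latency_{plane}"] = _mean(
            [m.return_latency for m in pro if m.return_latency is not None]
        )
        for para, prefix in (
            ("prosaccade", "prosaccade"),
            ("antisaccade", "anti"),
            ("memory", "memory"),
        ):
            errs = [
                m.error
                for m in metrics
                if m.paradigm == para and m.plane == plane and m.error is not None
            ]
            out[f"{prefix}_pos_error_{plane}"] = _mean([e for e in errs if e > 0])
            out[f"{prefix}_neg_error_{plane}"] = _mean([e for e in errs if e < 0])
        anti = [m for m in metrics if m.paradigm == "antisaccade" and m.plane == plane]
        out[f"anti_corrected_latency_{plane}"] = _mean(
            [m.corrected_latency for m in anti if m.corrected_latency is not None]
        )
        mem = [m for m in metrics if m.paradigm == "memory" and m.plane == plane]
        out[f"memory_latency_{plane}"] = _mean(
            [m.latency for m in mem if m.latency is not None]
        )
        pur = [m for m in metrics if m.paradigm == "pursuit" and m.plane == plane]
        out[f"pursuit_gain_{plane}"] = _mean(
            [m.gain for m in pur if m.gain is not None]
        )
        out[f"pursuit_error_{plane}"] = _mean(
            [m.pursuit_error for m in pur if m.pursuit_error is not None]
        )

    anti = [m for m in metrics if m.paradigm == "antisaccade" and m.valid]
    attempted = [m for m in anti if m.outcome is not None]
    if attempted:
        n_corr = sum(m.outcome == "correct" for m in attempted)
        n_err = sum(m.outcome in ("corrected", "uncorrected") for m in attempted)
        n_fixed = sum(m.outcome == "corrected" for m in attempted)
        out["anti_pct_correct"] = 100.0 * n_corr / len(attempted)
        out["anti_pct_corrected"] = 100.0 * n_fixed / n_err if n_err else np.nan
        out["anti_pct_successful"] = 100.0 * (n_corr + n_fixed) / len(attempted)
    mem = [m for m in metrics if m.paradigm == "memory"]
    if mem:
        out["memory_pct_correct"] = 100.0 * sum(
            m.outcome == "correct" for m in mem
        ) / len(mem)
    out["early_saccade_total"] = float(sum(m.early_count for m in metrics))
    return out


def extract_features(
    records: Iterable[SubjectRecord],
    params: DetectionParams | None = None,
) -> pd.DataFrame:
    """Extract the full feature table for a cohort (one row per subject)."""
    params = params or DetectionParams()
    rows = []
    for rec in records:
        metrics = [
            analyze_trial(tr, params)
            for trials in rec.recordings.values()
            for tr in trials
        ]
        row: dict[str, object] = {
            "subject": rec.subject_id,
            "group": rec.group,
            "age": rec.age,
            "sex": rec.sex,
            "sedatives": rec.sedatives,
        }
        row.update(aggregate_subject(metrics))
        rows.append(row)
    return pd.DataFrame(rows)
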