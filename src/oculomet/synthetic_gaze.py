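"""Synthetic video-oculography cohorts with known ground truth.

The generator emulates the four-test battery (prosaccade, antisaccade,
memory-guided saccade, sinusoidal smooth pursuit) for four diagnostic
profiles.  It is hierarchical: per-subject latent parameter means are drawn
from the published group (mean, SD) marginals as truncated normals
(latencies >= 80 ms, percentages in [0, 100], pursuit gain in [0, 1.5]),
and per-trial values are drawn around the subject means.  Saccades follow a
main-sequence kinematic model (raised-cosine displacement, duration
d0 + k * amplitude), positions carry white Gaussian noise and Poisson
blink spans flagged invalid.

Every synthesized trial has exactly one entry in the returned
:class:`SubjectTruth`, which records the values *actually realized* after
physical-consistency clamps (e.g. an endpoint error cannot push a landing
across the midline, a response must fit inside its stimulus window).
``SubjectTruth.feature_means()`` is the oracle against which the feature
extractor is validated.

Because only marginal means/SDs are published, features are drawn
independently per subject; no between-feature covariance is modeled.  This
is a known idealization that tends to overstate multivariate separability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .protocol_io import (
    FEATURE_NAMES,
    TABLE_FEATURES,
    GROUPS,
    GazeTrace,
    GroupProfile,
    ProtocolTimings,
    SubjectRecord,
    TestProtocol,
    Trial,
    build_protocol,
)

__all__ = [
    "SynthesisParams",
    "SubjectTruth",
    "FEATURE_BOUNDS",
    "truncated_normal",
    "sample_latents",
    "sample_feature_matrix",
    "sample_subject",
    "synthesize_saccade",
    "saccade_duration_ms",
    "saccade_peak_velocity",
    "synthesize_trial",
    "generate_cohort",
]


# Truncation bounds for latent/feature draws, keyed by feature kind.
_LATENCY_BOUNDS = (80.0, 6000.0)
_PCT_BOUNDS = (0.0, 100.0)
_GAIN_BOUNDS = (0.0, 1.5)
_POS_ERR_BOUNDS = (0.0, 30.0)
_NEG_ERR_BOUNDS = (-30.0, 0.0)
_PURSUIT_ERR_BOUNDS = (0.0, 30.0)
_COUNT_BOUNDS = (0.0, 40.0)


def _bounds_for(name: str) -> tuple[float, float]:
    if "latency" in name:
        return _LATENCY_BOUNDS
    if "pct" in name:
        return _PCT_BOUNDS
    if "gain" in name:
        return _GAIN_BOUNDS
    if "pursuit_error" in name:
        return _PURSUIT_ERR_BOUNDS
    if "pos_error" in name:
        return _POS_ERR_BOUNDS
    if "neg_error" in name:
        return _NEG_ERR_BOUNDS
    if name == "early_saccade_total":
        return _COUNT_BOUNDS
    raise KeyError(f"no truncation bounds for feature {name!r}")


FEATURE_BOUNDS: dict[str, tuple[float, float]] = {
    n: _bounds_for(n) for n in FEATURE_NAMES
}


def truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw from N(mean, sd) truncated to [lo, hi]; degenerate SD -> mean."""
    if sd == 0:
        value = np.clip(mean, lo, hi)
        return value if size is None else np.full(size, value)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(
        a, b, loc=mean, scale=sd, size=size, random_state=rng
    )


@dataclass
class SynthesisParams:
    """Tunable knobs of the trace generator (defaults are study conditions)."""

    fs: float = 100.0
    noise_sd: float = 0.3  # deg, white positional noise on the trial axis
    off_axis_noise_sd: float = 0.15
    blink_rate_hz: float = 0.1
    blink_duration_ms: float = 150.0
    saccade_d0_ms: float = 20.0  # main-sequence intercept
    saccade_k_ms_per_deg: float = 2.0  # main-sequence slope
    latency_trial_sd_fast: float = 40.0  # visually-guided within-subject SD
    latency_trial_sd_slow: float = 120.0  # volitional within-subject SD
    error_trial_sd: float = 0.5
    min_error_deg: float = 0.25  # smallest injectable endpoint error
    gain_trial_sd: float = 0.05
    pursuit_error_trial_sd: float = 0.3
    pursuit_switch_rate_hz: float = 0.3  # offset-reversal (catch-up) rate
    timings: ProtocolTimings = field(default_factory=ProtocolTimings)


@dataclass
class SubjectTruth:
    """Latent draws and realized per-trial values for one synthetic subject."""

    subject_id: str
    group: str
    latent: dict[str, float]
    trials: dict[str, list[dict]] = field(default_factory=dict)

    def feature_means(self) -> dict[str, float]:
        """The subject's true feature vector, aggregated exactly as the
        extractor aggregates measurements (the recovery oracle)."""
        out: dict[str, float] = {name: np.nan for name in FEATURE_NAMES}

        def _mean(vals: list[float]) -> float:
            return float(np.mean(vals)) if vals else np.nan

        for plane in ("h", "v"):
            pro = [t for t in self.trials.get("prosaccade", []) if t["plane"] == plane]
            out[f"prosaccade_latency_{plane}"] = _mean(
                [t["latency"] for t in pro if t["latency"] is not None]
            )
            out[f"return_latency_{plane}"] = _mean(
                [t["return_latency"] for t in pro if t.get("return_latency") is not None]
            )
            for para, prefix in (
                ("prosaccade", "prosaccade"),
                ("antisaccade", "anti"),
                ("memory", "memory"),
            ):
                trs = [t for t in self.trials.get(para, []) if t["plane"] == plane]
                errs = [t["error"] for t in trs if t.get("error") is not None]
                out[f"{prefix}_pos_error_{plane}"] = _mean([e for e in errs if e > 0])
                out[f"{prefix}_neg_error_{plane}"] = _mean([e for e in errs if e < 0])
            anti = [t for t in self.trials.get("antisaccade", []) if t["plane"] == plane]
            out[f"anti_corrected_latency_{plane}"] = _mean(
                [
                    t["corrected_latency"]
                    for t in anti
                    if t.get("corrected_latency") is not None
                ]
            )
            mem = [t for t in self.trials.get("memory", []) if t["plane"] == plane]
            out[f"memory_latency_{plane}"] = _mean(
                [t["latency"] for t in mem if t["latency"] is not None]
            )
            pur = [t for t in self.trials.get("pursuit", []) if t["plane"] == plane]
            out[f"pursuit_gain_{plane}"] = _mean([t["gain"] for t in pur])
            out[f"pursuit_error_{plane}"] = _mean([t["pursuit_error"] for t in pur])

        anti = self.trials.get("antisaccade", [])
        attempted = [t for t in anti if t["outcome"] is not None]
        if attempted:
            n_corr = sum(t["outcome"] == "correct" for t in attempted)
            n_err = sum(t["outcome"] in ("corrected", "uncorrected") for t in attempted)
            n_fixed = sum(t["outcome"] == "corrected" for t in attempted)
            out["anti_pct_correct"] = 100.0 * n_corr / len(attempted)
            out["anti_pct_corrected"] = (
                100.0 * n_fixed / n_err if n_err else np.nan
            )
            out["anti_pct_successful"] = 100.0 * (n_corr + n_fixed) / len(attempted)
        mem = self.trials.get("memory", [])
        if mem:
            out["memory_pct_correct"] = 100.0 * sum(
                t["outcome"] == "correct" for t in mem
            ) / len(mem)
        out["early_saccade_total"] = float(
            sum(t.get("early", False) for ts in self.trials.values() for t in ts)
        )
        return out


# ---------------------------------------------------------------------------
# Latent / feature sampling
# ---------------------------------------------------------------------------


def sample_latents(
    profile: GroupProfile,
    rng: np.random.Generator,
    features: Sequence[str] = FEATURE_NAMES,
) -> dict[str, float]:
    """Draw one subject's latent parameter means from the group profile."""
    out = {}
    for name in features:
        mean, sd = profile.features[name]
        lo, hi = FEATURE_BOUNDS[name]
        out[name] = float(truncated_normal(rng, mean, sd, lo, hi))
    return out


def sample_feature_matrix(
    profiles: Mapping[str, GroupProfile],
    sizes: Mapping[str, int],
    seed: int,
    features: Sequence[str] = TABLE_FEATURES,
) -> pd.DataFrame:
    """Sample ready-made feature vectors directly from the group marginals.

    Each feature is drawn independently from its truncated-normal group
    distribution — the idealized cohort used to exercise the classification
    stage without trace synthesis.  Returns a DataFrame with a ``group``
    column followed by the feature columns.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in sizes.items():
        profile = profiles[group]
        cols = {}
        for name in features:
            mean, sd = profile.features[name]
            lo, hi = FEATURE_BOUNDS[name]
            cols[name] = truncated_normal(rng, mean, sd, lo, hi, size=n)
        df = pd.DataFrame(cols)
        df.insert(0, "group", group)
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    out.insert(0, "subject", [f"s{i:04d}" for i in range(len(out))])
    return out


# ---------------------------------------------------------------------------
# Saccade kinematics
# ---------------------------------------------------------------------------


def saccade_duration_ms(
    amplitude_deg: float, d0: float = 20.0, k: float = 2.0
) -> float:
    """Main-sequence duration: d0 + k * |amplitude|."""
    return d0 + k * abs(amplitude_deg)


def saccade_peak_velocity(
    amplitude_deg: float, d0: float = 20.0, k: float = 2.0
) -> float:
    """Peak velocity (deg/s) of the raised-cosine profile: 2A/T."""
    a = abs(amplitude_deg)
    if a == 0:
        return 0.0
    return 2.0 * a / (saccade_duration_ms(a, d0, k) / 1000.0)


def _saccade_shape(tau: np.ndarray) -> np.ndarray:
    """Normalized displacement: smooth, monotone, zero end velocity."""
    tau = np.clip(tau, 0.0, 1.0)
    return tau - np.sin(2.0 * np.pi * tau) / (2.0 * np.pi)


def synthesize_saccade(
    start_deg: float,
    end_deg: float,
    onset_ms: float,
    fs: float,
    d0: float = 20.0,
    k: float = 2.0,
    pre_ms: float = 200.0,
    post_ms: float = 200.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize a single noiseless saccade segment.

    Returns ``(t_ms, position_deg)`` sampled at ``fs`` covering
    ``[onset - pre, onset + duration + post]``; position is constant before
    onset and after offset.
    """
    for v in (start_deg, end_deg, onset_ms):
        if not math.isfinite(v):
            raise ValueError("non-finite saccade parameters")
    amp = end_deg - start_deg
    if abs(amp) > 45.0:
        raise ValueError("saccade amplitude exceeds 45 deg")
    dur = saccade_duration_ms(amp, d0, k) if amp != 0 else 0.0
    dt = 1000.0 / fs
    t = np.arange(onset_ms - pre_ms, onset_ms + dur + post_ms + dt / 2, dt)
    if amp == 0:
        return t, np.full_like(t, start_deg)
    tau = (t - onset_ms) / dur
    return t, start_deg + amp * _saccade_shape(tau)


def _compose(
    t_ms: np.ndarray,
    start_level: float,
    moves: Sequence[tuple[float, float]],
    d0: float,
    k: float,
) -> np.ndarray:
    """Piecewise-constant gaze with raised-cosine saccadic transitions.

    ``moves`` is a sorted sequence of (onset_ms, new_level); overlapping
    transitions are shifted to start after the previous one ends.
    """
    pos = np.full_like(t_ms, float(start_level))
    level = float(start_level)
    prev_end = -np.inf
    for onset, new_level in moves:
        onset = max(float(onset), prev_end + 1.0)
        amp = new_level - level
        if amp == 0.0:
            continue
        dur = saccade_duration_ms(amp, d0, k)
        tau = (t_ms - onset) / dur
        pos += amp * _saccade_shape(tau) * (t_ms >= onset)
        # _saccade_shape clips tau, so samples past offset get the full step
        level = float(new_level)
        prev_end = onset + dur
    return pos


# ---------------------------------------------------------------------------
# Trial synthesis
# ---------------------------------------------------------------------------


def _trial_grid(duration_ms: float, fs: float) -> np.ndarray:
    dt = 1000.0 / fs
    return np.arange(0.0, duration_ms - dt / 2, dt)


def _draw_signed_error(
    rng: np.random.Generator,
    latent_pos: float,
    latent_neg: float,
    params: SynthesisParams,
    neg_cap: float,
    pos_cap: float,
) -> float:
    """Draw one trial's signed endpoint error around the subject latents.

    The sign is a fair coin; the magnitude is a truncated normal around the
    subject's latent mean for that sign, kept above the minimum measurable
    error and below the physical cap for the trial's eccentricity.
    """
    if rng.random() < 0.5:
        hi = max(pos_cap, params.min_error_deg + 0.01)
        mag = truncated_normal(
            rng, latent_pos, params.error_trial_sd, params.min_error_deg, hi
        )
        return float(mag)
    hi = max(neg_cap, params.min_error_deg + 0.01)
    mag = truncated_normal(
        rng, abs(latent_neg), params.error_trial_sd, params.min_error_deg, hi
    )
    return -float(mag)


def _landing(ecc: float, err: float) -> float:
    """Landing position for signed eccentricity and signed endpoint error."""
    return math.copysign(abs(ecc) + err, ecc)


def _latency(
    rng: np.random.Generator,
    latent: float,
    sd: float,
    lo: float,
    hi: float,
) -> float:
    return float(truncated_normal(rng, latent, sd, lo, min(hi, 6000.0)))


def _finalize_trace(
    trial: Trial,
    t: np.ndarray,
    axis_pos: np.ndarray,
    rng: np.random.Generator,
    params: SynthesisParams,
) -> None:
    """Attach noise + blinks and store the trace on the trial."""
    n = len(t)
    axis = axis_pos + rng.normal(0.0, params.noise_sd, n)
    off = rng.normal(0.0, params.off_axis_noise_sd, n)
    valid = np.ones(n, dtype=bool)
    dur_s = (t[-1] - t[0]) / 1000.0 if n > 1 else 0.0
    n_blinks = rng.poisson(params.blink_rate_hz * dur_s)
    dt = 1000.0 / params.fs
    span = max(1, int(round(params.blink_duration_ms / dt)))
    for _ in range(n_blinks):
        i0 = rng.integers(0, max(1, n - span))
        valid[i0 : i0 + span] = False
    axis[~valid] = np.nan
    off[~valid] = np.nan
    axis = np.clip(axis, -39.9, 39.9)
    if trial.plane == "h":
        x, y = axis, off
    else:
        x, y = off, axis
    trial.trace = GazeTrace(t, x, y, valid, fs=params.fs)


def synthesize_trial(
    trial_spec: Trial,
    latent: Mapping[str, float],
    rng: np.random.Generator,
    params: SynthesisParams | None = None,
    early: bool = False,
) -> tuple[Trial, dict]:
    """Synthesize one trial's gaze trace from a subject's latent parameters.

    Returns a copy of the trial spec with a trace attached, plus the truth
    record of realized values (latency, signed endpoint error, outcome
    class, corrected latency, pursuit gain/error, early-saccade flag).
    """
    params = params or SynthesisParams()
    p = trial_spec.paradigm
    plane = trial_spec.plane
    trial = Trial(
        p,
        plane,
        trial_spec.eccentricity,
        list(trial_spec.phases),
        pursuit_amplitude=trial_spec.pursuit_amplitude,
        pursuit_freq_hz=trial_spec.pursuit_freq_hz,
    )
    t = _trial_grid(trial.duration_ms, params.fs)
    d0, k = params.saccade_d0_ms, params.saccade_k_ms_per_deg
    truth: dict = {"plane": plane, "eccentricity": trial.eccentricity}

    if p == "pursuit":
        return _synthesize_pursuit(trial, t, latent, rng, params, truth)

    ecc = trial.eccentricity
    go = trial.go_time_ms
    moves: list[tuple[float, float]] = []
    truth["early"] = False

    if p == "prosaccade":
        lat = _latency(
            rng,
            latent[f"prosaccade_latency_{plane}"],
            params.latency_trial_sd_fast,
            80.0,
            params.timings.prosaccade_target_ms - 300.0,
        )
        if early:
            e_on = go + rng.uniform(0.0, 60.0)
            e_land = math.copysign(2.5, ecc)
            moves.append((e_on, e_land))
            lat = max(lat, e_on - go + saccade_duration_ms(2.5, d0, k) + 100.0)
            truth["early"] = True
        err = _draw_signed_error(
            rng,
            latent[f"prosaccade_pos_error_{plane}"],
            latent[f"prosaccade_neg_error_{plane}"],
            params,
            neg_cap=abs(ecc) - 1.25,
            pos_cap=35.0 - abs(ecc),
        )
        land = _landing(ecc, err)
        moves.append((go + lat, land))
        ret_phase = trial.phase("return")
        ret_lat = _latency(
            rng,
            latent[f"return_latency_{plane}"],
            params.latency_trial_sd_fast,
            80.0,
            params.timings.return_ms - 200.0,
        )
        moves.append((ret_phase.onset_ms + ret_lat, rng.normal(0.0, 0.3)))
        truth.update(latency=lat, error=err, return_latency=ret_lat)

    elif p == "antisaccade":
        window = params.timings.antisaccade_target_ms
        mirror = -ecc
        p_correct = latent["anti_pct_correct"] / 100.0
        p_fix = latent["anti_pct_corrected"] / 100.0
        err = _draw_signed_error(
            rng,
            latent[f"anti_pos_error_{plane}"],
            latent[f"anti_neg_error_{plane}"],
            params,
            neg_cap=abs(ecc) - 1.25,
            pos_cap=35.0 - abs(ecc),
        )
        if rng.random() < p_correct:
            lat = _latency(
                rng,
                latent[f"prosaccade_latency_{plane}"] * 1.4 + 100.0,
                params.latency_trial_sd_slow,
                150.0,
                window - 500.0,
            )
            moves.append((go + lat, _landing(mirror, err)))
            truth.update(
                outcome="correct", latency=lat, error=err, corrected_latency=None
            )
        else:
            reflex_lat = _latency(
                rng,
                latent[f"prosaccade_latency_{plane}"],
                params.latency_trial_sd_fast,
                80.0,
                800.0,
            )
            reflex_land = _landing(ecc, float(rng.normal(0.0, 0.5)))
            moves.append((go + reflex_lat, reflex_land))
            if rng.random() < p_fix:
                corr_lat = _latency(
                    rng,
                    latent[f"anti_corrected_latency_{plane}"],
                    params.latency_trial_sd_slow,
                    reflex_lat + 300.0,
                    window - 500.0,
                )
                moves.append((go + corr_lat, _landing(mirror, err)))
                truth.update(
                    outcome="corrected",
                    latency=reflex_lat,
                    error=err,
                    corrected_latency=corr_lat,
                )
            else:
                truth.update(
                    outcome="uncorrected",
                    latency=reflex_lat,
                    error=None,
                    corrected_latency=None,
                )

    elif p == "memory":
        # Visually-guided portion: acquire the target, then return to centre.
        tgt = trial.phase("target")
        ctr = trial.phase("center")
        vg_lat = _latency(
            rng,
            latent[f"prosaccade_latency_{plane}"],
            params.latency_trial_sd_fast,
            80.0,
            params.timings.memory_target_ms - 300.0,
        )
        moves.append((tgt.onset_ms + vg_lat, _landing(ecc, float(rng.normal(0.0, 0.4)))))
        back_lat = _latency(
            rng,
            latent[f"return_latency_{plane}"],
            params.latency_trial_sd_fast,
            80.0,
            params.timings.memory_center_ms - 200.0,
        )
        moves.append((ctr.onset_ms + back_lat, rng.normal(0.0, 0.3)))
        window = params.timings.memory_blank_ms
        p_mem = latent["memory_pct_correct"] / 100.0
        if rng.random() < p_mem:
            lat = _latency(
                rng,
                latent[f"memory_latency_{plane}"],
                params.latency_trial_sd_slow,
                120.0,
                window - 500.0,
            )
            err = _draw_signed_error(
                rng,
                latent[f"memory_pos_error_{plane}"],
                latent[f"memory_neg_error_{plane}"],
                params,
                neg_cap=0.4 * abs(ecc),  # keep landing >= 60% of eccentricity
                pos_cap=35.0 - abs(ecc),
            )
            moves.append((go + lat, _landing(ecc, err)))
            truth.update(outcome="correct", latency=lat, error=err)
        else:
            style = rng.random()
            if style < 0.2:  # no response at all
                truth.update(outcome="omission", latency=None, error=None)
            elif style < 0.6:  # wrong direction
                lat = _latency(
                    rng,
                    latent[f"memory_latency_{plane}"],
                    params.latency_trial_sd_slow,
                    120.0,
                    window - 500.0,
                )
                land = -math.copysign(
                    max(1.5, 0.6 * abs(ecc) + rng.normal(0.0, 1.0)), ecc
                )
                moves.append((go + lat, land))
                truth.update(outcome="wrong_direction", latency=lat, error=None)
            else:  # grossly hypometric (amplitude < 50% of eccentricity)
                lat = _latency(
                    rng,
                    latent[f"memory_latency_{plane}"],
                    params.latency_trial_sd_slow,
                    120.0,
                    window - 500.0,
                )
                frac = rng.uniform(0.25, 0.38)
                land = math.copysign(frac * abs(ecc), ecc)
                err = abs(land) - abs(ecc)
                moves.append((go + lat, land))
                truth.update(outcome="hypometric", latency=lat, error=err)

    axis = _compose(t, 0.0, moves, d0, k)
    _finalize_trace(trial, t, axis, rng, params)
    return trial, truth


def _synthesize_pursuit(
    trial: Trial,
    t: np.ndarray,
    latent: Mapping[str, float],
    rng: np.random.Generator,
    params: SynthesisParams,
    truth: dict,
) -> tuple[Trial, dict]:
    plane = trial.plane
    target = trial.target_position(t)
    gain = float(
        truncated_normal(
            rng, latent[f"pursuit_gain_{plane}"], params.gain_trial_sd, 0.0, 1.5
        )
    )
    wanted_err = float(
        truncated_normal(
            rng,
            latent[f"pursuit_error_{plane}"],
            params.pursuit_error_trial_sd,
            0.05,
            15.0,
        )
    )
    delta0 = (gain - 1.0) * target
    floor = float(np.mean(np.abs(delta0)))
    if wanted_err <= floor:
        b = 0.0
    else:
        b = optimize.brentq(
            lambda bb: float(np.mean(np.abs(delta0 + bb))) - wanted_err,
            0.0,
            wanted_err + float(np.max(np.abs(delta0))) + 1.0,
        )
    # Offset reversals stand in for catch-up corrections: the positional
    # offset flips sign through saccadic transitions at Poisson times.
    sign = 1.0 if rng.random() < 0.5 else -1.0
    offset = np.full_like(t, sign * b)
    trans_mask = np.zeros(len(t), dtype=bool)
    d0, k = params.saccade_d0_ms, params.saccade_k_ms_per_deg
    if b >= 0.5:
        dur_s = t[-1] / 1000.0
        n_switch = rng.poisson(params.pursuit_switch_rate_hz * dur_s)
        times = np.sort(rng.uniform(500.0, t[-1] - 500.0, n_switch))
        level = sign * b
        moves = []
        for on in times:
            level = -level
            moves.append((on, level))
        offset = _compose(t, sign * b, moves, d0, k)
        for on, lev in moves:
            dur = saccade_duration_ms(2.0 * b, d0, k)
            trans_mask |= (t >= on - 10.0) & (t <= on + dur + 10.0)
    eye = gain * target + offset
    keep = ~trans_mask
    realized_err = float(np.mean(np.abs(eye[keep] - target[keep])))
    _finalize_trace(trial, t, eye, rng, params)
    truth.update(gain=gain, pursuit_error=realized_err)
    return trial, truth


# ---------------------------------------------------------------------------
# Subjects and cohorts
# ---------------------------------------------------------------------------


def sample_subject(
    profile: GroupProfile,
    rng: np.random.Generator,
    subject_id: str = "s0000",
    params: SynthesisParams | None = None,
) -> tuple[SubjectRecord, SubjectTruth]:
    """Sample one subject: demographics, latent parameters, full recordings."""
    params = params or SynthesisParams()
    demo = profile.demographics
    age = float(
        truncated_normal(
            rng, demo["age"]["mean"], demo["age"]["sd"], 40.0, 95.0
        )
    )
    sex = "F" if rng.random() < demo["pct_female"] / 100.0 else "M"
    sed = int(
        round(
            float(
                truncated_normal(
                    rng,
                    demo["sedatives"]["mean"],
                    demo["sedatives"]["sd"],
                    0.0,
                    10.0,
                )
            )
        )
    )
    dur = demo.get("disease_duration")
    duration = (
        float(truncated_normal(rng, dur["mean"], dur["sd"], 0.5, 30.0))
        if dur
        else None
    )
    scores = {
        name: float(truncated_normal(rng, m, s, -1e9, 1e9))
        for name, (m, s) in profile.neuropsych.items()
    }

    latent = sample_latents(profile, rng)
    truth = SubjectTruth(subject_id=subject_id, group=profile.group, latent=latent)
    record = SubjectRecord(
        subject_id=subject_id,
        group=profile.group,
        age=age,
        sex=sex,
        sedatives=sed,
        disease_duration=duration,
        scores=scores,
    )

    # Distribute the latent early-saccade total over prosaccade trials.
    n_pro = 20
    p_early = min(0.9, latent["early_saccade_total"] / n_pro)

    for paradigm in ("prosaccade", "antisaccade", "memory", "pursuit"):
        proto = build_protocol(
            paradigm,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
            fs=params.fs,
            timings=params.timings,
        )
        trials, truths = [], []
        for spec in proto.trials:
            early = paradigm == "prosaccade" and rng.random() < p_early
            tr, tt = synthesize_trial(spec, latent, rng, params, early=early)
            trials.append(tr)
            truths.append(tt)
        record.recordings[paradigm] = trials
        truth.trials[paradigm] = truths
    return record, truth


def generate_cohort(
    profiles: Mapping[str, GroupProfile],
    sizes: Mapping[str, int] | Sequence[int],
    seed: int,
    params: SynthesisParams | None = None,
) -> tuple[list[SubjectRecord], list[SubjectTruth]]:
    """Generate a full multi-group cohort, deterministically under ``seed``.

    ``sizes`` is either a mapping group -> n or a sequence aligned with
    ``(control, AD, bvFTD, svPPA)``.
    """
    if not isinstance(sizes, Mapping):
        sizes = dict(zip(GROUPS, sizes))
    params = params or SynthesisParams()
    root = np.random.SeedSequence(seed)
    records: list[SubjectRecord] = []
    truths: list[SubjectTruth] = []
    idx = 0
    total = sum(sizes.values())
    children = root.spawn(total)
    for group, n in sizes.items():
        for _ in range(n):
            rng = np.random.default_rng(children[idx])
            sid = f"{group}_{idx:04d}"
            rec, tr = sample_subject(profiles[group], rng, sid, params)
            records.append(rec)
            truths.append(tr)
            idx += 1
    return records, truths
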