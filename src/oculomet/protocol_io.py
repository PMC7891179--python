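"""Data model and I/O for video-oculography recordings and test protocols.

The recording model mirrors how clinical eye-tracking batteries are
administered: a subject performs four tests (prosaccade, antisaccade,
memory-guided saccade, sinusoidal smooth pursuit), each consisting of a
fixed number of trials.  A trial is a sequence of stimulus phases (central
fixation, eccentric target, return target, blank response window) plus a
gaze trace sampled at a constant rate.  Gaze positions are degrees of
visual angle with the screen centre at (0, 0), rightward/upward positive.

Traces are stored column-wise (time, x, y, validity arrays); each row of
the columns is one ``GazeSample``.  The on-disk format is a plain CSV with
header ``subject,paradigm,trial,t_ms,x_deg,y_deg,valid`` plus a JSON
sidecar (``<name>.trials.json``) holding the stimulus schedule and subject
metadata, so that a written cohort can be re-read and re-analysed without
access to the generating code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "PARADIGMS",
    "SACCADIC_PARADIGMS",
    "HORIZONTAL_ECCENTRICITIES",
    "VERTICAL_ECCENTRICITIES",
    "FEATURE_NAMES",
    "TABLE_FEATURES",
    "GazeSample",
    "GazeTrace",
    "StimulusPhase",
    "Trial",
    "TestProtocol",
    "ProtocolTimings",
    "SubjectRecord",
    "GroupProfile",
    "build_protocol",
    "write_gaze_table",
    "read_gaze_table",
    "write_cohort",
    "read_cohort",
    "load_group_profiles",
]

PARADIGMS = ("prosaccade", "antisaccade", "memory", "pursuit")
SACCADIC_PARADIGMS = ("prosaccade", "antisaccade", "memory")

HORIZONTAL_ECCENTRICITIES = (5.0, 10.0, 20.0)
VERTICAL_ECCENTRICITIES = (5.0, 12.0)

GROUPS = ("control", "AD", "bvFTD", "svPPA")

#: Canonical per-subject feature names (one row of the published parameter
#: tables).  Plane-resolved metrics carry an ``_h``/``_v`` suffix; success
#: percentages are pooled over planes.
FEATURE_NAMES = (
    "prosaccade_latency_h",
    "prosaccade_latency_v",
    "return_latency_h",
    "return_latency_v",
    "prosaccade_pos_error_h",
    "prosaccade_pos_error_v",
    "prosaccade_neg_error_h",
    "prosaccade_neg_error_v",
    "pursuit_gain_h",
    "pursuit_gain_v",
    "pursuit_error_h",
    "pursuit_error_v",
    "anti_pct_correct",
    "anti_pct_corrected",
    "anti_pct_successful",
    "anti_corrected_latency_h",
    "anti_corrected_latency_v",
    "anti_pos_error_h",
    "anti_pos_error_v",
    "anti_neg_error_h",
    "anti_neg_error_v",
    "memory_pct_correct",
    "memory_latency_h",
    "memory_latency_v",
    "memory_pos_error_h",
    "memory_pos_error_v",
    "memory_neg_error_h",
    "memory_neg_error_v",
    "early_saccade_total",
)

#: Features whose group distributions come from the published tables (the
#: classifier input space); excludes the assumed early-saccade count.
TABLE_FEATURES = tuple(n for n in FEATURE_NAMES if n != "early_saccade_total")

MAX_GAZE_DEG = 40.0


@dataclass(frozen=True)
class GazeSample:
    """One gaze measurement: time (ms), gaze angles (deg) and validity."""

    t: float
    x: float
    y: float
    valid: bool = True


@dataclass
class GazeTrace:
    """Column-wise gaze samples for one trial at a constant sampling rate."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise ValueError("trace columns must have equal length")
        if n == 0:
            raise ValueError("empty trace")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise ValueError(f"non-monotonic time at sample {row}")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-6):
                raise ValueError("sampling interval not constant")
        ok = self.valid
        if np.any(np.abs(self.x[ok]) > MAX_GAZE_DEG) or np.any(
            np.abs(self.y[ok]) > MAX_GAZE_DEG
        ):
            raise ValueError(f"valid gaze samples exceed +-{MAX_GAZE_DEG} deg")

    def __len__(self) -> int:
        return len(self.t)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GazeTrace):
            return NotImplemented
        return (
            self.fs == other.fs
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.x, other.x, equal_nan=True)
            and np.array_equal(self.y, other.y, equal_nan=True)
            and np.array_equal(self.valid, other.valid)
        )


@dataclass(frozen=True)
class StimulusPhase:
    """A contiguous span of the trial with a fixed (or blank) target."""

    name: str
    onset_ms: float
    offset_ms: float
    target_x_deg: float
    target_y_deg: float
    visible: bool = True

    def __post_init__(self) -> None:
        if not self.onset_ms < self.offset_ms:
            raise ValueError("phase onset must precede offset")


@dataclass
class Trial:
    """One trial: paradigm, stimulus schedule and (optionally) a gaze trace."""

    paradigm: str
    plane: str  # "h" or "v"
    eccentricity: float  # signed target eccentricity, deg (0 for pursuit)
    phases: list[StimulusPhase] = field(default_factory=list)
    trace: GazeTrace | None = None
    pursuit_amplitude: float | None = None
    pursuit_freq_hz: float | None = None

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.plane not in ("h", "v"):
            raise ValueError(f"plane must be 'h' or 'v', got {self.plane!r}")
        if self.paradigm in SACCADIC_PARADIGMS:
            allowed = (
                HORIZONTAL_ECCENTRICITIES
                if self.plane == "h"
                else VERTICAL_ECCENTRICITIES
            )
            if abs(self.eccentricity) not in allowed:
                raise ValueError(
                    f"eccentricity {self.eccentricity} not allowed for "
                    f"{self.plane!r}-plane saccadic trials"
                )
        for a, b in zip(self.phases, self.phases[1:]):
            if not np.isclose(a.offset_ms, b.onset_ms):
                raise ValueError("phases must be contiguous and non-overlapping")

    # -- stimulus geometry helpers -------------------------------------------------

    @property
    def duration_ms(self) -> float:
        return self.phases[-1].offset_ms if self.phases else 0.0

    def phase(self, name: str) -> StimulusPhase:
        for p in self.phases:
            if p.name == name:
                return p
        raise KeyError(f"trial has no phase {name!r}")

    @property
    def go_time_ms(self) -> float:
        """Go-signal time: target onset, or blank onset for memory trials."""
        if self.paradigm == "memory":
            return self.phase("blank").onset_ms
        return self.phase("target").onset_ms

    def axis_position(self) -> np.ndarray:
        """Gaze position along the trial's movement axis."""
        if self.trace is None:
            raise ValueError("trial has no trace")
        return self.trace.x if self.plane == "h" else self.trace.y

    def target_position(self, t_ms: np.ndarray | None = None) -> np.ndarray:
        """Target position along the trial axis at the given times."""
        if t_ms is None:
            if self.trace is None:
                raise ValueError("trial has no trace")
            t_ms = self.trace.t
        t_ms = np.asarray(t_ms, dtype=float)
        if self.paradigm == "pursuit":
            if self.pursuit_amplitude is None or self.pursuit_freq_hz is None:
                raise ValueError("pursuit trial lacks sinusoid parameters")
            return self.pursuit_amplitude * np.sin(
                2.0 * np.pi * self.pursuit_freq_hz * t_ms / 1000.0
            )
        pos = np.zeros_like(t_ms)
        for p in self.phases:
            m = (t_ms >= p.onset_ms) & (t_ms < p.offset_ms)
            tgt = p.target_x_deg if self.plane == "h" else p.target_y_deg
            pos[m] = tgt if p.visible else np.nan
        return pos


@dataclass(frozen=True)
class ProtocolTimings:
    """Stimulus durations (ms).  Defaults are declared protocol assumptions.

    The response windows for volitional saccades are long (4,500 ms)
    because corrected-antisaccade and memory latencies in impaired groups
    run into the seconds.
    """

    fixation_ms: float = 1000.0
    prosaccade_target_ms: float = 1500.0
    return_ms: float = 1500.0
    antisaccade_target_ms: float = 4500.0
    memory_target_ms: float = 1500.0
    memory_center_ms: float = 1000.0
    memory_blank_ms: float = 4500.0
    pursuit_cycles: int = 2
    pursuit_freq_hz: float = 0.25
    pursuit_amplitude_h: float = 20.0
    pursuit_amplitude_v: float = 12.0


@dataclass
class TestProtocol:
    """A full test: ordered trial schedule for one paradigm."""

    paradigm: str
    fs: float
    trials: list[Trial]
    timings: ProtocolTimings = field(default_factory=ProtocolTimings)

    @property
    def n_horizontal_trials(self) -> int:
        return sum(1 for tr in self.trials if tr.plane == "h")

    @property
    def n_vertical_trials(self) -> int:
        return sum(1 for tr in self.trials if tr.plane == "v")


@dataclass
class SubjectRecord:
    """One subject: identity, group, demographics and per-test recordings."""

    subject_id: str
    group: str
    age: float
    sex: str  # "F" or "M"
    sedatives: int
    disease_duration: float | None = None
    scores: dict[str, float] = field(default_factory=dict)
    recordings: dict[str, list[Trial]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.sedatives < 0:
            raise ValueError("sedative count must be >= 0")


# ---------------------------------------------------------------------------
# Protocol construction
# ---------------------------------------------------------------------------


def _saccadic_phases(
    paradigm: str, plane: str, ecc: float, timings: ProtocolTimings
) -> list[StimulusPhase]:
    tx, ty = (ecc, 0.0) if plane == "h" else (0.0, ecc)
    t0 = timings.fixation_ms
    fix = StimulusPhase("fixation", 0.0, t0, 0.0, 0.0)
    if paradigm == "prosaccade":
        t1 = t0 + timings.prosaccade_target_ms
        return [
            fix,
            StimulusPhase("target", t0, t1, tx, ty),
            StimulusPhase("return", t1, t1 + timings.return_ms, 0.0, 0.0),
        ]
    if paradigm == "antisaccade":
        t1 = t0 + timings.antisaccade_target_ms
        return [fix, StimulusPhase("target", t0, t1, tx, ty)]
    if paradigm == "memory":
        t1 = t0 + timings.memory_target_ms
        t2 = t1 + timings.memory_center_ms
        t3 = t2 + timings.memory_blank_ms
        return [
            fix,
            StimulusPhase("target", t0, t1, tx, ty),
            StimulusPhase("center", t1, t2, 0.0, 0.0),
            StimulusPhase("blank", t2, t3, 0.0, 0.0, visible=False),
        ]
    raise ValueError(f"unknown saccadic paradigm {paradigm!r}")


def build_protocol(
    paradigm: str,
    rng_seed: int,
    fs: float = 100.0,
    timings: ProtocolTimings | None = None,
) -> TestProtocol:
    """Build a seeded trial schedule for one test.

    Saccadic tests comprise 12 horizontal trials followed by 8 vertical
    trials; the eccentricity sequence is a seeded random shuffle in which
    every allowed signed eccentricity (+-5, +-10, +-20 deg horizontally;
    +-5, +-12 deg vertically) appears exactly twice.  The pursuit test
    comprises 6 horizontal followed by 6 vertical sinusoidal trials.
    Identical ``(paradigm, rng_seed)`` always yields an identical schedule.
    """
    if paradigm not in PARADIGMS:
        raise ValueError(
            f"unknown paradigm {paradigm!r}; expected one of {PARADIGMS}"
        )
    timings = timings or ProtocolTimings()
    rng = np.random.default_rng(rng_seed)
    trials: list[Trial] = []
    if paradigm == "pursuit":
        dur = timings.pursuit_cycles / timings.pursuit_freq_hz * 1000.0
        for plane, amp, n in (
            ("h", timings.pursuit_amplitude_h, 6),
            ("v", timings.pursuit_amplitude_v, 6),
        ):
            for _ in range(n):
                phases = [StimulusPhase("pursuit", 0.0, dur, 0.0, 0.0)]
                trials.append(
                    Trial(
                        paradigm,
                        plane,
                        0.0,
                        phases,
                        pursuit_amplitude=amp,
                        pursuit_freq_hz=timings.pursuit_freq_hz,
                    )
                )
    else:
        for plane, base in (("h", HORIZONTAL_ECCENTRICITIES), ("v", VERTICAL_ECCENTRICITIES)):
            eccs = np.array([s * e for e in base for s in (+1.0, -1.0)])
            schedule = rng.permutation(np.repeat(eccs, 2))
            for ecc in schedule:
                trials.append(
                    Trial(
                        paradigm,
                        plane,
                        float(ecc),
                        _saccadic_phases(paradigm, plane, float(ecc), timings),
                    )
                )
    return TestProtocol(paradigm, fs, trials, timings)


# ---------------------------------------------------------------------------
# Gaze table I/O
# ---------------------------------------------------------------------------

GAZE_COLUMNS = ("subject", "paradigm", "trial", "t_ms", "x_deg", "y_deg", "valid")


def _phase_to_dict(p: StimulusPhase) -> dict:
    return {
        "name": p.name,
        "onset_ms": p.onset_ms,
        "offset_ms": p.offset_ms,
        "target_x_deg": p.target_x_deg,
        "target_y_deg": p.target_y_deg,
        "visible": p.visible,
    }


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".trials.json")


def write_gaze_table(record: SubjectRecord, path: str | Path) -> Path:
    """Write one subject's recordings as a gaze CSV plus a JSON sidecar.

    The CSV holds one row per sample; the sidecar holds the stimulus
    schedule and subject metadata needed to re-analyse the recording.
    Returns the CSV path.
    """
    path = Path(path)
    frames = []
    meta: dict = {
        "subject": record.subject_id,
        "group": record.group,
        "age": record.age,
        "sex": record.sex,
        "sedatives": record.sedatives,
        "disease_duration": record.disease_duration,
        "scores": record.scores,
        "tests": {},
    }
    for paradigm, trials in record.recordings.items():
        meta["tests"][paradigm] = []
        for i, tr in enumerate(trials):
            if tr.trace is None or len(tr.trace) == 0:
                raise ValueError(
                    f"empty trace: subject {record.subject_id}, "
                    f"{paradigm} trial {i}"
                )
            frames.append(
                pd.DataFrame(
                    {
                        "subject": record.subject_id,
                        "paradigm": paradigm,
                        "trial": i,
                        "t_ms": tr.trace.t,
                        "x_deg": tr.trace.x,
                        "y_deg": tr.trace.y,
                        "valid": tr.trace.valid.astype(int),
                    }
                )
            )
            meta["tests"][paradigm].append(
                {
                    "plane": tr.plane,
                    "eccentricity": tr.eccentricity,
                    "fs": tr.trace.fs,
                    "pursuit_amplitude": tr.pursuit_amplitude,
                    "pursuit_freq_hz": tr.pursuit_freq_hz,
                    "phases": [_phase_to_dict(p) for p in tr.phases],
                }
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    _sidecar_path(path).write_text(json.dumps(meta))
    return path


def read_gaze_table(path: str | Path) -> SubjectRecord:
    """Read a subject record written by :func:`write_gaze_table`.

    Validates the dialect: required columns, known paradigms, strictly
    increasing time within each trial and non-empty traces; violations
    raise ``ValueError`` naming the offending trial/row.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {', '.join(missing)}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"missing trial sidecar {sidecar.name}")
    meta = json.loads(sidecar.read_text())

    bad = set(df["paradigm"]) - set(PARADIGMS)
    if bad:
        row = int(df.index[df["paradigm"].isin(bad)][0]) + 2  # 1-based + header
        raise ValueError(f"unknown paradigm {bad.pop()!r} at line {row}")

    recordings: dict[str, list[Trial]] = {}
    for paradigm, specs in meta["tests"].items():
        sub = df[df["paradigm"] == paradigm]
        trials: list[Trial] = []
        for i, spec in enumerate(specs):
            rows = sub[sub["trial"] == i]
            if rows.empty:
                raise ValueError(f"empty trace: {paradigm} trial {i}")
            t = rows["t_ms"].to_numpy(float)
            dt = np.diff(t)
            if len(t) > 1 and np.any(dt <= 0):
                row = int(rows.index[np.argmax(dt <= 0) + 1]) + 2
                raise ValueError(
                    f"non-monotonic time in {paradigm} trial {i} at line {row}"
                )
            trace = GazeTrace(
                t,
                rows["x_deg"].to_numpy(float),
                rows["y_deg"].to_numpy(float),
                rows["valid"].to_numpy().astype(bool),
                fs=float(spec["fs"]),
            )
            trials.append(
                Trial(
                    paradigm,
                    spec["plane"],
                    float(spec["eccentricity"]),
                    [StimulusPhase(**p) for p in spec["phases"]],
                    trace=trace,
                    pursuit_amplitude=spec["pursuit_amplitude"],
                    pursuit_freq_hz=spec["pursuit_freq_hz"],
                )
            )
        recordings[paradigm] = trials
    return SubjectRecord(
        subject_id=str(meta["subject"]),
        group=meta["group"],
        age=float(meta["age"]),
        sex=meta["sex"],
        sedatives=int(meta["sedatives"]),
        disease_duration=meta["disease_duration"],
        scores=meta.get("scores", {}),
        recordings=recordings,
    )


def write_cohort(records: Iterable[SubjectRecord], outdir: str | Path) -> list[Path]:
    """Write one gaze CSV (+sidecar) per subject into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    return [write_gaze_table(r, outdir / f"{r.subject_id}.csv") for r in records]


def read_cohort(indir: str | Path) -> list[SubjectRecord]:
    """Read every subject gaze CSV in a directory (sorted by filename)."""
    indir = Path(indir)
    return [read_gaze_table(p) for p in sorted(indir.glob("*.csv"))]


# ---------------------------------------------------------------------------
# Group profile fixtures
# ---------------------------------------------------------------------------


@dataclass
class GroupProfile:
    """Generative parameters for one diagnostic group.

    ``features`` maps parameter name -> (mean, sd) on the scale of the
    published tables (%-success parameters are percentages).  SDs may be
    zero for degenerate published cells; sampling then returns the mean.
    """

    group: str
    n: int
    features: Mapping[str, tuple[float, float]]
    demographics: Mapping[str, object] = field(default_factory=dict)
    neuropsych: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        for name, (_, sd) in self.features.items():
            if sd < 0:
                raise ValueError(f"negative SD for {name!r}")

    def mean(self, name: str) -> float:
        return self.features[name][0]

    def sd(self, name: str) -> float:
        return self.features[name][1]

    def with_features(self, updates: Mapping[str, tuple[float, float]]) -> "GroupProfile":
        feats = dict(self.features)
        feats.update(updates)
        return replace(self, features=feats)


def load_group_profiles(
    fixture_name: str = "default",
) -> dict[str, GroupProfile]:
    """Load packaged group profiles (``default``) or a JSON file path.

    Returns a map group label -> :class:`GroupProfile` with every published
    table cell retrievable by feature name.
    """
    if fixture_name == "default":
        ref = resources.files("oculomet.fixtures") / "group_profiles.json"
        raw = json.loads(ref.read_text())
    else:
        p = Path(fixture_name)
        if not p.exists():
            raise ValueError(f"unknown fixture {fixture_name!r}")
        raw = json.loads(p.read_text())
    profiles: dict[str, GroupProfile] = {}
    for group, g in raw["groups"].items():
        profiles[group] = GroupProfile(
            group=group,
            n=int(g["n"]),
            features={
                k: (float(v["mean"]), float(v["sd"]))
                for k, v in g["features"].items()
            },
            demographics=g.get("demographics", {}),
            neuropsych={
                k: (float(v["mean"]), float(v["sd"]))
                for k, v in g.get("neuropsych", {}).items()
            },
        )
    return profiles
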