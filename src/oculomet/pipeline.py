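"""Config-driven end-to-end runs: simulate -> extract -> stats -> classify.

A run is fully determined by its :class:`RunConfig` (seed mandatory); the
stage outputs (``features.csv``, ``stats.json``, ``report.json``,
``run.log``) are written into a run directory together with a provenance
block (config hash, seed, package version), and re-running the same config
reproduces the outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .classifier import PipelineConfig, cv_confidence_loop, search_models
from .group_stats import parameter_table
from .oculometrics import DetectionParams, analyze_trial, aggregate_subject
from .protocol_io import (
    FEATURE_NAMES,
    TABLE_FEATURES,
    load_group_profiles,
    write_cohort,
)
from .synthetic_gaze import SynthesisParams, sample_subject

__all__ = ["RunConfig", "StageError", "run_pipeline", "render_report"]

log = logging.getLogger(__name__)

DEFAULT_SIZES = {"control": 29, "AD": 18, "bvFTD": 18, "svPPA": 7}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    seed: int
    sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SIZES))
    fixture: str = "default"
    write_traces: bool = False
    detection: dict = field(default_factory=dict)
    synthesis: dict = field(default_factory=dict)
    stats_parameters: list[str] | None = None
    classify_enabled: bool = True
    pairs: list[str] = field(default_factory=lambda: ["AD:control"])
    model: str = "auto"
    model_kinds: list[str] = field(default_factory=lambda: ["svm", "knn"])
    iterations: int = 1000
    selection: str = "split"
    p_threshold: float = 0.001
    use_pls: bool = False

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        raw = dict(raw)
        if "seed" not in raw:
            raise ValueError("config must set a seed (stochastic stages)")
        cl = dict(raw.pop("classify", {}))
        kwargs = dict(
            seed=int(raw.pop("seed")),
            sizes={str(k): int(v) for k, v in raw.pop("sizes", DEFAULT_SIZES).items()},
            fixture=raw.pop("fixture", "default"),
            write_traces=bool(raw.pop("write_traces", False)),
            detection=dict(raw.pop("detection", {})),
            synthesis=dict(raw.pop("synthesis", {})),
            stats_parameters=raw.pop("stats_parameters", None),
        )
        if cl:
            kwargs.update(
                classify_enabled=bool(cl.get("enabled", True)),
                pairs=list(cl.get("pairs", ["AD:control"])),
                model=cl.get("model", "auto"),
                model_kinds=list(cl.get("kinds", ["svm", "knn"])),
                iterations=int(cl.get("iterations", 1000)),
                selection=cl.get("selection", "split"),
                p_threshold=float(cl.get("p_threshold", 0.001)),
                use_pls=bool(cl.get("use_pls", False)),
            )
        if raw:
            raise ValueError(f"unknown config keys: {sorted(raw)}")
        return cls(**kwargs)

    def canonical_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def run_pipeline(config: RunConfig | Mapping, outdir: str | Path) -> Path:
    """Run all enabled stages into ``outdir`` and return the directory."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_dict(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events: list[dict] = []

    def _log(stage: str, **kw):
        events.append(_jsonify({"stage": stage, **kw}))

    det = DetectionParams(**config.detection)
    synth = SynthesisParams(**config.synthesis)

    # simulate + extract (streamed per subject to bound memory)
    try:
        profiles = load_group_profiles(config.fixture)
    except Exception as exc:  # noqa: BLE001
        raise StageError("profiles", str(exc)) from exc
    try:
        rows = []
        truth_rows = []
        root = np.random.SeedSequence(config.seed)
        total = sum(config.sizes.values())
        children = root.spawn(total)
        idx = 0
        trace_dir = outdir / "traces"
        for group, n in config.sizes.items():
            for _ in range(n):
                rng = np.random.default_rng(children[idx])
                sid = f"{group}_{idx:04d}"
                rec, truth = sample_subject(profiles[group], rng, sid, synth)
                if config.write_traces:
                    write_cohort([rec], trace_dir)
                metrics = [
                    analyze_trial(tr, det)
                    for trials in rec.recordings.values()
                    for tr in trials
                ]
                row = {
                    "subject": sid,
                    "group": group,
                    "age": rec.age,
                    "sex": rec.sex,
                    "sedatives": rec.sedatives,
                }
                row.update(aggregate_subject(metrics))
                rows.append(row)
                truth_rows.append(
                    {"subject": sid, "group": group, **truth.feature_means()}
                )
                idx += 1
        features = pd.DataFrame(rows)
        features.to_csv(outdir / "features.csv", index=False)
        pd.DataFrame(truth_rows).to_csv(outdir / "truth.csv", index=False)
        _log("simulate_extract", subjects=total, sizes=config.sizes)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate_extract", str(exc)) from exc

    # univariate stats
    try:
        params = config.stats_parameters or list(FEATURE_NAMES)
        table = parameter_table(features, params)
        stats_out = {
            name: {
                "group_p": res.group_p,
                "group_means": res.group_means,
                "group_sds": res.group_sds,
                "crude_pairwise_p": {
                    f"{a}:{b}": p for (a, b), p in res.crude_pairwise_p.items()
                },
                "adjusted_pairwise_p": {
                    f"{a}:{b}": p for (a, b), p in res.adjusted_pairwise_p.items()
                },
                "mean_differences": {
                    f"{a}:{b}": d for (a, b), d in res.mean_differences.items()
                },
                "covariates": list(res.covariates),
            }
            for name, res in table.items()
        }
        (outdir / "stats.json").write_text(
            json.dumps(_jsonify(stats_out), sort_keys=True, indent=1)
        )
        _log("stats", parameters=len(stats_out))
    except Exception as exc:  # noqa: BLE001
        raise StageError("stats", str(exc)) from exc

    # classification
    reports: list[dict] = []
    if config.classify_enabled:
        try:
            rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
            for pair in config.pairs:
                a, b = pair.split(":")
                sub = features[features["group"].isin([a, b])]
                x = sub[list(TABLE_FEATURES)]
                y = sub["group"].to_numpy()
                model = config.model
                if model == "auto":
                    model, _ = search_models(
                        x,
                        y,
                        seed=int(rng.integers(2**31 - 1)),
                        kinds=config.model_kinds,
                        p_threshold=config.p_threshold,
                    )
                pc = PipelineConfig(
                    model=model,
                    selection=config.selection,
                    p_threshold=config.p_threshold,
                    use_pls=config.use_pls,
                    iterations=config.iterations,
                )
                report = cv_confidence_loop(
                    x, y, pc, seed=int(rng.integers(2**31 - 1)), pair=pair
                )
                reports.append(report.as_dict())
                _log("classify", pair=pair, mean_auc=report.mean_auc,
                     algorithm=report.algorithm)
        except Exception as exc:  # noqa: BLE001
            raise StageError("classify", str(exc)) from exc
        (outdir / "report.json").write_text(
            json.dumps(_jsonify(reports), sort_keys=True, indent=1)
        )

    provenance = {
        "config": json.loads(config.canonical_json()),
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "detection": det.as_dict(),
    }
    (outdir / "provenance.json").write_text(
        json.dumps(_jsonify(provenance), sort_keys=True, indent=1)
    )
    (outdir / "run.log").write_text(
        "\n".join(json.dumps(e, sort_keys=True) for e in events) + "\n"
    )
    return outdir


def render_report(run_dir: str | Path) -> str:
    """Render a run directory as a human-readable markdown summary.

    Incomplete runs produce a partial report with warnings rather than an
    error.
    """
    run_dir = Path(run_dir)
    lines: list[str] = ["# Oculomotor pipeline report", ""]
    warnings: list[str] = []

    prov_p = run_dir / "provenance.json"
    if prov_p.exists():
        prov = json.loads(prov_p.read_text())
        lines += [
            f"- config hash: `{prov['config_hash']}`",
            f"- seed: {prov['seed']}",
            f"- package version: {prov['version']}",
            f"- detection thresholds: velocity {prov['detection']['velocity_threshold']}"
            f" deg/s, min amplitude {prov['detection']['min_amplitude']} deg,"
            f" min duration {prov['detection']['min_duration_ms']} ms,"
            f" anticipatory floor {prov['detection']['anticipatory_floor_ms']} ms",
            "",
        ]
    else:
        warnings.append("missing provenance.json")

    feat_p = run_dir / "features.csv"
    stats_p = run_dir / "stats.json"
    if feat_p.exists() and stats_p.exists():
        features = pd.read_csv(feat_p)
        stats_d = json.loads(stats_p.read_text())
        groups = sorted(features["group"].unique())
        lines += ["## Group means (SD)", ""]
        lines.append("| parameter | " + " | ".join(groups) + " | group P |")
        lines.append("|---" * (len(groups) + 2) + "|")
        for name, res in sorted(stats_d.items()):
            cells = []
            for g in groups:
                m = res["group_means"].get(g)
                s = res["group_sds"].get(g)
                cells.append("–" if m is None else f"{m:.2f} ({s:.2f})")
            gp = res["group_p"]
            lines.append(
                f"| {name} | " + " | ".join(cells)
                + f" | {gp:.4g} |"
            )
        lines.append("")
        lines += ["## Discriminating parameters (P < 0.05, crude)", ""]
        pairs: dict[str, list[str]] = {}
        for name, res in stats_d.items():
            for key, p in res["crude_pairwise_p"].items():
                if p is not None and p < 0.05:
                    pairs.setdefault(key, []).append(name)
        for key in sorted(pairs):
            lines.append(f"- **{key}**: " + ", ".join(sorted(pairs[key])))
        lines.append("")
    else:
        warnings.append("missing features.csv/stats.json")

    rep_p = run_dir / "report.json"
    if rep_p.exists():
        reports = json.loads(rep_p.read_text())
        lines += ["## Classifier performance", ""]
        lines.append(
            "| pair | algorithm | best AUC | worst AUC | mean AUC |"
            " best acc | worst acc | mean acc |"
        )
        lines.append("|---" * 8 + "|")
        for r in reports:
            lines.append(
                f"| {r['pair']} | {r['algorithm']} | {r['best_auc']:.4f} |"
                f" {r['worst_auc']:.4f} | {r['mean_auc']:.4f} |"
                f" {r['best_accuracy']:.4f} | {r['worst_accuracy']:.4f} |"
                f" {r['mean_accuracy']:.4f} |"
            )
        lines.append("")

    if warnings:
        lines += ["## Warnings", ""] + [f"- {w}" for w in warnings] + [""]
    text = "\n".join(lines)
    (run_dir / "report.md").write_text(text)
    return text
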