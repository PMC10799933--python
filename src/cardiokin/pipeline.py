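"""End-to-end orchestration: simulate -> track -> beats -> compare -> classify.

A single :class:`RunConfig` (typically loaded from YAML) drives the whole
pipeline deterministically from one master seed.  Every stage writes its
outputs under the run directory and registers them in a manifest; a stage
error is recorded and halts only the stages that depend on it.
"""

from __future__ import annotations

import json
import time
import traceback
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beats as beats_mod
from . import compare as compare_mod
from . import ml as ml_mod
from .errors import CardiokinError
from .flow import flow_profiles
from .intensity import intensity_profile, reference_frame
from .io import VideoClip, read_video
from .markers import marker_speed_profile, mean_profiles, place_markers, track_markers
from .profiles import ContractionProfile, SpeedProfile
from .synthetic import (
    BenchmarkProtocol,
    cardioid_protocol,
    cells_protocol,
    iter_benchmark,
)

__all__ = ["RunConfig", "run", "track_clip", "analyze_clip"]

TRACKERS = ("intensity", "flow", "marker")


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    output_dir: str = "cardiokin_run"
    master_seed: int = 0
    trackers: tuple[str, ...] = TRACKERS
    # synthetic protocol
    sample_types: tuple[str, ...] = ("cells", "cardioid")
    treatment: str = "caffeine_like"
    replicates: int = 3
    spec_overrides: dict = field(default_factory=dict)
    # recorded-video inputs: list of {path, fps, pixel_size, frequency, arm,
    # sample_type, label} dicts; used instead of the simulator when non-empty
    inputs: list = field(default_factory=list)
    # beat analysis
    onset_epsilon: float = 0.05
    derivative_scheme: str = "forward"
    # comparison
    base_frequency: float = 0.5
    # ML
    classifiers: tuple[str, ...] = ml_mod.CLASSIFIERS

    def __post_init__(self):
        self.trackers = tuple(self.trackers)
        if not self.trackers:
            raise ValueError("at least one tracker is required")
        unknown = set(self.trackers) - set(TRACKERS)
        if unknown:
            raise ValueError(f"unknown trackers: {sorted(unknown)}")
        if self.master_seed is None:
            raise ValueError("a master seed is required")
        for item in self.inputs:
            if not Path(item["path"]).exists():
                raise FileNotFoundError(item["path"])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def track_clip(
    clip: VideoClip, tracker: str, derivative_scheme: str = "forward"
) -> tuple[SpeedProfile, ContractionProfile]:
    """Run one tracking back-end on a clip.

    intensity: frame-difference contraction profile, derivative for speed.
    flow:      dense-flow speed, radially integrated contraction profile.
    marker:    auto-placed kernel trajectory, displacement and step speed.
    """
    if tracker == "intensity":
        contraction = intensity_profile(clip, reference_frame(clip))
        speed = beats_mod.derivative(contraction, scheme=derivative_scheme)
        return speed, contraction
    if tracker == "flow":
        return flow_profiles(clip)
    if tracker == "marker":
        markers = place_markers(clip, mode="auto_contrast", k=1)
        if not markers:
            raise CardiokinError("no markers could be placed on this clip")
        trajs = track_markers(clip, markers)
        profiles = [
            marker_speed_profile(t, clip.pixel_size, clip.fps) for t in trajs
        ]
        return mean_profiles(profiles)
    raise ValueError(f"unknown tracker {tracker!r}")


def analyze_clip(
    clip: VideoClip,
    tracker: str,
    video_id: str = "",
    pacing_hint: float | None = None,
    onset_epsilon: float = 0.05,
    derivative_scheme: str = "forward",
) -> pd.DataFrame:
    """Track one clip and return its per-beat parameter table."""
    speed, contraction = track_clip(clip, tracker, derivative_scheme)
    beats = beats_mod.segment_beats(
        speed, contraction, pacing_hint=pacing_hint, onset_epsilon=onset_epsilon
    )
    return beats_mod.beats_table(beats, speed, contraction, video_id, tracker)


def _protocols(config: RunConfig) -> list[BenchmarkProtocol]:
    protos = []
    for st in config.sample_types:
        maker = cells_protocol if st == "cells" else cardioid_protocol
        protos.append(
            maker(
                treatment=config.treatment,
                replicates=config.replicates,
                master_seed=config.master_seed,
                **config.spec_overrides.get(st, {}),
            )
        )
    return protos


def _iter_clips(config: RunConfig):
    """Yield (clip, label dict) pairs from files or the simulator."""
    if config.inputs:
        for i, item in enumerate(config.inputs):
            clip = read_video(
                item["path"], fps=item.get("fps"), pixel_size=item.get("pixel_size")
            )
            label = {
                "sample_type": item.get("sample_type", "cells"),
                "frequency": item.get("frequency"),
                "arm": item.get("arm", "control"),
                "label": item.get("label", 0),
                "replicate": item.get("replicate", i),
            }
            yield clip, label
    else:
        for proto in _protocols(config):
            for item in iter_benchmark(proto):
                yield item.clip, item.label


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "stages": {},
        "files": [],
    }

    def record(stage: str, status: str, error: str | None = None, t0: float = 0.0):
        manifest["stages"][stage] = {
            "status": status,
            "seconds": round(time.time() - t0, 3) if t0 else None,
            "error": error,
        }

    def emit(name: str, df: pd.DataFrame):
        path = outdir / name
        df.to_csv(path, index=False)
        manifest["files"].append(str(path))

    per_beat = None
    t0 = time.time()
    try:
        rows = []
        for clip, label in _iter_clips(config):
            vid = (
                f"{label['sample_type']}_f{label['frequency']}"
                f"_{label['arm']}_r{label['replicate']}"
            )
            for tracker in config.trackers:
                table = analyze_clip(
                    clip,
                    tracker,
                    video_id=vid,
                    pacing_hint=label.get("frequency"),
                    onset_epsilon=config.onset_epsilon,
                    derivative_scheme=config.derivative_scheme,
                )
                for k, v in label.items():
                    table[k] = v
                rows.append(table)
        per_beat = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
        emit("per_beat.csv", per_beat)
        record("track", "ok", t0=t0)
    except Exception as exc:  # noqa: BLE001
        record("track", "error", error=f"{exc}\n{traceback.format_exc()}", t0=t0)

    summaries = None
    if per_beat is not None and len(per_beat):
        t0 = time.time()
        try:
            melted = per_beat.melt(
                id_vars=["tracker", "frequency", "arm"],
                value_vars=list(beats_mod.PARAMETER_COLUMNS),
                var_name="parameter",
                value_name="value",
            )
            summaries = (
                melted.groupby(["tracker", "frequency", "arm", "parameter"])["value"]
                .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
                .reset_index()
            )
            emit("summaries.csv", summaries)
            record("beats", "ok", t0=t0)
        except Exception as exc:  # noqa: BLE001
            record("beats", "error", error=str(exc), t0=t0)
    else:
        record("beats", "skipped (track failed or empty)")

    if summaries is not None:
        t0 = time.time()
        try:
            arms = set(summaries["arm"])
            if len(arms) == 2 and "control" in arms:
                treated_name = next(a for a in arms if a != "control")
                ctrl = summaries[summaries["arm"] == "control"]
                trt = summaries[summaries["arm"] == treated_name]
                emit("treatment_delta.csv", compare_mod.treatment_delta(ctrl, trt))
            ctrl = summaries[summaries["arm"] == "control"]
            emit(
                "frequency_ratios.csv",
                compare_mod.frequency_ratio(ctrl, config.base_frequency),
            )
            if len(config.trackers) >= 2:
                tables = {
                    trk: grp
                    for trk, grp in per_beat.groupby("tracker")
                    if len(grp)
                }
                agree = compare_mod.cross_tracker_agreement(
                    {
                        t: g.groupby("beat_index", as_index=False).mean(
                            numeric_only=True
                        )
                        for t, g in tables.items()
                    }
                )
                emit("cross_tracker_agreement.csv", agree)
            record("compare", "ok", t0=t0)
        except Exception as exc:  # noqa: BLE001
            record("compare", "error", error=str(exc), t0=t0)
    else:
        record("compare", "skipped (beats failed)")

    if per_beat is not None and len(per_beat):
        t0 = time.time()
        try:
            datasets = ml_mod.assemble_datasets(per_beat)
            report = ml_mod.evaluate_datasets(
                datasets, classifiers=tuple(config.classifiers),
                seed=config.master_seed,
            )
            emit("classifier_report.csv", report)
            radar = report.pivot_table(
                index=["tracker", "frequency"],
                columns="classifier",
                values=["accuracy", "tpr"],
            )
            radar.columns = [f"{m}_{c}" for m, c in radar.columns]
            path = outdir / "radar_summary.csv"
            radar.reset_index().to_csv(path, index=False)
            manifest["files"].append(str(path))
            record("classify", "ok", t0=t0)
        except Exception as exc:  # noqa: BLE001
            record("classify", "error", error=str(exc), t0=t0)
    else:
        record("classify", "skipped (track failed or empty)")

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    manifest["files"].append(str(manifest_path))
    return manifest
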