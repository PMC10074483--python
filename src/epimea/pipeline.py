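"""End-to-end pipeline: simulate -> detect -> map -> classify -> summarize -> compare.

Every stage consumes only persisted artifacts of prior stages and persists
its own, so the CLI subcommands compose without hidden state. A manifest
records the resolved configuration, the seed, and a SHA-256 hash of every
artifact; rerunning with the same configuration reproduces byte-identical
event tables and reports.

Two simulation modes: ``render=True`` writes full HDF5 voltage recordings
and runs the threshold detector on them; ``render=False`` (default) writes
the ground-truth per-electrode FP tables directly, which is exact at the
event level and feasible at the paper's full protocol scale.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activity import area_region, compute_map, select_active_area
from .classify import (
    ClassifierParams,
    T1_WINDOW,
    T2_WINDOW,
    population_fps,
    segment_and_classify,
    summarize_slice,
)
from .conditions import (
    GEOMETRY_PRESETS,
    EffectModel,
    desk_effect_model,
    scenario,
    scenario_names,
)
from .detect import DetectorParams, FPEvent, detect_fps
from .io import (
    read_area_mask,
    read_fp_events,
    read_recording,
    write_area_mask,
    write_events,
    write_fp_events,
    write_json,
    write_recording,
)
from .simulate import SliceTrain, render_traces, simulate_event_trains
from .stats import GROUP_TABLE_COLUMNS, experiment_report, report_text

__all__ = [
    "PipelineConfig",
    "StageError",
    "run_pipeline",
    "trains_to_fp_events",
    "analyze_slice",
    "SliceAnalysis",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, path: str | Path, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {path}: {cause}")
        self.stage = stage
        self.path = str(path)


DEFAULT_WINDOWS = {"T1": list(T1_WINDOW), "T2": list(T2_WINDOW)}


@dataclass
class PipelineConfig:
    conditions: list[str] = field(default_factory=lambda: ["0mg_4ap", "lps_0mg_4ap"])
    geometry: str = "desk"
    effect_preset: str = "paper"  # "paper" | "desk"
    effect_overrides: dict = field(default_factory=dict)
    detector: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    activity: dict = field(default_factory=lambda: {"min_size": 4, "percentile": 75.0})
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))
    contrasts: list[dict] = field(default_factory=list)
    n_slices: int = 5
    seed: int = 0
    ictogenic_duration: float = 2400.0
    render: bool = False
    out_dir: str = "epimea_out"

    # -- validation / resolution -------------------------------------------

    def validate(self) -> None:
        known = set(scenario_names())
        for cond in self.conditions:
            if cond not in known:
                raise ValueError(f"unknown scenario {cond!r}")
        if self.geometry not in GEOMETRY_PRESETS:
            raise ValueError(f"unknown geometry preset {self.geometry!r}")
        if self.effect_preset not in ("paper", "desk"):
            raise ValueError(f"unknown effect preset {self.effect_preset!r}")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        for contrast in self.contrasts:
            for side in ("a", "b"):
                if contrast[side] not in self.conditions:
                    raise ValueError(
                        f"contrast references condition {contrast[side]!r} "
                        "not in the configured conditions"
                    )
        self.effect_model()  # validates overrides

    def effect_model(self) -> EffectModel:
        base = desk_effect_model if self.effect_preset == "desk" else EffectModel
        model = base(**self.effect_overrides)
        model.validate()
        return model

    def detector_params(self) -> DetectorParams:
        return DetectorParams(**self.detector)

    def classifier_params(self) -> ClassifierParams:
        params = dict(self.classifier)
        params.setdefault("se_min_duration", self.effect_model().se_min_duration)
        return ClassifierParams(**params)

    def window_bounds(self) -> dict[str, tuple[float, float]]:
        return {k: (float(v[0]), float(v[1])) for k, v in self.windows.items()}

    # -- (de)serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)


# ---------------------------------------------------------------------------
# In-memory analysis helpers (shared by pipeline, tests, acceptance)
# ---------------------------------------------------------------------------


def trains_to_fp_events(train: SliceTrain, amplitude: float | None = None) -> list[FPEvent]:
    """Ground-truth per-electrode FP times as detector-style FP events."""
    amp = amplitude if amplitude is not None else 350.0
    fps = [
        FPEvent(r, c, float(t), 0.0, amp)
        for (r, c), times in sorted(train.fp_times.items())
        for t in times
    ]
    fps.sort(key=lambda fp: (fp.row, fp.col, fp.onset))
    return fps


@dataclass
class SliceAnalysis:
    fps: list[FPEvent]
    rates: np.ndarray
    area_mask: np.ndarray
    region: str
    pop_times: np.ndarray
    events: list
    summaries: dict  # window label -> SliceSummary
    has_ictal: bool  # over the full recording
    has_se: bool
    first_fp_latency: float


def analyze_slice(
    fps: list[FPEvent],
    geometry,
    region_labels: np.ndarray | None,
    cparams: ClassifierParams,
    windows: dict[str, tuple[float, float]],
    full_window: tuple[float, float],
    min_size: int = 4,
    percentile: float = 75.0,
) -> SliceAnalysis:
    """Run map -> area -> population FPs -> classify -> summarize for one slice."""
    rates = compute_map(fps, geometry, full_window)
    mask = select_active_area(rates, region_labels, min_size=min_size, percentile=percentile)
    pop = population_fps(fps, mask, cparams)
    events = segment_and_classify(pop, cparams)
    summaries = {
        label: summarize_slice(fps, events, mask, bounds, label=label, pop_fps=pop)
        for label, bounds in windows.items()
    }
    return SliceAnalysis(
        fps=fps,
        rates=rates,
        area_mask=mask,
        region=area_region(mask, region_labels),
        pop_times=pop,
        events=events,
        summaries=summaries,
        has_ictal=any(e.klass == "ictal" for e in events),
        has_se=any(e.klass == "SE" for e in events),
        first_fp_latency=float(pop.min()) if len(pop) else float("nan"),
    )


# ---------------------------------------------------------------------------
# Pipeline stages (artifact-to-artifact)
# ---------------------------------------------------------------------------


def _log(stage: str, msg: str) -> None:
    print(f"[epimea:{stage}] {msg}", file=sys.stderr)


def _slice_tag(cond: str, i: int) -> str:
    return f"{cond}_{i:03d}"


def _condition_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence((seed, index)).generate_state(1)[0] % (2**31))


def stage_simulate(config: PipelineConfig, out: Path) -> list[Path]:
    """Simulate every configured condition; persist recordings or FP tables."""
    effect = config.effect_model()
    geometry = GEOMETRY_PRESETS[config.geometry]
    artifacts: list[Path] = []
    for k, cond in enumerate(config.conditions):
        eff, timeline = scenario(cond, effect, ictogenic_duration=config.ictogenic_duration)
        trains = simulate_event_trains(
            eff, timeline, geometry, config.n_slices, _condition_seed(config.seed, k)
        )
        for i, train in enumerate(trains):
            tag = _slice_tag(cond, i)
            meta = {
                "condition": cond,
                "slice": i,
                "seed": train.seed,
                "geometry": {
                    "n_rows": geometry.n_rows,
                    "n_cols": geometry.n_cols,
                    "pitch_um": geometry.pitch_um,
                    "sampling_rate": geometry.sampling_rate,
                },
                "ictogenic_duration": timeline.ictogenic_duration,
                "region_labels": train.region_labels.tolist(),
                "injected_area": [list(rc) for rc in train.area],
                "injected_events": [
                    {"class": e.klass, "start": e.start, "end": e.end, "n_fps": e.n_fps}
                    for e in train.events
                ],
            }
            meta_path = out / f"slice_{tag}.json"
            write_json(meta_path, meta)
            artifacts.append(meta_path)
            if config.render:
                rec = render_traces(train, eff, geometry)
                rec_path = out / f"rec_{tag}.h5"
                write_recording(rec_path, rec)
                artifacts.append(rec_path)
            else:
                fp_path = out / f"fps_{tag}.csv"
                write_fp_events(fp_path, trains_to_fp_events(train, eff.fp_template.peak_pos_uv))
                artifacts.append(fp_path)
        _log("simulate", f"{cond}: {config.n_slices} slices")
    return artifacts


def stage_detect(config: PipelineConfig, out: Path) -> list[Path]:
    """Detect FPs on every persisted recording (render mode only)."""
    artifacts: list[Path] = []
    params = config.detector_params()
    for cond in config.conditions:
        for i in range(config.n_slices):
            tag = _slice_tag(cond, i)
            rec_path = out / f"rec_{tag}.h5"
            if not rec_path.exists():
                continue
            rec = read_recording(rec_path)
            fps = detect_fps(rec, params)
            fp_path = out / f"fps_{tag}.csv"
            write_fp_events(fp_path, fps)
            artifacts.append(fp_path)
            _log("detect", f"{tag}: {len(fps)} FPs")
    return artifacts


def _load_meta(out: Path, tag: str) -> dict:
    with open(out / f"slice_{tag}.json") as f:
        return json.load(f)


def stage_map(config: PipelineConfig, out: Path) -> list[Path]:
    """Activity map and most-active-area selection per slice."""
    artifacts: list[Path] = []
    geometry = GEOMETRY_PRESETS[config.geometry]
    for cond in config.conditions:
        for i in range(config.n_slices):
            tag = _slice_tag(cond, i)
            fps = read_fp_events(out / f"fps_{tag}.csv")
            meta = _load_meta(out, tag)
            full = (0.0, float(meta["ictogenic_duration"]))
            labels = np.array(meta["region_labels"], dtype=np.int8)
            rates = compute_map(fps, geometry, full)
            mask = select_active_area(
                rates,
                labels,
                min_size=int(config.activity.get("min_size", 4)),
                percentile=float(config.activity.get("percentile", 75.0)),
            )
            pd.DataFrame(rates).to_csv(out / f"map_{tag}.csv", index=False, header=False,
                                       float_format="%.6f")
            write_area_mask(out / f"area_{tag}.json", mask, area_region(mask, labels))
            artifacts += [out / f"map_{tag}.csv", out / f"area_{tag}.json"]
    _log("map", f"{len(artifacts) // 2} activity maps")
    return artifacts


def stage_classify(config: PipelineConfig, out: Path) -> list[Path]:
    """Population FPs and epileptiform event tables per slice."""
    artifacts: list[Path] = []
    cparams = config.classifier_params()
    for cond in config.conditions:
        for i in range(config.n_slices):
            tag = _slice_tag(cond, i)
            fps = read_fp_events(out / f"fps_{tag}.csv")
            mask, _region = read_area_mask(out / f"area_{tag}.json")
            pop = population_fps(fps, mask, cparams)
            events = segment_and_classify(pop, cparams)
            pd.DataFrame({"time_s": pop}).to_csv(
                out / f"popfps_{tag}.csv", index=False, float_format="%.6f"
            )
            write_events(out / f"events_{tag}.csv", events)
            artifacts += [out / f"popfps_{tag}.csv", out / f"events_{tag}.csv"]
    _log("classify", f"{len(artifacts) // 2} slices classified")
    return artifacts


def stage_summarize(config: PipelineConfig, out: Path) -> list[Path]:
    """Per-slice window summaries and the aggregated group table."""
    from .classify import EpileptiformEvent

    artifacts: list[Path] = []
    windows = config.window_bounds()
    rows = []
    for cond in config.conditions:
        for i in range(config.n_slices):
            tag = _slice_tag(cond, i)
            fps = read_fp_events(out / f"fps_{tag}.csv")
            mask, _ = read_area_mask(out / f"area_{tag}.json")
            pop = pd.read_csv(out / f"popfps_{tag}.csv")["time_s"].to_numpy()
            edf = pd.read_csv(out / f"events_{tag}.csv")
            events = [
                EpileptiformEvent(r.klass, r.start_s, r.end_s, int(r.n_fps), r.mean_freq_hz)
                for r in edf.rename(columns={"class": "klass"}).itertuples(index=False)
            ] if len(edf) else []
            has_ictal = any(e.klass == "ictal" for e in events)
            has_se = any(e.klass == "SE" for e in events)
            slice_summary: dict = {"condition": cond, "slice": i, "windows": {}}
            for label, bounds in windows.items():
                s = summarize_slice(fps, events, mask, bounds, label=label, pop_fps=pop)
                slice_summary["windows"][label] = {
                    "fp_freq": s.fp_freq,
                    "amplitude": s.amplitude,
                    "burst_duration": s.burst_duration,
                    "first_fp_latency": s.first_fp_latency,
                    "has_ictal": s.has_ictal,
                    "has_se": s.has_se,
                }
                rows.append(
                    {
                        "slice_id": tag,
                        "condition": cond,
                        "window": label,
                        "fp_freq": s.fp_freq,
                        "amplitude": s.amplitude,
                        "burst_duration": s.burst_duration,
                        "first_fp_latency": s.first_fp_latency,
                        # incidence flags over the full recording, not the window
                        "has_ictal": has_ictal,
                        "has_se": has_se,
                    }
                )
            spath = out / f"summary_{tag}.json"
            write_json(spath, slice_summary)
            artifacts.append(spath)
    table = pd.DataFrame(rows, columns=list(GROUP_TABLE_COLUMNS))
    tpath = out / "group_table.csv"
    table.to_csv(tpath, index=False, float_format="%.6f")
    artifacts.append(tpath)
    _log("summarize", f"group table: {len(table)} rows")
    return artifacts


def stage_compare(config: PipelineConfig, out: Path) -> list[Path]:
    """Group statistics and the experiment report."""
    table = pd.read_csv(out / "group_table.csv")
    report = experiment_report(table, config.contrasts)
    write_json(out / "report.json", report)
    (out / "report.txt").write_text(report_text(report) + "\n")
    _log("compare", f"{len(config.contrasts)} contrasts")
    return [out / "report.json", out / "report.txt"]


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

_STAGES = (
    ("simulate", stage_simulate),
    ("detect", stage_detect),
    ("map", stage_map),
    ("classify", stage_classify),
    ("summarize", stage_summarize),
    ("compare", stage_compare),
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return the manifest (also persisted as manifest.json)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config_resolved.yaml")
    artifacts: list[Path] = [out / "config_resolved.yaml"]
    for name, stage in _STAGES:
        try:
            artifacts += stage(config, out)
        except Exception as e:  # noqa: BLE001 - annotate and re-raise
            raise StageError(name, out, e) from e
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "artifacts": {
            str(p.relative_to(out)): {"sha256": _sha256(p), "bytes": p.stat().st_size}
            for p in artifacts
        },
    }
    write_json(out / "manifest.json", manifest)
    return manifest
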