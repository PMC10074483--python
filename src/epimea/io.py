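"""Persistence: HDF5 recording container, CSV event tables, JSON artifacts.

The recording container stores /traces (electrodes x samples, float32 uV),
/region_labels (int8 grid), and the ground-truth event tables, with geometry,
timeline and seed as attributes. Round-trips are lossless for metadata and
event tables (traces are float32 on both sides).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .classify import EpileptiformEvent
from .conditions import ArrayGeometry, ConditionTimeline, Phase
from .detect import FPEvent
from .simulate import GroundTruthEvent, Recording, SliceTrain

__all__ = [
    "write_recording",
    "read_recording",
    "fp_events_to_frame",
    "frame_to_fp_events",
    "write_fp_events",
    "read_fp_events",
    "events_to_frame",
    "write_events",
    "write_area_mask",
    "read_area_mask",
    "write_json",
]

FP_CSV_COLUMNS = ("electrode_row", "electrode_col", "onset_s", "duration_s", "amplitude_uV")
EVENT_CSV_COLUMNS = ("class", "start_s", "end_s", "n_fps", "mean_freq_hz")


# ---------------------------------------------------------------------------
# Timeline (de)serialization
# ---------------------------------------------------------------------------


def timeline_to_dict(timeline: ConditionTimeline) -> list[dict]:
    return [
        {"label": p.label, "duration": p.duration, "drugs": list(p.drugs)}
        for p in timeline.phases
    ]


def timeline_from_dict(data: list[dict]) -> ConditionTimeline:
    return ConditionTimeline(
        tuple(Phase(p["label"], float(p["duration"]), tuple(p.get("drugs", ()))) for p in data)
    )


# ---------------------------------------------------------------------------
# HDF5 recording container
# ---------------------------------------------------------------------------


def write_recording(path: str | Path, recording: Recording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=recording.traces, track_times=False)
        f.create_dataset(
            "region_labels", data=recording.region_labels.astype(np.int8), track_times=False
        )
        g = recording.geometry
        f.attrs["n_rows"] = g.n_rows
        f.attrs["n_cols"] = g.n_cols
        f.attrs["pitch_um"] = g.pitch_um
        f.attrs["sampling_rate"] = g.sampling_rate
        f.attrs["seed"] = recording.seed
        f.attrs["timeline"] = json.dumps(timeline_to_dict(recording.timeline))
        gt = recording.ground_truth
        if gt is not None:
            grp = f.create_group("ground_truth")
            grp.attrs["region"] = gt.region
            grp.create_dataset(
                "area", data=np.array(gt.area, dtype=np.int32).reshape(-1, 2), track_times=False
            )
            grp.create_dataset("background_times", data=gt.background_times, track_times=False)
            klass = np.array([e.klass for e in gt.events], dtype="S10")
            grp.create_dataset("event_class", data=klass, track_times=False)
            grp.create_dataset(
                "event_span",
                data=np.array([[e.start, e.end] for e in gt.events]).reshape(-1, 2),
                track_times=False,
            )
            pop_rows = [
                (i, t) for i, e in enumerate(gt.events) for t in e.pop_times
            ]
            grp.create_dataset(
                "event_fps", data=np.array(pop_rows, dtype=float).reshape(-1, 2), track_times=False
            )
            fp_rows = [
                (r, c, t) for (r, c), times in sorted(gt.fp_times.items()) for t in times
            ]
            grp.create_dataset(
                "electrode_fps",
                data=np.array(fp_rows, dtype=float).reshape(-1, 3),
                track_times=False,
            )


def read_recording(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        geometry = ArrayGeometry(
            n_rows=int(f.attrs["n_rows"]),
            n_cols=int(f.attrs["n_cols"]),
            pitch_um=float(f.attrs["pitch_um"]),
            sampling_rate=float(f.attrs["sampling_rate"]),
        )
        timeline = timeline_from_dict(json.loads(f.attrs["timeline"]))
        seed = int(f.attrs["seed"])
        traces = f["traces"][()]
        region_labels = f["region_labels"][()]
        ground_truth = None
        if "ground_truth" in f:
            grp = f["ground_truth"]
            area = [tuple(map(int, rc)) for rc in grp["area"][()]]
            event_fps = grp["event_fps"][()]
            events = []
            for i, (klass, (start, end)) in enumerate(
                zip(grp["event_class"][()], grp["event_span"][()])
            ):
                times = event_fps[event_fps[:, 0] == i, 1]
                events.append(
                    GroundTruthEvent(klass.decode(), float(start), float(end), times)
                )
            fp_times: dict[tuple[int, int], list[float]] = {}
            for r, c, t in grp["electrode_fps"][()]:
                fp_times.setdefault((int(r), int(c)), []).append(float(t))
            ground_truth = SliceTrain(
                geometry=geometry,
                timeline=timeline,
                seed=seed,
                area=area,
                region=grp.attrs["region"],
                region_labels=region_labels,
                events=events,
                background_times=grp["background_times"][()],
                fp_times={k: np.array(v) for k, v in fp_times.items()},
            )
    return Recording(
        geometry=geometry,
        traces=traces,
        region_labels=region_labels,
        timeline=timeline,
        seed=seed,
        ground_truth=ground_truth,
    )


# ---------------------------------------------------------------------------
# FP / event tables
# ---------------------------------------------------------------------------


def fp_events_to_frame(fps: list[FPEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(fp.row, fp.col, fp.onset, fp.duration, fp.amplitude) for fp in fps],
        columns=list(FP_CSV_COLUMNS),
    )


def frame_to_fp_events(frame: pd.DataFrame) -> list[FPEvent]:
    return [
        FPEvent(int(r.electrode_row), int(r.electrode_col), float(r.onset_s),
                float(r.duration_s), float(r.amplitude_uV))
        for r in frame.itertuples(index=False)
    ]


def write_fp_events(path: str | Path, fps: list[FPEvent]) -> None:
    fp_events_to_frame(fps).to_csv(path, index=False, float_format="%.6f")


def read_fp_events(path: str | Path) -> list[FPEvent]:
    return frame_to_fp_events(pd.read_csv(path))


def events_to_frame(events: list[EpileptiformEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.klass, e.start, e.end, e.n_fps, e.mean_freq) for e in events],
        columns=list(EVENT_CSV_COLUMNS),
    )


def write_events(path: str | Path, events: list[EpileptiformEvent]) -> None:
    events_to_frame(events).to_csv(path, index=False, float_format="%.6f")


def write_area_mask(path: str | Path, mask: np.ndarray, region: str = "unknown") -> None:
    coords = [[int(r), int(c)] for r, c in zip(*np.nonzero(mask))]
    write_json(path, {"shape": list(mask.shape), "region": region, "electrodes": coords})


def read_area_mask(path: str | Path) -> tuple[np.ndarray, str]:
    with open(path) as f:
        data = json.load(f)
    mask = np.zeros(tuple(data["shape"]), dtype=bool)
    for r, c in data["electrodes"]:
        mask[r, c] = True
    return mask, data.get("region", "unknown")


def write_json(path: str | Path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as f:
        json.dump(obj, f, indent=2, sort_keys=True, default=_default)
        f.write("\n")
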