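"""Population-discharge aggregation and epileptiform event classification.

Per-electrode FPs inside the active area are clustered into population FPs
(coincidence window + minimum fraction of area electrodes), then segmented
into discharges at gaps above ``burst_max_gap`` and classified:

* **SE-like**: duration above ``se_min_duration`` with mean frequency inside
  [``se_freq_low``, ``se_freq_high``] (0.8-1.3 Hz, > 5 min by default) —
  takes precedence over ictal where both hold;
* **ictal**: duration above ``ictal_min_duration`` (5 s) with mean frequency
  above ``ictal_min_freq`` (1 Hz);
* **burst**: a short discharge of at least ``burst_min_fps`` (3) FPs with
  inter-FP gaps <= 1 s — reported as its own class, understood as a
  sub-label of interictal activity;
* **interictal**: everything else (single or few synchronous FPs, < 5 s).

Mean frequency uses the inter-event-interval convention (n-1)/span, exact
for periodic trains.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .detect import FPEvent

__all__ = [
    "ClassifierParams",
    "EpileptiformEvent",
    "SliceSummary",
    "T1_WINDOW",
    "T2_WINDOW",
    "population_fps",
    "segment_and_classify",
    "summarize_slice",
]

#: Analysis windows, seconds from the start of the ictogenic perfusion.
T1_WINDOW = (0.0, 600.0)
T2_WINDOW = (1200.0, 1800.0)


@dataclass(frozen=True)
class ClassifierParams:
    coincidence_window: float = 0.020  # s, cross-electrode synchrony
    min_sync_fraction: float = 0.25  # fraction of area electrodes per population FP
    burst_min_fps: int = 3
    burst_max_gap: float = 1.0  # s, also the discharge segmentation gap
    ictal_min_duration: float = 5.0  # s
    ictal_min_freq: float = 1.0  # Hz
    se_freq_low: float = 0.8  # Hz
    se_freq_high: float = 1.3  # Hz
    se_min_duration: float = 300.0  # s

    def __post_init__(self) -> None:
        if not self.se_freq_low < self.se_freq_high:
            raise ValueError("need se_freq_low < se_freq_high")
        if not self.ictal_min_duration < self.se_min_duration:
            raise ValueError("need ictal_min_duration < se_min_duration")
        vals = (
            self.coincidence_window,
            self.min_sync_fraction,
            self.burst_min_fps,
            self.burst_max_gap,
            self.ictal_min_duration,
            self.ictal_min_freq,
            self.se_freq_low,
        )
        if min(vals) <= 0:
            raise ValueError("classifier parameters must be positive")


@dataclass(frozen=True)
class EpileptiformEvent:
    klass: str  # "interictal" | "burst" | "ictal" | "SE"
    start: float
    end: float
    n_fps: int
    mean_freq: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def is_interictal(self) -> bool:
        """Bursts are interictal-scale activity; ictal/SE are not."""
        return self.klass in ("interictal", "burst")


@dataclass(frozen=True)
class SliceSummary:
    """Active-area metrics of one slice over one analysis window."""

    window: str  # "T1" | "T2" | custom
    window_start: float
    window_end: float
    fp_freq: float  # Hz, mean over active-area electrodes
    amplitude: float  # uV, mean FP amplitude in the window (nan if no FPs)
    burst_duration: float  # s, mean over burst events overlapping (nan if none)
    first_fp_latency: float  # s from perfusion start (nan if silent slice)
    has_ictal: bool
    has_se: bool


def population_fps(
    fps: list[FPEvent],
    area: set[tuple[int, int]] | list[tuple[int, int]] | np.ndarray,
    params: ClassifierParams | None = None,
) -> np.ndarray:
    """Cluster active-area FP onsets into population FP times.

    Greedy in time: starting from the earliest unassigned onset, all onsets
    within one coincidence window form a candidate; it becomes a population
    FP (timed at its earliest member) when FPs from at least
    ``min_sync_fraction`` of area electrodes participate. Each FP belongs to
    at most one population FP; failed seeds are discarded one at a time.
    """
    params = params or ClassifierParams()
    if isinstance(area, np.ndarray):
        area_set = {(int(r), int(c)) for r, c in zip(*np.nonzero(area))}
    else:
        area_set = set(area)
    if not area_set:
        raise ValueError("active area is empty")
    need = max(1, ceil(params.min_sync_fraction * len(area_set) - 1e-9))

    members = [(fp.onset, fp.electrode) for fp in fps if fp.electrode in area_set]
    members.sort()
    onsets = np.array([m[0] for m in members])
    electrodes = [m[1] for m in members]

    out: list[float] = []
    i = 0
    n = len(members)
    while i < n:
        j = int(np.searchsorted(onsets, onsets[i] + params.coincidence_window, "right"))
        if len(set(electrodes[i:j])) >= need:
            out.append(float(onsets[i]))
            i = j
        else:
            i += 1
    return np.asarray(out)


def _classify(duration: float, n: int, freq: float, p: ClassifierParams) -> str:
    if duration > p.se_min_duration and p.se_freq_low <= freq <= p.se_freq_high:
        return "SE"
    if duration > p.ictal_min_duration and freq > p.ictal_min_freq:
        return "ictal"
    if n >= p.burst_min_fps:
        return "burst"
    return "interictal"


def segment_and_classify(
    pop_fps: np.ndarray | list[float], params: ClassifierParams | None = None
) -> list[EpileptiformEvent]:
    """Segment sorted population FP times into discharges and classify them.

    Consecutive FPs with gaps <= ``burst_max_gap`` belong to one discharge;
    every population FP is covered by exactly one event.
    """
    params = params or ClassifierParams()
    times = np.asarray(pop_fps, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("population FP times must be sorted")
    events: list[EpileptiformEvent] = []
    if times.size == 0:
        return events
    breaks = np.flatnonzero(np.diff(times) > params.burst_max_gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [times.size - 1]])
    for a, b in zip(starts, ends):
        seg = times[a : b + 1]
        n = len(seg)
        start, end = float(seg[0]), float(seg[-1])
        freq = (n - 1) / (end - start) if n >= 2 and end > start else 0.0
        events.append(
            EpileptiformEvent(_classify(end - start, n, freq, params), start, end, n, freq)
        )
    return events


def _overlaps(ev: EpileptiformEvent, t0: float, t1: float) -> bool:
    # events straddling a boundary count in every window they touch
    return ev.start < t1 and ev.end >= t0


def summarize_slice(
    fps: list[FPEvent],
    events: list[EpileptiformEvent],
    area: set[tuple[int, int]] | list[tuple[int, int]] | np.ndarray,
    window: tuple[float, float],
    label: str = "",
    pop_fps: np.ndarray | None = None,
) -> SliceSummary:
    """Active-area metrics over one half-open analysis window [t0, t1).

    ``fp_freq`` averages per-electrode FP counts over *all* area electrodes
    (silent ones included); ``first_fp_latency`` is the earliest population
    FP of the whole recording, not window-restricted.
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must have positive length")
    if isinstance(area, np.ndarray):
        area_set = {(int(r), int(c)) for r, c in zip(*np.nonzero(area))}
    else:
        area_set = set(area)
    if not area_set:
        raise ValueError("active area is empty")

    in_area = [fp for fp in fps if fp.electrode in area_set]
    in_win = [fp for fp in in_area if t0 <= fp.onset < t1]
    counts = {e: 0 for e in area_set}
    for fp in in_win:
        counts[fp.electrode] += 1
    fp_freq = float(np.mean([c / (t1 - t0) for c in counts.values()]))
    amplitude = float(np.mean([fp.amplitude for fp in in_win])) if in_win else float("nan")

    bursts = [ev for ev in events if ev.klass == "burst" and _overlaps(ev, t0, t1)]
    burst_duration = float(np.mean([ev.duration for ev in bursts])) if bursts else float("nan")

    if pop_fps is not None and len(pop_fps):
        latency = float(np.min(pop_fps))
    elif events:
        latency = min(ev.start for ev in events)
    elif in_area:
        latency = min(fp.onset for fp in in_area)
    else:
        latency = float("nan")

    return SliceSummary(
        window=label or f"[{t0:g},{t1:g})",
        window_start=t0,
        window_end=t1,
        fp_freq=fp_freq,
        amplitude=amplitude,
        burst_duration=burst_duration,
        first_fp_latency=latency,
        has_ictal=any(ev.klass == "ictal" and _overlaps(ev, t0, t1) for ev in events),
        has_se=any(ev.klass == "SE" and _overlaps(ev, t0, t1) for ev in events),
    )
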