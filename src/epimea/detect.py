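"""Per-electrode field-potential detection by threshold crossing.

Detector semantics (the parameter defaults replicate the acquisition
software settings used for the slice recordings):

* an event opens at the first sample crossing above ``high_threshold`` or
  below ``low_threshold``;
* further crossings within ``energy_window`` of the last crossing extend the
  event, capped at ``max_wave_duration`` from onset — a crossing beyond the
  cap seeds a new event;
* a new event may not open within ``refractory`` of the previous onset;
* amplitude is max |v| over the event span; onset is the first crossing;
* events still open at the end of the trace are closed there and kept.

The "energy window" is read as a merge horizon (crossings within the window
belong to the same event); the acquisition software's exact semantics are
unpublished, so this reading is isolated behind :class:`DetectorParams`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import Recording

__all__ = ["DetectorParams", "FPEvent", "detect_fps", "detect_trace"]


@dataclass(frozen=True)
class DetectorParams:
    high_threshold: float = 200.0  # uV
    low_threshold: float = -200.0  # uV
    energy_window_ms: float = 40.0
    refractory_ms: float = 5.0
    max_wave_duration_ms: float = 500.0

    def __post_init__(self) -> None:
        if not (self.high_threshold > 0 > self.low_threshold):
            raise ValueError("need high_threshold > 0 > low_threshold")
        if min(self.energy_window_ms, self.refractory_ms, self.max_wave_duration_ms) <= 0:
            raise ValueError("window, refractory and max duration must be positive")
        if not (self.refractory_ms < self.energy_window_ms < self.max_wave_duration_ms):
            raise ValueError("need refractory < energy_window < max_wave_duration")

    def in_samples(self, sampling_rate: float) -> tuple[int, int, int]:
        to_s = lambda ms: max(1, int(round(ms * sampling_rate / 1000.0)))
        return (
            to_s(self.energy_window_ms),
            to_s(self.refractory_ms),
            to_s(self.max_wave_duration_ms),
        )


@dataclass(frozen=True)
class FPEvent:
    """One detected field potential on one electrode."""

    row: int
    col: int
    onset: float  # s, first threshold crossing
    duration: float  # s, onset to last crossing
    amplitude: float  # uV, max |v| over the span

    @property
    def electrode(self) -> tuple[int, int]:
        return (self.row, self.col)


def detect_trace(
    v: np.ndarray,
    sampling_rate: float,
    params: DetectorParams,
    row: int = 0,
    col: int = 0,
) -> list[FPEvent]:
    """Detect FPs on a single voltage trace (vectorised crossing scan)."""
    v = np.asarray(v, dtype=float)
    if np.isnan(v).any():
        raise ValueError(f"NaN sample in trace of electrode ({row}, {col})")
    ew, ref, cap = params.in_samples(sampling_rate)
    crossings = np.flatnonzero((v > params.high_threshold) | (v < params.low_threshold))
    events: list[FPEvent] = []
    last_onset = -ref - 1
    onset = -1
    last = -1

    def emit(o: int, l: int) -> None:
        amp = float(np.max(np.abs(v[o : l + 1])))
        events.append(
            FPEvent(row, col, o / sampling_rate, (l - o) / sampling_rate, amp)
        )

    for c in crossings:
        c = int(c)
        if onset >= 0:
            if c - onset <= cap and c - last <= ew:
                last = c
                continue
            emit(onset, last)
            last_onset = onset
            onset = -1
        if c - last_onset >= ref:
            onset = c
            last = c
    if onset >= 0:
        emit(onset, last)
    return events


def detect_fps(recording: Recording, params: DetectorParams | None = None) -> list[FPEvent]:
    """Detect FPs on every electrode; output sorted by (electrode, onset)."""
    params = params or DetectorParams()
    geom = recording.geometry
    fs = geom.sampling_rate
    events: list[FPEvent] = []
    for idx in range(recording.traces.shape[0]):
        trace = recording.traces[idx]
        r, c = divmod(idx, geom.n_cols)
        events.extend(detect_trace(trace, fs, params, row=r, col=c))
    return events
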