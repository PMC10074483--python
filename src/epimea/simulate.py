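"""Synthetic MEA slice recordings with known ground truth.

The generator realizes the condition structure of the slice experiment as a
semi-Markov point process over the ictogenic phase: a background of sparse
interictal population FPs (homogeneous Poisson), plus non-overlapping
episodes — bursts (>= 3 FPs, inter-FP gaps <= 1 s), ictal discharges
(> 5 s at > 1 Hz) and SE-like discharges (0.8-1.3 Hz sustained beyond the
SE minimum duration). LPS multiplies rates and burst durations and shifts
the slice toward the SE regime; drugs scale rates by (1 - efficacy);
immunomodulators silence all activity before their onset delay.

Every population FP is assigned to all electrodes of one contiguous k x k
"active area" cluster with small per-electrode jitter, mirroring how the
most active slice region dominates the recorded discharge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .conditions import ArrayGeometry, ConditionTimeline, EffectModel

__all__ = [
    "GroundTruthEvent",
    "SliceTrain",
    "Recording",
    "simulate_event_trains",
    "render_traces",
    "fp_template_waveform",
]

REGION_CODES = {"off_slice": 0, "HPC": 1, "CTX": 2}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}

# Margin (s) kept clear of episode boundaries when placing background FPs and
# neighbouring episodes, so discharges never merge across the 1 s
# segmentation gap used downstream.
_EPISODE_MARGIN = 1.5
_EPISODE_SPACING = 3.0


@dataclass(frozen=True)
class GroundTruthEvent:
    """One injected episode: class, span, and its population FP times."""

    klass: str  # "burst" | "ictal" | "SE"
    start: float
    end: float
    pop_times: np.ndarray

    @property
    def n_fps(self) -> int:
        return len(self.pop_times)

    @property
    def mean_freq(self) -> float:
        if self.n_fps < 2 or self.end <= self.start:
            return 0.0
        return (self.n_fps - 1) / (self.end - self.start)


@dataclass
class SliceTrain:
    """Ground-truth event trains for one simulated slice."""

    geometry: ArrayGeometry
    timeline: ConditionTimeline
    seed: int
    area: list[tuple[int, int]]
    region: str
    region_labels: np.ndarray  # (n_rows, n_cols) int8, REGION_CODES
    events: list[GroundTruthEvent]
    background_times: np.ndarray
    fp_times: dict[tuple[int, int], np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def pop_times(self) -> np.ndarray:
        parts = [self.background_times] + [e.pop_times for e in self.events]
        return np.sort(np.concatenate(parts)) if parts else np.empty(0)

    @property
    def n_fps(self) -> int:
        return len(self.background_times) + sum(e.n_fps for e in self.events)

    def area_mask(self) -> np.ndarray:
        mask = np.zeros((self.geometry.n_rows, self.geometry.n_cols), dtype=bool)
        for r, c in self.area:
            mask[r, c] = True
        return mask


@dataclass
class Recording:
    """Voltage traces on the electrode grid for the ictogenic phase."""

    geometry: ArrayGeometry
    traces: np.ndarray  # (n_electrodes, n_samples) float32 uV, row-major grid
    region_labels: np.ndarray  # (n_rows, n_cols) int8
    timeline: ConditionTimeline
    seed: int
    ground_truth: SliceTrain | None = None

    @property
    def duration(self) -> float:
        return self.traces.shape[1] / self.geometry.sampling_rate


# ---------------------------------------------------------------------------
# Event-train simulation
# ---------------------------------------------------------------------------


def _make_region_labels(geometry: ArrayGeometry) -> np.ndarray:
    """Left half HPC, right half CTX, one off-slice border ring."""
    labels = np.zeros((geometry.n_rows, geometry.n_cols), dtype=np.int8)
    labels[1:-1, 1 : geometry.n_cols // 2] = REGION_CODES["HPC"]
    labels[1:-1, geometry.n_cols // 2 : -1] = REGION_CODES["CTX"]
    return labels


def _place_area(
    rng: np.random.Generator, geometry: ArrayGeometry, labels: np.ndarray, k: int
) -> tuple[list[tuple[int, int]], str]:
    region = "HPC" if rng.random() < 0.5 else "CTX"
    code = REGION_CODES[region]
    rows, cols = np.nonzero(labels == code)
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    k = min(k, r1 - r0 + 1, c1 - c0 + 1)
    r = int(rng.integers(r0, r1 - k + 2))
    c = int(rng.integers(c0, c1 - k + 2))
    return [(r + i, c + j) for i in range(k) for j in range(k)], region


def _periodic_train(
    rng: np.random.Generator, start: float, duration: float, freq: float
) -> np.ndarray:
    """Near-periodic FP train at `freq` spanning about `duration` seconds."""
    n = max(2, int(round(duration * freq)) + 1)
    times = start + np.arange(n) / freq
    jitter = rng.uniform(-0.01, 0.01, size=n)
    jitter[0] = 0.0
    return times + jitter


def _draw_episodes(
    rng: np.random.Generator,
    effect: EffectModel,
    lps: bool,
    regime: str,
    T: float,
    t0: float,
    rate_factor: float,
) -> list[GroundTruthEvent]:
    """Draw non-overlapping episodes within [t0, T]."""
    proposals: list[tuple[str, float]] = []  # (class, duration)

    if regime == "se":
        factor = rng.uniform(*effect.se_duration_factor_range)
        proposals.append(("SE", effect.se_min_duration * factor))
    elif regime == "ictal":
        n_ictal = max(1, rng.poisson(effect.ictal_episode_rate * (T - t0)))
        for _ in range(n_ictal):
            proposals.append(("ictal", rng.uniform(*effect.ictal_duration_range)))

    burst_mult = effect.lps_burst_duration_multiplier if lps else 1.0
    n_bursts = rng.poisson(effect.burst_rate * rate_factor * (T - t0))
    lo, hi = effect.burst_gap_range
    mean_gap = 0.5 * (lo + hi)
    for _ in range(n_bursts):
        dur = min(rng.exponential(effect.burst_mean_duration * burst_mult), effect.burst_max_duration)
        dur = max(dur, 2 * mean_gap)  # at least 3 FPs
        proposals.append(("burst", dur))

    # Sequential placement with spacing; drop proposals that no longer fit.
    events: list[GroundTruthEvent] = []
    occupied: list[tuple[float, float]] = []
    for klass, dur in proposals:
        if dur > T - t0:
            continue
        placed = False
        for _attempt in range(40):
            s = rng.uniform(t0, T - dur)
            e = s + dur
            if all(
                e + _EPISODE_SPACING < a or s - _EPISODE_SPACING > b for a, b in occupied
            ):
                placed = True
                break
        if not placed:
            continue
        occupied.append((s, e))
        if klass == "SE":
            freq = rng.uniform(*effect.se_freq_range)
            times = _periodic_train(rng, s, dur, freq)
        elif klass == "ictal":
            freq = rng.uniform(*effect.ictal_freq_range)
            times = _periodic_train(rng, s, dur, freq)
        else:
            gaps = [rng.uniform(lo, hi)]
            while sum(gaps) < dur - hi:
                gaps.append(rng.uniform(lo, hi))
            if len(gaps) < 2:
                gaps.append(rng.uniform(lo, hi))
            times = s + np.concatenate([[0.0], np.cumsum(gaps)])
        events.append(GroundTruthEvent(klass, float(times[0]), float(times[-1]), times))
    events.sort(key=lambda e: e.start)
    return events


def simulate_event_trains(
    effect: EffectModel,
    timeline: ConditionTimeline,
    geometry: ArrayGeometry,
    n_slices: int,
    seed: int,
) -> list[SliceTrain]:
    """Simulate ground-truth event trains for ``n_slices`` slices.

    Deterministic given ``seed``; per-slice substreams are spawned from the
    global seed, so increasing ``n_slices`` leaves earlier slices unchanged.
    """
    effect.validate()
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    lps = timeline.has_lps
    drugs = timeline.active_drugs
    T = timeline.ictogenic_duration
    t0 = effect.onset_delay(drugs)
    rate_factor = effect.rate_factor(lps, drugs)
    p_ictal, p_se = effect.episode_probs(lps, drugs)
    if p_se > 0 and t0 + effect.se_min_duration * effect.se_duration_factor_range[0] > T:
        raise ValueError(
            "ictogenic phase too short to hold an SE episode; lower se_min_duration "
            "or set p_se to 0"
        )

    children = np.random.SeedSequence(seed).spawn(n_slices)
    slices: list[SliceTrain] = []
    for child in children:
        slice_seed = int(child.generate_state(1)[0])
        rng = np.random.Generator(np.random.PCG64(child))
        labels = _make_region_labels(geometry)
        area, region = _place_area(rng, geometry, labels, effect.active_area_size)

        u = rng.random()
        if u < p_se:
            regime = "se"
        elif u < p_se + p_ictal:
            regime = "ictal"
        else:
            regime = "background"

        events = (
            _draw_episodes(rng, effect, lps, regime, T, t0, rate_factor)
            if T > t0
            else []
        )

        bg_rate = effect.base_fp_rate * rate_factor
        if bg_rate > 0 and T > t0:
            n_bg = rng.poisson(bg_rate * (T - t0))
            bg = np.sort(rng.uniform(t0, T, size=n_bg))
            for ev in events:
                bg = bg[(bg < ev.start - _EPISODE_MARGIN) | (bg > ev.end + _EPISODE_MARGIN)]
        else:
            bg = np.empty(0)

        pop = np.sort(np.concatenate([bg] + [e.pop_times for e in events]))
        fp_times = {
            (r, c): np.sort(pop + rng.uniform(0.0, effect.electrode_jitter, size=pop.size))
            for (r, c) in area
        }
        slices.append(
            SliceTrain(
                geometry=geometry,
                timeline=timeline,
                seed=slice_seed,
                area=area,
                region=region,
                region_labels=labels,
                events=events,
                background_times=bg,
                fp_times=fp_times,
            )
        )
    return slices


# ---------------------------------------------------------------------------
# Trace rendering
# ---------------------------------------------------------------------------


def fp_template_waveform(template, sampling_rate: float) -> np.ndarray:
    """Sampled biphasic waveform: positive half-sine lobe then negative lobe."""
    n = max(4, int(round(template.width_ms * sampling_rate / 1000.0)))
    half = n // 2

    def lobe(n_samples: int, peak: float) -> np.ndarray:
        x = np.sin(np.pi * np.arange(n_samples) / max(n_samples - 1, 1))
        return peak * x / x.max()  # hit the exact peak on any sample grid

    return np.concatenate(
        [lobe(half, template.peak_pos_uv), lobe(n - half, template.peak_neg_uv)]
    ).astype(np.float32)


def render_traces(
    train: SliceTrain,
    effect: EffectModel,
    geometry: ArrayGeometry | None = None,
    detector_high_threshold: float = 200.0,
) -> Recording:
    """Render one slice's event trains into noisy voltage traces.

    Superimposes the FP template at each ground-truth FP time on its assigned
    electrode and adds i.i.d. Gaussian noise with ``effect.noise_sd``.
    """
    effect.validate(detector_high_threshold)
    if effect.fp_template.width_ms > 500.0:
        warnings.warn(
            "FP template wider than the 500 ms maximum wave duration; "
            "single injected FPs will split into multiple detections",
            stacklevel=2,
        )
    geometry = geometry or train.geometry
    fs = geometry.sampling_rate
    n_samples = int(round(train.timeline.ictogenic_duration * fs))
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([train.seed, 0xA5])))
    if effect.noise_sd > 0:
        traces = rng.normal(0.0, effect.noise_sd, size=(geometry.n_electrodes, n_samples))
        traces = traces.astype(np.float32)
    else:
        traces = np.zeros((geometry.n_electrodes, n_samples), dtype=np.float32)

    wave = fp_template_waveform(effect.fp_template, fs)
    w = len(wave)
    for (r, c), times in train.fp_times.items():
        idx = r * geometry.n_cols + c
        starts = np.round(times * fs).astype(int)
        for s in starts:
            if s >= n_samples:
                continue
            e = min(s + w, n_samples)
            traces[idx, s:e] += wave[: e - s]
    return Recording(
        geometry=geometry,
        traces=traces,
        region_labels=train.region_labels,
        timeline=train.timeline,
        seed=train.seed,
        ground_truth=train,
    )
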