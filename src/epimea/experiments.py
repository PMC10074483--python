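"""Replicate in-silico experiments at the protocol scale.

These helpers run the full event-level analysis chain (simulate trains ->
activity map -> most-active-area -> population FPs -> classify -> summarize)
for whole slice groups, without trace rendering, which is exact at the event
level; they back the group-statistics examples and the reproduction of the
condition-effect structure (LPS exacerbation, ASM resistance, delayed onset
under immunomodulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import ClassifierParams, T1_WINDOW, T2_WINDOW
from .conditions import DESK_GEOMETRY, ArrayGeometry, EffectModel, scenario
from .pipeline import SliceAnalysis, analyze_slice, trains_to_fp_events
from .simulate import simulate_event_trains

__all__ = ["GroupResult", "run_condition_group", "replicate_direction_rates"]


@dataclass
class GroupResult:
    condition: str
    analyses: list[SliceAnalysis]

    def mean_fp_freq(self, window: str = "T2") -> float:
        return float(np.mean([a.summaries[window].fp_freq for a in self.analyses]))

    def se_flags(self) -> list[bool]:
        return [a.has_se for a in self.analyses]

    def ictal_or_se_flags(self) -> list[bool]:
        return [a.has_ictal or a.has_se for a in self.analyses]

    def mean_latency(self) -> float:
        return float(np.nanmean([a.first_fp_latency for a in self.analyses]))


def run_condition_group(
    condition: str,
    n_slices: int,
    seed: int,
    effect: EffectModel | None = None,
    geometry: ArrayGeometry = DESK_GEOMETRY,
    ictogenic_duration: float = 2400.0,
    windows: dict[str, tuple[float, float]] | None = None,
) -> GroupResult:
    """Simulate and analyze one slice group under a named condition."""
    eff, timeline = scenario(condition, effect, ictogenic_duration=ictogenic_duration)
    cparams = ClassifierParams(se_min_duration=eff.se_min_duration)
    windows = windows or {"T1": T1_WINDOW, "T2": T2_WINDOW}
    trains = simulate_event_trains(eff, timeline, geometry, n_slices, seed)
    analyses = [
        analyze_slice(
            trains_to_fp_events(t, eff.fp_template.peak_pos_uv),
            geometry,
            t.region_labels,
            cparams,
            windows,
            (0.0, timeline.ictogenic_duration),
        )
        for t in trains
    ]
    return GroupResult(condition, analyses)


def replicate_direction_rates(
    n_replicates: int = 50,
    n_slices: int = 10,
    seed: int = 0,
    n_immuno: int = 6,
) -> dict[str, float]:
    """Fraction of replicate experiments reproducing each effect direction.

    Each replicate draws fresh control ("0mg_4ap"), LPS ("lps_0mg_4ap") and
    anakinra ("lps_0mg_4ap_anakinra") groups and compares group means / SE
    counts. Returns the fraction of replicates in which the LPS group shows
    strictly higher mean FP frequency, strictly more SE-positive slices, and
    the immunomodulator group strictly later first-FP onset than LPS alone.
    """
    root = np.random.SeedSequence(seed)
    seeds = root.generate_state(3 * n_replicates) % (2**31)
    freq_hits = se_hits = latency_hits = 0
    for r in range(n_replicates):
        ctrl = run_condition_group("0mg_4ap", n_slices, int(seeds[3 * r]))
        lps = run_condition_group("lps_0mg_4ap", n_slices, int(seeds[3 * r + 1]))
        imm = run_condition_group("lps_0mg_4ap_anakinra", n_immuno, int(seeds[3 * r + 2]))
        freq_hits += lps.mean_fp_freq("T2") > ctrl.mean_fp_freq("T2")
        se_hits += sum(lps.se_flags()) > sum(ctrl.se_flags())
        latency_hits += imm.mean_latency() > lps.mean_latency()
    return {
        "fp_freq_lps_higher": freq_hits / n_replicates,
        "se_incidence_lps_higher": se_hits / n_replicates,
        "latency_immunomodulator_delayed": latency_hits / n_replicates,
    }
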