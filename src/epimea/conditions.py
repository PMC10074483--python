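"""Experimental conditions: array geometry, perfusion timelines, effect models.

These types describe the acute-slice MEA experiment being emulated: a
hippocampal/temporal-cortex slice on a high-density CMOS array, pre-incubated
in aCSF or in LPS (the neuroinflammatory challenge), then perfused with the
ictogenic cocktail (0 Mg2+ + 100 uM 4-AP) with or without an antiseizure
medication or an immunomodulatory drug.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ArrayGeometry",
    "PAPER_GEOMETRY",
    "DESK_GEOMETRY",
    "TINY_GEOMETRY",
    "GEOMETRY_PRESETS",
    "Phase",
    "ConditionTimeline",
    "protocol",
    "FPTemplate",
    "EffectModel",
    "desk_effect_model",
    "SCENARIOS",
    "scenario",
    "scenario_names",
]

# ---------------------------------------------------------------------------
# Array geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArrayGeometry:
    """Electrode grid layout and sampling rate.

    Defaults replicate the BioCamX chip: 64 x 64 electrodes on a 21 um pitch
    sampled at 10 kHz per channel.
    """

    n_rows: int = 64
    n_cols: int = 64
    pitch_um: float = 21.0
    sampling_rate: float = 10_000.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols


PAPER_GEOMETRY = ArrayGeometry()
#: Desk-scale preset: identical downstream logic at a fraction of the cost.
DESK_GEOMETRY = ArrayGeometry(n_rows=16, n_cols=16, pitch_um=21.0, sampling_rate=1_000.0)
TINY_GEOMETRY = ArrayGeometry(n_rows=8, n_cols=8, pitch_um=21.0, sampling_rate=500.0)

GEOMETRY_PRESETS = {"paper": PAPER_GEOMETRY, "desk": DESK_GEOMETRY, "tiny": TINY_GEOMETRY}


# ---------------------------------------------------------------------------
# Perfusion timeline
# ---------------------------------------------------------------------------

PHASE_LABELS = (
    "preincubation_acsf",
    "preincubation_lps",
    "washout",
    "drug_preperfusion",
    "ictogenic",
    "ictogenic_plus_drug",
)

ICTOGENIC_LABELS = ("ictogenic", "ictogenic_plus_drug")


@dataclass(frozen=True)
class Phase:
    label: str
    duration: float  # seconds
    drugs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.label not in PHASE_LABELS:
            raise ValueError(f"unknown phase label {self.label!r}")
        if self.duration <= 0:
            raise ValueError("phase duration must be positive")


@dataclass(frozen=True)
class ConditionTimeline:
    """Contiguous ordered perfusion phases with the drugs active in each."""

    phases: tuple[Phase, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("timeline needs at least one phase")
        if not any(p.label in ICTOGENIC_LABELS for p in self.phases):
            raise ValueError("timeline must contain an ictogenic phase")

    @property
    def has_lps(self) -> bool:
        return any(p.label == "preincubation_lps" for p in self.phases)

    @property
    def ictogenic_duration(self) -> float:
        return sum(p.duration for p in self.phases if p.label in ICTOGENIC_LABELS)

    @property
    def active_drugs(self) -> tuple[str, ...]:
        drugs: list[str] = []
        for p in self.phases:
            if p.label in ICTOGENIC_LABELS:
                for d in p.drugs:
                    if d not in drugs:
                        drugs.append(d)
        return tuple(drugs)

    @property
    def total_duration(self) -> float:
        return sum(p.duration for p in self.phases)


def protocol(
    lps: bool = False,
    drug: str | None = None,
    immunomodulator: bool = False,
    ictogenic_duration: float = 2400.0,
) -> ConditionTimeline:
    """Build the standard perfusion protocols.

    - aCSF or LPS pre-incubation for 30 min; LPS followed by a 5 min washout.
    - Immunomodulators are pre-perfused for 15 min before the ictogenic
      cocktail and remain present during it.
    - ASMs are dissolved in the ictogenic cocktail for the whole 40 min.
    """
    phases: list[Phase] = []
    if lps:
        phases.append(Phase("preincubation_lps", 1800.0))
        phases.append(Phase("washout", 300.0))
    else:
        phases.append(Phase("preincubation_acsf", 1800.0))
    if immunomodulator:
        if drug is None:
            raise ValueError("immunomodulator protocol requires a drug name")
        phases.append(Phase("drug_preperfusion", 900.0, drugs=(drug,)))
    if drug is None:
        phases.append(Phase("ictogenic", ictogenic_duration))
    else:
        phases.append(Phase("ictogenic_plus_drug", ictogenic_duration, drugs=(drug,)))
    return ConditionTimeline(tuple(phases))


# ---------------------------------------------------------------------------
# Effect model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FPTemplate:
    """Biphasic field-potential waveform: positive lobe then negative lobe."""

    peak_pos_uv: float = 350.0
    peak_neg_uv: float = -250.0
    width_ms: float = 20.0


def _default_drug_efficacy() -> dict[str, float]:
    # Fractional FP-rate reduction at maximal human therapeutic concentration,
    # naive slices: each ASM is partially effective.
    return {"valproate": 0.5, "phenytoin": 0.5, "phenobarbital": 0.6, "midazolam": 0.6}


def _default_drug_efficacy_lps() -> dict[str, float]:
    # After LPS, valproate and phenytoin lose their effect on FP frequency;
    # midazolam and phenobarbital stay partially effective.
    return {"valproate": 0.05, "phenytoin": 0.05, "phenobarbital": 0.3, "midazolam": 0.3}


def _default_episode_suppression() -> dict[str, float]:
    # Without LPS, every ASM abolishes ictal and SE episodes.
    return {"valproate": 1.0, "phenytoin": 1.0, "phenobarbital": 1.0, "midazolam": 1.0}


def _default_episode_suppression_lps() -> dict[str, float]:
    # After LPS, suppression is partial; values calibrated to the observed
    # ictal+SE incidences (57/33/33/20 %) against the 86.6 % LPS baseline,
    # jointly with the residual rate efficacies.
    return {"valproate": 0.31, "phenytoin": 0.60, "midazolam": 0.45, "phenobarbital": 0.67}


@dataclass(frozen=True)
class EffectModel:
    """Condition-dependent statistics of the simulated epileptiform activity.

    Rates are population-discharge rates during the ictogenic phase.
    `p_ictal`/`p_se` are per-slice probabilities that the slice develops
    ictal episodes or an SE-like episode; they are mutually exclusive slice
    regimes, so their sum must not exceed 1.
    """

    base_fp_rate: float = 0.2  # Hz, background interictal population FPs
    lps_rate_multiplier: float = 2.5
    lps_burst_duration_multiplier: float = 2.0

    # Per-slice episode regime probabilities (without / with LPS).
    p_ictal: float = 0.46
    p_se: float = 0.18
    p_ictal_lps: float = 0.146
    p_se_lps: float = 0.72

    # drug -> fractional rate reduction in [0, 1]
    drug_efficacy: dict[str, float] = field(default_factory=_default_drug_efficacy)
    drug_efficacy_lps: dict[str, float] = field(default_factory=_default_drug_efficacy_lps)
    # drug -> fractional reduction of episode-entry probability
    drug_episode_suppression: dict[str, float] = field(
        default_factory=_default_episode_suppression
    )
    drug_episode_suppression_lps: dict[str, float] = field(
        default_factory=_default_episode_suppression_lps
    )

    immunomodulators: tuple[str, ...] = ("anakinra", "anti_il6r")
    immunomodulator_onset_delay: float = 600.0  # s of complete silence
    immunomodulator_rate_reduction: float = 0.6
    immunomodulator_episode_suppression: float = 1.0

    # Burst episodes (all slices): entry rate and shape.
    burst_rate: float = 1.0 / 120.0  # Hz
    burst_mean_duration: float = 1.5  # s, before the LPS multiplier
    burst_max_duration: float = 4.5  # keep bursts below the ictal duration bound
    burst_gap_range: tuple[float, float] = (0.3, 0.9)  # s between burst FPs

    # Ictal episodes (ictal-regime slices).
    ictal_episode_rate: float = 1.0 / 600.0  # Hz
    ictal_duration_range: tuple[float, float] = (8.0, 30.0)  # s
    ictal_freq_range: tuple[float, float] = (1.5, 3.0)  # Hz

    # SE-like episode (SE-regime slices): one sustained discharge.
    se_min_duration: float = 300.0  # s; the classifier reads the same bound
    se_duration_factor_range: tuple[float, float] = (1.15, 1.4)
    se_freq_range: tuple[float, float] = (1.05, 1.25)  # Hz, see methods note

    # Spatial layout and rendering.
    active_area_size: int = 4  # k x k electrode cluster
    electrode_jitter: float = 0.008  # s, per-electrode FP-time jitter
    noise_sd: float = 10.0  # uV
    fp_template: FPTemplate = field(default_factory=FPTemplate)

    def validate(self, detector_high_threshold: float = 200.0) -> None:
        if self.base_fp_rate < 0:
            raise ValueError("base_fp_rate must be non-negative")
        if self.lps_rate_multiplier <= 0 or self.lps_burst_duration_multiplier <= 0:
            raise ValueError("LPS multipliers must be positive")
        for p in (self.p_ictal, self.p_se, self.p_ictal_lps, self.p_se_lps):
            if not 0.0 <= p <= 1.0:
                raise ValueError("episode probabilities must lie in [0, 1]")
        if self.p_ictal + self.p_se > 1.0 or self.p_ictal_lps + self.p_se_lps > 1.0:
            raise ValueError("p_ictal + p_se must not exceed 1")
        for m in (self.drug_efficacy, self.drug_efficacy_lps):
            for drug, eff in m.items():
                if not 0.0 <= eff <= 1.0:
                    raise ValueError(f"efficacy for {drug!r} must lie in [0, 1]")
        if not 0.0 <= self.immunomodulator_rate_reduction <= 1.0:
            raise ValueError("immunomodulator_rate_reduction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.fp_template.peak_pos_uv <= detector_high_threshold:
            raise ValueError(
                "FP template peak must exceed the detector high threshold; "
                "injected events would be undetectable by construction"
            )
        lo, hi = self.se_freq_range
        if not (0 < lo <= hi):
            raise ValueError("se_freq_range must be positive and ordered")

    # -- condition resolution -----------------------------------------------

    def rate_factor(self, lps: bool, drugs: tuple[str, ...]) -> float:
        """Multiplier on the background/burst-entry rate for a condition."""
        f = self.lps_rate_multiplier if lps else 1.0
        eff_map = self.drug_efficacy_lps if lps else self.drug_efficacy
        for d in drugs:
            if d in self.immunomodulators:
                f *= 1.0 - self.immunomodulator_rate_reduction
            else:
                f *= 1.0 - eff_map.get(d, 0.0)
        return f

    def episode_probs(self, lps: bool, drugs: tuple[str, ...]) -> tuple[float, float]:
        """(p_ictal, p_se) for a condition, after drug suppression."""
        if lps:
            p_i, p_s = self.p_ictal_lps, self.p_se_lps
            eff_map = self.drug_efficacy_lps
            sup_map = self.drug_episode_suppression_lps
        else:
            p_i, p_s = self.p_ictal, self.p_se
            eff_map = self.drug_efficacy
            sup_map = self.drug_episode_suppression
        for d in drugs:
            if d in self.immunomodulators:
                factor = (1.0 - self.immunomodulator_rate_reduction) * (
                    1.0 - self.immunomodulator_episode_suppression
                )
            else:
                factor = (1.0 - eff_map.get(d, 0.0)) * (1.0 - sup_map.get(d, 0.0))
            p_i *= factor
            p_s *= factor
        return p_i, p_s

    def onset_delay(self, drugs: tuple[str, ...]) -> float:
        """Complete-silence window at the start of the ictogenic phase."""
        if any(d in self.immunomodulators for d in drugs):
            return self.immunomodulator_onset_delay
        return 0.0


def desk_effect_model(**overrides) -> EffectModel:
    """Effect model scaled for short desk-scale recordings.

    SE minimum duration 30 s instead of 5 min, ictal episodes 6-15 s, and a
    proportionally shorter immunomodulator onset delay, so a 120 s ictogenic
    phase can hold every episode class.
    """
    params = dict(
        se_min_duration=30.0,
        ictal_duration_range=(6.0, 15.0),
        burst_rate=1.0 / 40.0,
        ictal_episode_rate=1.0 / 120.0,
        immunomodulator_onset_delay=30.0,
    )
    params.update(overrides)
    return EffectModel(**params)


# ---------------------------------------------------------------------------
# Named scenarios
# ---------------------------------------------------------------------------

ASMS = ("valproate", "phenytoin", "phenobarbital", "midazolam")


def _build_scenarios() -> dict[str, dict]:
    s: dict[str, dict] = {
        "0mg_4ap": {"lps": False, "drug": None, "immunomodulator": False},
        "lps_0mg_4ap": {"lps": True, "drug": None, "immunomodulator": False},
    }
    for asm in ASMS:
        s[f"0mg_4ap_{asm}"] = {"lps": False, "drug": asm, "immunomodulator": False}
        s[f"lps_0mg_4ap_{asm}"] = {"lps": True, "drug": asm, "immunomodulator": False}
    for imm in ("anakinra", "anti_il6r"):
        s[f"lps_0mg_4ap_{imm}"] = {"lps": True, "drug": imm, "immunomodulator": True}
    return s


SCENARIOS = _build_scenarios()


def scenario_names() -> list[str]:
    return sorted(SCENARIOS)


def scenario(
    name: str,
    effect: EffectModel | None = None,
    ictogenic_duration: float = 2400.0,
) -> tuple[EffectModel, ConditionTimeline]:
    """Resolve a named condition to (EffectModel, ConditionTimeline)."""
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(scenario_names())}"
        )
    spec = SCENARIOS[name]
    timeline = protocol(
        lps=spec["lps"],
        drug=spec["drug"],
        immunomodulator=spec["immunomodulator"],
        ictogenic_duration=ictogenic_duration,
    )
    return (effect if effect is not None else EffectModel()), timeline
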