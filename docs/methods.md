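# Methods

This note documents the models, parameter choices and numerical conventions
behind `epimea`, and what the synthetic-data experiments do and do not show
about real slice recordings.

## The recording and the detector

The emulated acquisition system is a 64 × 64 CMOS electrode array (21 µm
pitch) sampled at 10 kHz per channel; a desk-scale preset (16 × 16 at
1 kHz) and a tiny preset (8 × 8 at 500 Hz) run the identical downstream
logic at a fraction of the cost. All times are seconds (float), electrode
coordinates are 0-based (row, col), and analysis windows are half-open
[start, end).

Field potentials are detected per electrode by threshold crossing with the
acquisition-software settings used in the assay: high/low thresholds
+200 / −200 µV, energy window 40 ms, refractory period 5 ms, maximum wave
duration 500 ms. The exact semantics of the vendor's "energy window" are
unpublished; here it is read as a **merge horizon**: crossings within 40 ms
of the previous crossing extend the same event, capped at 500 ms from onset
(a crossing beyond the cap seeds a new event). This is the simplest reading
that yields one event per discharge rather than one per suprathreshold
sample, and it is isolated behind `DetectorParams` so an alternative
(e.g. a sliding-energy trigger) could be substituted. Further conventions:

- the refractory period constrains event **onsets** (standard
  spike-detection convention); note that with refractory < energy window it
  can never bind, but it is enforced so other parameterisations behave;
- onset is the first threshold crossing, not the peak (deterministic and
  oracle-checkable); amplitude is max |v| over the event span;
- events reaching the duration cap are closed, not discarded (discarding
  would silently delete sustained SE deflections and break FP-frequency
  monotonicity); events still open at the trace end are closed there and
  kept.

The detector is validated by exact equivalence against an independent naive
per-sample state machine on hundreds of random traces, including
parameterisations away from the defaults.

## Event taxonomy and classification

Population FPs are formed from per-electrode FP onsets inside the active
area by a greedy coincidence rule: all onsets within one 20 ms window form a
population FP when at least 25 % of the area electrodes participate, timed
at the earliest member. The assay's original analysis identified
synchronous discharges visually; the window-plus-fraction rule is this
package's explicit, parameterised surrogate (`coincidence_window`,
`min_sync_fraction`).

Population FP times are segmented into discharges at gaps above 1 s — the
only gap scale the assay defines (the burst criterion) — and classified:

| class | rule |
|---|---|
| SE-like | duration > 300 s (parameter) and mean frequency in [0.8, 1.3] Hz |
| ictal | duration > 5 s and mean frequency > 1 Hz |
| burst | ≥ 3 FPs (with gaps ≤ 1 s by construction of the segmentation) |
| interictal | everything else |

Mean frequency uses the inter-event-interval convention (n−1)/span, which is
exact for periodic trains (a 1.0 Hz train measures exactly 1.0 Hz). Where a
discharge satisfies both the SE and the ictal rubric (e.g. 1.2 Hz sustained
beyond 5 min), SE wins: it is the distinct longer-duration category.
"Burst" is reported as its own class but is understood as a sub-label of
interictal activity (`EpileptiformEvent.is_interictal` is true for both);
whether the original taxonomy intended bursts to be reported separately is
not knowable from its definitions, so the package keeps both views.

The SE minimum duration is a single parameter (default 300 s) read by both
the generator and the classifier; the desk-scale preset sets it to 30 s so
that complete SE episodes fit in two-minute test recordings.

Per-slice metrics are averaged over all active-area electrodes (silent ones
included): FP frequency = mean of per-electrode counts / window length; the
default analysis windows are T1 = 0–600 s and T2 = 1200–1800 s from the
start of the ictogenic perfusion. Events straddling a window boundary count
toward every window they overlap. Incidence flags (`has_ictal`, `has_se`)
in group tables are computed over the **full** ictogenic recording rather
than per window, since ictal/SE incidence in the assay is a per-recording
judgement and a window-restricted flag would drop episodes falling between
T1 and T2; per-window flags remain available in `SliceSummary`.

## Activity map and most-active-area selection

The rate map is per-electrode FP count / window length. The original
analysis selected the most active area by overlaying a slice photograph on
the activity map by eye; here the step is algorithmic and parameterised:
threshold the map strictly above the 75th percentile of nonzero rates
(falling back to ≥ on flat maps, so a uniform map selects everything), take
4-connected components, keep the component with the largest total rate (ties
broken by larger size, then by smallest row-major top-left index), and
dilate by one electrode ring — confined to on-slice electrodes — until a
minimum size (default 4) is reached. The area is fixed per slice using
full-recording activity rather than re-chosen per window; HPC/CTX
attribution is by majority vote of the region labels under the mask.

## The synthetic-recording generator

No generative model of the biology is given by the assay, so the generator
is a deliberately simple semi-Markov surrogate whose *statistics* realize
the observed condition structure:

- **Background**: homogeneous Poisson population FPs at `base_fp_rate`
  (default 0.2 Hz) over the ictogenic phase.
- **Episodes**: per slice, a latent regime — SE (probability `p_se`), ictal
  (`p_ictal`, mutually exclusive with SE, so p_se + p_ictal ≤ 1) or
  background-only. SE slices receive one sustained discharge at
  1.05–1.25 Hz lasting 1.15–1.4 × the SE minimum duration; ictal slices
  receive Poisson-counted episodes of 8–30 s at 1.5–3 Hz; all slices
  receive bursts (entry rate 1/120 Hz, ≥ 3 FPs, gaps 0.3–0.9 s, mean
  duration 1.5 s capped at 4.5 s so a burst can never satisfy the ictal
  rubric). Episodes are placed without overlap, 3 s apart, and background
  FPs within 1.5 s of an episode are removed so discharges never merge
  across the 1 s segmentation gap.
- **SE frequency band**: generated SE uses 1.05–1.25 Hz, inside the
  0.8–1.3 Hz class band but above 1 Hz, because inter-FP intervals longer
  than 1 s would be split by the segmentation gap — the rubric's 1 s gap
  and its 0.8 Hz lower band edge are mutually inconsistent for an
  event-level generator, and the band is narrowed rather than the gap
  widened.
- **Condition effects**: LPS multiplies background/burst rates by 2.5 and
  burst durations by 2, and shifts the regime probabilities; drugs multiply
  rates by (1 − efficacy) and episode-entry probabilities by
  (1 − efficacy)(1 − episode suppression); immunomodulators silence all
  activity before their onset delay (600 s) and reduce rates by 60 % and
  episode entry fully thereafter. Efficacy = 1 therefore silences a
  condition entirely.
- **Space**: every population FP is placed on all electrodes of one
  contiguous k × k cluster (default 4 × 4) positioned uniformly inside a
  randomly chosen region (HPC = left half, CTX = right half, one off-slice
  border ring), with per-electrode jitter ≤ 8 ms — below the 20 ms
  coincidence window.
- **Rendering**: a biphasic template (+350 / −250 µV half-sine lobes, 20 ms
  wide; only its suprathreshold peak matters to the detector contract) is
  superimposed at each FP time, plus i.i.d. Gaussian noise (sd 10 µV). No
  1/f or line noise, no volume conduction, no electrode impedance
  modelling: detection operates ~17 sd above the noise floor, so detection
  performance reported here is an upper bound relative to real recordings.

**Calibration.** The assay reports effect *directions*, three in-text
incidence counts, and a "four-fold" SE-incidence increase; group bar heights
are figure-only. The defaults are calibrated once to those anchors and are
not fit to data: p_se = 0.18 → 0.72 under LPS (exactly four-fold) and
p_ictal = 0.46 → 0.146, so combined ictal+SE incidence is 64 % without and
86.6 % with LPS; LPS-era ASM episode suppressions (valproate 0.31,
phenytoin 0.60, midazolam 0.45, phenobarbital 0.67, combined with residual
rate efficacies 0.05/0.05/0.3/0.3) reproduce the observed 57/33/33/20 %
incidences in expectation; without LPS every ASM suppresses episodes fully
(0 % incidence) while reducing FP rates only partially (efficacies 0.5–0.6).
Consequently, passing tests show the *pipeline* recovers what was injected
and that the injected structure has the assay's direction-of-effect
signature — they are not evidence about biology.

**Determinism.** One global seed spawns independent per-slice substreams
(`numpy` `SeedSequence.spawn`), so identical seeds give bit-identical
trains and increasing `n_slices` leaves earlier slices unchanged. At the
event level the pipeline is exact without rendering traces; replicate
experiments at the full 2400 s protocol scale therefore run on event trains
(a 16 × 16 desk grid), while trace rendering and detection are exercised on
shorter recordings. Problem sizes used by the shipped checks: 100 seeds for
ground-truth recovery at desk scale (120 s ictogenic phase, SE minimum
30 s), 50 replicate experiments of 10 + 10 (and 6 immunomodulator) slices
for the effect directions, 300 slices per arm for the incidence estimates,
500 random traces for detector–oracle equivalence.

## Group statistics

Two-sided p-values throughout (sidedness is not specified by the assay's
analysis; two-sided is the conservative Prism-style default). Mann–Whitney
U uses the full permutation distribution (every assignment of the pooled
values, extremeness measured by |U − E[U]|, valid under ties) when the
combined n ≤ 12, and the tie-corrected normal approximation with continuity
correction otherwise. Kruskal–Wallis H is tie-corrected (via scipy); Dunn's
pairwise z statistics use the pooled mean-rank difference with tie-corrected
variance and Bonferroni adjustment over the tested pairs (the common Prism
default; the adjustment is a parameter). The 2×2 incidence comparison is
Pearson's chi-square without continuity correction (Prism's default for this
test; Yates correction available as a flag); a degenerate table (an all-zero
margin) returns χ² = 0, p = 1. SEM uses the n − 1 standard deviation.
Incidence percentages are rounded half-up to integers (4/7 → 57 %).

## qPCR quantification

Replicate wells are averaged arithmetically per (sample, gene); the
reference summary is the arithmetic mean of the reference-gene Cts, which on
the log2 Ct scale equals the log of the geometric mean of the reference
quantities; ΔCt = target − reference summary; ΔΔCt subtracts the
control-group mean ΔCt per gene (slices are independent units, not paired);
fold = efficiency^−ΔΔCt with efficiency fixed at 2 (no per-primer
efficiencies are available; the parameter is exposed per call). By this
construction the *geometric* mean control fold is exactly 1; group summaries
report arithmetic mean ± SEM, as the assay plots. The Il1b/Il1rn balance is
computed as the ratio of per-sample fold changes — an assumption, since a
ratio of ΔCt-derived relative quantities per sample is equally consistent
with its description. The synthetic Ct generator writes
Ct = baseline − log2(fold) + Gaussian noise per well; its default induction
magnitudes (log2 folds of 4–5 for Il1b/Tnf/Cxcl1, 1.5–2 for Il1rn) are
invented, reproducing only the induction pattern (strong pro-inflammatory
induction, minor antagonist induction), since the underlying measurements
are figure-only.

## Known limitations

- The generator is an event-level surrogate: no biophysics, no waveform
  diversity, white noise only, one rectangular active area per slice with
  full within-area participation. Detection and area-selection performance
  on real data will be worse than the near-perfect figures obtained here.
- The "energy window" interpretation and the synchrony rule are documented
  assumptions, not vendor semantics.
- Effect-size defaults beyond the incidence anchors (rate multipliers,
  latencies, burst-duration multiplier, ASM efficacies) encode directions
  and plausible magnitudes, not measured values.
- The exact Mann–Whitney mode enumerates up to C(12,6) = 924 assignments;
  above combined n = 12 the asymptotic mode is used automatically.
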