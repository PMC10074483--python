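"""Generator contracts: determinism, rate arithmetic, ground-truth validity."""

import dataclasses

import numpy as np
import pytest

from epimea.conditions import (
    DESK_GEOMETRY,
    TINY_GEOMETRY,
    ConditionTimeline,
    Phase,
    desk_effect_model,
    protocol,
    scenario,
)
from epimea.detect import detect_fps
from epimea.io import read_recording, write_recording
from epimea.simulate import fp_template_waveform, render_traces, simulate_event_trains


def _counts(trains):
    return [t.n_fps for t in trains]


def _thin(times, min_gap):
    """Keep only times at least min_gap after the previously kept one."""
    kept = []
    for t in times:
        if not kept or t - kept[-1] >= min_gap:
            kept.append(t)
    return np.asarray(kept)


class TestEventTrains:
    def test_zero_rate_gives_empty_trains(self, short_timeline):
        eff = dataclasses.replace(
            desk_effect_model(), base_fp_rate=0.0, p_ictal=0.0, p_se=0.0, burst_rate=0.0
        )
        trains = simulate_event_trains(eff, short_timeline, DESK_GEOMETRY, 5, 3)
        assert all(t.n_fps == 0 for t in trains)

    def test_identical_seed_identical_trains(self, desk_effect, short_timeline):
        a = simulate_event_trains(desk_effect, short_timeline, DESK_GEOMETRY, 4, 11)
        b = simulate_event_trains(desk_effect, short_timeline, DESK_GEOMETRY, 4, 11)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.pop_times, tb.pop_times)
            assert ta.area == tb.area and ta.region == tb.region
            for rc in ta.fp_times:
                np.testing.assert_array_equal(ta.fp_times[rc], tb.fp_times[rc])

    def test_more_slices_leave_earlier_slices_unchanged(self, desk_effect, short_timeline):
        a = simulate_event_trains(desk_effect, short_timeline, DESK_GEOMETRY, 2, 5)
        b = simulate_event_trains(desk_effect, short_timeline, DESK_GEOMETRY, 6, 5)
        for ta, tb in zip(a, b[:2]):
            np.testing.assert_array_equal(ta.pop_times, tb.pop_times)

    def test_background_poisson_mean(self, background_only_effect):
        """Mean FP count over seeds matches the Poisson mean lambda * T."""
        eff = dataclasses.replace(background_only_effect, base_fp_rate=2.0)
        tl = protocol(ictogenic_duration=60.0)
        counts = []
        for seed in range(200):
            (train,) = simulate_event_trains(eff, tl, TINY_GEOMETRY, 1, seed)
            counts.append(len(train.background_times))
        mean = np.mean(counts)
        se = np.sqrt(120.0 / 200)  # Poisson variance = mean
        assert abs(mean - 120.0) < 3 * se

    def test_lps_rate_multiplier_monotonic(self, background_only_effect):
        tl = protocol(lps=True, ictogenic_duration=120.0)
        means = []
        for mult in (1.5, 3.0):
            eff = dataclasses.replace(background_only_effect, lps_rate_multiplier=mult)
            counts = [
                simulate_event_trains(eff, tl, TINY_GEOMETRY, 1, s)[0].n_fps
                for s in range(100)
            ]
            means.append(np.mean(counts))
        assert means[1] > means[0]

    def test_full_efficacy_silences_drug_condition(self, background_only_effect):
        eff = dataclasses.replace(
            background_only_effect, drug_efficacy={"valproate": 1.0}
        )
        tl = protocol(drug="valproate", ictogenic_duration=120.0)
        trains = simulate_event_trains(eff, tl, TINY_GEOMETRY, 10, 0)
        assert all(t.n_fps == 0 for t in trains)

    def test_zero_efficacy_indistinguishable_from_no_drug(self, background_only_effect):
        from epimea.stats import compare_two_groups

        eff = dataclasses.replace(
            background_only_effect,
            drug_efficacy={"placebo": 0.0},
            drug_episode_suppression={"placebo": 0.0},
        )
        tl_drug = protocol(drug="placebo", ictogenic_duration=120.0)
        tl_none = protocol(ictogenic_duration=120.0)
        with_drug = [
            simulate_event_trains(eff, tl_drug, TINY_GEOMETRY, 1, s)[0].n_fps
            for s in range(60)
        ]
        without = [
            simulate_event_trains(eff, tl_none, TINY_GEOMETRY, 1, 1000 + s)[0].n_fps
            for s in range(60)
        ]
        assert compare_two_groups(with_drug, without).p > 0.01

    def test_ground_truth_round_trip_class_definitions(self, desk_effect, short_timeline):
        """Every injected episode satisfies its own class rubric when re-measured."""
        for seed in range(20):
            (train,) = simulate_event_trains(desk_effect, short_timeline, DESK_GEOMETRY, 1, seed)
            for ev in train.events:
                gaps = np.diff(ev.pop_times)
                if ev.klass == "burst":
                    assert ev.n_fps >= 3
                    assert np.all(gaps <= 1.0)
                    assert ev.end - ev.start < 5.0
                elif ev.klass == "ictal":
                    assert ev.end - ev.start > 5.0
                    assert ev.mean_freq > 1.0
                    assert np.all(gaps <= 1.0)
                elif ev.klass == "SE":
                    assert ev.end - ev.start > desk_effect.se_min_duration
                    assert 0.8 <= ev.mean_freq <= 1.3
                    assert np.all(gaps <= 1.0)
                else:  # pragma: no cover
                    pytest.fail(f"unexpected injected class {ev.klass}")

    def test_immunomodulator_silences_before_onset_delay(self):
        eff = desk_effect_model()
        tl = protocol(lps=True, drug="anakinra", immunomodulator=True, ictogenic_duration=120.0)
        for seed in range(10):
            (train,) = simulate_event_trains(eff, tl, TINY_GEOMETRY, 1, seed)
            pop = train.pop_times
            if len(pop):
                assert pop.min() >= eff.immunomodulator_onset_delay

    def test_probability_overflow_rejected(self, short_timeline):
        eff = dataclasses.replace(desk_effect_model(), p_ictal=0.7, p_se=0.5)
        with pytest.raises(ValueError, match="p_ictal"):
            simulate_event_trains(eff, short_timeline, TINY_GEOMETRY, 1, 0)

    def test_subthreshold_template_rejected(self):
        from epimea.conditions import FPTemplate

        eff = dataclasses.replace(
            desk_effect_model(), fp_template=FPTemplate(peak_pos_uv=150.0)
        )
        with pytest.raises(ValueError, match="threshold"):
            eff.validate()


class TestRenderTraces:
    def test_empty_trains_zero_noise_all_zero(self, background_only_effect):
        eff = dataclasses.replace(background_only_effect, base_fp_rate=0.0, noise_sd=0.0)
        tl = protocol(ictogenic_duration=10.0)
        (train,) = simulate_event_trains(eff, tl, TINY_GEOMETRY, 1, 0)
        rec = render_traces(train, eff)
        assert rec.traces.shape == (64, 5000)
        assert np.all(rec.traces == 0.0)

    def test_single_fp_peak_equals_template_peak(self, background_only_effect):
        eff = dataclasses.replace(
            background_only_effect, noise_sd=0.0, electrode_jitter=0.0
        )
        tl = protocol(ictogenic_duration=10.0)
        (train,) = simulate_event_trains(
            dataclasses.replace(eff, base_fp_rate=0.0), tl, TINY_GEOMETRY, 1, 0
        )
        rc = train.area[0]
        train.fp_times = {rc: np.array([1.0])}
        rec = render_traces(train, eff)
        idx = rc[0] * TINY_GEOMETRY.n_cols + rc[1]
        trace = rec.traces[idx]
        assert trace.max() == pytest.approx(eff.fp_template.peak_pos_uv)
        peak_sample = int(np.argmax(trace))
        assert abs(peak_sample / TINY_GEOMETRY.sampling_rate - 1.0) < eff.fp_template.width_ms / 1000

    def test_detector_recovers_injected_fps(self, background_only_effect):
        """>= 99% of isolated injected FPs recovered within 5 ms at default SNR.

        FPs closer than the template width + energy window merge into one
        detected event by construction, so the injected train is thinned to
        isolated FPs before rendering.
        """
        eff = dataclasses.replace(background_only_effect, base_fp_rate=0.5)
        tl = protocol(ictogenic_duration=200.0)
        (train,) = simulate_event_trains(eff, tl, TINY_GEOMETRY, 1, 12)
        train.fp_times = {
            rc: _thin(times, min_gap=0.1) for rc, times in train.fp_times.items()
        }
        rec = render_traces(train, eff)
        detected = detect_fps(rec)
        by_electrode = {}
        for fp in detected:
            by_electrode.setdefault(fp.electrode, []).append(fp.onset)
        n_injected = matched = 0
        for rc, times in train.fp_times.items():
            onsets = np.asarray(by_electrode.get(rc, []))
            for t in times:
                n_injected += 1
                if onsets.size and np.min(np.abs(onsets - t)) <= 0.005:
                    matched += 1
        assert n_injected >= 100
        assert matched / n_injected >= 0.99
        # false positives: events on electrodes that received no injections
        off_area = [fp for fp in detected if fp.electrode not in train.fp_times]
        assert len(off_area) / (64 * 200.0) < 0.01  # Hz per electrode

    def test_wide_template_warns(self, background_only_effect):
        from epimea.conditions import FPTemplate

        eff = dataclasses.replace(
            background_only_effect,
            fp_template=FPTemplate(width_ms=600.0),
            base_fp_rate=0.0,
            noise_sd=0.0,
        )
        tl = protocol(ictogenic_duration=5.0)
        (train,) = simulate_event_trains(eff, tl, TINY_GEOMETRY, 1, 0)
        with pytest.warns(UserWarning, match="maximum wave duration"):
            render_traces(train, eff)


class TestRecordingContainer:
    def test_hdf5_round_trip(self, desk_effect, tmp_path):
        tl = protocol(lps=True, ictogenic_duration=40.0)
        eff = dataclasses.replace(desk_effect, p_se=0.0, p_ictal=0.5)
        (train,) = simulate_event_trains(eff, tl, TINY_GEOMETRY, 1, 9)
        rec = render_traces(train, eff)
        path = tmp_path / "rec.h5"
        write_recording(path, rec)
        back = read_recording(path)
        assert back.geometry == rec.geometry
        assert back.timeline == rec.timeline
        assert back.seed == rec.seed
        np.testing.assert_array_equal(back.traces, rec.traces)
        np.testing.assert_array_equal(back.region_labels, rec.region_labels)
        gt, gt0 = back.ground_truth, rec.ground_truth
        assert gt.region == gt0.region and gt.area == gt0.area
        assert [e.klass for e in gt.events] == [e.klass for e in gt0.events]
        for e1, e0 in zip(gt.events, gt0.events):
            np.testing.assert_allclose(e1.pop_times, e0.pop_times)
        for rc in gt0.fp_times:
            np.testing.assert_allclose(gt.fp_times[rc], gt0.fp_times[rc])


def test_template_waveform_is_biphasic():
    from epimea.conditions import FPTemplate

    wave = fp_template_waveform(FPTemplate(), 1000.0)
    assert wave.max() == pytest.approx(350.0)
    assert wave.min() == pytest.approx(-250.0)
    assert np.argmax(wave) < np.argmin(wave)


def test_scenario_resolution():
    eff, tl = scenario("lps_0mg_4ap_anakinra")
    assert tl.has_lps
    assert "anakinra" in tl.active_drugs
    assert any(p.label == "drug_preperfusion" for p in tl.phases)
    with pytest.raises(KeyError, match="unknown scenario"):
        scenario("nonexistent")


def test_timeline_validation():
    with pytest.raises(ValueError):
        Phase("ictogenic", -1.0)
    with pytest.raises(ValueError, match="ictogenic"):
        ConditionTimeline((Phase("washout", 10.0),))
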