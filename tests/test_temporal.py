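"""Sliding-window classification, label filtering, zone extraction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trajmode import (
    ModeSchedule,
    ModelLabel,
    PolynomialPotential,
    SimConfig,
    classify,
    detect_switch,
    extract_zones,
    lowpass,
    make_fixture,
    match_zones,
    simulate,
    spring_constant_to_kT,
    window_classify,
)
from trajmode.temporal import ConfinementZone, LabelSeries, estimate_switch_frame

F = ModelLabel.FREE
S = ModelLabel.SPRING2


def _series(labels, first_center=25, w=51):
    labels = np.array(labels, dtype=object)
    centers = np.arange(first_center, first_center + labels.size)
    return LabelSeries(centers=centers, labels=labels, w=w)


def _lowpass_reference(labels, persistence):
    """Literal restatement of the filtering rule, kept independent of the
    implementation: a switch happens only when `persistence` consecutive
    inputs all carry the new mode."""
    out = []
    current = labels[0]
    for i in range(len(labels)):
        candidate = labels[i]
        if candidate != current:
            window = labels[i : i + persistence]
            if len(window) == persistence and all(v == candidate for v in window):
                current = candidate
        out.append(current)
    return out


class TestLowpass:
    def test_constant_series_unchanged(self):
        s = _series([S] * 10)
        assert list(lowpass(s, 3).labels) == [S] * 10

    def test_single_blip_suppressed(self):
        s = _series([F, F, S, F, F])
        assert list(lowpass(s, 3).labels) == [F] * 5

    def test_exhaustive_length8_against_reference(self):
        for bits in itertools.product([F, S], repeat=8):
            s = _series(list(bits))
            got = list(lowpass(s, 3).labels)
            assert got == _lowpass_reference(list(bits), 3), bits

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.sampled_from([F, S]), min_size=1, max_size=40),
        st.integers(min_value=1, max_value=5),
    )
    def test_never_introduces_new_labels(self, labels, persistence):
        out = lowpass(_series(labels), persistence)
        assert set(out.labels) <= set(labels)

    def test_invalid_persistence(self):
        with pytest.raises(ValueError):
            lowpass(_series([F, S]), 0)


class TestExtractZones:
    def test_all_free_no_zones(self):
        assert extract_zones(_series([F] * 40), 5) == []

    def test_all_confined_single_spanning_zone(self):
        s = _series([S] * 40, first_center=25)
        zones = extract_zones(s, 10)
        assert len(zones) == 1
        assert (zones[0].start_frame, zones[0].end_frame) == (25, 64)

    def test_handcrafted_runs(self):
        labels = [F] * 100 + [S] * 60 + [F] * 50 + [S] * 10 + [F] * 80
        zones = extract_zones(_series(labels, first_center=0), min_duration=25)
        assert [(z.start_frame, z.end_frame) for z in zones] == [(100, 159)]

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.sampled_from([F, S]), min_size=1, max_size=60))
    def test_zone_count_monotone_in_min_duration(self, labels):
        s = _series(labels)
        counts = [len(extract_zones(s, d)) for d in (1, 3, 8, 20)]
        assert counts == sorted(counts, reverse=True)


class TestMatchZones:
    def test_fragment_counts_as_false_positive(self):
        truth = [ConfinementZone(100, 299)]
        detected = [ConfinementZone(110, 180), ConfinementZone(220, 280)]
        assert match_zones(detected, truth) == (1, 1)

    def test_disjoint_detection_is_false(self):
        truth = [ConfinementZone(100, 200)]
        detected = [ConfinementZone(300, 350)]
        assert match_zones(detected, truth) == (0, 1)

    def test_each_truth_matched_once(self):
        truth = [ConfinementZone(0, 50), ConfinementZone(100, 150)]
        detected = [ConfinementZone(10, 120)]
        assert match_zones(detected, truth) == (1, 0)


class TestDetectSwitch:
    def test_simple_switch(self):
        labels = [S] * 200 + [F] * 249
        s = _series(labels, first_center=25)
        assert detect_switch(s) == 225

    def test_no_switch_errors(self):
        with pytest.raises(ValueError, match="found 0"):
            detect_switch(_series([S] * 10))

    def test_multiple_switches_listed(self):
        with pytest.raises(ValueError, match="central frames"):
            detect_switch(_series([S, S, F, F, S, S]))

    def test_estimator_agrees_on_clean_series(self):
        labels = [S] * 120 + [F] * 200
        s = _series(labels, first_center=25)
        assert estimate_switch_frame(s) == detect_switch(s)

    def test_estimator_robust_to_flips(self):
        labels = [S] * 100 + [F, S, S] + [S] * 47 + [F] * 150
        s = _series(labels, first_center=0)
        assert estimate_switch_frame(s) == 150


class TestWindowClassify:
    def test_window_equals_trajectory_reduces_to_stage1(self):
        traj = make_fixture("fig3_spring", count=1)[0].window(0, 51)
        series = window_classify(traj, w=51, sigma=0.03)
        assert len(series) == 1
        decision = classify(traj, sigma=0.03)
        expected = F if decision.stage1 == "free" else S
        assert series.labels[0] == expected

    def test_confined_windows_labeled_confined_in_validated_regime(self):
        # k = 0.6 pN/um puts the 51-frame window inside the validated region
        pot = PolynomialPotential.spring(spring_constant_to_kT(0.6))
        rates = []
        for seed in (1, 2, 3):
            cfg = SimConfig(D=0.1, dt=0.05, n_frames=500, sigma=0.03, seed=seed)
            traj = simulate(cfg, ModeSchedule.confined(500, pot))
            series = window_classify(traj, w=51, sigma=0.03)
            rates.append(np.mean([lab is S for lab in series.labels]))
        assert np.mean(rates) >= 0.90

    def test_translation_invariance(self):
        traj = make_fixture("fig3_spring", count=1)[0].window(0, 101)
        a = window_classify(traj, w=51, sigma=0.03)
        b = window_classify(traj.translated(7.7, -3.1), w=51, sigma=0.03)
        assert list(a.labels) == list(b.labels)

    def test_centers_trimmed_by_half_window(self):
        traj = make_fixture("fig2_free", count=1)[0].window(0, 120)
        series = window_classify(traj, w=51, sigma=0.03)
        assert series.centers[0] == 25
        assert series.centers[-1] == 120 - 1 - 25

    def test_input_validation(self):
        traj = make_fixture("fig2_free", count=1)[0].window(0, 60)
        with pytest.raises(ValueError, match="odd"):
            window_classify(traj, w=50)
        with pytest.raises(ValueError, match="smaller window"):
            window_classify(traj, w=61)

    def test_switch_detected_early_on_ensemble(self):
        # windows overlapping the free tail bias toward FREE, so the mean
        # detected switch lies below the true switch frame
        trajs = make_fixture("fig7_switch", count=8)
        detected = []
        for traj in trajs:
            filtered = lowpass(window_classify(traj, w=51, sigma=0.03), 3)
            detected.append(estimate_switch_frame(filtered))
        assert np.mean(detected) < 250
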