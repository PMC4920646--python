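"""SWD detection: filter, baseline, crossings, grouping rules, acceptance."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swdkit.design import SessionDesign
from swdkit.detect import (
    BaselineStats,
    DetectionParams,
    PutativeSwd,
    amalgamate,
    auto_baseline,
    baseline_stats,
    detect_crossings,
    detect_swds,
    duration_filter,
    frequency_criterion,
    group_crossings,
    highpass_dc_remove,
)
from swdkit.io import Event, EventList, Recording
from swdkit.synth import SessionConfig, generate_background


class TestHighpass:
    def test_dc_rejection(self):
        fs, tau = 1000.0, 0.1
        x = np.full(int(fs), 42.0)
        y = highpass_dc_remove(x, fs, tau)
        assert abs(y[int(5 * tau * fs)]) < 0.05 * 42.0
        assert abs(y[-1]) < 1e-3 * 42.0

    def test_passband_amplitude_preserved(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        y = highpass_dc_remove(np.sin(2 * np.pi * 10 * t), fs, 0.1)
        # cutoff ~1.6 Hz: 10 Hz is essentially untouched
        assert abs(y[int(fs) :].max() - 1.0) < 0.05

    def test_ramp_response_bounded_by_slope_times_tau(self):
        fs, tau, slope = 1000.0, 0.1, 7.0
        t = np.arange(int(5 * fs)) / fs
        y = highpass_dc_remove(slope * t, fs, tau)
        # steady-state response of an RC high-pass to a ramp is slope * tau
        assert abs(y[-1] - slope * tau) < 0.02 * slope * tau
        assert np.all(np.abs(y) <= slope * tau * 1.05)


class TestBaseline:
    def test_white_noise_sd(self, rng):
        x = rng.standard_normal(60_000)
        bl = baseline_stats(x, 1000.0, (0.0, 60.0))
        assert abs(bl.sd_uv - 1.0) < 0.05

    def test_degenerate_baseline_rejected(self):
        with pytest.raises(ValueError, match="degenerate|positive"):
            baseline_stats(np.zeros(20_000), 1000.0, (0.0, 20.0))

    def test_interval_outside_recording(self, rng):
        with pytest.raises(ValueError, match="outside"):
            baseline_stats(rng.standard_normal(1000), 100.0, (0.0, 60.0))

    def test_auto_baseline_clean_control(self):
        design = SessionDesign()
        rec = Recording(np.zeros(int(2400 * 64.0)), fs=64.0, t0=-2400.0)
        start, end = auto_baseline(rec, EventList([]), design)
        assert start == -2400.0 and end == -2280.0  # earliest, capped at 120 s

    def test_auto_baseline_picks_longest_gap(self):
        design = SessionDesign()
        rec = Recording(np.zeros(int(2400 * 64.0)), fs=64.0, t0=-2400.0)
        # leave gaps of 30 s and 90 s between seizures in the control period
        events = EventList(
            [
                Event(-2400.0, -800.0, "swd"),
                Event(-770.0, -740.0, "swd"),  # 30 s gap before this
                Event(-650.0, -10.0, "swd"),  # 90 s gap before this
            ],
            validate=False,
        )
        start, end = auto_baseline(rec, events, design)
        assert (start, end) == (-740.0, -650.0)

    def test_auto_baseline_all_masked(self):
        design = SessionDesign()
        rec = Recording(np.zeros(int(2400 * 64.0)), fs=64.0, t0=-2400.0)
        events = EventList([Event(-2400.0, 0.0, "sleep")])
        with pytest.raises(ValueError):
            auto_baseline(rec, events, design)


class TestCrossings:
    BL = BaselineStats(0.0, 60.0, 0.0, 1.0)

    def test_pure_noise_essentially_silent_at_6_sd(self, rng):
        x = rng.standard_normal(60_000)  # 60 s at 1 kHz
        events = detect_crossings(x, 1000.0, self.BL, 6.0)
        # Gaussian tail: ~2 * Phi(-6) * 60000 ~ 1e-4 expected crossings
        assert events.size <= 1

    def test_single_spike_single_event(self):
        x = np.zeros(10_000)
        x[5000:5020] = 10.0  # 20 ms excursion at 10 SD
        events = detect_crossings(x, 1000.0, self.BL, 6.0)
        assert events.size == 1
        assert abs(events[0] - 5.0) < 1e-6

    def test_swd_train_event_rate(self):
        from swdkit.synth import SwdShapeParams, synthesize_swd

        fs = 1000.0
        w = synthesize_swd(10.0, SwdShapeParams(cycle_freq_hz=7.0), fs)
        bl = BaselineStats(0.0, 60.0, 0.0, 50.0)
        events = detect_crossings(w, fs, bl, 6.0)
        assert abs(events.size - 70) <= 3

    def test_both_polarities_merged_and_collapsed(self):
        x = np.zeros(2000)
        x[100:110] = 10.0
        x[130:140] = -10.0  # 30 ms later: same complex
        x[600:610] = -10.0  # separate event
        events = detect_crossings(x, 1000.0, self.BL, 6.0, collapse_window_s=0.06)
        assert events.size == 2

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(5000) * rng.uniform(0.5, 3.0)
        x[rng.integers(0, 5000, size=20)] += rng.uniform(-20, 20, size=20)
        counts = [
            detect_crossings(x, 1000.0, self.BL, k, collapse_window_s=0.0).size
            for k in (5.0, 6.0, 7.0, 9.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestGrouping:
    def test_onset_then_continuation(self):
        groups = group_crossings(np.array([0.0, 0.15, 0.50, 0.85]))
        assert len(groups) == 1
        assert groups[0].n_peaks == 4

    def test_no_pair_within_onset_interval(self):
        assert group_crossings(np.array([0.0, 0.30, 0.60])) == []

    def test_continuation_gap_closes_event(self):
        groups = group_crossings(np.array([0.0, 0.15, 0.60, 0.75]))
        assert [g.n_peaks for g in groups] == [2, 2]
        assert groups[0].peak_times_s.tolist() == [0.0, 0.15]
        assert groups[1].peak_times_s.tolist() == [0.60, 0.75]

    def test_extent_extended_by_half_collapse_window(self):
        (g,) = group_crossings(np.array([1.0, 1.1]), collapse_window_s=0.06)
        assert g.start_s == pytest.approx(0.97)
        assert g.end_s == pytest.approx(1.13)


class TestAmalgamation:
    @staticmethod
    def _put(start, end):
        return PutativeSwd(start, end, np.array([start, end]))

    def test_gap_rule(self):
        puts = [self._put(0.0, 1.0), self._put(1.4, 2.4), self._put(3.0, 4.0)]
        out = amalgamate(puts, 0.5)
        assert [(p.start_s, p.end_s) for p in out] == [(0.0, 2.4), (3.0, 4.0)]

    def test_single_identity(self):
        out = amalgamate([self._put(0.0, 1.0)])
        assert len(out) == 1 and out[0].start_s == 0.0

    def test_chain_merges_to_fixed_point(self):
        puts = [self._put(i * 1.4, i * 1.4 + 1.0) for i in range(5)]  # all gaps 0.4
        out = amalgamate(puts, 0.5)
        assert len(out) == 1
        assert out[0].end_s == pytest.approx(5.6 + 1.0)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.tuples(st.floats(0, 50), st.floats(0.1, 3.0)), max_size=12))
    def test_idempotence(self, spans):
        spans = sorted((round(s, 3), round(s + d, 3)) for s, d in spans)
        # drop overlaps to satisfy the precondition
        puts = []
        for s, e in spans:
            if not puts or s >= puts[-1].end_s:
                puts.append(self._put(s, e))
        once = amalgamate(puts, 0.5)
        twice = amalgamate(once, 0.5)
        assert [(p.start_s, p.end_s) for p in once] == [
            (p.start_s, p.end_s) for p in twice
        ]


class TestDurationFilter:
    def test_boundary_inclusive(self):
        puts = [
            PutativeSwd(0.0, d, np.array([0.0, d])) for d in (0.8, 1.0, 16.1)
        ]
        kept = duration_filter(puts, 1.0)
        assert [p.duration_s for p in kept] == [1.0, 16.1]

    def test_empty_and_all_short(self):
        assert duration_filter([], 1.0) == []
        short = [PutativeSwd(0.0, 0.5, np.array([0.0, 0.5]))]
        assert duration_filter(short, 1.0) == []


class TestFrequencyCriterion:
    def test_regular_7hz_accepted(self):
        peaks = np.arange(0, 2.0, 1 / 7.0)
        p = frequency_criterion(PutativeSwd(0.0, 2.0, peaks))
        assert p.accepted and p.frac_in_band == 1.0
        assert np.allclose(p.instantaneous_freqs_hz, 7.0)

    def test_fraction_at_boundary_accepted(self):
        # 8 intervals at 7 Hz + 2 at 20 Hz -> frac 0.8 >= 0.75
        times = [0.0]
        for df in [1 / 7.0] * 8 + [1 / 20.0] * 2:
            times.append(times[-1] + df)
        p = frequency_criterion(PutativeSwd(0.0, times[-1], np.array(times)))
        assert p.frac_in_band == pytest.approx(0.8)
        assert p.accepted

    def test_spindle_like_train_rejected(self):
        peaks = np.arange(0, 1.0, 1 / 14.0)
        p = frequency_criterion(PutativeSwd(0.0, 1.0, peaks))
        assert p.frac_in_band == 0.0 and not p.accepted

    def test_single_peak_rejected_with_zero_fraction(self):
        p = frequency_criterion(PutativeSwd(0.0, 1.0, np.array([0.5])))
        assert not p.accepted and p.frac_in_band == 0.0


class TestPipelineOrder:
    def test_amalgamation_precedes_duration_filter(self):
        # two 0.66 s putative SWDs, 0.39 s apart: only the stated order
        # (amalgamate first, then duration-filter) keeps the merged event
        peaks = np.r_[np.arange(0, 0.61, 0.15), np.arange(1.05, 1.66, 0.15)]
        groups = group_crossings(peaks)
        assert len(groups) == 2
        correct = duration_filter(amalgamate(groups, 0.5), 1.0)
        swapped = amalgamate(duration_filter(groups, 1.0), 0.5)
        assert len(correct) == 1
        assert swapped == []

    def test_detect_swds_keeps_merged_event(self, rng):
        # same geometry embedded in a signal: the full pipeline keeps one event
        fs = 1000.0
        x = rng.normal(0.0, 1.0, int(20 * fs))
        peaks = np.r_[np.arange(0, 0.61, 0.15), np.arange(1.05, 1.66, 0.15)] + 4.0
        for t in peaks:
            x[int(t * fs) : int(t * fs) + 8] += 15.0
        rec = Recording(x, fs=fs, t0=0.0)
        events = detect_swds(rec, None, (8.0, 20.0))
        assert len(events) == 1


class TestEndToEnd:
    def test_fidelity_on_synthetic_session(self, small_session, small_config):
        from swdkit.detect import match_events

        rec, gt = small_session
        detected = detect_swds(rec, ground_truth=gt, design=small_config.design)
        m = match_events(detected, gt, min_truth_duration_s=1.2)
        assert m["precision"] >= 0.95
        assert m["recall"] >= 0.95
        assert m["median_onset_error_s"] < 0.25
        assert m["median_offset_error_s"] < 0.25

    def test_spindle_only_recording_yields_no_detections(self):
        cfg = SessionConfig(
            fs=256.0,
            sleep_bout_offset_s=60.0,
            sleep_bout_len_s=1100.0,
            artifact_rate_per_min=0.0,
        )
        rec, _ = generate_background(1200.0, 256.0, 17, config=cfg, t0=0.0)
        events = detect_swds(rec, None, (0.0, 55.0))
        assert len(events) == 0

    def test_higher_threshold_events_covered_by_lower_threshold_crossings(
        self, small_session, small_config
    ):
        rec, gt = small_session
        x = highpass_dc_remove(rec.channel(0), rec.fs)
        interval = auto_baseline(rec, gt, small_config.design)
        bl = baseline_stats(x, rec.fs, interval, t0=rec.t0)
        k5_peaks = detect_crossings(x, rec.fs, bl, 5.0, t0=rec.t0)
        high = detect_swds(
            rec, DetectionParams(threshold_sd=9.0), ground_truth=gt, design=small_config.design
        )
        assert len(high) > 0
        # everything found at k=9 lies in time already covered by k=5 crossings
        for e in high:
            inside = (k5_peaks >= e.start_s - 0.1) & (k5_peaks <= e.end_s + 0.1)
            assert inside.sum() >= 2
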