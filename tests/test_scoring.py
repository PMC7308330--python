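"""Beat grids, event-to-strike matching, completion and flam scoring."""

import numpy as np
import pytest

from paradiddle import (
    CaptureWindow,
    DrumEvent,
    PerformanceSummary,
    build_grid,
    delta_score,
    flam_errors,
    hrs_error,
    make_template,
    match_events,
    pct_bars_completed,
    score_performance,
)
from paradiddle.simulate import DrummerParams, simulate_performance

from _oracles import exhaustive_assignment
from conftest import perfect_quarter_events


class TestTemplates:
    @pytest.mark.parametrize(
        "pattern_id, tempo, tolerance",
        [
            ("quarter_pattern", 120.0, 250.0),   # half a beat at 120 bpm
            ("eighth_pattern", 120.0, 125.0),    # half an eighth note
            ("quarter_pattern", 60.0, 500.0),
        ],
    )
    def test_half_beat_tolerance(self, pattern_id, tempo, tolerance):
        assert make_template(pattern_id, tempo).tolerance_ms == pytest.approx(tolerance)

    def test_quarter_pattern_structure(self, quarter):
        # RH+RF on beats 1/3, RH+LH+LF on beats 2/4: 10 strikes per bar
        assert quarter.slots_per_bar == 4
        assert quarter.expected[0] == {("RH", "ride"), ("RF", "kick")}
        assert quarter.expected[1] == {("RH", "ride"), ("LH", "snare"), ("LF", "hihat_pedal")}
        assert quarter.expected[2] == quarter.expected[0]
        assert quarter.expected[3] == quarter.expected[1]
        assert quarter.strikes_per_bar == 10

    def test_eighth_pattern_structure(self, eighth):
        # hi-hat on all 8 slots, kick on beats 1/3, snare on beats 2/4
        assert eighth.slots_per_bar == 8
        assert all(("RH", "hihat_closed") in s for s in eighth.expected)
        kick_slots = [i for i, s in enumerate(eighth.expected) if ("RF", "kick") in s]
        snare_slots = [i for i, s in enumerate(eighth.expected) if ("LH", "snare") in s]
        assert kick_slots == [0, 4] and snare_slots == [2, 6]
        assert eighth.strikes_per_bar == 12

    def test_unknown_pattern_and_bad_tempo(self):
        with pytest.raises(ValueError):
            make_template("samba_pattern")
        with pytest.raises(ValueError):
            make_template("quarter_pattern", tempo_bpm=0.0)

    def test_tolerance_override(self):
        assert make_template("quarter_pattern", 120, tolerance_override=99.0).tolerance_ms == 99.0


class TestGrid:
    def test_two_minute_window_has_60_bars(self, quarter, window):
        grid = build_grid(quarter, window)  # 2 s bars over [60, 180) s
        assert grid.n_bars == 60
        assert len(grid.slots) == 240

    def test_small_window(self):
        tpl = make_template("quarter_pattern", 60.0)  # 4 s bars
        assert build_grid(tpl, CaptureWindow(0.0, 8.0)).n_bars == 2

    def test_offset_translates_grid_exactly(self, quarter, window):
        base = build_grid(quarter, window, song_offset_ms=0.0)
        shifted = build_grid(quarter, window, song_offset_ms=137.0)
        for a, b in zip(shifted.slots, base.slots):
            assert a.nominal_ms == pytest.approx(b.nominal_ms + 137.0)

    def test_window_shorter_than_bar_errors(self, quarter):
        with pytest.raises(ValueError, match="shorter than one bar"):
            build_grid(quarter, CaptureWindow(0.0, 1.0))

    def test_slot_spacing_constant(self, eighth, window):
        grid = build_grid(eighth, window)
        nominal = [s.nominal_ms for s in grid.slots]
        assert np.allclose(np.diff(nominal), 250.0)  # eighth notes at 120 bpm


class TestMatching:
    def four_bar_grid(self):
        return build_grid(make_template("quarter_pattern", 120.0), CaptureWindow(0.0, 8.0))

    def test_perfect_performance_all_completed(self):
        grid = self.four_bar_grid()
        results = match_events(perfect_quarter_events(grid), grid)
        assert all(r.completed for r in results)
        assert all(
            sm.deviation_ms == 0.0 for r in results for sm in r.slot_matches
        )

    def test_one_displaced_snare_breaks_one_bar(self):
        grid = self.four_bar_grid()
        events = []
        for e in perfect_quarter_events(grid):
            if e.instrument == "snare" and e.onset_ms == 500.0:  # bar 0, beat 2
                e = DrumEvent(e.onset_ms + 300.0, e.instrument, e.limb, e.velocity)
            events.append(e)
        results = match_events(sorted(events, key=lambda e: e.onset_ms), grid)
        assert [r.completed for r in results] == [False, True, True, True]
        # and it agrees with the exhaustive oracle on the snare instrument
        snare_nominals = [s.nominal_ms for s in grid.slots if ("LH", "snare") in s.expected]
        snare_onsets = sorted(e.onset_ms for e in events if e.instrument == "snare")
        n_matched, _, _ = exhaustive_assignment(snare_nominals, snare_onsets, 250.0)
        assert n_matched == 7

    def test_distance_tie_goes_to_earlier_event(self):
        grid = build_grid(make_template("quarter_pattern", 120.0), CaptureWindow(0.0, 2.0))
        events = [e for e in perfect_quarter_events(grid)
                  if not (e.instrument == "snare" and e.onset_ms == 500.0)]
        events += [DrumEvent(450.0, "snare", "LH"), DrumEvent(550.0, "snare", "LH")]
        results = match_events(sorted(events, key=lambda e: e.onset_ms), grid)
        (match,) = [sm for sm in results[0].slot_matches
                    if sm.instrument == "snare" and sm.slot_index == 1]
        assert match.event.onset_ms == 450.0

    def test_events_are_consumed_at_most_once(self):
        # a single snare event cannot satisfy both snare slots of the bar
        grid = build_grid(make_template("quarter_pattern", 120.0), CaptureWindow(0.0, 2.0))
        events = [e for e in perfect_quarter_events(grid)
                  if not (e.instrument == "snare" and e.onset_ms == 1500.0)]
        results = match_events(events, grid)
        snare_matches = [sm for sm in results[0].slot_matches if sm.instrument == "snare"]
        assert sum(sm.matched for sm in snare_matches) == 1
        assert not results[0].completed

    def test_tolerance_monotonicity_on_fixed_stream(self):
        tpl = make_template("quarter_pattern", 120.0)
        win = CaptureWindow(0.0, 60.0)
        events = simulate_performance(
            tpl, win, DrummerParams(jitter_sd_ms=120.0, miss_prob=0.05,
                                    extra_rate=0.5, seed=7))
        grid = build_grid(tpl, win)
        rates = [
            pct_bars_completed(match_events(events, grid, tolerance_ms=tol))
            for tol in (50, 100, 150, 200, 250, 350, 500)
        ]
        assert all(a <= b for a, b in zip(rates, rates[1:]))

    def test_translation_invariance(self):
        tpl = make_template("quarter_pattern", 120.0)
        win = CaptureWindow(0.0, 30.0)
        events = simulate_performance(
            tpl, win, DrummerParams(jitter_sd_ms=80.0, miss_prob=0.1, seed=3))
        base = score_performance(events, tpl, win)
        delta = 1500.0
        shifted_events = [DrumEvent(e.onset_ms + delta, e.instrument, e.limb, e.velocity)
                          for e in events]
        shifted = score_performance(shifted_events, tpl,
                                    CaptureWindow(1.5, 31.5), song_offset_ms=delta)
        assert shifted.pct_bars_completed == base.pct_bars_completed
        assert shifted.hrs_flam_mean_ms == pytest.approx(base.hrs_flam_mean_ms)


class TestScores:
    def test_pct_bars_completed(self):
        def bar(completed):
            from paradiddle.scoring import BarResult
            return BarResult(0, completed, [])

        assert pct_bars_completed([bar(True)] * 4) == 100.0
        assert pct_bars_completed([bar(True)] * 3 + [bar(False)]) == 75.0
        with pytest.raises(ValueError):
            pct_bars_completed([])

    def test_flam_is_first_to_last_spread(self):
        grid = build_grid(make_template("quarter_pattern", 120.0), CaptureWindow(0.0, 2.0))
        events = []
        for e in perfect_quarter_events(grid):
            if e.onset_ms == 500.0:  # beat-2 triplet: spread the three limbs
                offset = {"ride": 0.0, "snare": 10.0, "hihat_pedal": 25.0}[e.instrument]
                e = DrumEvent(e.onset_ms + offset, e.instrument, e.limb, e.velocity)
            events.append(e)
        results = match_events(sorted(events, key=lambda e: e.onset_ms), grid)
        flams = dict(
            ((b, s), ms) for b, s, ms in flam_errors(results)
        )
        assert flams[(0, 1)] == pytest.approx(25.0)  # 1025 - 1000 pattern: max-min
        assert flams[(0, 0)] == 0.0                  # simultaneous pair
        assert flams[(0, 3)] == 0.0

    def test_incomplete_bars_contribute_no_flams(self):
        grid = build_grid(make_template("quarter_pattern", 120.0), CaptureWindow(0.0, 4.0))
        events = [e for e in perfect_quarter_events(grid) if e.onset_ms != 0.0]
        results = match_events(events, grid)
        assert not results[0].completed and results[1].completed
        assert {b for b, _, _ in flam_errors(results)} == {1}

    def test_hrs_is_mean_of_beats_2_and_4(self, quarter):
        grid = build_grid(quarter, CaptureWindow(0.0, 8.0))
        events = []
        for e in perfect_quarter_events(grid):
            # spread the triplets: 10 ms on beat 2, 30 ms on beat 4
            beat_in_bar = (e.onset_ms % 2000.0) / 500.0
            if e.instrument == "hihat_pedal":
                e = DrumEvent(e.onset_ms + (10.0 if beat_in_bar == 1 else 30.0),
                              e.instrument, e.limb, e.velocity)
            events.append(e)
        results = match_events(sorted(events, key=lambda e: e.onset_ms), grid)
        assert hrs_error(results, quarter) == pytest.approx(20.0)

    def test_hrs_requires_quarter_template(self, eighth):
        with pytest.raises(ValueError):
            hrs_error([], eighth)

    def test_hrs_absent_without_completed_bars(self, quarter):
        grid = build_grid(quarter, CaptureWindow(0.0, 4.0))
        assert hrs_error(match_events([], grid), quarter) is None


class TestDelta:
    def summary(self, pct, hrs):
        return PerformanceSummary("quarter_pattern", pct, 60, int(0.6 * pct), hrs)

    def test_delta_pct_bars(self):
        d = delta_score(self.summary(13.0, 100.0), self.summary(47.0, 100.0))
        assert d["delta_pct_bars"] == pytest.approx(34.0)

    def test_identical_summaries_give_zero_deltas(self):
        d = delta_score(self.summary(50.0, 80.0), self.summary(50.0, 80.0))
        assert d["delta_pct_bars"] == 0.0
        assert d["delta_hrs_ms"] == 0.0
        assert d["delta_hrs_precision_pct"] == 0.0

    def test_hrs_precision_change_convention(self):
        d = delta_score(self.summary(10.0, 100.0), self.summary(20.0, 82.0))
        assert d["delta_hrs_ms"] == pytest.approx(-18.0)
        assert d["delta_hrs_precision_pct"] == pytest.approx(18.0)

    def test_absent_hrs_propagates(self):
        d = delta_score(self.summary(10.0, None), self.summary(20.0, 50.0))
        assert d["delta_hrs_ms"] is None

    def test_pattern_mismatch_errors(self):
        pre = self.summary(10.0, 50.0)
        post = PerformanceSummary("eighth_pattern", 20.0, 60, 12, None)
        with pytest.raises(ValueError):
            delta_score(pre, post)
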