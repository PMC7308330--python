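"""Bar-completion and flam scoring of multi-limb drum performances.

The two assessment patterns are played to fixed-tempo songs, so "perfect
timing" is a rigid beat grid.  A bar counts as completed when every expected
strike of the pattern has a matching event within half a beat of its nominal
time (250 ms for the quarter-note pattern and 125 ms for the eighth-note
pattern at the default 120 bpm).  Flam error is the first-to-last spread (ms)
of events that should have been simultaneous; it is evaluated only in
completed bars so that a collapsing performance cannot inflate it.  The HRS
(hi-hat-pedal / ride / snare) coordination error is the flam on beats 2 and 4
of the quarter-note pattern — the three-limb strikes combining both hands
with the left foot.

Matching is per-instrument, one-to-one and globally optimal: among
assignments of events to expected strikes it maximizes the number of strikes
matched within tolerance and, among those, minimizes the total absolute
deviation (ties broken toward the earlier event).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .events import CaptureWindow, DrumEvent

__all__ = [
    "PatternTemplate",
    "GridSlot",
    "BeatGrid",
    "StrikeMatch",
    "BarResult",
    "PerformanceSummary",
    "make_template",
    "build_grid",
    "match_events",
    "pct_bars_completed",
    "flam_errors",
    "hrs_error",
    "score_performance",
    "delta_score",
]

QUARTER = "quarter_pattern"
EIGHTH = "eighth_pattern"

# Strike = (limb, instrument).  Quarter pattern ("Green Onions"): RH+RF
# together on beats 1 and 3, RH+LH+LF together on beats 2 and 4.
_QUARTER_EXPECTED = (
    frozenset({("RH", "ride"), ("RF", "kick")}),
    frozenset({("RH", "ride"), ("LH", "snare"), ("LF", "hihat_pedal")}),
    frozenset({("RH", "ride"), ("RF", "kick")}),
    frozenset({("RH", "ride"), ("LH", "snare"), ("LF", "hihat_pedal")}),
)
# Eighth pattern ("Billie Jean"): hi-hats on all eight eighth notes with
# kick on beats 1/3 and snare on beats 2/4.
_EIGHTH_EXPECTED = (
    frozenset({("RH", "hihat_closed"), ("RF", "kick")}),
    frozenset({("RH", "hihat_closed")}),
    frozenset({("RH", "hihat_closed"), ("LH", "snare")}),
    frozenset({("RH", "hihat_closed")}),
    frozenset({("RH", "hihat_closed"), ("RF", "kick")}),
    frozenset({("RH", "hihat_closed")}),
    frozenset({("RH", "hihat_closed"), ("LH", "snare")}),
    frozenset({("RH", "hihat_closed")}),
)

# HRS condition: the three-limb slots of the quarter pattern, beats 2 and 4
# (0-based slot indices 1 and 3).
HRS_SLOTS = (1, 3)


@dataclass(frozen=True)
class PatternTemplate:
    pattern_id: str
    tempo_bpm: float
    slots_per_bar: int
    expected: tuple[frozenset, ...]
    tolerance_ms: float
    beats_per_bar: int = 4

    @property
    def beat_ms(self) -> float:
        return 60_000.0 / self.tempo_bpm

    @property
    def bar_ms(self) -> float:
        return self.beats_per_bar * self.beat_ms

    @property
    def slot_interval_ms(self) -> float:
        return self.bar_ms / self.slots_per_bar

    @property
    def strikes_per_bar(self) -> int:
        return sum(len(s) for s in self.expected)


def make_template(pattern_id: str, tempo_bpm: float = 120.0,
                  tolerance_override: Optional[float] = None) -> PatternTemplate:
    """Build an assessment-pattern template at a given tempo.

    The completion tolerance is half the pattern's subdivision interval:
    half a beat (0.5 * 60000 / bpm ms) for the quarter pattern and half an
    eighth note (0.25 * 60000 / bpm ms) for the eighth pattern — 250 and
    125 ms at the default 120 bpm.
    """
    if tempo_bpm <= 0:
        raise ValueError(f"tempo_bpm must be > 0, got {tempo_bpm}")
    if pattern_id == QUARTER:
        expected, slots = _QUARTER_EXPECTED, 4
    elif pattern_id == EIGHTH:
        expected, slots = _EIGHTH_EXPECTED, 8
    else:
        raise ValueError(f"unknown pattern_id {pattern_id!r} (expected {QUARTER!r} or {EIGHTH!r})")
    beat_ms = 60_000.0 / tempo_bpm
    tolerance = tolerance_override if tolerance_override is not None else 0.5 * beat_ms * 4 / slots
    if tolerance <= 0:
        raise ValueError("tolerance_ms must be > 0")
    return PatternTemplate(pattern_id, tempo_bpm, slots, expected, tolerance)


@dataclass(frozen=True)
class GridSlot:
    bar_index: int
    slot_index: int
    nominal_ms: float
    expected: frozenset


@dataclass(frozen=True)
class BeatGrid:
    template: PatternTemplate
    slots: tuple[GridSlot, ...]

    @property
    def n_bars(self) -> int:
        return self.slots[-1].bar_index + 1 if self.slots else 0


def build_grid(template: PatternTemplate, window: CaptureWindow,
               song_offset_ms: float = 0.0) -> BeatGrid:
    """Lay out the nominal strike times of every bar whose start falls in the window.

    Bars are anchored to the song: bar k starts at song_offset_ms + k*bar_ms.
    A bar belongs to the grid iff its bar-start time is in [start, end).
    """
    bar_ms = template.bar_ms
    if window.duration_ms < bar_ms:
        raise ValueError(
            f"capture window ({window.duration_ms:.0f} ms) shorter than one bar ({bar_ms:.0f} ms)"
        )
    first_bar = math.ceil((window.start_ms - song_offset_ms) / bar_ms - 1e-9)
    first_bar = max(first_bar, 0)
    slots = []
    bar_out = 0
    k = first_bar
    while song_offset_ms + k * bar_ms < window.end_ms - 1e-9:
        bar_start = song_offset_ms + k * bar_ms
        for s, expected in enumerate(template.expected):
            slots.append(GridSlot(bar_out, s, bar_start + s * template.slot_interval_ms, expected))
        bar_out += 1
        k += 1
    return BeatGrid(template, tuple(slots))


@dataclass(frozen=True)
class StrikeMatch:
    """One expected strike and the event assigned to it (if any)."""

    bar_index: int
    slot_index: int
    limb: str
    instrument: str
    nominal_ms: float
    event: Optional[DrumEvent] = None
    deviation_ms: Optional[float] = None

    @property
    def matched(self) -> bool:
        return self.event is not None


@dataclass
class BarResult:
    bar_index: int
    completed: bool
    slot_matches: list[StrikeMatch]
    flam_ms: dict = field(default_factory=dict)  # slot_index -> ms, completed bars only


def _assign_instrument(nominals: list[float], onsets: list[float],
                       tolerance_ms: float) -> list[Optional[int]]:
    """Optimal one-to-one matching of expected strike times to event onsets.

    Lexicographic objective: maximize strikes matched within tolerance, then
    minimize the summed |deviation|.  Realized as a rectangular assignment
    with a prohibitively large cost on out-of-tolerance pairs; an
    infinitesimal per-event-index penalty makes distance ties resolve toward
    the earlier event.
    """
    assignment: list[Optional[int]] = [None] * len(nominals)
    if not nominals or not onsets:
        return assignment

    # No feasible pair spans more than tolerance_ms, so the problem splits
    # exactly at every gap > tolerance in the merged sorted positions; each
    # connected block is solved as its own (small) assignment problem.
    items = sorted(
        [(t, 0, i) for i, t in enumerate(nominals)] + [(t, 1, j) for j, t in enumerate(onsets)]
    )
    blocks: list[tuple[list[int], list[int]]] = []
    current: tuple[list[int], list[int]] = ([], [])
    prev_pos = None
    for pos, kind, idx in items:
        if prev_pos is not None and pos - prev_pos > tolerance_ms + 1e-9 and any(current):
            blocks.append(current)
            current = ([], [])
        current[kind].append(idx)
        prev_pos = pos
    blocks.append(current)

    nominals_arr = np.asarray(nominals)
    onsets_arr = np.asarray(onsets)
    for strike_idx, event_idx in blocks:
        if not strike_idx or not event_idx:
            continue
        dev = np.abs(np.subtract.outer(nominals_arr[strike_idx], onsets_arr[event_idx]))
        feasible = dev <= tolerance_ms + 1e-9
        big = max(1.0, dev[feasible].sum() if feasible.any() else 1.0) * 1e6
        cost = np.where(feasible, dev, big)
        cost = cost + np.asarray(event_idx) * 1e-7  # tie-break toward earlier events
        rows, cols = linear_sum_assignment(cost)
        for r, c in zip(rows, cols):
            if feasible[r, c]:
                assignment[strike_idx[r]] = event_idx[c]
    return assignment


def match_events(events: Sequence[DrumEvent], grid: BeatGrid,
                 tolerance_ms: Optional[float] = None) -> list[BarResult]:
    """Assign events to the grid's expected strikes and flag completed bars.

    Events are pooled per instrument across the whole grid (an event can
    satisfy at most one strike anywhere, not just in its own bar); unmatched
    extra events are ignored.  Flam spreads are recorded for multi-strike
    slots of completed bars.
    """
    tol = grid.template.tolerance_ms if tolerance_ms is None else tolerance_ms

    strikes: list[tuple[GridSlot, str, str]] = []
    for slot in grid.slots:
        for limb, instrument in sorted(slot.expected):
            strikes.append((slot, limb, instrument))

    by_instrument: dict[str, list[int]] = {}
    for i, (_, _, instrument) in enumerate(strikes):
        by_instrument.setdefault(instrument, []).append(i)

    events_by_instrument: dict[str, list[DrumEvent]] = {}
    for e in sorted(events, key=lambda e: e.onset_ms):
        events_by_instrument.setdefault(e.instrument, []).append(e)

    matched_event: list[Optional[DrumEvent]] = [None] * len(strikes)
    for instrument, strike_idx in by_instrument.items():
        evs = events_by_instrument.get(instrument, [])
        nominals = [strikes[i][0].nominal_ms for i in strike_idx]
        assignment = _assign_instrument(nominals, [e.onset_ms for e in evs], tol)
        for i, j in zip(strike_idx, assignment):
            if j is not None:
                matched_event[i] = evs[j]

    n_bars = grid.n_bars
    bars = [BarResult(b, True, []) for b in range(n_bars)]
    for (slot, limb, instrument), event in zip(strikes, matched_event):
        deviation = event.onset_ms - slot.nominal_ms if event is not None else None
        sm = StrikeMatch(slot.bar_index, slot.slot_index, limb, instrument,
                         slot.nominal_ms, event, deviation)
        bar = bars[slot.bar_index]
        bar.slot_matches.append(sm)
        if not sm.matched:
            bar.completed = False

    for bar in bars:
        if not bar.completed:
            continue
        per_slot: dict[int, list[float]] = {}
        for sm in bar.slot_matches:
            per_slot.setdefault(sm.slot_index, []).append(sm.event.onset_ms)
        for slot_index, onsets in per_slot.items():
            if len(onsets) >= 2:
                bar.flam_ms[slot_index] = max(onsets) - min(onsets)
    return bars


def pct_bars_completed(results: Sequence[BarResult]) -> float:
    """Percent of scored bars completed (0-100)."""
    if not results:
        raise ValueError("no bars scored")
    return 100.0 * sum(r.completed for r in results) / len(results)


def flam_errors(results: Sequence[BarResult]) -> list[tuple[int, int, float]]:
    """All (bar_index, slot_index, flam_ms) spreads from completed bars."""
    return [
        (bar.bar_index, slot_index, ms)
        for bar in results
        if bar.completed
        for slot_index, ms in sorted(bar.flam_ms.items())
    ]


def hrs_error(results: Sequence[BarResult], template: PatternTemplate) -> Optional[float]:
    """Mean flam (ms) on beats 2 and 4 of the quarter pattern, pooled over completed bars.

    Returns None when no bar was completed (the measure is undefined).
    """
    if template.pattern_id != QUARTER:
        raise ValueError("HRS coordination error is defined on the quarter-note pattern only")
    flams = [ms for _, slot, ms in flam_errors(results) if slot in HRS_SLOTS]
    return float(np.mean(flams)) if flams else None


@dataclass(frozen=True)
class PerformanceSummary:
    pattern_id: str
    pct_bars_completed: float
    n_bars_scored: int
    n_bars_completed: int
    hrs_flam_mean_ms: Optional[float] = None
    flam_mean_ms: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "pattern_id": self.pattern_id,
            "pct_bars_completed": self.pct_bars_completed,
            "n_bars_scored": self.n_bars_scored,
            "n_bars_completed": self.n_bars_completed,
            "hrs_flam_mean_ms": self.hrs_flam_mean_ms,
            "flam_mean_ms": self.flam_mean_ms,
        }


def score_performance(events: Sequence[DrumEvent], template: PatternTemplate,
                      window: CaptureWindow | None = None,
                      song_offset_ms: float = 0.0) -> PerformanceSummary:
    """Clip, grid, match and summarize one performance of one pattern."""
    from .events import clip_window

    window = window or CaptureWindow()
    grid = build_grid(template, window, song_offset_ms)
    results = match_events(clip_window(events, window), grid)
    all_flams = [ms for _, _, ms in flam_errors(results)]
    return PerformanceSummary(
        pattern_id=template.pattern_id,
        pct_bars_completed=pct_bars_completed(results),
        n_bars_scored=len(results),
        n_bars_completed=sum(r.completed for r in results),
        hrs_flam_mean_ms=hrs_error(results, template) if template.pattern_id == QUARTER else None,
        flam_mean_ms=float(np.mean(all_flams)) if all_flams else None,
    )


def delta_score(pre: PerformanceSummary, post: PerformanceSummary) -> dict:
    """Post-minus-pre change of the performance measures.

    ``delta_hrs_ms`` is the raw post - pre change (negative = improvement);
    ``delta_hrs_precision_pct`` is 100*(pre - post)/pre, the percent gain in
    precision (positive = improvement).  Both are emitted; which one feeds a
    downstream test is a pipeline configuration choice.
    """
    if pre.pattern_id != post.pattern_id:
        raise ValueError("delta requires summaries of the same pattern")
    out = {"delta_pct_bars": post.pct_bars_completed - pre.pct_bars_completed}
    if pre.hrs_flam_mean_ms is None or post.hrs_flam_mean_ms is None:
        out["delta_hrs_ms"] = None
        out["delta_hrs_precision_pct"] = None
    else:
        out["delta_hrs_ms"] = post.hrs_flam_mean_ms - pre.hrs_flam_mean_ms
        out["delta_hrs_precision_pct"] = (
            100.0 * (pre.hrs_flam_mean_ms - post.hrs_flam_mean_ms) / pre.hrs_flam_mean_ms
            if pre.hrs_flam_mean_ms != 0 else None
        )
    return out
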