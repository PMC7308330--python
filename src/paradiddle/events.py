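"""Drum event streams: domain types, MIDI/CSV ingest, and capture-window clipping.

A performance is a time-sorted sequence of :class:`DrumEvent`.  MIDI note
numbers are mapped to kit instruments and instruments to limbs through a
:class:`LimbMap`; the default follows the General MIDI percussion map and the
four-limb kit assignment of the quarter-note assessment pattern (right hand
ride, left hand snare, right foot kick, left foot hi-hat pedal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import smf

__all__ = [
    "INSTRUMENTS",
    "LIMBS",
    "DrumEvent",
    "LimbMap",
    "CaptureWindow",
    "SchemaError",
    "read_smf",
    "write_smf",
    "clip_window",
    "read_events_csv",
    "write_events_csv",
]

INSTRUMENTS = ("kick", "snare", "ride", "hihat_closed", "hihat_pedal", "other")
LIMBS = ("RH", "LH", "RF", "LF", "unknown")

CSV_COLUMNS = ["onset_ms", "instrument", "limb", "velocity"]


class SchemaError(ValueError):
    """A CSV event table does not match the fixed schema."""


@dataclass(frozen=True, order=True)
class DrumEvent:
    """One percussive onset."""

    onset_ms: float
    instrument: str
    limb: str
    velocity: int = 100

    def __post_init__(self):
        if not (self.onset_ms >= 0.0 and self.onset_ms == self.onset_ms):
            raise ValueError(f"onset_ms must be finite and >= 0, got {self.onset_ms}")
        if self.instrument not in INSTRUMENTS:
            raise ValueError(f"unknown instrument {self.instrument!r}")
        if self.limb not in LIMBS:
            raise ValueError(f"unknown limb {self.limb!r}")
        if not 0 <= int(self.velocity) <= 127:
            raise ValueError(f"velocity out of MIDI range: {self.velocity}")


# General MIDI percussion numbers for the pieces of the assessment kit.
_GM_NOTE_TO_INSTRUMENT = {
    35: "kick",  # acoustic bass drum
    36: "kick",
    38: "snare",
    40: "snare",  # electric snare
    51: "ride",
    59: "ride",  # ride 2
    42: "hihat_closed",
    44: "hihat_pedal",
}

# Kit assignment of the quarter-note pattern: RH ride, LH snare, RF kick,
# LF hi-hat pedal.  Closed hi-hat (stick on hats) is a hand instrument and
# defaults to the right hand, as in the eighth-note pattern.
_DEFAULT_INSTRUMENT_TO_LIMB = {
    "kick": "RF",
    "snare": "LH",
    "ride": "RH",
    "hihat_closed": "RH",
    "hihat_pedal": "LF",
    "other": "unknown",
}


@dataclass(frozen=True)
class LimbMap:
    """Two-stage mapping MIDI note -> instrument -> limb.

    Unmapped notes route to ``("other", "unknown")`` rather than erroring, so
    stray kit pieces in a capture do not abort ingest.
    """

    note_to_instrument: Mapping[int, str] = field(default_factory=lambda: dict(_GM_NOTE_TO_INSTRUMENT))
    instrument_to_limb: Mapping[str, str] = field(default_factory=lambda: dict(_DEFAULT_INSTRUMENT_TO_LIMB))

    def classify(self, note: int) -> tuple[str, str]:
        instrument = self.note_to_instrument.get(note, "other")
        return instrument, self.instrument_to_limb.get(instrument, "unknown")

    def note_for(self, instrument: str) -> int:
        """First note number mapping to ``instrument`` (used by the SMF writer)."""
        for note, inst in sorted(self.note_to_instrument.items()):
            if inst == instrument:
                return note
        return 39  # GM hand clap, maps back to "other"

    @classmethod
    def from_yaml(cls, path) -> "LimbMap":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        note_to_instrument = dict(_GM_NOTE_TO_INSTRUMENT)
        note_to_instrument.update({int(k): str(v) for k, v in (cfg.get("note_to_instrument") or {}).items()})
        instrument_to_limb = dict(_DEFAULT_INSTRUMENT_TO_LIMB)
        instrument_to_limb.update({str(k): str(v) for k, v in (cfg.get("instrument_to_limb") or {}).items()})
        bad = [i for i in instrument_to_limb.values() if i not in LIMBS]
        if bad:
            raise ValueError(f"unknown limb(s) in limb map: {bad}")
        return cls(note_to_instrument, instrument_to_limb)


@dataclass(frozen=True)
class CaptureWindow:
    """Half-open assessment window [start_s, end_s) in seconds from song start.

    The default 60-180 s is the 2-minute capture taken from minute 1 to
    minute 3 of each song.
    """

    start_s: float = 60.0
    end_s: float = 180.0

    def __post_init__(self):
        if not 0 <= self.start_s < self.end_s:
            raise ValueError(f"need 0 <= start_s < end_s, got [{self.start_s}, {self.end_s})")

    @property
    def start_ms(self) -> float:
        return self.start_s * 1000.0

    @property
    def end_ms(self) -> float:
        return self.end_s * 1000.0

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms


def read_smf(path, limb_map: LimbMap | None = None) -> list[DrumEvent]:
    """Read note-on events from an SMF type 0/1 file as drum events in ms.

    Tick times are converted with the file's tempo map (constant tempo if a
    single tempo event, piecewise-constant otherwise).  Raises
    :class:`paradiddle.smf.SMFError` for unreadable files and
    :class:`paradiddle.smf.EmptyStreamError` when the file has no note-ons.
    """
    limb_map = limb_map or LimbMap()
    events = []
    for note_on in smf.read_note_ons(path):
        instrument, limb = limb_map.classify(note_on.note)
        events.append(DrumEvent(note_on.onset_ms, instrument, limb, note_on.velocity))
    events.sort(key=lambda e: e.onset_ms)
    return events


def write_smf(events: Sequence[DrumEvent], path, limb_map: LimbMap | None = None,
              *, tempo_us: int = smf.DEFAULT_TEMPO_US, division: int = 480) -> None:
    """Write drum events as a type-0 SMF (inverse of :func:`read_smf` up to tick quantization)."""
    limb_map = limb_map or LimbMap()
    notes = [(e.onset_ms, limb_map.note_for(e.instrument), e.velocity) for e in events]
    smf.write_smf_notes(path, notes, tempo_us=tempo_us, division=division)


def clip_window(events: Iterable[DrumEvent], window: CaptureWindow) -> list[DrumEvent]:
    """Keep events with start_ms <= onset < end_ms, order preserved."""
    return [e for e in events if window.start_ms <= e.onset_ms < window.end_ms]


def rebase(events: Iterable[DrumEvent], offset_ms: float) -> list[DrumEvent]:
    """Shift all onsets by ``offset_ms`` (must keep onsets non-negative)."""
    return [replace(e, onset_ms=e.onset_ms + offset_ms) for e in events]


def write_events_csv(events: Sequence[DrumEvent], path) -> None:
    df = pd.DataFrame(
        [(e.onset_ms, e.instrument, e.limb, e.velocity) for e in events],
        columns=CSV_COLUMNS,
    )
    # %.17g keeps the round trip lossless for float64 onsets
    df.to_csv(path, index=False, float_format="%.17g")


def read_events_csv(path) -> list[DrumEvent]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path!r}: missing column(s) {missing}; expected {CSV_COLUMNS}")
    events = [
        DrumEvent(float(r.onset_ms), str(r.instrument), str(r.limb), int(r.velocity))
        for r in df.itertuples()
    ]
    events.sort(key=lambda e: e.onset_ms)
    return events
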