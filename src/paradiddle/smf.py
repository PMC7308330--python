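"""Minimal Standard MIDI File (SMF) type 0/1 reading and writing.

Only what percussion-timing analysis needs is implemented: note events,
running status, tempo meta events, and tick-to-millisecond conversion with
a piecewise-constant tempo map.  SMPTE time divisions are rejected.
"""

from __future__ import annotations

import struct
from typing import NamedTuple

__all__ = ["SMFError", "EmptyStreamError", "NoteOn", "read_note_ons", "write_smf_notes"]

DEFAULT_TEMPO_US = 500_000  # microseconds per quarter note (120 bpm)


class SMFError(ValueError):
    """The file is not a readable SMF type 0/1."""


class EmptyStreamError(SMFError):
    """The file parsed but contains no note-on events."""


class NoteOn(NamedTuple):
    onset_ms: float
    note: int
    velocity: int
    channel: int


def _read_varlen(data: bytes, i: int) -> tuple[int, int]:
    value = 0
    while True:
        if i >= len(data):
            raise SMFError("truncated variable-length quantity")
        byte = data[i]
        i += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, i


def _parse_track(data: bytes) -> tuple[list[tuple[int, int, int, int]], list[tuple[int, int]]]:
    """Return ([(tick, note, velocity, channel)], [(tick, us_per_beat)])."""
    notes: list[tuple[int, int, int, int]] = []
    tempos: list[tuple[int, int]] = []
    tick = 0
    i = 0
    status = 0
    while i < len(data):
        delta, i = _read_varlen(data, i)
        tick += delta
        if i >= len(data):
            raise SMFError("truncated track")
        byte = data[i]
        if byte & 0x80:
            status = byte
            i += 1
        elif status == 0:
            raise SMFError("data byte with no running status")
        if status == 0xFF:  # meta event
            if i >= len(data):
                raise SMFError("truncated meta event")
            meta_type = data[i]
            length, i = _read_varlen(data, i + 1)
            payload = data[i : i + length]
            if len(payload) < length:
                raise SMFError("truncated meta payload")
            i += length
            if meta_type == 0x51:
                if length != 3:
                    raise SMFError("malformed tempo event")
                tempos.append((tick, int.from_bytes(payload, "big")))
            if meta_type == 0x2F:  # end of track
                break
        elif status in (0xF0, 0xF7):  # sysex
            length, i = _read_varlen(data, i)
            i += length
        else:
            kind = status & 0xF0
            n_data = 1 if kind in (0xC0, 0xD0) else 2
            if i + n_data > len(data):
                raise SMFError("truncated channel message")
            if kind == 0x90 and data[i + 1] > 0:  # note-on, velocity 0 is note-off
                notes.append((tick, data[i], data[i + 1], status & 0x0F))
            i += n_data
    return notes, tempos


def _ticks_to_ms(tick: int, division: int, tempo_map: list[tuple[int, int]]) -> float:
    """Convert an absolute tick to milliseconds under a piecewise-constant tempo map."""
    ms = 0.0
    prev_tick = 0
    tempo = DEFAULT_TEMPO_US
    for t_tick, t_tempo in tempo_map:
        if t_tick >= tick:
            break
        ms += (t_tick - prev_tick) * tempo / (1000.0 * division)
        prev_tick, tempo = t_tick, t_tempo
    ms += (tick - prev_tick) * tempo / (1000.0 * division)
    return ms


def read_note_ons(path) -> list[NoteOn]:
    """Parse an SMF type 0/1 file into note-on events with onsets in ms.

    Tempo events from all tracks are merged into one tempo map (the type-1
    convention keeps them in the first track, but merging is harmless and
    tolerant).  Raises :class:`SMFError` on malformed input and
    :class:`EmptyStreamError` when no note-on is present.
    """
    try:
        with open(path, "rb") as fh:
            data = fh.read()
    except OSError as exc:
        raise SMFError(f"cannot read SMF file {path!r}: {exc}") from exc
    if len(data) < 14 or data[:4] != b"MThd":
        raise SMFError(f"{path!r} is not a Standard MIDI File (missing MThd)")
    header_len, fmt, ntrks, division = struct.unpack(">IHHH", data[4:14])
    if header_len < 6:
        raise SMFError(f"{path!r}: malformed MThd header")
    if fmt not in (0, 1):
        raise SMFError(f"{path!r}: SMF format {fmt} not supported (only 0/1)")
    if division & 0x8000:
        raise SMFError(f"{path!r}: SMPTE time division not supported")
    if division == 0:
        raise SMFError(f"{path!r}: zero ticks-per-beat division")

    i = 8 + header_len
    raw_notes: list[tuple[int, int, int, int]] = []
    tempo_map: list[tuple[int, int]] = []
    tracks_seen = 0
    while tracks_seen < ntrks and i + 8 <= len(data):
        chunk_id = data[i : i + 4]
        (chunk_len,) = struct.unpack(">I", data[i + 4 : i + 8])
        chunk = data[i + 8 : i + 8 + chunk_len]
        if chunk_id == b"MTrk":
            if len(chunk) < chunk_len:
                raise SMFError(f"{path!r}: truncated track chunk")
            notes, tempos = _parse_track(chunk)
            raw_notes.extend(notes)
            tempo_map.extend(tempos)
            tracks_seen += 1
        i += 8 + chunk_len
    if tracks_seen == 0:
        raise SMFError(f"{path!r}: no MTrk chunk found")
    if not raw_notes:
        raise EmptyStreamError(f"{path!r}: no note-on events")

    tempo_map.sort(key=lambda t: t[0])
    out = [
        NoteOn(_ticks_to_ms(tick, division, tempo_map), note, vel, ch)
        for tick, note, vel, ch in raw_notes
    ]
    out.sort(key=lambda n: (n.onset_ms, n.note))
    return out


def _varlen(value: int) -> bytes:
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append((value & 0x7F) | 0x80)
        value >>= 7
    return bytes(reversed(chunks))


def write_smf_notes(
    path,
    notes: list[tuple[float, int, int]],
    *,
    tempo_us: int = DEFAULT_TEMPO_US,
    division: int = 480,
    channel: int = 9,
) -> None:
    """Write (onset_ms, note, velocity) triples as a type-0 SMF.

    Onsets are quantized to the nearest tick; each note-on gets a matching
    note-off one tick later so players terminate notes cleanly.  Channel 9
    is the General MIDI percussion channel.
    """
    events: list[tuple[int, bytes]] = [(0, bytes([0xFF, 0x51, 0x03]) + tempo_us.to_bytes(3, "big"))]
    for onset_ms, note, velocity in notes:
        tick = round(onset_ms * 1000.0 * division / tempo_us)
        events.append((tick, bytes([0x90 | channel, note & 0x7F, max(1, min(127, velocity))])))
        events.append((tick + 1, bytes([0x80 | channel, note & 0x7F, 0])))
    events.sort(key=lambda e: e[0])

    body = bytearray()
    prev = 0
    for tick, msg in events:
        body += _varlen(tick - prev) + msg
        prev = tick
    body += _varlen(0) + bytes([0xFF, 0x2F, 0x00])

    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, division))
        fh.write(b"MTrk" + struct.pack(">I", len(body)) + bytes(body))
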