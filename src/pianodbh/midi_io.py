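"""Standard MIDI File (SMF) reading and writing for performed-note records.

Only the events the analysis needs are interpreted: note-on, note-off
(including the running-status convention of note-on with velocity 0), and
set-tempo meta events.  The tempo map is applied to convert delta ticks to
seconds.  Overlapping same-pitch notes are resolved first-in-first-out,
which matches how piano capture systems emit re-struck keys.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

DEFAULT_TEMPO_US = 500_000  # microseconds per quarter note (120 bpm)


class MidiError(ValueError):
    """Raised for malformed or unsupported MIDI files."""


@dataclass(frozen=True)
class PerformedNote:
    pitch: int
    onset_sec: float
    offset_sec: float
    velocity: int
    source_track: int = 0

    def __post_init__(self) -> None:
        if self.onset_sec < 0:
            raise MidiError(f"note pitch={self.pitch}: negative onset {self.onset_sec}")
        if self.offset_sec <= self.onset_sec:
            raise MidiError(
                f"note pitch={self.pitch}: offset {self.offset_sec} <= onset {self.onset_sec}"
            )
        if not 1 <= self.velocity <= 127:
            raise MidiError(f"velocity {self.velocity} outside [1, 127]")

    @property
    def duration_sec(self) -> float:
        return self.offset_sec - self.onset_sec


@dataclass
class Performance:
    performer_id: str = ""
    group: str = "unknown"
    excerpt_id: str = ""
    notes: list[PerformedNote] = field(default_factory=list)
    truth_hand: list[str] | None = None  # synthetic ground truth only

    def sort(self) -> None:
        """Sort notes by (onset, pitch), carrying truth labels along."""
        if self.truth_hand is None:
            self.notes.sort(key=lambda n: (n.onset_sec, n.pitch))
        else:
            order = sorted(
                range(len(self.notes)),
                key=lambda i: (self.notes[i].onset_sec, self.notes[i].pitch),
            )
            self.notes = [self.notes[i] for i in order]
            self.truth_hand = [self.truth_hand[i] for i in order]


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def _write_varlen(value: int) -> bytes:
    if value < 0:
        raise MidiError(f"negative delta time {value}")
    out = [value & 0x7F]
    value >>= 7
    while value:
        out.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(out))


def _parse_track(data: bytes) -> list[tuple[int, int, int, int]]:
    """Yield (abs_tick, status, data1, data2) events; meta tempo encoded
    as status 0xFF51 with data1 = tempo (µs/qn)."""
    events = []
    pos = 0
    tick = 0
    running = 0
    while pos < len(data):
        delta, pos = _read_varlen(data, pos)
        tick += delta
        status = data[pos]
        if status & 0x80:
            pos += 1
            if status < 0xF0:
                running = status
        else:
            if not running:
                raise MidiError("running status byte with no prior status")
            status = running
        if status == 0xFF:
            meta_type = data[pos]
            pos += 1
            length, pos = _read_varlen(data, pos)
            payload = data[pos : pos + length]
            pos += length
            if meta_type == 0x51:
                tempo = int.from_bytes(payload, "big")
                events.append((tick, 0xFF51, tempo, 0))
        elif status in (0xF0, 0xF7):  # sysex
            length, pos = _read_varlen(data, pos)
            pos += length
        else:
            kind = status & 0xF0
            n_data = 1 if kind in (0xC0, 0xD0) else 2
            d1 = data[pos]
            d2 = data[pos + 1] if n_data == 2 else 0
            pos += n_data
            if kind in (0x80, 0x90):
                events.append((tick, kind, d1, d2))
    return events


def _ticks_to_seconds(events, ppq: int):
    """Return a function mapping absolute tick to seconds using the tempo map."""
    tempo_changes = sorted(
        [(t, d1) for t, s, d1, _ in [(e[0], e[1], e[2], e[3]) for e in events] if s == 0xFF51]
    )
    # segment boundaries: (tick, seconds_at_tick, us_per_qn)
    segments = [(0, 0.0, DEFAULT_TEMPO_US)]
    for tick, tempo in tempo_changes:
        last_tick, last_sec, last_tempo = segments[-1]
        sec = last_sec + (tick - last_tick) * last_tempo / (ppq * 1e6)
        if tick == last_tick:
            segments[-1] = (tick, sec, tempo)
        else:
            segments.append((tick, sec, tempo))

    def convert(tick: int) -> float:
        seg_tick, seg_sec, tempo = segments[0]
        for t, s, tp in segments:
            if t > tick:
                break
            seg_tick, seg_sec, tempo = t, s, tp
        return seg_sec + (tick - seg_tick) * tempo / (ppq * 1e6)

    return convert


def read_smf(path) -> Performance:
    """Read an SMF format 0 or 1 file into a Performance.

    Note-on/note-off pairs are resolved per pitch in FIFO order; a note-on
    with velocity 0 counts as a note-off.  A note-on left open at end of
    file raises a dangling-note error listing the pitches.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != b"MThd":
        raise MidiError(f"{path}: not a Standard MIDI File")
    header_len, fmt, n_tracks, division = struct.unpack(">IHHH", data[4:14])
    if fmt not in (0, 1):
        raise MidiError(f"unsupported SMF format {fmt}")
    if division & 0x8000:
        raise MidiError("SMPTE time division is not supported")
    ppq = division

    pos = 8 + header_len
    track_events = []
    for _ in range(n_tracks):
        if data[pos : pos + 4] != b"MTrk":
            raise MidiError("missing MTrk chunk")
        length = struct.unpack(">I", data[pos + 4 : pos + 8])[0]
        track_events.append(_parse_track(data[pos + 8 : pos + 8 + length]))
        pos += 8 + length

    all_events = [e for tr in track_events for e in tr]
    to_sec = _ticks_to_seconds(all_events, ppq)

    notes: list[PerformedNote] = []
    dangling: list[int] = []
    for track_idx, events in enumerate(track_events):
        open_notes: dict[int, list[tuple[int, int]]] = {}
        for tick, kind, d1, d2 in sorted(events, key=lambda e: e[0]):
            if kind == 0x90 and d2 > 0:
                open_notes.setdefault(d1, []).append((tick, d2))
            elif kind == 0x80 or (kind == 0x90 and d2 == 0):
                stack = open_notes.get(d1)
                if stack:
                    on_tick, vel = stack.pop(0)  # FIFO
                    if tick > on_tick:
                        notes.append(
                            PerformedNote(
                                d1, to_sec(on_tick), to_sec(tick), vel, track_idx
                            )
                        )
        dangling.extend(p for p, stack in open_notes.items() if stack)
    if dangling:
        raise MidiError(f"dangling note-on events at end of file: pitches {sorted(dangling)}")

    perf = Performance(notes=notes)
    perf.sort()
    return perf


def write_smf(
    performance: Performance, path, ppq: int = 480, tempo_us: int = DEFAULT_TEMPO_US
) -> None:
    """Write a type-1 SMF with a single note track; quantization error is at
    most half a tick."""
    def to_tick(sec: float) -> int:
        return round(sec * ppq * 1e6 / tempo_us)

    events: list[tuple[int, int, bytes]] = [(0, 0, bytes([0xFF, 0x51, 0x03]) + tempo_us.to_bytes(3, "big"))]
    for n in performance.notes:
        events.append((to_tick(n.onset_sec), 1, bytes([0x90, n.pitch, n.velocity])))
        events.append((max(to_tick(n.offset_sec), to_tick(n.onset_sec) + 1), 0, bytes([0x80, n.pitch, 0])))
    # note-offs before note-ons at the same tick so re-struck keys stay paired
    events.sort(key=lambda e: (e[0], e[1]))

    body = bytearray()
    last_tick = 0
    for tick, _, payload in events:
        body += _write_varlen(tick - last_tick)
        body += payload
        last_tick = tick
    body += _write_varlen(0) + bytes([0xFF, 0x2F, 0x00])  # end of track

    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 1, 1, ppq))
        fh.write(b"MTrk" + struct.pack(">I", len(body)) + bytes(body))
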