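"""Symbolic scores for the two technical excerpts and a tabular score format.

Both built-in excerpts are isochronous unison studies: the right and left
hands play the same melodic line in parallel octaves, so the k-th note of
each hand falls on the same beat.  The Hanon exercise is written in eighth
notes at 120 bpm, the C-major scale in sixteenth notes at 60 bpm; at those
tempi every note nominally lasts 0.25 s, which makes the two excerpts
directly comparable note for note.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

RH = "RH"
LH = "LH"

# C-major pitch classes, used for diatonic transposition of the Hanon pattern
_MAJOR_STEPS = [0, 2, 4, 5, 7, 9, 11]

#: Hanon No. 1 ascending cell, in semitones above the pattern root
#: (C-E-F-G-A-G-F-E when rooted on C).
HANON_TEMPLATE = (0, 4, 5, 7, 9, 7, 5, 4)


class ScoreError(ValueError):
    """Raised for invalid or inconsistent symbolic scores."""


@dataclass(frozen=True)
class ScoreNote:
    """One written note of a single hand's monophonic stream."""

    pitch: int
    onset_beats: float
    duration_beats: float
    hand: str
    measure_index: int = 1
    ordinal: int = 0

    def __post_init__(self) -> None:
        if not 21 <= self.pitch <= 108:
            raise ScoreError(f"pitch {self.pitch} outside the 88-key range 21-108")
        if self.duration_beats <= 0:
            raise ScoreError("duration_beats must be > 0")
        if self.hand not in (RH, LH):
            raise ScoreError(f"hand must be RH or LH, got {self.hand!r}")


@dataclass
class Score:
    excerpt_id: str
    nominal_bpm: float
    beat_unit: str = "quarter"
    notes: list[ScoreNote] = field(default_factory=list)

    def hand_notes(self, hand: str) -> list[ScoreNote]:
        """Notes of one hand, in onset order (ordinal order)."""
        return sorted(
            (n for n in self.notes if n.hand == hand), key=lambda n: n.onset_beats
        )

    @property
    def seconds_per_beat(self) -> float:
        return 60.0 / self.nominal_bpm

    def duration_sec(self, note: ScoreNote) -> float:
        """Nominal duration of a written note in seconds at the score tempo."""
        return note.duration_beats * self.seconds_per_beat

    def validate(self) -> None:
        for hand in (RH, LH):
            notes = self.hand_notes(hand)
            for a, b in zip(notes, notes[1:]):
                if b.onset_beats <= a.onset_beats:
                    raise ScoreError(
                        f"{hand} onsets not strictly increasing at beat {b.onset_beats}"
                    )
                if a.onset_beats + a.duration_beats > b.onset_beats + 1e-9:
                    raise ScoreError(
                        f"{hand} notes overlap at beat {a.onset_beats} (monophonic per hand)"
                    )

    def unison_pairs(self) -> list[tuple[ScoreNote, ScoreNote]]:
        """(RH, LH) note pairs sharing the same written onset.

        For the built-in excerpts every note belongs to exactly one pair.
        """
        lh_by_onset = {n.onset_beats: n for n in self.hand_notes(LH)}
        pairs = []
        for rn in self.hand_notes(RH):
            ln = lh_by_onset.get(rn.onset_beats)
            if ln is not None:
                pairs.append((rn, ln))
        return pairs


def _renumber(notes: list[ScoreNote]) -> list[ScoreNote]:
    """Assign per-hand ordinals in onset order."""
    out: list[ScoreNote] = []
    for hand in (RH, LH):
        hand_notes = sorted(
            (n for n in notes if n.hand == hand), key=lambda n: n.onset_beats
        )
        out.extend(replace(n, ordinal=i) for i, n in enumerate(hand_notes))
    out.sort(key=lambda n: (n.onset_beats, n.hand != RH))
    return out


def _degree_of(semitone: int) -> int:
    """C-major scale degree of a diatonic semitone offset (octave-aware)."""
    octave, pc = divmod(semitone, 12)
    if pc not in _MAJOR_STEPS:
        raise ScoreError(f"semitone offset {semitone} is not diatonic in C major")
    return octave * 7 + _MAJOR_STEPS.index(pc)


def _pitch_from_degree(root: int, degree: int) -> int:
    octave, step = divmod(degree, 7)
    return root + octave * 12 + _MAJOR_STEPS[step]


def build_hanon_score(
    n_patterns: int = 7,
    include_descending: bool = True,
    bpm: float = 120.0,
    template: tuple[int, ...] = HANON_TEMPLATE,
    rh_start: int = 60,
    lh_start: int = 36,
) -> Score:
    """Hanon Exercise No. 1: a repeating eight-note cell climbing the C-major
    scale one step per pattern, right hand from middle C (C4), left hand two
    octaves below (C2), in eighth notes.

    The descending half, when included, mirrors the ascending note sequence.
    """
    if n_patterns < 1:
        raise ScoreError("n_patterns must be >= 1")
    degrees = [_degree_of(s) for s in template]
    rh_pitches: list[int] = []
    for k in range(n_patterns):
        rh_pitches.extend(_pitch_from_degree(rh_start, d + k) for d in degrees)
    if include_descending:
        rh_pitches.extend(reversed(rh_pitches))
    offset = rh_start - lh_start
    if max(rh_pitches) > 108 or min(rh_pitches) - offset < 21:
        raise ScoreError("n_patterns exceeds the keyboard range")

    notes: list[ScoreNote] = []
    for i, p in enumerate(rh_pitches):
        onset = 0.5 * i
        measure = int(onset // 4) + 1  # 4/4, eight eighth-notes per measure
        notes.append(ScoreNote(p, onset, 0.5, RH, measure))
        notes.append(ScoreNote(p - offset, onset, 0.5, LH, measure))
    return Score("hanon1", bpm, "quarter", _renumber(notes))


def build_scale_score(
    octaves: int = 4,
    bpm: float = 60.0,
    rh_start: int = 60,
    lh_start: int = 48,
) -> Score:
    """C-major scale, hands one octave apart, ascending then descending in
    sixteenth notes; the top note is not repeated at the turn."""
    if octaves < 1:
        raise ScoreError("octaves must be >= 1")
    up = [_pitch_from_degree(rh_start, d) for d in range(7 * octaves + 1)]
    rh_pitches = up + up[-2::-1]
    if max(rh_pitches) > 108 or min(rh_pitches) - (rh_start - lh_start) < 21:
        raise ScoreError("octaves exceeds the keyboard range")

    offset = rh_start - lh_start
    notes: list[ScoreNote] = []
    for i, p in enumerate(rh_pitches):
        onset = 0.25 * i
        measure = int(onset // 4) + 1
        notes.append(ScoreNote(p, onset, 0.25, RH, measure))
        notes.append(ScoreNote(p - offset, onset, 0.25, LH, measure))
    return Score("cmajor_scale", bpm, "quarter", _renumber(notes))


SCORE_CSV_COLUMNS = ["pitch", "onset_beats", "duration_beats", "hand", "measure"]


def write_score_csv(score: Score, path) -> None:
    df = pd.DataFrame(
        {
            "pitch": [n.pitch for n in score.notes],
            "onset_beats": [n.onset_beats for n in score.notes],
            "duration_beats": [n.duration_beats for n in score.notes],
            "hand": [n.hand for n in score.notes],
            "measure": [n.measure_index for n in score.notes],
        }
    )
    df.to_csv(path, index=False)


def read_score_csv(path, excerpt_id: str = "custom", nominal_bpm: float = 120.0) -> Score:
    """Read a tabular score; per-hand ordinals are recomputed on read."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ScoreError(f"empty score file: {path}") from exc
    missing = set(SCORE_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ScoreError(f"score CSV missing columns: {sorted(missing)}")
    if df.empty:
        raise ScoreError(f"score file has no notes: {path}")
    notes = [
        ScoreNote(
            int(r.pitch),
            float(r.onset_beats),
            float(r.duration_beats),
            str(r.hand),
            int(r.measure),
        )
        for r in df.itertuples()
    ]
    score = Score(excerpt_id, nominal_bpm, "quarter", _renumber(notes))
    score.validate()
    return score


def get_builtin_score(excerpt_id: str, **kwargs) -> Score:
    if excerpt_id == "hanon1":
        return build_hanon_score(**kwargs)
    if excerpt_id == "cmajor_scale":
        return build_scale_score(**kwargs)
    raise ScoreError(f"unknown built-in excerpt {excerpt_id!r}")
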