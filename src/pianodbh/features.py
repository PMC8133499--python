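"""Per-note performance features and the 64-dimensional aggregate vector.

Basic features are computed per hand and per note.  With ``dur`` the
performed duration, ``ioi`` the performed inter-onset interval to the
hand's next matched note, and ``sdur`` the written duration in seconds at
the excerpt's nominal tempo:

    rDuration    = ln(dur / sdur)      absolute-tempo duration ratio
    rIOI         = ln(ioi / sdur)      absolute-tempo pacing ratio
    Articulation = ln(dur / ioi)       legato/staccato at the player's own tempo
    Velocity     = MIDI velocity       loudness proxy (1-127)

On the isochronous excerpts the written duration equals the written IOI,
so Articulation = rDuration - rIOI identically.  Delta features are
first differences along each hand's stream; their SD measures smoothness.

DBH (difference-between-hands) features take the written unison pairs in
which both members were matched and subtract LH from RH: performed
duration difference (s), attack deviation = RH onset - LH onset (s,
negative when the right hand leads), articulation difference (log-ratio),
and velocity difference (MIDI units), each with a delta variant.

Aggregation yields mean and sample SD (n-1) per feature for RH, LH and
DBH; BH (both hands) is the arithmetic mean of the RH and LH statistics.
48 Basic (3 scopes x 8 features x 2 stats) + 16 DBH = 64 values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import MATCH, NoteAlignment
from .midi_io import PerformedNote
from .score import LH, RH, Score

BASIC_FEATURES = [
    "rDuration",
    "rDuration_delta",
    "rIOI",
    "rIOI_delta",
    "Articulation",
    "Articulation_delta",
    "Velocity",
    "Velocity_delta",
]
DBH_FEATURES = [
    "duration",
    "duration_delta",
    "attack_dev",
    "attack_dev_delta",
    "articulation",
    "articulation_delta",
    "velocity",
    "velocity_delta",
]
SCOPES = ["BH", "RH", "LH"]

#: canonical order of the 64 aggregate feature names
FEATURE_NAMES: list[str] = [
    f"{scope}_{feat}_{stat}"
    for scope in SCOPES
    for feat in BASIC_FEATURES
    for stat in ("mean", "sd")
] + [f"DBH_{feat}_{stat}" for feat in DBH_FEATURES for stat in ("mean", "sd")]

BASIC_COLUMNS = FEATURE_NAMES[:48]
DBH_COLUMNS = FEATURE_NAMES[48:]


@dataclass
class NoteFeatureRecord:
    hand: str
    score_ordinal: int
    rDuration: float = math.nan
    rIOI: float = math.nan
    Articulation: float = math.nan
    Velocity: float = math.nan
    rDuration_delta: float = math.nan
    rIOI_delta: float = math.nan
    Articulation_delta: float = math.nan
    Velocity_delta: float = math.nan


@dataclass
class DBHRecord:
    pair_ordinal: int
    duration: float = math.nan
    attack_dev: float = math.nan
    articulation: float = math.nan
    velocity: float = math.nan
    duration_delta: float = math.nan
    attack_dev_delta: float = math.nan
    articulation_delta: float = math.nan
    velocity_delta: float = math.nan


def compute_note_features(
    alignments: tuple[NoteAlignment, NoteAlignment],
    score: Score,
) -> tuple[list[NoteFeatureRecord], int]:
    """Per-note Basic features for both hands.

    Only matched notes contribute.  A note's IOI runs to the hand's next
    matched note; where that next note is not the immediate score
    successor (a missed note left a gap) the IOI-based features are left
    undefined rather than divided by a single written duration.  Deltas
    are likewise only taken between score-adjacent matched notes.  Returns
    the records and a count of notes dropped for non-positive IOI.
    """
    records: list[NoteFeatureRecord] = []
    dropped = 0
    for al in alignments:
        hand = al.hand
        score_notes = {n.ordinal: n for n in score.hand_notes(hand)}
        matched = sorted(al.matched, key=lambda p: p.score_ordinal)
        hand_records: list[NoteFeatureRecord] = []
        for idx, pair in enumerate(matched):
            sn = score_notes[pair.score_ordinal]
            pn: PerformedNote = pair.performed
            sdur = score.duration_sec(sn)
            rec = NoteFeatureRecord(hand, pair.score_ordinal)
            rec.Velocity = float(pn.velocity)
            rec.rDuration = math.log(pn.duration_sec / sdur)
            if idx + 1 < len(matched):
                nxt = matched[idx + 1]
                adjacent = nxt.score_ordinal == pair.score_ordinal + 1
                ioi = nxt.performed.onset_sec - pn.onset_sec
                if ioi <= 0:
                    dropped += 1
                    continue
                if adjacent:
                    rec.rIOI = math.log(ioi / sdur)
                    rec.Articulation = math.log(pn.duration_sec / ioi)
            hand_records.append(rec)
        # deltas between score-adjacent matched notes
        for prev, cur in zip(hand_records, hand_records[1:]):
            if cur.score_ordinal != prev.score_ordinal + 1:
                continue
            for feat in ("rDuration", "rIOI", "Articulation", "Velocity"):
                a, b = getattr(prev, feat), getattr(cur, feat)
                if not (math.isnan(a) or math.isnan(b)):
                    setattr(cur, feat + "_delta", b - a)
        records.extend(hand_records)
    return records, dropped


def compute_dbh(
    note_records: list[NoteFeatureRecord],
    alignments: tuple[NoteAlignment, NoteAlignment],
    score: Score,
) -> list[DBHRecord]:
    """Right-minus-left features over written unison pairs with both
    members matched.  Pairs with a missed member are skipped; deltas are
    taken between consecutive usable pairs only."""
    al_by_hand = {al.hand: al.matched_by_ordinal() for al in alignments}
    rec_by_hand = {
        (r.hand, r.score_ordinal): r for r in note_records
    }
    out: list[DBHRecord] = []
    for k, (rn, ln) in enumerate(score.unison_pairs()):
        pr = al_by_hand.get(RH, {}).get(rn.ordinal)
        pl = al_by_hand.get(LH, {}).get(ln.ordinal)
        if pr is None or pl is None:
            continue
        rec = DBHRecord(k)
        rec.duration = pr.duration_sec - pl.duration_sec
        rec.attack_dev = pr.onset_sec - pl.onset_sec
        rec.velocity = float(pr.velocity - pl.velocity)
        fr = rec_by_hand.get((RH, rn.ordinal))
        fl = rec_by_hand.get((LH, ln.ordinal))
        if (
            fr is not None
            and fl is not None
            and not math.isnan(fr.Articulation)
            and not math.isnan(fl.Articulation)
        ):
            rec.articulation = fr.Articulation - fl.Articulation
        out.append(rec)
    for prev, cur in zip(out, out[1:]):
        if cur.pair_ordinal != prev.pair_ordinal + 1:
            continue
        for feat in ("duration", "attack_dev", "articulation", "velocity"):
            a, b = getattr(prev, feat), getattr(cur, feat)
            if not (math.isnan(a) or math.isnan(b)):
                setattr(cur, feat + "_delta", b - a)
    return out


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray([v for v in values if not math.isnan(v)], dtype=float)
    if arr.size < 2:
        return (float(arr[0]) if arr.size == 1 else math.nan, math.nan)
    return float(arr.mean()), float(arr.std(ddof=1))


def aggregate(
    note_records: list[NoteFeatureRecord], dbh_records: list[DBHRecord]
) -> pd.Series:
    """The 64-entry aggregate vector for one performance of one excerpt.

    Statistics with fewer than two usable notes come out as NaN, which
    flags them as undefined downstream.
    """
    values: dict[str, float] = {}
    for hand in (RH, LH):
        hand_recs = [r for r in note_records if r.hand == hand]
        for feat in BASIC_FEATURES:
            m, s = _mean_sd([getattr(r, feat) for r in hand_recs])
            values[f"{hand}_{feat}_mean"] = m
            values[f"{hand}_{feat}_sd"] = s
    for feat in BASIC_FEATURES:
        for stat in ("mean", "sd"):
            values[f"BH_{feat}_{stat}"] = (
                values[f"RH_{feat}_{stat}"] + values[f"LH_{feat}_{stat}"]
            ) / 2.0
    for feat in DBH_FEATURES:
        m, s = _mean_sd([getattr(r, feat) for r in dbh_records])
        values[f"DBH_{feat}_mean"] = m
        values[f"DBH_{feat}_sd"] = s
    return pd.Series(values, index=FEATURE_NAMES, dtype=float)


def average_excerpts(*vectors: pd.Series) -> pd.Series:
    """Element-wise mean of per-excerpt vectors (the 'all'-excerpts row)."""
    if not vectors:
        raise ValueError("need at least one feature vector")
    return pd.concat(vectors, axis=1).mean(axis=1).reindex(FEATURE_NAMES)


def note_feature_frame(
    note_records: list[NoteFeatureRecord], dbh_records: list[DBHRecord]
) -> pd.DataFrame:
    """Long-form per-note table (one row per record) for CSV export."""
    rows = [
        {"kind": "basic", "hand": r.hand, "ordinal": r.score_ordinal,
         **{f: getattr(r, f) for f in BASIC_FEATURES}}
        for r in note_records
    ]
    rows += [
        {"kind": "dbh", "hand": "DBH", "ordinal": r.pair_ordinal,
         **{f: getattr(r, f) for f in DBH_FEATURES}}
        for r in dbh_records
    ]
    return pd.DataFrame(rows)
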