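"""Score-to-performance note alignment by dynamic programming.

Both excerpts are monophonic within each hand, so alignment reduces to
order-preserving matching of two pitch sequences.  A match of equal pitch
costs nothing, a substitution within +/-2 semitones (a mis-hit adjacent
key) costs ``c_sub``, and a skipped score note (missed) or unmatched
performed note (extra) costs ``c_gap``.  Substitutions further than two
semitones are disallowed: on scalar material a large pitch error is better
explained as one missed plus one extra note.

Hand assignment is a joint problem: the performed stream interleaves both
hands, and within a written unison pair either hand may sound first.  The
joint aligner therefore walks the score's onset groups (each holding one
note per hand) and lets a group's two members be consumed in either order,
minimizing the same alignment cost globally.  Each matched performed note
inherits the hand of its score note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .midi_io import Performance, PerformedNote
from .score import LH, RH, Score, ScoreNote

MATCH = "match"
MISSED = "missed"
EXTRA = "extra"

DEFAULT_C_SUB = 1.0
DEFAULT_C_GAP = 0.6
SUB_WINDOW = 2  # semitones


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AlignedPair:
    """One alignment decision: a score note matched/missed, or an extra
    performed note (score_ordinal is the insertion position then)."""

    score_ordinal: int
    status: str
    performed: PerformedNote | None = None
    score_pitch: int | None = None


@dataclass
class NoteAlignment:
    hand: str
    pairs: list[AlignedPair] = field(default_factory=list)

    @property
    def matched(self) -> list[AlignedPair]:
        return [p for p in self.pairs if p.status == MATCH]

    def n_with_status(self, status: str) -> int:
        return sum(1 for p in self.pairs if p.status == status)

    def matched_by_ordinal(self) -> dict[int, PerformedNote]:
        return {p.score_ordinal: p.performed for p in self.matched}


def _pair_cost(score_pitch: int, perf_pitch: int, c_sub: float) -> float | None:
    """Cost of pairing, or None when disallowed."""
    d = abs(score_pitch - perf_pitch)
    if d == 0:
        return 0.0
    if d <= SUB_WINDOW:
        return c_sub
    return None


def align_hand(
    score_notes: list[ScoreNote],
    performed_notes: list[PerformedNote],
    c_sub: float = DEFAULT_C_SUB,
    c_gap: float = DEFAULT_C_GAP,
) -> NoteAlignment:
    """Global minimum-cost alignment of one hand's pitch sequences.

    Ties are broken preferring match > substitution > score-gap (missed) >
    performance-gap (extra), resolving earlier performed notes first.
    """
    hand = score_notes[0].hand if score_notes else RH
    n, m = len(score_notes), len(performed_notes)
    INF = float("inf")
    # cost[i][j]: best cost aligning score[i:] with performed[j:]
    cost = [[INF] * (m + 1) for _ in range(n + 1)]
    cost[n][m] = 0.0
    for j in range(m - 1, -1, -1):
        cost[n][j] = c_gap * (m - j)
    for i in range(n - 1, -1, -1):
        cost[i][m] = c_gap * (n - i)
        for j in range(m - 1, -1, -1):
            best = cost[i + 1][j] + c_gap  # score note missed
            best = min(best, cost[i][j + 1] + c_gap)  # performed note extra
            pc = _pair_cost(score_notes[i].pitch, performed_notes[j].pitch, c_sub)
            if pc is not None:
                best = min(best, cost[i + 1][j + 1] + pc)
            cost[i][j] = best

    eps = 1e-9
    pairs: list[AlignedPair] = []
    i = j = 0
    while i < n or j < m:
        here = cost[i][j]
        pc = (
            _pair_cost(score_notes[i].pitch, performed_notes[j].pitch, c_sub)
            if i < n and j < m
            else None
        )
        if pc is not None and abs(cost[i + 1][j + 1] + pc - here) < eps:
            pairs.append(
                AlignedPair(score_notes[i].ordinal, MATCH, performed_notes[j], score_notes[i].pitch)
            )
            i += 1
            j += 1
        elif i < n and abs(cost[i + 1][j] + c_gap - here) < eps:
            pairs.append(AlignedPair(score_notes[i].ordinal, MISSED, None, score_notes[i].pitch))
            i += 1
        else:
            pairs.append(AlignedPair(i, EXTRA, performed_notes[j], None))
            j += 1
    return NoteAlignment(hand, pairs)


def _onset_groups(score: Score) -> list[list[ScoreNote]]:
    """Score notes grouped by written onset, each group holding one note
    per hand for unison material."""
    by_onset: dict[float, list[ScoreNote]] = {}
    for note in sorted(score.notes, key=lambda n: (n.onset_beats, n.hand != RH)):
        by_onset.setdefault(note.onset_beats, []).append(note)
    return [by_onset[k] for k in sorted(by_onset)]


def split_hands(
    performance: Performance,
    score: Score,
    c_sub: float = DEFAULT_C_SUB,
    c_gap: float = DEFAULT_C_GAP,
) -> tuple[NoteAlignment, NoteAlignment]:
    """Jointly align the performed stream against both hands of the score,
    assigning each performed note the hand of its matched score note.

    Dynamic program over (onset group, consumed-members mask, performed
    index); within a group the hands may be consumed in either order, which
    accommodates both melody lead (RH early) and lag.  Unmatched performed
    notes become ``extra`` in the hand of the nearest-cost candidate.
    """
    if not performance.notes:
        raise AlignmentError("empty performance")
    groups = _onset_groups(score)
    perf = performance.notes
    G, M = len(groups), len(perf)
    INF = float("inf")

    # state: (g, mask) -> list over j of cost; mask = bitset of consumed members
    # iterate backward over groups
    masks_per_group = [1 << len(g) for g in groups]

    # memo[g][mask][j]
    memo: list[dict[int, list[float]]] = [dict() for _ in range(G + 1)]
    choice: list[dict[int, list[int]]] = [dict() for _ in range(G + 1)]
    # encode choices: 0 = advance group (mask full), 1 = extra perf note,
    # 2 + 2*k + (0 match /1 miss) = consume member k

    full_tail = [c_gap * (M - j) for j in range(M + 1)]
    memo[G][0] = full_tail
    choice[G][0] = [1] * (M + 1)

    for g in range(G - 1, -1, -1):
        members = groups[g]
        nmem = len(members)
        full = masks_per_group[g] - 1
        for mask in range(full, -1, -1):
            row = [INF] * (M + 1)
            ch = [-1] * (M + 1)
            if mask == full:
                nxt = memo[g + 1][0]
                for j in range(M, -1, -1):
                    row[j] = nxt[j]
                    ch[j] = 0
                memo[g][mask] = row
                choice[g][mask] = ch
                continue
            for j in range(M, -1, -1):
                best, op = INF, -1
                # ties resolved in check order: match/substitution first,
                # then score-gap (missed), then performance-gap (extra)
                if j < M:
                    for k in range(nmem):
                        if mask & (1 << k):
                            continue
                        pc = _pair_cost(members[k].pitch, perf[j].pitch, c_sub)
                        if pc is None:
                            continue
                        cand = memo[g][mask | (1 << k)][j + 1] + pc
                        if cand < best - 1e-12:
                            best, op = cand, 2 + 2 * k
                for k in range(nmem):
                    if mask & (1 << k):
                        continue
                    cand = memo[g][mask | (1 << k)][j] + c_gap
                    if cand < best - 1e-12:
                        best, op = cand, 2 + 2 * k + 1
                if j < M and row[j + 1] < INF:
                    # row[j+1] already computed for this mask (j descending)
                    cand = row[j + 1] + c_gap
                    if cand < best - 1e-12:
                        best, op = cand, 1
                row[j] = best
                ch[j] = op
            memo[g][mask] = row
            choice[g][mask] = ch

    # backtrack
    pairs_by_hand: dict[str, list[AlignedPair]] = {RH: [], LH: []}
    extras: list[PerformedNote] = []
    g, mask, j = 0, 0, 0
    while g < G or j < M:
        op = choice[g][mask][j] if g < G else 1
        if g < G and op == 0:
            g, mask = g + 1, 0
        elif op == 1:
            extras.append(perf[j])
            j += 1
        else:
            k, missed = divmod(op - 2, 2)
            note = groups[g][k]
            if missed:
                pairs_by_hand[note.hand].append(
                    AlignedPair(note.ordinal, MISSED, None, note.pitch)
                )
            else:
                pairs_by_hand[note.hand].append(
                    AlignedPair(note.ordinal, MATCH, perf[j], note.pitch)
                )
                j += 1
            mask |= 1 << k
            if mask == masks_per_group[g] - 1:
                g, mask = g + 1, 0

    # attribute extras to the nearest-cost hand (closest pitch at that time)
    for note in extras:
        best_hand, best_key = RH, None
        for hand in (RH, LH):
            for sn in score.hand_notes(hand):
                key = (abs(sn.pitch - note.pitch), abs(
                    sn.onset_beats * score.seconds_per_beat - note.onset_sec
                ))
                if best_key is None or key < best_key:
                    best_key, best_hand = key, hand
        pos = sum(
            1
            for p in pairs_by_hand[best_hand]
            if p.status == MATCH and p.performed.onset_sec <= note.onset_sec
        )
        pairs_by_hand[best_hand].append(AlignedPair(pos, EXTRA, note, None))

    return (
        NoteAlignment(RH, pairs_by_hand[RH]),
        NoteAlignment(LH, pairs_by_hand[LH]),
    )


def alignment_report(rh: NoteAlignment, lh: NoteAlignment) -> pd.DataFrame:
    """Tabular alignment report (one row per alignment decision)."""
    rows = []
    for al in (rh, lh):
        for p in al.pairs:
            rows.append(
                {
                    "hand": al.hand,
                    "score_ordinal": p.score_ordinal,
                    "status": p.status,
                    "perf_onset_sec": p.performed.onset_sec if p.performed else None,
                    "perf_pitch": p.performed.pitch if p.performed else None,
                    "score_pitch": p.score_pitch,
                }
            )
    return pd.DataFrame(rows)


def hand_assignment_accuracy(
    performance: Performance, rh: NoteAlignment, lh: NoteAlignment
) -> float:
    """Fraction of performed notes whose assigned hand matches the synthetic
    ground-truth label (matched notes only)."""
    if performance.truth_hand is None:
        raise AlignmentError("performance carries no truth_hand labels")
    truth = {id(n): h for n, h in zip(performance.notes, performance.truth_hand)}
    correct = total = 0
    for al in (rh, lh):
        for p in al.matched:
            total += 1
            if truth.get(id(p.performed)) == al.hand:
                correct += 1
    return correct / total if total else 0.0
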