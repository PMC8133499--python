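import dataclasses
import math

import numpy as np
import pytest

from pianodbh import (
    Performance,
    PerformedNote,
    aggregate,
    average_excerpts,
    compute_dbh,
    compute_note_features,
    generate_performance,
    split_hands,
)
from pianodbh.features import (
    BASIC_COLUMNS,
    DBH_COLUMNS,
    FEATURE_NAMES,
)
from pianodbh.score import LH, RH
from pianodbh.synthetic import EXPERT_PARAMS, HandPair

NOISE_FREE = dataclasses.replace(
    EXPERT_PARAMS,
    tempo_factor_sd=0.0, ioi_jitter_sd=0.0, dur_articulation_sd=0.0,
    dur_articulation_common_sd=0.0, vel_common_sd=0.0,
    dur_articulation_sd_between=0.0, attack_async_mean=0.0, attack_async_sd=0.0,
    attack_async_sd_between=0.0, vel_offset_rh=11.0, vel_offset_sd_between=0.0,
    vel_base_sd_between=0.0,
    vel_contour_gain=HandPair(0.0, 0.0), vel_sd=0.0, vel_delta_sd=0.0,
    error_rates=(0.0, 0.0, 0.0),
)


@pytest.fixture(scope="module")
def hanon_aligned(scores_module):
    score = scores_module["hanon1"]
    perf = generate_performance(score, NOISE_FREE, 0)
    return perf, score, split_hands(perf, score)


@pytest.fixture(scope="session")
def scores_module(scores):
    return scores


def _legato_perf(score, ioi=0.25, dur_ratio=1.0, vel=64):
    """Deterministic performance: exact nominal tempo, dur = ratio * IOI."""
    notes, truth = [], []
    for rn, ln in score.unison_pairs():
        t = rn.onset_beats * score.seconds_per_beat
        for sn, hand in ((rn, RH), (ln, LH)):
            notes.append(PerformedNote(sn.pitch, t, t + dur_ratio * ioi, vel))
            truth.append(hand)
    perf = Performance(notes=notes, truth_hand=truth)
    perf.sort()
    return perf


class TestNoteFeatureFormulas:
    def test_nominal_tempo_full_legato_gives_all_zeros(self, hanon_small):
        """Playing exactly at score tempo with dur = IOI makes rDuration,
        rIOI and Articulation all zero."""
        perf = _legato_perf(hanon_small)
        als = split_hands(perf, hanon_small)
        records, dropped = compute_note_features(als, hanon_small)
        assert dropped == 0
        for rec in records:
            assert rec.rDuration == pytest.approx(0.0, abs=1e-12)
            if not math.isnan(rec.rIOI):
                assert rec.rIOI == pytest.approx(0.0, abs=1e-12)
                assert rec.Articulation == pytest.approx(0.0, abs=1e-12)

    def test_half_duration_log_ratio(self, hanon_small):
        """A 0.125 s note against a 0.25 s written note gives ln(1/2)."""
        perf = _legato_perf(hanon_small, dur_ratio=0.5)
        records, _ = compute_note_features(split_hands(perf, hanon_small), hanon_small)
        for rec in records:
            assert rec.rDuration == pytest.approx(math.log(0.5), abs=1e-12)

    def test_articulation_log_ratio(self, hanon_small):
        """dur 0.20 s over IOI 0.25 s gives Articulation = ln 0.8."""
        perf = _legato_perf(hanon_small, dur_ratio=0.8)
        records, _ = compute_note_features(split_hands(perf, hanon_small), hanon_small)
        for rec in records:
            if not math.isnan(rec.Articulation):
                assert rec.Articulation == pytest.approx(math.log(0.8), abs=1e-12)

    def test_articulation_identity_on_isochronous_scores(self, scores):
        """Articulation = rDuration - rIOI per note, to 1e-12, on both
        built-in excerpts (written duration equals written IOI)."""
        for name, score in scores.items():
            perf = generate_performance(score, EXPERT_PARAMS, 17)
            records, _ = compute_note_features(split_hands(perf, score), score)
            checked = 0
            for rec in records:
                if math.isnan(rec.rIOI):
                    continue
                assert rec.Articulation == pytest.approx(
                    rec.rDuration - rec.rIOI, abs=1e-12
                )
                checked += 1
            assert checked > 50

    def test_delta_telescoping(self, hanon_aligned):
        """Deltas of a fully matched hand sum to last - first."""
        perf, score, als = hanon_aligned
        records, _ = compute_note_features(als, score)
        for hand in (RH, LH):
            recs = sorted(
                (r for r in records if r.hand == hand), key=lambda r: r.score_ordinal
            )
            vals = [r.Velocity for r in recs]
            deltas = [r.Velocity_delta for r in recs if not math.isnan(r.Velocity_delta)]
            assert sum(deltas) == pytest.approx(vals[-1] - vals[0], abs=1e-9)

    def test_first_note_delta_and_last_note_ioi_undefined(self, hanon_aligned):
        perf, score, als = hanon_aligned
        records, _ = compute_note_features(als, score)
        for hand in (RH, LH):
            recs = sorted(
                (r for r in records if r.hand == hand), key=lambda r: r.score_ordinal
            )
            assert math.isnan(recs[0].Velocity_delta)
            assert math.isnan(recs[-1].rIOI)
            assert not math.isnan(recs[-2].rIOI)

    def test_velocity_features_invariant_to_time_scaling(self, hanon_small):
        perf = _legato_perf(hanon_small)
        slow = Performance(
            notes=[
                PerformedNote(n.pitch, 2 * n.onset_sec, 2 * n.offset_sec, n.velocity)
                for n in perf.notes
            ],
            truth_hand=list(perf.truth_hand),
        )
        slow.sort()
        r1, _ = compute_note_features(split_hands(perf, hanon_small), hanon_small)
        r2, _ = compute_note_features(split_hands(slow, hanon_small), hanon_small)
        assert [r.Velocity for r in r1] == [r.Velocity for r in r2]

    def test_temporal_features_invariant_to_velocity(self, hanon_small):
        perf = _legato_perf(hanon_small, vel=40)
        loud = Performance(
            notes=[
                PerformedNote(n.pitch, n.onset_sec, n.offset_sec, 100)
                for n in perf.notes
            ],
            truth_hand=list(perf.truth_hand),
        )
        r1, _ = compute_note_features(split_hands(perf, hanon_small), hanon_small)
        r2, _ = compute_note_features(split_hands(loud, hanon_small), hanon_small)
        for a, b in zip(r1, r2):
            for feat in ("rDuration", "rIOI", "Articulation"):
                x, y = getattr(a, feat), getattr(b, feat)
                assert (math.isnan(x) and math.isnan(y)) or x == pytest.approx(y)


class TestDBH:
    def test_attack_deviation_sign(self, hanon_small):
        """RH 4 ms before LH gives attack_dev = -0.004 s."""
        notes, truth = [], []
        for rn, ln in hanon_small.unison_pairs():
            t = rn.onset_beats * 0.5
            notes.append(PerformedNote(rn.pitch, t, t + 0.2, 60))
            truth.append(RH)
            notes.append(PerformedNote(ln.pitch, t + 0.004, t + 0.204, 50))
            truth.append(LH)
        perf = Performance(notes=notes, truth_hand=truth)
        perf.sort()
        als = split_hands(perf, hanon_small)
        records, _ = compute_note_features(als, hanon_small)
        dbh = compute_dbh(records, als, hanon_small)
        for rec in dbh:
            assert rec.attack_dev == pytest.approx(-0.004, abs=1e-12)
            assert rec.velocity == pytest.approx(10.0)

    def test_identical_hand_streams_give_zero_dbh(self, hanon_small):
        perf = _legato_perf(hanon_small)
        als = split_hands(perf, hanon_small)
        records, _ = compute_note_features(als, hanon_small)
        for rec in compute_dbh(records, als, hanon_small):
            assert rec.duration == pytest.approx(0.0, abs=1e-12)
            assert rec.attack_dev == pytest.approx(0.0, abs=1e-12)
            assert rec.velocity == 0.0
            if not math.isnan(rec.articulation):
                assert rec.articulation == pytest.approx(0.0, abs=1e-12)

    def test_pairs_with_missed_member_skipped(self, hanon_small):
        perf = _legato_perf(hanon_small)
        # drop one LH note
        drop = next(
            i for i, h in enumerate(perf.truth_hand) if h == LH and i > 4
        )
        perf.notes.pop(drop)
        perf.truth_hand.pop(drop)
        als = split_hands(perf, hanon_small)
        records, _ = compute_note_features(als, hanon_small)
        dbh = compute_dbh(records, als, hanon_small)
        n_pairs = len(hanon_small.unison_pairs())
        assert len(dbh) == n_pairs - 1
        ordinals = [r.pair_ordinal for r in dbh]
        # delta skipped across the gap
        gap_following = [r for r in dbh if r.pair_ordinal - 1 not in ordinals
                         and r.pair_ordinal > 0]
        assert all(math.isnan(r.velocity_delta) for r in gap_following)


class TestAggregate:
    def test_vector_shape_and_partition(self, hanon_aligned):
        perf, score, als = hanon_aligned
        records, _ = compute_note_features(als, score)
        vec = aggregate(records, compute_dbh(records, als, score))
        assert list(vec.index) == FEATURE_NAMES
        assert len(vec) == 64
        assert len(BASIC_COLUMNS) == 48
        assert len(DBH_COLUMNS) == 16
        assert sum(c.startswith(("BH_", "RH_", "LH_")) for c in vec.index) == 48
        assert sum(c.startswith("DBH_") for c in vec.index) == 16

    def test_constant_velocity_aggregates(self, hanon_small):
        perf = _legato_perf(hanon_small, vel=64)
        als = split_hands(perf, hanon_small)
        records, _ = compute_note_features(als, hanon_small)
        vec = aggregate(records, compute_dbh(records, als, hanon_small))
        for scope in ("RH", "LH", "BH"):
            assert vec[f"{scope}_Velocity_mean"] == pytest.approx(64.0)
            assert vec[f"{scope}_Velocity_sd"] == pytest.approx(0.0, abs=1e-12)

    def test_bh_is_average_of_hands(self, scores):
        perf = generate_performance(scores["hanon1"], EXPERT_PARAMS, 23)
        als = split_hands(perf, scores["hanon1"])
        records, _ = compute_note_features(als, scores["hanon1"])
        vec = aggregate(records, compute_dbh(records, als, scores["hanon1"]))
        for name in BASIC_COLUMNS:
            if name.startswith("BH_"):
                rh = vec["RH_" + name[3:]]
                lh = vec["LH_" + name[3:]]
                assert vec[name] == pytest.approx((rh + lh) / 2, rel=1e-12)

    def test_sample_sd_uses_n_minus_1(self, hanon_small):
        perf = _legato_perf(hanon_small)
        als = split_hands(perf, hanon_small)
        records, _ = compute_note_features(als, hanon_small)
        vals = np.array([r.Velocity for r in records if r.hand == RH])
        vals[0] += 6  # perturb one note to get nonzero SD
        for i, r in enumerate([r for r in records if r.hand == RH]):
            r.Velocity = vals[i]
        vec = aggregate(records, [])
        assert vec["RH_Velocity_sd"] == pytest.approx(vals.std(ddof=1))


class TestAverageExcerpts:
    def test_identity_and_halving(self, hanon_aligned):
        perf, score, als = hanon_aligned
        records, _ = compute_note_features(als, score)
        vec = aggregate(records, compute_dbh(records, als, score))
        same = average_excerpts(vec, vec)
        assert np.allclose(same.to_numpy(), vec.to_numpy(), equal_nan=True)
        halved = average_excerpts(vec, vec * 0.0)
        assert np.allclose(halved.to_numpy(), vec.to_numpy() / 2, equal_nan=True)
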