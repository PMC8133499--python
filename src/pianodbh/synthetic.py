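"""Synthetic expert/amateur performance cohorts.

The generator emulates the statistical structure the analysis assumes:
each performer draws a personal tempo factor, the left hand lays down a
timeline of tempo-scaled written inter-onset intervals plus AR(1) timing
jitter, and the right-hand member of every written unison pair is offset
from its left-hand partner by a draw of the attack asynchrony (negative
mean = melody lead).  Durations are per-hand articulation-ratio draws
times the realized IOI; velocities are a per-hand base level plus a
mean-centered pitch-contour term and stationary AR(1) noise whose
marginal SD and increment SD control loudness variability and smoothness
separately.  Wrong (+/-1-2 semitones), missed and extra notes are
injected at configurable rates.

Group defaults are calibrated to published group-level moments: the
expert right-minus-left velocity offset (11.083 MIDI units), duration
difference (0.021 s), attack asynchrony (-0.004 s) and the corresponding
amateur values, with between-performer spreads matching the reported
group SDs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .midi_io import Performance, PerformedNote
from .score import LH, RH, Score

_AR_TIMING = 0.3  # AR(1) coefficient of the onset jitter


@dataclass(frozen=True)
class HandPair:
    """A per-hand (RH, LH) parameter pair."""

    rh: float
    lh: float

    def get(self, hand: str) -> float:
        return self.rh if hand == RH else self.lh


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters of one proficiency group.

    SDs suffixed ``_between`` vary per performer; the others vary per
    note.  ``vel_sd``/``vel_delta_sd`` jointly set the AR(1) velocity
    noise: the autocorrelation is 1 - vel_delta_sd^2 / (2 vel_sd^2).
    """

    tempo_factor_mean: float = 1.0
    tempo_factor_sd: float = 0.05
    ioi_jitter_sd: float = 0.010  # seconds, per note
    # performed-duration / IOI ratio per hand
    dur_articulation: HandPair = HandPair(0.976, 0.892)
    dur_articulation_sd: float = 0.074  # per note, each hand independently
    dur_articulation_common_sd: float = 0.10  # per note, shared by both hands
    dur_articulation_sd_between: float = 0.037  # per performer, each hand
    attack_async_mean: float = -0.004  # seconds, RH minus LH
    attack_async_sd: float = 0.008  # per note
    attack_async_sd_between: float = 0.004  # per performer
    vel_base_lh: float = 60.0
    vel_base_sd_between: float = 6.0  # per-performer overall loudness level
    vel_offset_rh: float = 11.083  # mean RH-LH velocity
    vel_offset_sd_between: float = 3.472
    vel_contour_gain: HandPair = HandPair(8.0, 6.0)
    vel_sd: float = 3.25  # stationary hand-specific velocity noise SD
    vel_delta_sd: float = 3.876  # hand-specific SD of note-to-note noise increments
    vel_common_sd: float = 5.0  # shared expressive dynamics, cancels in DBH
    # between-performer CVs of the per-family noise magnitudes
    noise_cv_timing: float = 0.25
    noise_cv_articulation: float = 0.31
    noise_cv_velocity: float = 0.14
    error_rates: tuple[float, float, float] = (0.002, 0.002, 0.002)  # wrong, miss, extra

    def __post_init__(self) -> None:
        for name in ("tempo_factor_sd", "ioi_jitter_sd", "dur_articulation_sd",
                     "attack_async_sd", "vel_sd", "vel_delta_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(not 0 <= r <= 1 for r in self.error_rates):
            raise ValueError("error rates must lie in [0, 1]")

    @property
    def vel_ar_coeff(self) -> float:
        if self.vel_sd == 0:
            return 0.0
        phi = 1.0 - self.vel_delta_sd**2 / (2 * self.vel_sd**2)
        return min(max(phi, 0.0), 0.999)


EXPERT_PARAMS = GroupParams()

AMATEUR_PARAMS = GroupParams(
    tempo_factor_sd=0.08,
    ioi_jitter_sd=0.018,
    dur_articulation=HandPair(0.9656, 0.9296),
    dur_articulation_sd=0.139,
    dur_articulation_sd_between=0.051,
    attack_async_mean=0.0008,
    attack_async_sd=0.014,
    attack_async_sd_between=0.005,
    vel_offset_rh=7.521,
    vel_offset_sd_between=2.606,
    vel_contour_gain=HandPair(5.0, 4.0),
    vel_sd=3.63,
    vel_delta_sd=4.989,
    noise_cv_timing=0.43,
    noise_cv_articulation=0.47,
    noise_cv_velocity=0.20,
    error_rates=(0.01, 0.01, 0.01),
)

DEFAULT_PARAMS = {"expert": EXPERT_PARAMS, "amateur": AMATEUR_PARAMS}


@dataclass
class CohortSpec:
    n_expert: int = 34
    n_amateur: int = 34
    excerpts: tuple[str, ...] = ("hanon1", "cmajor_scale")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_expert < 1 or self.n_amateur < 1:
            raise ValueError("need at least one performer per group")


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """Stationary AR(1) series with marginal SD ``sd``."""
    if n == 0:
        return np.empty(0)
    if sd == 0:
        return np.zeros(n)
    x = np.empty(n)
    innov_sd = sd * math.sqrt(max(1.0 - phi**2, 1e-12))
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


@dataclass(frozen=True)
class PerformerTraits:
    """Per-performer draws, shared across a performer's excerpts.

    A performer keeps the same personal tempo, articulation habits,
    asynchrony tendency, loudness balance and precision level on every
    excerpt; only note-level noise is redrawn per performance.
    """

    tempo_factor: float
    articulation_rh: float
    articulation_lh: float
    attack_async_mean: float
    vel_base_shift: float  # common-mode loudness level, cancels in DBH
    vel_offset: float
    # per-performer precision levels, one per feature family
    scale_timing: float
    scale_articulation: float
    scale_velocity: float

    def articulation(self, hand: str) -> float:
        return self.articulation_rh if hand == RH else self.articulation_lh


def draw_traits(params: GroupParams, rng: np.random.Generator) -> PerformerTraits:
    return PerformerTraits(
        tempo_factor=max(
            rng.normal(params.tempo_factor_mean, params.tempo_factor_sd), 0.2
        ),
        articulation_rh=max(
            rng.normal(params.dur_articulation.rh, params.dur_articulation_sd_between),
            0.05,
        ),
        articulation_lh=max(
            rng.normal(params.dur_articulation.lh, params.dur_articulation_sd_between),
            0.05,
        ),
        attack_async_mean=rng.normal(
            params.attack_async_mean, params.attack_async_sd_between
        ),
        vel_base_shift=rng.normal(0.0, params.vel_base_sd_between),
        vel_offset=rng.normal(params.vel_offset_rh, params.vel_offset_sd_between),
        scale_timing=max(rng.normal(1.0, params.noise_cv_timing), 0.2),
        scale_articulation=max(rng.normal(1.0, params.noise_cv_articulation), 0.2),
        scale_velocity=max(rng.normal(1.0, params.noise_cv_velocity), 0.2),
    )


def generate_performance(
    score: Score,
    params: GroupParams,
    performer_seed: int,
    performer_id: str = "p0",
    group: str = "unknown",
    traits: PerformerTraits | None = None,
) -> Performance:
    """One synthetic performance with per-note ground-truth hand labels.

    ``traits`` carries the performer-level draws; when omitted they are
    drawn from the same seed, which keeps the single-seed API
    reproducible for standalone performances.
    """
    rng = np.random.default_rng(performer_seed)
    if traits is None:
        traits = draw_traits(params, rng)
    pairs = score.unison_pairs()
    n = len(pairs)
    if n == 0:
        raise ValueError("score has no unison pairs to perform")

    tempo = traits.tempo_factor
    spb = score.seconds_per_beat

    art = {h: traits.articulation(h) for h in (RH, LH)}
    async_mean = traits.attack_async_mean
    lh_level = params.vel_base_lh + traits.vel_base_shift
    vel_base = {LH: lh_level, RH: lh_level + traits.vel_offset}

    # LH timeline: cumulative tempo-scaled written IOIs + AR(1) jitter
    onsets_beats = np.array([p[1].onset_beats for p in pairs])
    written_ioi = np.diff(onsets_beats) * spb
    base = np.concatenate([[0.0], np.cumsum(written_ioi * tempo)])
    jitter = _ar1(rng, n, params.ioi_jitter_sd * traits.scale_timing, _AR_TIMING)
    lh_onsets = base + jitter - jitter[0]
    if np.any(np.diff(lh_onsets) <= 0):
        raise ValueError("timing parameters produced non-positive IOIs")
    rh_onsets = lh_onsets + rng.normal(
        async_mean, params.attack_async_sd * traits.scale_timing, size=n
    )
    # shift the whole timeline so the earliest note starts at t = 0
    t_shift = min(lh_onsets[0], rh_onsets.min())
    if t_shift < 0:
        lh_onsets = lh_onsets - t_shift
        rh_onsets = rh_onsets - t_shift

    # velocities: base + centered contour + shared dynamics + AR(1) noise
    phi = params.vel_ar_coeff
    vel_common = _ar1(rng, n, params.vel_common_sd, phi)
    velocities: dict[str, np.ndarray] = {}
    for h, notes in ((RH, [p[0] for p in pairs]), (LH, [p[1] for p in pairs])):
        pitches = np.array([sn.pitch for sn in notes], dtype=float)
        span = pitches.max() - pitches.min()
        height = (pitches - pitches.min()) / span if span > 0 else np.zeros(n)
        contour = params.vel_contour_gain.get(h) * (height - height.mean())
        noise = _ar1(rng, n, params.vel_sd * traits.scale_velocity, phi)
        velocities[h] = vel_base[h] + contour + vel_common + noise

    notes: list[PerformedNote] = []
    truth: list[str] = []
    p_wrong, p_miss, p_extra = params.error_rates
    # phrase-level articulation shaping shared by both hands
    art_common = rng.normal(0.0, params.dur_articulation_common_sd, size=n)
    for h, onsets in ((RH, rh_onsets), (LH, lh_onsets)):
        ratio = np.maximum(
            art[h]
            + art_common
            + rng.normal(
                0.0, params.dur_articulation_sd * traits.scale_articulation, size=n
            ),
            0.05,
        )
        for i in range(n):
            if rng.random() < p_miss:
                continue
            sn = pairs[i][0] if h == RH else pairs[i][1]
            pitch = sn.pitch
            if rng.random() < p_wrong:
                pitch += int(rng.choice([-2, -1, 1, 2]))
            ioi = (
                onsets[i + 1] - onsets[i]
                if i + 1 < n
                else pairs[i][0].duration_beats * spb * tempo
            )
            dur = max(float(ratio[i]) * float(ioi), 0.01)
            vel = int(np.clip(round(velocities[h][i]), 1, 127))
            notes.append(PerformedNote(pitch, float(onsets[i]), float(onsets[i] + dur), vel))
            truth.append(h)
            if rng.random() < p_extra:
                # a brushed adjacent key shortly after the intended note
                off = int(rng.choice([-2, -1, 1, 2]))
                t0 = float(onsets[i] + 0.4 * ioi)
                notes.append(
                    PerformedNote(sn.pitch + off, t0, t0 + 0.3 * float(ioi), vel)
                )
                truth.append(h)

    perf = Performance(performer_id, group, score.excerpt_id, notes, truth)
    perf.sort()
    return perf


def generate_cohort(
    spec: CohortSpec,
    scores: dict[str, Score],
    expert_params: GroupParams = EXPERT_PARAMS,
    amateur_params: GroupParams = AMATEUR_PARAMS,
) -> tuple[list[Performance], pd.DataFrame]:
    """All performances of a cohort plus a metadata table.

    Per-performer seeds are derived from the cohort seed with a seed
    sequence, so the cohort is reproducible and performers independent.
    """
    root = np.random.SeedSequence(spec.seed)
    group_of = ["expert"] * spec.n_expert + ["amateur"] * spec.n_amateur
    params_of = {"expert": expert_params, "amateur": amateur_params}
    children = root.spawn(len(group_of))

    performances: list[Performance] = []
    rows = []
    for idx, (group, child) in enumerate(zip(group_of, children)):
        pid = f"{group[0].upper()}{idx:03d}"
        state = child.generate_state(len(spec.excerpts) + 1)
        # one performer-level draw shared by all of the performer's excerpts
        traits = draw_traits(params_of[group], np.random.default_rng(int(state[0])))
        for excerpt, sub in zip(spec.excerpts, state[1:]):
            perf = generate_performance(
                scores[excerpt], params_of[group], int(sub) % (2**31), pid, group,
                traits=traits,
            )
            performances.append(perf)
            rows.append({"performer_id": pid, "group": group, "excerpt": excerpt,
                         "n_notes": len(perf.notes)})
    return performances, pd.DataFrame(rows)
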