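"""Statistical protocol: 2x2 split-plot ANOVA, pooled t-tests, Bonferroni,
Cohen's d, and assumption checks.

The design has hand (RH/LH) as the within-subject factor and proficiency
group (expert/amateur) as the between-subject factor, one value per
subject and hand.  Sums of squares are decomposed directly: subjects
within groups form the error term for the group effect; the hand-by-
subject interaction within groups forms the error term for the hand and
interaction effects.  Partial eta squared is SS_effect / (SS_effect +
SS_error) against each effect's own error term.

The between-group t-test is the pooled-variance (Student) form with
df = n_A + n_B - 2, oriented amateur minus expert so that a positive t
means the amateur group scored higher.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class AnovaEffect:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


@dataclass
class MixedAnovaResult:
    hand: AnovaEffect
    group: AnovaEffect
    interaction: AnovaEffect
    ss: dict = field(default_factory=dict)  # full decomposition for auditing


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int


@dataclass
class EffectSize:
    cohens_d: float
    comparison: str = ""


@dataclass
class AssumptionTestResult:
    statistic: float
    p: float
    test: str


def mixed_anova_2x2(
    rh: np.ndarray, lh: np.ndarray, group: np.ndarray
) -> MixedAnovaResult:
    """Split-plot ANOVA with two within levels (per-subject RH and LH
    values) and two groups.

    Degenerate effects (zero SS for both effect and error) are reported as
    F = 0, p = 1.
    """
    rh = np.asarray(rh, dtype=float)
    lh = np.asarray(lh, dtype=float)
    group = np.asarray(group)
    if rh.shape != lh.shape or rh.shape != group.shape:
        raise ValueError("rh, lh and group must have equal length")
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels.size}")
    for g in labels:
        if (group == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")

    y = np.stack([rh, lh], axis=1)  # subjects x hands
    N = y.shape[0]
    grand = y.mean()

    subj_means = y.mean(axis=1)
    hand_means = y.mean(axis=0)
    ss_total = ((y - grand) ** 2).sum()

    ss_group = 0.0
    ss_subj = 0.0
    ss_inter = 0.0
    for g in labels:
        sel = group == g
        ng = sel.sum()
        gm = y[sel].mean()
        ss_group += 2 * ng * (gm - grand) ** 2
        ss_subj += 2 * ((subj_means[sel] - gm) ** 2).sum()
        for h in range(2):
            cell = y[sel, h].mean()
            ss_inter += ng * (cell - gm - hand_means[h] + grand) ** 2
    ss_hand = N * ((hand_means - grand) ** 2).sum()
    ss_err_within = ss_total - ss_group - ss_subj - ss_hand - ss_inter

    df2 = N - 2

    def effect(ss_eff: float, ss_err: float) -> AnovaEffect:
        if ss_err <= 0 and ss_eff <= 0:
            return AnovaEffect(0.0, 1, df2, 1.0, 0.0)
        if ss_err <= 0:
            return AnovaEffect(math.inf, 1, df2, 0.0, 1.0)
        F = (ss_eff / 1) / (ss_err / df2)
        p = float(sps.f.sf(F, 1, df2))
        eta = ss_eff / (ss_eff + ss_err)
        return AnovaEffect(float(F), 1, df2, p, float(eta))

    return MixedAnovaResult(
        hand=effect(ss_hand, ss_err_within),
        group=effect(ss_group, ss_subj),
        interaction=effect(ss_inter, ss_err_within),
        ss={
            "total": float(ss_total),
            "group": float(ss_group),
            "subjects_within_groups": float(ss_subj),
            "hand": float(ss_hand),
            "interaction": float(ss_inter),
            "hand_x_subjects_within_groups": float(ss_err_within),
        },
    )


def independent_t_pooled(
    a=None, b=None, *, summary_a=None, summary_b=None
) -> TTestResult:
    """Pooled-variance two-sample t-test, oriented B minus A.

    Call with two raw samples, or with ``summary_a``/``summary_b`` as
    (mean, sd, n) tuples (the worked-example route for published group
    statistics).  A zero pooled variance with unequal means yields an
    infinite t, flagged by the result itself.
    """
    if summary_a is not None or summary_b is not None:
        mean_a, sd_a, n_a = summary_a
        mean_b, sd_b, n_b = summary_b
    else:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        mean_a, sd_a, n_a = a.mean(), a.std(ddof=1), a.size
        mean_b, sd_b, n_b = b.mean(), b.std(ddof=1), b.size
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    diff = mean_b - mean_a
    if sp2 == 0:
        t = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        t = diff / math.sqrt(sp2 * (1 / n_a + 1 / n_b))
    p = float(2 * sps.t.sf(abs(t), df)) if math.isfinite(t) else 0.0
    return TTestResult(
        float(t), int(df), p,
        float(mean_a), float(sd_a), int(n_a),
        float(mean_b), float(sd_b), int(n_b),
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Multiply p-values by the number of comparisons, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(1.0, p * m)


def cohens_d_hands(rh, lh, comparison: str = "RH vs LH") -> EffectSize:
    """Cohen's d for the RH-LH contrast using the two-condition pooled SD
    sqrt((s_RH^2 + s_LH^2) / 2)."""
    rh = np.asarray(rh, dtype=float)
    lh = np.asarray(lh, dtype=float)
    s_pool = math.sqrt((rh.std(ddof=1) ** 2 + lh.std(ddof=1) ** 2) / 2)
    diff = rh.mean() - lh.mean()
    d = 0.0 if diff == 0 else diff / s_pool
    return EffectSize(float(d), comparison)


def levene_test(*groups) -> AssumptionTestResult:
    """Classic mean-centered Levene test of equal variances."""
    for g in groups:
        if len(np.atleast_1d(g)) < 2:
            raise ValueError("each group needs at least 2 values")
    stat, p = sps.levene(*groups, center="mean")
    return AssumptionTestResult(float(stat), float(p), "levene")


def shapiro_wilk(sample) -> AssumptionTestResult:
    sample = np.asarray(sample, dtype=float)
    if sample.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 values")
    stat, p = sps.shapiro(sample)
    return AssumptionTestResult(float(stat), float(p), "shapiro_wilk")
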