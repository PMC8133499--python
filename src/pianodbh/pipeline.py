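"""End-to-end orchestration: simulate -> align -> extract -> analyze -> classify.

The feature table is the central artifact: one row per performer and
excerpt (plus an ``all`` row averaging the two excerpts), the 64
aggregate feature columns, and ``performer_id``/``group``/``excerpt``
identifiers.  The statistical stage reproduces the published table
layouts: split-plot ANOVA per Basic feature (hand x group) and pooled
t-tests per DBH feature, each for every excerpt and for ``all``, with
Bonferroni adjustment across excerpts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import alignment as al
from . import classify as cl
from . import features as ft
from . import stats as st
from .midi_io import Performance, read_smf, write_smf
from .score import LH, RH, Score, get_builtin_score
from .synthetic import (
    AMATEUR_PARAMS,
    EXPERT_PARAMS,
    CohortSpec,
    GroupParams,
    generate_cohort,
)

log = logging.getLogger("pianodbh")


@dataclass
class RunConfig:
    out_dir: str = "pianodbh_run"
    n_expert: int = 34
    n_amateur: int = 34
    excerpts: tuple[str, ...] = ("hanon1", "cmajor_scale")
    seed: int = 0
    hanon_patterns: int = 7
    scale_octaves: int = 4
    c_sub: float = al.DEFAULT_C_SUB
    c_gap: float = al.DEFAULT_C_GAP
    bonferroni_m: int = 3  # hanon, scale, all
    folds: int = 10
    svm_c: float = 1.0
    classify_seed: int = 0
    fold_safe: bool = False

    def validate(self) -> None:
        if self.n_expert < 1 or self.n_amateur < 1:
            raise ValueError("cohort sizes must be >= 1")
        if not self.excerpts:
            raise ValueError("at least one excerpt required")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        cfg = cls(**data)
        cfg.validate()
        return cfg


def builtin_scores(config: RunConfig | None = None) -> dict[str, Score]:
    cfg = config or RunConfig()
    return {
        "hanon1": get_builtin_score("hanon1", n_patterns=cfg.hanon_patterns),
        "cmajor_scale": get_builtin_score("cmajor_scale", octaves=cfg.scale_octaves),
    }


def extract_performance_features(
    performance: Performance,
    score: Score,
    c_sub: float = al.DEFAULT_C_SUB,
    c_gap: float = al.DEFAULT_C_GAP,
) -> pd.Series:
    """Align one performance against its score and compute the 64-entry
    aggregate vector."""
    rh, lh = al.split_hands(performance, score, c_sub, c_gap)
    note_records, _ = ft.compute_note_features((rh, lh), score)
    dbh_records = ft.compute_dbh(note_records, (rh, lh), score)
    return ft.aggregate(note_records, dbh_records)


def build_feature_table(
    performances: list[Performance],
    scores: dict[str, Score],
    c_sub: float = al.DEFAULT_C_SUB,
    c_gap: float = al.DEFAULT_C_GAP,
) -> pd.DataFrame:
    """Per-performer x excerpt feature rows plus the 'all' average rows."""
    rows = []
    for perf in performances:
        vec = extract_performance_features(perf, scores[perf.excerpt_id], c_sub, c_gap)
        row = {"performer_id": perf.performer_id, "group": perf.group,
               "excerpt": perf.excerpt_id}
        row.update(vec.to_dict())
        rows.append(row)
    table = pd.DataFrame(rows)

    all_rows = []
    for (pid, group), sub in table.groupby(["performer_id", "group"], sort=False):
        vec = ft.average_excerpts(
            *(sub.iloc[i][ft.FEATURE_NAMES].astype(float) for i in range(len(sub)))
        )
        row = {"performer_id": pid, "group": group, "excerpt": "all"}
        row.update(vec.to_dict())
        all_rows.append(row)
    return pd.concat([table, pd.DataFrame(all_rows)], ignore_index=True)


_BASIC_BASES = ["rDuration", "rIOI", "Articulation", "Velocity",
                "rDuration_delta", "rIOI_delta", "Articulation_delta",
                "Velocity_delta"]
_DBH_BASES = ["duration", "attack_dev", "articulation", "velocity",
              "duration_delta", "attack_dev_delta", "articulation_delta",
              "velocity_delta"]


def analyze_feature_table(table: pd.DataFrame, bonferroni_m: int = 3) -> dict[str, pd.DataFrame]:
    """Published-layout statistics.

    ``anova``: per Basic feature base and statistic (mean/SD), split-plot
    ANOVA of the per-hand values with hand within and group between, plus
    the per-group RH-vs-LH Cohen's d.  ``ttests``: per DBH feature, the
    pooled t-test oriented amateur minus expert, with Levene and per-group
    Shapiro-Wilk assumption checks and Bonferroni-adjusted p.
    """
    excerpts = [e for e in table["excerpt"].unique()]
    anova_rows, t_rows = [], []
    for excerpt in excerpts:
        sub = table[table["excerpt"] == excerpt]
        group = sub["group"].to_numpy()
        for base in _BASIC_BASES:
            for stat in ("mean", "sd"):
                rh = sub[f"RH_{base}_{stat}"].to_numpy(dtype=float)
                lh = sub[f"LH_{base}_{stat}"].to_numpy(dtype=float)
                ok = ~(np.isnan(rh) | np.isnan(lh))
                res = st.mixed_anova_2x2(rh[ok], lh[ok], group[ok])
                row = {"feature": base, "stat": stat, "excerpt": excerpt}
                for eff_name, eff in (("hand", res.hand), ("group", res.group),
                                      ("interaction", res.interaction)):
                    row[f"F_{eff_name}"] = eff.F
                    row[f"p_{eff_name}"] = eff.p
                    row[f"peta2_{eff_name}"] = eff.partial_eta_sq
                for g in ("expert", "amateur"):
                    gsel = ok & (group == g)
                    if gsel.sum() >= 2:
                        row[f"cohens_d_{g}"] = st.cohens_d_hands(
                            rh[gsel], lh[gsel]
                        ).cohens_d
                anova_rows.append(row)
        for base in _DBH_BASES:
            for stat in ("mean", "sd"):
                col = f"DBH_{base}_{stat}"
                vals = sub[col].to_numpy(dtype=float)
                ok = ~np.isnan(vals)
                exp = vals[ok & (sub["group"] == "expert").to_numpy()]
                ama = vals[ok & (sub["group"] == "amateur").to_numpy()]
                res = st.independent_t_pooled(exp, ama)
                row = {
                    "feature": base, "stat": stat, "excerpt": excerpt,
                    "expert_mean": res.mean_a, "expert_sd": res.sd_a,
                    "amateur_mean": res.mean_b, "amateur_sd": res.sd_b,
                    "t": res.t, "df": res.df, "p": res.p,
                }
                row["levene_p"] = st.levene_test(exp, ama).p
                if len(exp) >= 3 and len(ama) >= 3:
                    row["shapiro_p_expert"] = st.shapiro_wilk(exp).p
                    row["shapiro_p_amateur"] = st.shapiro_wilk(ama).p
                t_rows.append(row)
    anova = pd.DataFrame(anova_rows)
    ttests = pd.DataFrame(t_rows)
    ttests["p_bonferroni"] = st.bonferroni(ttests["p"].to_numpy(), bonferroni_m)
    return {"anova": anova, "ttests": ttests}


def run_all(config: RunConfig) -> dict:
    """Full pipeline; writes all artifacts under ``config.out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scores = builtin_scores(config)

    stage = "simulate"
    try:
        spec = CohortSpec(config.n_expert, config.n_amateur, tuple(config.excerpts),
                          config.seed)
        performances, meta = generate_cohort(spec, scores)
        midi_dir = out / "midi"
        midi_dir.mkdir(exist_ok=True)
        files = []
        for perf in performances:
            fname = f"{perf.performer_id}_{perf.excerpt_id}.mid"
            write_smf(perf, midi_dir / fname)
            files.append(fname)
        meta = meta.assign(file=files)
        meta.to_csv(out / "cohort.csv", index=False)
        log.info("simulated %d performances", len(performances))

        stage = "extract"
        table = build_feature_table(performances, scores, config.c_sub, config.c_gap)
        table.to_csv(out / "feature_table.csv", index=False)
        log.info("feature table: %d rows x %d cols", *table.shape)

        stage = "analyze"
        results = analyze_feature_table(table, config.bonferroni_m)
        results["anova"].to_csv(out / "anova.csv", index=False)
        results["ttests"].to_csv(out / "ttests.csv", index=False)

        stage = "classify"
        all_rows = table[table["excerpt"] == "all"].reset_index(drop=True)
        reports = cl.run_comparison(
            all_rows, folds=config.folds, C=config.svm_c,
            seed=config.classify_seed, fold_safe=config.fold_safe,
        )
        report_dicts = [r.to_dict() for r in reports]
        with open(out / "classification.json", "w") as fh:
            json.dump(report_dicts, fh, indent=2)
        pd.DataFrame(report_dicts).drop(columns="fold_f1").to_csv(
            out / "classification.csv", index=False
        )
    except Exception as exc:  # pragma: no cover - error path
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return {
        "config": asdict(config),
        "feature_table": table,
        "anova": results["anova"],
        "ttests": results["ttests"],
        "classification": report_dicts,
    }
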