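# pianodbh

Quantitative analysis of piano performance proficiency from MIDI, focused
on the **difference between hands (DBH)**: how differently a pianist's
right and left hands time, articulate, and weight nominally simultaneous
notes, and whether those differences separate expert from amateur
players.

The package is aimed at researchers in music performance science and
music information retrieval who want a transparent, testable pipeline
for: symbolic scores of two standard technical excerpts (Hanon No. 1 and
a C-major scale in parallel octaves), Standard MIDI File I/O, dynamic-
programming score–performance alignment with hand attribution, note-level
feature extraction, split-plot statistics, and PCA + linear-SVM
proficiency classification. Because the underlying human recordings are
not publicly deposited, a calibrated synthetic cohort generator (34
experts + 34 amateurs) reproduces the published group-level moments so
every stage is runnable and testable end to end.

## The model in brief

Per matched note of each hand, with `dur` the performed duration, `ioi`
the performed inter-onset interval to the hand's next note, and `sdur`
the written duration in seconds at nominal tempo (0.25 s in both
excerpts):

    rDuration    = ln(dur / sdur)
    rIOI         = ln(ioi / sdur)
    Articulation = ln(dur / ioi)
    Velocity     = MIDI velocity

plus first-difference (delta) variants. DBH features subtract LH from RH
over written unison pairs: duration difference (s), attack deviation
(RH onset − LH onset, s; negative = the right hand leads, i.e. melody
lead), articulation difference, velocity difference, with deltas. Mean
and sample SD per scope (RH, LH, their average BH, and DBH) give 48
Basic + 16 DBH = 64 aggregates per performance.

Basic features are analyzed with 2×2 split-plot ANOVAs (hand within
subjects × proficiency group between subjects, partial η², Bonferroni
post hocs, Cohen's d); DBH features with pooled two-sample t-tests
(df = n₁ + n₂ − 2, oriented amateur − expert). Classification z-scores a
feature set, reduces it by PCA (95%/99% cumulative variance, best-k, or
fixed k), and scores a linear SVM (C = 1.0) by stratified 10-fold CV
with per-fold F1 (expert positive).

See `docs/methods.md` for assumptions, calibration and limitations.

## Worked example

Run the whole pipeline on a synthetic cohort at the study's scale:

```python
from pianodbh import RunConfig, run_all

result = run_all(RunConfig(out_dir="demo", n_expert=34, n_amateur=34, seed=3))
t = result["ttests"]
row = t[(t.feature == "velocity") & (t.stat == "mean") & (t.excerpt == "all")].iloc[0]
print(f"DBH velocity mean: expert {row.expert_mean:.3f} (SD {row.expert_sd:.3f}), "
      f"amateur {row.amateur_mean:.3f} (SD {row.amateur_sd:.3f}), "
      f"t({int(row.df)}) = {row.t:.3f}")
```

which prints (for this seed):

```
DBH velocity mean: expert 11.900 (SD 3.028), amateur 7.527 (SD 2.600), t(66) = -6.390
```

Read: on average the experts strike right-hand notes ~11.9 MIDI-velocity
units harder than left-hand notes while amateurs differ by only ~7.5,
and with 34 performers per group this gap is far beyond chance (pooled
t on 66 df; the sign is negative because the test is oriented
amateur − expert). The run directory also receives the cohort SMFs and
metadata (`cohort.csv`), the per-performer 64-column feature table
(`feature_table.csv`), the full ANOVA and t-test tables (`anova.csv`,
`ttests.csv`), and classification reports for the Basic / DBH /
Basic+DBH feature sets under all component-selection modes
(`classification.json`/`.csv`).

The same stages are available from the shell:

```sh
pianodbh simulate --n-expert 34 --n-amateur 34 --seed 3 --out demo
pianodbh extract --cohort demo/cohort.csv --out demo/features.csv
pianodbh analyze --features demo/features.csv --out-dir demo
pianodbh classify --features demo/features.csv --mode cumvar99 --out demo/clf.json
pianodbh run-all --out demo --seed 3
```

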