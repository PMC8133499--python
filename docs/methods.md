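# Methods

`pianodbh` quantifies how differently a pianist's two hands behave on
technically simple, nominally symmetric material, and uses those
differences to separate expert from amateur performances. This note
documents the models, the calibration of the synthetic cohort, the
numerical choices, and what the package's tests do and do not establish.

## Material and its representation

Two unison excerpts are built in symbolically: the first Hanon exercise
(an eight-note cell climbing the C-major scale, right hand from C4, left
hand two octaves below, eighth notes at 120 bpm) and a C-major scale in
parallel octaves (four octaves up and down, sixteenth notes at 60 bpm).
At these tempi every written note in both excerpts lasts 0.25 s, so the
two excerpts are directly comparable note for note, and written duration
equals written inter-onset interval (IOI) everywhere — the scores are
isochronous.

The exact lengths of the recorded excerpts are not pinned down by the
material itself; defaults (7 Hanon patterns with the descending mirror,
112 notes per hand; 4 scale octaves, 57 notes per hand) were chosen once
so that nominal playing time is in the range the cohort-level timing
figures imply, and are configurable. The scale's hand registers (RH from
C4, LH from C3) are a convention choice; only the Hanon registers are
fixed by the exercise itself. Hanon pattern
transposition is diatonic (the semitone template is mapped to C-major
scale degrees and shifted one degree per pattern), which keeps every
pattern inside C major as the exercise itself does.

## Alignment and hand attribution

Performances arrive as Standard MIDI Files with no reliable track or
channel identity, so each performed note's hand must be inferred. Both
excerpts are monophonic per hand, which reduces score-performance
matching to order-preserving alignment of pitch sequences. A dynamic
program minimizes total cost with: exact-pitch match 0, substitution
(|Δpitch| ≤ 2 semitones) 1.0, gap (missed score note or extra performed
note) 0.6. Substitutions beyond two semitones are disallowed — on scalar
material a large pitch error is better explained as a miss plus an
insertion. Onset times deliberately do not enter the cost; pitch order
alone identifies these excerpts, and time-free costs make the alignment
invariant to tempo and global offset.

Hand attribution is joint: the aligner walks the score's onset groups
(one note per hand at each written onset) against the single merged
performed stream, allowing the two members of a unison pair to be
consumed in either order, since either hand may strike first. Matched
performed notes inherit their score note's hand; unmatched performed
notes are labeled extra and attributed to the nearest-cost hand. On toy
instances the DP cost is verified against exhaustive enumeration of all
monotone matchings; on noisy synthetic cohorts with 2% error rates,
hand-assignment accuracy against generator ground truth exceeds 99%.

Ties among equal-cost alignments are broken preferring match >
substitution > score-gap > performance-gap, resolved during backtracking.

## Features

Per matched note, with `dur` the performed duration, `ioi` the performed
IOI to the hand's next matched note, and `sdur` = 0.25 s the written
duration at nominal tempo:

- rDuration = ln(dur / sdur) — duration against the *absolute* written
  tempo;
- rIOI = ln(ioi / sdur) — pacing against the written tempo;
- Articulation = ln(dur / ioi) — legato/staccato at the performer's own
  tempo;
- Velocity — the MIDI velocity (1–127).

Natural logarithms are used throughout; the magnitudes of the published
between-hand articulation differences (~0.09) are consistent with
natural-log ratios and inconsistent with base-10. On isochronous scores
Articulation = rDuration − rIOI identically, which the tests check per
note at 1e-12.

Notes whose next matched neighbour is not the immediate score successor
(a missed note left a gap) have rIOI and Articulation left undefined
rather than divided by a single written duration; delta features (first
differences along a hand's stream) are likewise only taken between
score-adjacent matched notes. Missed and extra notes contribute nothing.

DBH (difference-between-hands) features subtract LH from RH over written
unison pairs in which both members matched: performed-duration
difference (s), attack deviation = RH onset − LH onset (s; negative
means the right hand leads — melody lead), articulation difference
(log-ratio), velocity difference (MIDI units), each with a delta
variant.

Aggregation computes mean and sample SD (n−1) of each feature for RH,
LH, and DBH; BH (both hands) is the arithmetic mean of the RH and LH
statistics — including the SDs, i.e. an average of per-hand SDs, not a
pooled SD. This yields 48 Basic (3 scopes × 8 features × 2 statistics)
plus 16 DBH = 64 aggregates per performance. The per-performer "all"
row is the element-wise mean of the two excerpt vectors.

## Statistics

For each Basic feature, a 2×2 split-plot ANOVA: hand within subjects,
proficiency group between subjects, one value per subject and hand.
Sums of squares are decomposed directly (subjects within groups are the
error term for the group effect; hand × subjects within groups for the
hand and interaction effects); partial eta squared is
SS_effect/(SS_effect + SS_error) against each effect's own error term;
dfs are (1, N−2). The implementation is cross-checked against an
independent mixed-ANOVA routine in the test suite. The all-identical
degenerate case reports F = 0, p = 1.

DBH features are compared between groups with the pooled-variance
(Student) t-test, df = n_A + n_B − 2, oriented amateur − expert. The
pooled form (not Welch) is deliberate: plugging the published group
summary statistics into it reproduces the published t values to a
fraction of a percent, which pins down the variant used. The test is
callable from summary statistics for exactly this kind of worked
example. Bonferroni adjustment multiplies p by the number of comparisons
(default 3: the two excerpts and their average), capped at 1. Cohen's d
for the hand contrast uses the two-condition pooled SD
√((s_RH² + s_LH²)/2), the standard two-condition form. Assumption
checks are mean-centered Levene and Shapiro–Wilk; the normality test is
fixed to Shapiro–Wilk, the usual choice at these sample sizes.

## Classification

Feature sets: Basic (48), DBH (16), Basic+DBH (64). Columns are
z-scored to sample SD 1, PCA is fitted, components are selected by one
of: smallest k reaching 95% or 99% cumulative explained variance; the k
maximizing mean F1 (ties to smallest k); or fixed k ∈ {10, 20, 40} —
fixed k beyond a set's width (k > 16 for DBH-only) is skipped. A linear
soft-margin SVM (C = 1.0) is evaluated by stratified 10-fold
cross-validation with per-fold F1, expert positive; the report carries
mean and SD over folds.

By default the scaler and PCA are fitted on the whole dataset before
cross-validation, mirroring the analysis protocol as described; this
leaks distributional information across folds. `fold_safe=True` refits
both inside each training fold for a leakage-free estimate. Fold
construction is a seeded stratified shuffle (the original fold scheme is
unspecified). PCA component signs are fixed by making each component's
largest-magnitude loading positive.

## Synthetic cohort

No recordings are deposited, so a generative model supplies cohorts with
the statistical structure the analysis assumes: 34 experts and 34
amateurs, each playing both excerpts. Per performer (traits shared
across that performer's excerpts):

- a personal tempo factor (mean 1, SD 0.05 expert / 0.08 amateur);
- per-hand articulation ratios (performed duration / IOI);
- a mean attack asynchrony (RH − LH onset);
- a common-mode loudness level (SD 6 MIDI units, both groups);
- an RH − LH velocity offset;
- three precision scales (timing, articulation, dynamics) multiplying
  the corresponding note-level noise magnitudes.

Per note: the left hand lays down tempo-scaled written IOIs plus AR(1)
jitter (coefficient 0.3; SD 10 ms expert / 18 ms amateur); the right
hand offsets each unison partner by an asynchrony draw; durations are
articulation-ratio draws times the realized IOI, with a phrase-level
component shared by both hands (SD 0.10) plus hand-specific noise;
velocities are base + mean-centered pitch-contour term + shared
expressive dynamics (AR(1), SD 5) + hand-specific AR(1) noise whose
marginal SD and increment SD are set separately so loudness variability
and smoothness calibrate independently (the implied autocorrelation is
1 − Δ²/(2σ²)). Wrong notes (±1–2 semitones), misses and extras are
injected at 0.2% (expert) / 1% (amateur) per note. Velocities are
clipped to [1, 127] and rounded to integers, as MIDI requires.

Calibration targets are the published group-level moments: the expert /
amateur "all"-excerpt means of the between-hand velocity offset
(11.083 / 7.521 MIDI units), duration difference (0.021 / 0.009 s),
attack asynchrony (−0.004 / +0.0008 s) and articulation difference
(0.090 / 0.038), the within-performance SDs of those quantities, the
between-performer spreads of the group means, and the family-specific
between-performer coefficients of variation of the precision scales
(expert / amateur: timing 0.25/0.43, articulation 0.31/0.47, dynamics
0.14/0.20), all read off the published group tables. The articulation
ratio pair per group is solved so the duration difference in seconds
and the log-articulation difference are matched simultaneously
(expert 0.976/0.892, amateur 0.9656/0.9296 at the 0.25 s nominal IOI).

What the generator does *not* reproduce: note-level correlation
structure beyond AR(1), fatigue or drift across a performance, pitch- or
finger-dependent error patterns, pedal, and — importantly — whatever
latent structure made between-hand features add classification accuracy
over per-hand features in the original recordings (see limitations).
Passing tests therefore demonstrate correctness of the pipeline and
self-consistency of the calibration, not fidelity to unobserved human
data.

## Numerical choices

- Alignment costs (substitution 1.0, gap 0.6) chosen so one wrong
  adjacent key (substitution) is cheaper than miss + extra (1.2), while
  far pitch errors decompose into miss + extra.
- Sample SDs use n−1 everywhere; fold-F1 SD uses the population form
  over the 10 folds, matching how per-fold score spreads are usually
  reported.
- Zero-variance columns in z-scoring pass through as zeros with a
  warning rather than dividing by zero.
- Degenerate ANOVA cells (all values equal) report F = 0, p = 1.
- A zero pooled variance with unequal means yields an explicit ±inf t.
- SMF writing quantizes to half a tick (default 480 ppq); note-offs sort
  before note-ons at the same tick so re-struck keys pair FIFO.

## Problem sizes

Default test and acceptance runs use the full 34 + 34 cohort on both
excerpts (the study's own size); end-to-end simulation, alignment,
extraction, statistics and classification complete in well under a
minute on one core. The classification ceiling study in the acceptance
suite repeats the cohort over 10 seeds.

## Known limitations

- The between-hand *mean* aggregates are exact linear combinations of
  the per-hand aggregates (e.g. DBH velocity mean = RH mean − LH mean
  when all pairs match), so on synthetic cohorts whose group structure
  is fully described by the published summary moments, adding DBH
  features to Basic features yields only a small expected F1 gain —
  comparable to the fold-sampling noise of 10-fold cross-validation at
  n = 68. The consistent gain reported for the original recordings
  evidently reflects correlation structure that published summary
  statistics do not pin down. The acceptance suite states this property
  directionally and measures it honestly; see the repository's test
  output for the observed rate.
- The aligner is pitch-sequence-based and per-hand monophonic; it is not
  suitable for polyphony within a hand, trills, or ornaments.
- Velocity rounding to integers introduces sub-unit quantization noise,
  negligible at cohort level.
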