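# Methods

This note documents the models, parameters and numerical choices behind
`guidedreading`, and what its synthetic experiments do and do not show.

## The staircase assessment

The assessment estimates two reader parameters at once: the recognition
span `s` (letters recognizable in a single fixation) and the required
fixation time `T` (presentation time at which recognition succeeds).
Lists of 20 unique pseudowords of one length are presented; a list is
*passed* when at least 19 of 20 (95%) are read correctly. The schedule:

- start at 4 letters / 250 ms;
- on failure, raise the presentation time by 50 ms up to 500 ms
  (temporal summation is effective only up to roughly this exposure,
  which is why the grid stops there);
- on failure at 500 ms, reduce the word length by one and restart the
  time sweep at 250 ms;
- on a pass at 250 ms before any demotion, increase length by one;
- any other pass terminates, defining the profile.

Three policies are deliberate design choices where the procedure's
verbal description is ambiguous:

1. **Time reset after demotion.** The sweep restarts at 250 ms rather
   than continuing from 500 ms, so the reported time is the *minimal*
   sufficient one — consistent with reporting a single (length, time)
   pair per reader.
2. **Termination on any pass above 250 ms.** A reader who needs
   300+ ms at length `n` is not promoted to `n+1`; each reader gets
   exactly one profile cell.
3. **Demotion latch.** After any demotion, passes terminate instead of
   re-promoting. This forbids pass/fail oscillation and bounds the
   procedure at 36 list administrations for *any* response sequence
   (property-tested). A session budget (`max_lists`, default 30,
   standing for a bounded session duration) additionally caps the run;
   if it triggers, the best passing condition is returned with a
   `budget_exhausted` flag.

A pass at (2, 500) failing means the reader is below the measurable
floor (`at_floor`); a terminal (6, 250) pass is flagged `at_ceiling`.

## The recognition model (synthetic readers)

Recognition of an `n`-letter string fixated for `t` ms uses a shifted
logistic in time with a linear length cost:

    tau(n) = T* + kappa * (n - s*)            n >= s*
    tau(n) = max(150 ms, T* - kappa * (s*-n)) n <  s*
    p(n,t) = logistic(slope * (t - tau(n)) + logit(0.995))

`slope = inf` gives the deterministic step reader `p = 1[t >= tau(n)]`.
Only monotonicity (nondecreasing in `t`, nonincreasing in `n`) is an
empirical commitment; the logistic family itself is a modelling choice.
Two calibration decisions matter:

- **Anchor at p(tau) = 0.995.** A reader "at threshold" must pass a
  19-of-20 criterion; with per-word success 0.95 a list pass has only
  ~74% probability, which would make the staircase unstable at its own
  threshold. Anchoring near-certainty at `tau` makes a finite-slope
  reader behave like its step limit with high probability (the suite
  verifies ≥95% agreement over 200 replicates at slope 0.5/ms).
- **kappa = 300 ms/letter** (default). One extra letter beyond the span
  then costs more than the whole 250–500 ms grid, so a reader's span is
  crisply identified; one letter under the span is recognizable at the
  fastest grid time. Under these defaults every noise-free (span, time)
  combination on the 5 × 6 grid is recovered exactly, and assessing the
  60-reader cohort fixture reproduces its generating cross-tabulation
  cell for cell.

Speech onsets are modelled as `max(retrieval, tone) + reaction`, with
retrieval ~ N(mean, 300 ms) per reader (cohort means set so each span
column of the fixture matches the published column means), a 700 ms
guard tone in the assessment, and reaction ~ N(150, 50) ms.

## Error generation

A failed recognition produces one letter-error event drawn from a
mixture over {omission 0.35, substitution 0.40, transposition 0.15,
addition 0.10}; the victim position is drawn with weights
`1 + g * i/(L-1)` (`g` = `position_gradient`, default 1), reproducing
the empirical left-to-right rise of per-position misreading rates.
The scorer classifies errors from a minimal edit alignment (unit costs;
traceback prefers match > substitute > delete > insert): deletions are
omissions, insertions additions, and a pair of substitutions no more
than two positions apart whose letters reappear at each other's
positions is a transposition. Insertions are charged to the nearest
following target position so positional profiles keep the target's
length. Responses are compared case-insensitively after trimming.

## Free vs. guided reading

**Free reading** advances in chunks of the reader's *attempted* span.
Only the first `min(s*, attempted)` letters of a chunk fall inside the
recognizable window; the remaining gap letters are guessed correctly
with probability `guess_p` (≈ 1/alphabet for pseudowords; high, default
0.9 in the miscalibrated-cohort preset, for real connected text, which
is guessable from partial letters). Fixation durations are lognormal
around `free_duration_scale * T*` and halved with probability
`premature_speech_p` (premature saccades). Each planned saccade is,
with probability `regression_rate`, a one-chunk regression (refixation
without re-scoring), so the negative-saccade fraction equals the rate.

**Guided reading** follows the guidance script: segments no longer than
the profiled span, fixation on each segment's middle letter
(left-of-middle for even lengths), tone at cursor + 1000 ms, speech
window at tone + 250 ms, segment advance after a 500 ms pronunciation
window, 50 ms saccade gap. The fixated interval (cursor to tone, 1 s)
always covers the profiled fixation time on the 250–500 ms grid, so a
compliant reader whose script matches their ability reads error-free.
Misrecognized segments are retried once, then advanced. Hidden
already-read text means regressions occur only through compliance
lapses (default probability 0).

## The crossover experiment

The cohort fixture instantiates 60 readers whose (span, time) cells
match the published assessment cross-tabulation (19/18/18/5 readers at
spans 3–6). Group matching stratifies by span, then fixation time,
sorts by age within stratum, and alternates assignment starting each
stratum with the currently smaller group: group sizes differ by at most
one per stratum and overall. The crossover gives half of each group the
part order (1, 2) and half (2, 1); therapy readers' second-read halves
are computer-guided, controls never are. Four synthetic texts carry the
canonical part word/letter counts (29/142, 30/139; 33/156, 34/161;
26/129, 25/130; 20/131, 19/127 — 216 words), so error percentages use
the exact four-text denominator. Effect sizes are pooled-SD Cohen *d*
on misread-word counts, signed so an error decrease is positive
(therapy: unaided − aided; control: first − second); the headline
contrast is `d_therapy − d_control`. Session reading time runs from the
first fixation to the last scheduled segment end.

## What the simulation does and does not show

The simulated crossover reproduces the *direction and design* of the
empirical finding: across master seeds, guided reading reduces
misread-word counts in the therapy group far more than control-group
drift, with guided sessions substantially slower (the tone-enforced
≥1.25 s per segment dominates). It does **not** reproduce the empirical
*magnitudes*: synthetic miscalibrated readers fail on ~40% of words
unaided and ~0% guided, versus ~7.7% and ~2.3% in children. The model
corrupts a whole chunk on any failed recognition and knows nothing of
context, partial phonology, or self-correction, so its unaided error
rate is an overestimate and its guided rate an underestimate. Passing
tests therefore validate the machinery and the qualitative effect, not
a quantitative model of child reading. Free-reading saccade and
duration distributions are invented defaults (no published quantitative
distributions exist to fit) and are labelled as such in the parameter
documentation.

## Statistics

- Pooled SD and Cohen *d* follow the two-sample formulas exactly; *d*
  is antisymmetric and invariant under common affine rescaling.
- The *d* confidence interval is the standard large-sample normal
  interval `d ± z * sqrt((n1+n2)/(n1 n2) + d²/(2(n1+n2)))`. Published
  interval bounds for these data are not reproducible from any standard
  formula and are not targeted.
- Wilcoxon tests: signed-rank for within-reader comparisons, rank-sum
  for between-group ones. Exact two-sided tail probabilities
  (`2·min(P(W≤w), P(W≥w))`, capped at 1) are computed by dynamic
  programming over doubled mid-ranks — valid under ties, where
  textbook exact tables are not — for up to 25 informative pairs
  (signed-rank) or 10 per group (rank-sum); larger samples use the
  normal approximation with continuity correction. Zero differences
  are dropped.
- Holm–Bonferroni adjustment is the standard step-down
  `cummax((m−rank+1)·p)` capped at 1 (delegated to statsmodels and
  verified against a hand-stepped oracle).
- Positional misreading comparisons are paired signed-rank tests across
  readers' per-position rates, Holm-corrected within each word length.

## Problem sizes and determinism

All stochastic components draw from a single seeded NumPy generator per
run; experiment outputs are bit-reproducible under a fixed master seed.
The test suite exercises the directional crossover claim over 50 master
seeds with the full 60-reader cohort and 216-word material, exact
staircase recovery over all 30 grid combinations, alignment-cost
equivalence against brute force over 10⁴ random string pairs (length
≤ 6), and exact-test equivalence against full enumeration for up to 8
pairs / 6-per-group samples.
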