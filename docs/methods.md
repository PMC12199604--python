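# Methods

## The task model

The Weather Prediction Task (WPT) presents 1–3 of 4 cue cards per trial;
the participant predicts "sun" or "rain". Each card `i` carries a fixed
P(sun) `p_i`. The probability attached to a multi-card combination is the
independent-cue odds product (naive Bayes with a uniform prior over the
two outcomes):

    odds = Π p_i / (1 − p_i),    P(sun | cards) = odds / (1 + odds)

with a certain card (`p_i` exactly 0 or 1) forcing the combined value and
a mix of certain-sun and certain-rain cards rejected as contradictory.
This is the standard construction for the paradigm; the published design
states only that combination probabilities derive from the individual
cards, so the rule is a design choice of this package.

The enumeration of 1–3 card subsets of a 4-card set gives 14
combinations. Training (200 trials, four 50-trial blocks) balances the
14 combinations within blocks: each block holds each combination 3 or 4
times, with the 8 leftover slots per block rotated through a seeded
permutation so whole-session totals stay in {14, 15}. This satisfies
both a per-block and a whole-session reading of "balanced"; exact
within-block balance is impossible at 50/14. The 100-trial test uses
near-uniform coverage (7 or 8 appearances, the two extra slots drawn
without replacement); the published design does not state the test's
composition, so this too is configurable. Reactivation shows each
combination exactly once, with the expected response being the number of
cards shown. Training outcomes are sampled per trial from the
combination's probability. All sequence generators are pure functions of
(configuration, seed).

### Card probabilities

The actual per-card probabilities appear only in a figure of the source
study and are not printed; the defaults here are Set 1 = (0.80, 0.60,
0.45, 0.25) and Set 2 = (0.75, 0.55, 0.40, 0.20), chosen so that no
combination is a TIE under the odds-product rule while preserving the
classic strong/weak cue structure. Both sets are overridable in the
study config. If a user configuration does create TIE combinations
(combined probability exactly 0.5), those trials are excluded from the
correct-score numerator and denominator, since the "higher-probability
outcome" is undefined there.

## Scoring and exclusion

Raw score is the fraction of test trials answered with the optimal
outcome; unanswered trials count as incorrect (the task advances after
5 s regardless, so a non-response is a real task failure). Adjusted
score is `(raw − 0.5)/0.5`. Training compliance — the fraction of
training trials whose response matches the displayed outcome, an
attention measure — excludes a participant when strictly below 96%
(192/200 is retained).

Chance-level performance uses the exact two-sided binomial test against
p = 0.5 (twice the smaller tail, capped at 1); the chance band is the
widest integer interval around n/2 with p > alpha. For n = 100,
alpha = 0.05 this is 40–60 correct. The study as published prints a
40.9%–59.1% band, which no exact two-sided binomial on 100 trials
reproduces (its derivation is unstated); this package implements the
reconstructible exact rule and exposes the band as an override for
anyone wishing to force the printed bounds.

Key-reversal repair: a session is flagged as key-reversed only when its
correct count is strictly below the chance band AND the count after
flipping every answered response is strictly above it — a conservative
reading of "strong evidence" of reversal. Flagged sessions are repaired
(responses flipped, rescored). Repair is an involution, preserves the
number of answered trials, and commutes with the global sun/rain
relabeling symmetry. Exclusions are evaluated on post-repair scores
(the published account does not state pre- or post-repair; post-repair
is the choice here, since repaired sessions were explicitly retained),
and repair alone never excludes.

## Prospective balanced randomization

Each participant is assigned to a group immediately after the initial
test. Only the currently smallest groups are eligible (so sizes never
differ by more than one, matching the observed 17/17/17/18 split); among
eligible groups the allocator minimizes, after a hypothetical placement,
the sum of squared deviations of the nonempty group means from their
grand mean. The published description says only "minimize the
differences in group means while not distorting the number in each
group"; the squared-deviation objective is the symmetric, smooth member
of that family, and a max-pairwise-gap objective is available by config.
Ties are broken uniformly with a seeded RNG to preserve randomization
validity. Empty groups are filled before the objective is ever
evaluated (forced by the size rule). The allocator is deterministic
given (seed, arrival order, scores), checkpoints to JSON, and speaks a
line-oriented JSON protocol so external experiment software can stream
enrollments.

## Group statistics

All report-level quantities are in adjusted-score percentage points.
Per group: mean, sem, sd of the per-participant change; one-sample
two-sided t of the change against zero (t = mean/sem, df = n−1);
Cohen's d = mean/sd (standard one-sample convention). The same
quantities are reconstructed from printed (mean, sem, n) via
`summary_from_moments` (sd = sem·√n, t = mean/sem), which is how the
published table is verified without raw data.

Two documented non-reproductions of the published table: (1) one
column's printed t values equal that column's means rather than
mean/sem — a transcription slip; the package asserts the
standard-convention values for that column. (2) The printed d row runs
roughly twice mean/sd for three of four columns; the convention is
unexplained and internally inconsistent, so the package reports the
standard d = mean/sd (for the reactivation+interference group:
−6.02/12.1 = −0.50, versus a printed 1.0).

Percent change is computed per participant, `100·(t2 − t1)/t1`, then
averaged; participants with a zero baseline are dropped from the percent
vector with a warning. The group-level ratio of means is a different
(and here wrong) quantity.

Across groups: classic one-way fixed-effects ANOVA (explicit
between/within sum-of-squares decomposition, cross-checked against an
independent implementation in the tests) with Fisher's LSD post hocs —
pairwise t on the pooled within-group mean square and its df, unadjusted
two-sided p per the LSD convention. Unpaired comparisons use the
equal-variance Student's t (Welch by flag). Report rounding: 3
significant figures for sd, 2 for t and d, 3 decimals for p.

## The synthetic cohort

The generator stands in for the study's deposited raw data; no
cognitive model is specified in the publication, so the learner here is
a deliberate stand-in: error-correcting associative weights
(Rescorla–Wagner), one weight per card, updated each training trial by
`learning_rate · (outcome − prediction)` on the cards shown, where the
prediction is 0.5 plus the summed active weights. Test choices are
logistic in the summed active weights with scale `temperature`, with a
per-trial `lapse_prob` of non-response, a training `compliance`
probability of echoing the displayed outcome, and a per-session
`reversal_prob` of answering with swapped keys.

Defaults: learning_rate 0.02, temperature 0.01, lapse_prob 0.01,
compliance 0.99, reversal_prob 0. These were fixed once so that a clean
simulated cohort's mean initial adjusted score lands near the observed
~80-point level (simulated mean ≈ 78, between-participant sd ≈ 13);
they are the simplest settings producing above-chance, sub-ceiling
performance of that magnitude and are not re-tuned per experiment.

Retest effects per group come in two modes. DIRECT (default for
calibration work) draws a per-participant target change from
Normal(delta_mean, delta_sd) in adjusted points and constructs the
retest response vector to realize the nearest achievable change at the
test's count resolution (2 adjusted points per trial at n = 100);
targets pushing the score outside [0, 100] raw are truncated with a
flag. Lapses are not drawn in DIRECT mode — the correct count is the
controlled quantity. MECHANISTIC decays the learned weights
(multiplicative `decay`, additive `jitter`) and simulates the retest
through the choice rule; `calibrate_mechanistic_decay` grid-searches the
decay whose mean change matches a target. The default group effects are
patterned on the study's per-group change moments: (−R−I) +1.39 sd
5.01, (−R+I) −0.64 sd 11.3, (+R−I) −0.94 sd 6.93, (+R+I) −6.02 sd 12.1,
with n_total 69.

The cohort simulator runs enrollment in arrival order (training, test,
prospective assignment on the baseline adjusted score, protocol phases,
retest) and emits trial-level logs in the same CSV schema the scoring
stage reads, plus a ground-truth table. Pathologies can be injected by
count — low-compliance participants (compliance 0.90), non-learners
(learning_rate 0), and whole-session key-reversers (retest flipped) —
to exercise the exclusion and repair rules; `recovery_report` compares
pipeline output against the injected truth (per-group bias/RMSE of mean
change, repair and chance-exclusion confusion counts).

### What the generator does and does not emulate

It reproduces the statistical structure the analysis assumes: trial
counts and balance, above-chance learned performance with realistic
between-participant spread, lapses, compliance failures, whole-session
reversals, and per-group change distributions with specified moments.
It does not model reaction times, within-session learning drift at
test, circadian or sleep effects, questionnaire responses, or any
mechanistic coupling between interference training and the first card
set's memory (a shared-category interference option exists only as the
MECHANISTIC mode's decay/jitter, with no calibrated default). Passing
tests therefore show the pipeline's correctness and calibration on data
with the assumed structure, not fidelity of any cognitive claim about
real participants.

## Numerical and procedural choices

- Trial indices and blocks are 0-based in memory, 1-based in CSV
  exports; block ranges are half-open.
- Randomness: one master seed per study; per-participant generators are
  spawned via `numpy.random.SeedSequence`, so cohorts are bit-identical
  for a fixed seed and independent of participant count changes
  elsewhere.
- Allocator tie detection uses a relative 1e-12 tolerance on the
  objective; ties are broken by seeded uniform choice.
- Degenerate inputs: zero-variance change vectors give t = 0, p = 1
  when the mean is zero and a flagged infinite t otherwise; zero
  within-group variance gives a flagged infinite F (or F = 0 when all
  values are identical); zero-sd Cohen's d is flagged NaN; groups with
  n < 2 are dropped from the report with a warning.
- Replicate-based checks in the test suite use 500 full-pipeline
  cohorts (≈0.1 s each with protocol-phase logs disabled, which do not
  affect scores); effect-injection calibration uses 10,000 score-level
  cohorts.

## Known limitations

- The exact binomial chance band differs from the published 40.9–59.1%
  band (derivation unstated); the band is overridable but the default
  is the reconstructible rule.
- The original allocator's exact objective is not published; this one
  is a faithful reconstruction of the stated contract, not a port.
- The learner is a stand-in; MECHANISTIC mode has no calibrated default
  for interference-specific forgetting.
- With the published effect moments, per-group power for the
  significant group is only ~0.5 at n = 18, so single simulated cohorts
  frequently fail to reproduce the qualitative pattern; only replicate
  majorities are meaningful, and even those are near the knife's edge —
  as the power arithmetic (d ≈ 0.5, n = 18) dictates.
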