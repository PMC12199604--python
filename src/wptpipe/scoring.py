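"""Scoring, chance-level exclusion, and key-reversal repair.

A test response is correct when it matches the optimal outcome of the
displayed combination; unanswered trials count as incorrect, and trials
showing a TIE combination (combined probability exactly 0.5) are removed
from both numerator and denominator. Raw score is the fraction correct;
the chance-corrected adjusted score is ``(raw - 0.5) / 0.5``, mapping
guessing to 0 and perfection to 1.

Chance-level performance is judged with an exact two-sided binomial test
against p = 0.5 (twice the smaller tail, capped at 1): ``chance_range``
returns the widest integer band of correct counts around n/2 whose
p-value stays above alpha, and a score inside the band is "at chance".
For n = 100, alpha = 0.05 the band is [40, 60] correct.

A whole-session key reversal (participant swapped the sun/rain keys) is
flagged when the session scores strictly below the chance band while its
key-flipped version scores strictly above it; repair flips every answered
response and rescores. Repair is an involution.

Exclusion rules: (i) training compliance below 96% (responses matching the
displayed outcome, an attention measure); (ii) at-chance performance at
either the initial test or the retest, evaluated after repair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import binom

from .logs import DataError, SessionLog
from .task import Combination, NO_RESPONSE, RAIN, SUN, TIE, TEST_PHASES, TRAINING_PHASES

TRAINING_COMPLIANCE_THRESHOLD = 0.96

REASON_LOW_TRAINING_COMPLIANCE = "LOW_TRAINING_COMPLIANCE"
REASON_AT_CHANCE_TEST = "AT_CHANCE_TEST"
REASON_AT_CHANCE_RETEST = "AT_CHANCE_RETEST"


def adjust(raw: float) -> float:
    """Chance-corrected score: (raw - 0.5) / 0.5."""
    return (raw - 0.5) / 0.5


def two_sided_binom_p(x: int, n: int) -> float:
    """Exact two-sided binomial p against p=0.5: twice the smaller tail, capped at 1."""
    lower = binom.cdf(x, n, 0.5)
    upper = binom.sf(x - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def chance_range(n_trials: int, alpha: float = 0.05) -> tuple[int, int]:
    """Widest integer band [lo, hi] around n/2 with exact binomial p > alpha.

    A correct count inside the band is statistically indistinguishable
    from guessing at the given alpha.
    """
    if n_trials < 1:
        raise DataError(f"n_trials={n_trials} < 1")
    if not 0.0 < alpha < 1.0:
        raise DataError(f"alpha={alpha} outside (0, 1)")
    xs = np.arange(n_trials + 1)
    lower = binom.cdf(xs, n_trials, 0.5)
    upper = binom.sf(xs - 1, n_trials, 0.5)
    p = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    inside = np.flatnonzero(p > alpha)
    # p is unimodal around n/2, so the band is contiguous by construction
    return int(inside.min()), int(inside.max())


@dataclass(frozen=True)
class TestScore:
    """Scoring result for one test session (TIE trials excluded throughout)."""

    n_trials: int
    n_answered: int
    n_correct: int
    raw: float
    adjusted: float
    chance_p: float
    at_chance: bool
    reversed_flag: bool = False
    repaired: bool = False
    n_tie_excluded: int = 0


def score_training_compliance(log: SessionLog) -> float:
    """Fraction of training trials whose response matches the displayed outcome.

    Non-responses count as mismatches. This is an attention measure, not
    an optimal-answer rate; the study retains participants at or above 96%.
    """
    if log.phase not in TRAINING_PHASES:
        raise DataError(f"expected a training-phase log, got {log.phase!r}")
    if len(log) == 0:
        raise DataError("empty training log")
    return float((log.response == log.displayed).sum() / len(log))


def score_test(
    log: SessionLog,
    combinations: Sequence[Combination],
    alpha: float = 0.05,
    chance_bounds: tuple[int, int] | None = None,
) -> TestScore:
    """Score one test session against the optimal outcomes of its card set.

    ``chance_bounds`` may override the exact-binomial band (the study
    reported a slightly different band than the exact test reconstructs).
    """
    if log.phase not in TEST_PHASES:
        raise DataError(f"expected a test-phase log, got {log.phase!r}")
    if len(log) == 0:
        raise DataError("empty test log")
    if int(log.combo_idx.max(initial=0)) >= len(combinations) or int(
        log.combo_idx.min(initial=0)
    ) < 0:
        raise DataError("log references an unknown combination")
    optimal = np.array([c.optimal_outcome for c in combinations], dtype=np.int8)[log.combo_idx]
    scoreable = optimal != TIE
    n = int(scoreable.sum())
    n_tie = len(log) - n
    if n == 0:
        raise DataError("no scoreable (non-TIE) trials in test log")
    resp = log.response[scoreable]
    n_answered = int((resp != NO_RESPONSE).sum())
    n_correct = int((resp == optimal[scoreable]).sum())
    raw = n_correct / n
    lo, hi = chance_bounds if chance_bounds is not None else chance_range(n, alpha)
    return TestScore(
        n_trials=n,
        n_answered=n_answered,
        n_correct=n_correct,
        raw=raw,
        adjusted=adjust(raw),
        chance_p=two_sided_binom_p(n_correct, n),
        at_chance=lo <= n_correct <= hi,
        n_tie_excluded=n_tie,
    )


def flip_responses(log: SessionLog) -> SessionLog:
    """Swap SUN and RAIN on every answered trial (repair primitive; involution)."""
    out = log.copy()
    sun = out.response == SUN
    rain = out.response == RAIN
    out.response[sun] = RAIN
    out.response[rain] = SUN
    return out


def detect_and_repair_reversal(
    logs: Sequence[SessionLog],
    combinations: Sequence[Combination],
    alpha: float = 0.05,
    chance_bounds: tuple[int, int] | None = None,
) -> tuple[list[SessionLog], list[TestScore]]:
    """Flag and repair whole-session key reversals.

    A session is reversed when its correct count is strictly below the
    chance band while the count after flipping every answered response is
    strictly above it — i.e. the participant was reliably tracking the
    contingencies with swapped keys. Flagged sessions are returned
    repaired (responses flipped, rescored, ``repaired=True``); all other
    sessions pass through untouched.
    """
    out_logs: list[SessionLog] = []
    out_scores: list[TestScore] = []
    for log in logs:
        score = score_test(log, combinations, alpha, chance_bounds)
        lo, hi = (
            chance_bounds if chance_bounds is not None else chance_range(score.n_trials, alpha)
        )
        if score.n_correct < lo:
            flipped = flip_responses(log)
            fscore = score_test(flipped, combinations, alpha, chance_bounds)
            if fscore.n_correct > hi:
                out_logs.append(flipped)
                out_scores.append(replace(fscore, reversed_flag=True, repaired=True))
                continue
        out_logs.append(log)
        out_scores.append(score)
    return out_logs, out_scores


@dataclass
class ParticipantScores:
    """Post-repair scoring summary for one participant."""

    participant_id: str
    training_compliance: float
    test: TestScore
    retest: TestScore | None = None
    interference_test: TestScore | None = None
    repaired_sessions: list[str] = field(default_factory=list)


@dataclass
class ExclusionReport:
    participant_id: str
    excluded: bool
    reasons: list[str]
    repaired_sessions: list[str] = field(default_factory=list)


def apply_exclusions(
    cohort_scores: Sequence[ParticipantScores],
    compliance_threshold: float = TRAINING_COMPLIANCE_THRESHOLD,
) -> list[ExclusionReport]:
    """Apply the two exclusion rules to post-repair scores.

    Rule (i): training compliance strictly below the threshold (default
    96%, boundary inclusive on the retained side). Rule (ii): at-chance
    performance at the initial test or the retest. Repair alone never
    causes exclusion.
    """
    reports = []
    for ps in cohort_scores:
        reasons = []
        if ps.training_compliance < compliance_threshold:
            reasons.append(REASON_LOW_TRAINING_COMPLIANCE)
        if ps.test.at_chance:
            reasons.append(REASON_AT_CHANCE_TEST)
        if ps.retest is not None and ps.retest.at_chance:
            reasons.append(REASON_AT_CHANCE_RETEST)
        reports.append(
            ExclusionReport(
                participant_id=ps.participant_id,
                excluded=bool(reasons),
                reasons=reasons,
                repaired_sessions=list(ps.repaired_sessions),
            )
        )
    return reports
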