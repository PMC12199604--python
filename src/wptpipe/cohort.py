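"""Synthetic participant cohort generator.

Stands in for the study's raw behavioral data: every participant is a
simulated learner run through the full protocol (11AM training + test,
1PM reactivation for +R groups, 2PM interference training on the second
card set for +I groups, 4PM retest), producing trial-level session logs
in exactly the schema the scoring pipeline reads, plus a ground-truth
table of everything that was injected.

The learner is an error-correcting associative model (Rescorla-Wagner
style): per-card weights, updated on each training trial by
``learning_rate * (outcome - prediction)`` for the cards shown, with a
logistic choice rule over the summed active-card weights at test
(``temperature`` scales choice noise), a per-trial ``lapse_prob`` of not
responding, a training ``compliance`` probability of echoing the
displayed outcome, and a per-session ``reversal_prob`` of answering an
entire test with the response keys swapped. The defaults are calibrated
so a clean cohort's mean initial adjusted score lands near the observed
~80 points.

Group effects at retest come in two modes. DIRECT (the default for
calibration work) draws a per-participant target change from
Normal(delta_mean, delta_sd) in adjusted points and constructs the
retest so the realized change is the nearest value achievable at the
test's integer-count resolution (2 adjusted points per trial at n=100);
targets pushing the raw score outside [0, 1] are truncated with a flag.
MECHANISTIC decays/perturbs the learned weights before retest and lets
the choice rule produce the change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import randomizer as rnd
from .logs import SessionLog
from .scoring import TestScore, score_test
from .task import (
    CardSet,
    Combination,
    NO_RESPONSE,
    PHASE_INTERFERENCE_TEST,
    PHASE_INTERFERENCE_TRAINING,
    PHASE_REACTIVATION,
    PHASE_RETEST,
    PHASE_TEST,
    PHASE_TRAINING,
    RAIN,
    SUN,
    TIE,
    as_rng,
    default_card_set,
    enumerate_combinations,
    sample_outcomes,
    test_combo_arrays,
    training_combo_arrays,
)

MODE_DIRECT = "DIRECT"
MODE_MECHANISTIC = "MECHANISTIC"


@dataclass(frozen=True)
class LearnerParams:
    """Synthetic learner: acquisition, choice noise, lapses, compliance, reversals."""

    learning_rate: float = 0.02
    temperature: float = 0.01
    lapse_prob: float = 0.01
    compliance: float = 0.99
    reversal_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.learning_rate <= 1.0:
            raise ValueError("learning_rate must be in [0, 1] (0 disables learning)")
        if self.temperature < 0.0:
            raise ValueError("temperature must be >= 0")
        if not 0.0 <= self.lapse_prob < 1.0:
            raise ValueError("lapse_prob must be in [0, 1)")
        if not 0.0 < self.compliance <= 1.0:
            raise ValueError("compliance must be in (0, 1]")
        if not 0.0 <= self.reversal_prob < 1.0:
            raise ValueError("reversal_prob must be in [0, 1)")


@dataclass(frozen=True)
class GroupEffect:
    """Target test->retest change for one group, in adjusted points."""

    group_label: str
    delta_mean: float = 0.0
    delta_sd: float = 0.0
    mode: str = MODE_DIRECT
    decay: float = 1.0   # MECHANISTIC: multiplicative weight decay before retest
    jitter: float = 0.0  # MECHANISTIC: sd of additive weight noise before retest

    def __post_init__(self) -> None:
        if self.delta_sd < 0:
            raise ValueError("delta_sd must be >= 0")
        if self.mode not in (MODE_DIRECT, MODE_MECHANISTIC):
            raise ValueError(f"unknown mode {self.mode!r}")


def table_patterned_effects() -> dict[str, GroupEffect]:
    """DIRECT-mode effects with the study's per-group change moments."""
    vals = {"-R-I": (1.39, 5.01), "-R+I": (-0.64, 11.3), "+R-I": (-0.94, 6.93), "+R+I": (-6.02, 12.1)}
    return {g: GroupEffect(g, m, s) for g, (m, s) in vals.items()}


def null_effects(mode: str = MODE_MECHANISTIC) -> dict[str, GroupEffect]:
    """No injected effect: retest is a fresh draw from the unchanged learner."""
    return {g: GroupEffect(g, 0.0, 0.0, mode=mode) for g in rnd.DEFAULT_GROUPS}


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort."""

    n_total: int = 69
    group_labels: tuple[str, ...] = rnd.DEFAULT_GROUPS
    group_effects: dict[str, GroupEffect] = field(default_factory=table_patterned_effects)
    learner: LearnerParams = field(default_factory=LearnerParams)
    n_training: int = 200
    n_blocks: int = 4
    n_test: int = 100
    alpha: float = 0.05
    card_set_1: CardSet = field(default_factory=lambda: default_card_set(1))
    card_set_2: CardSet = field(default_factory=lambda: default_card_set(2))
    # injected pathologies, for exercising the exclusion/repair rules
    n_noncompliant: int = 0
    n_nonlearner: int = 0
    n_reverser: int = 0
    include_protocol_phases: bool = True
    randomizer_objective: str = rnd.OBJECTIVE_VARIANCE
    size_slack: int = 0
    # protocol schedule (labels only; recorded in exports/manifest)
    schedule: dict[str, str] = field(
        default_factory=lambda: {
            "training": "11AM",
            "test": "11AM",
            "reactivation": "1PM",
            "interference": "2PM",
            "retest": "4PM",
        }
    )

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        missing = [g for g in self.group_labels if g not in self.group_effects]
        if missing:
            raise ValueError(f"group_effects missing for {missing}")
        if self.n_noncompliant + self.n_nonlearner + self.n_reverser > self.n_total:
            raise ValueError("injected pathology counts exceed n_total")


# -- learner ---------------------------------------------------------------

def _member_indices(card_set: CardSet, combos: Sequence[Combination]) -> list[tuple[int, ...]]:
    pos = {c.card_id: i for i, c in enumerate(sorted(card_set.cards, key=lambda c: c.card_id))}
    return [tuple(pos[cid] for cid in combo.card_ids) for combo in combos]


def train_weights(
    members: Sequence[tuple[int, ...]],
    combo_seq: Sequence[int],
    outcomes: Sequence[int],
    learning_rate: float,
    n_cards: int = 4,
    weights: Sequence[float] | None = None,
) -> list[float]:
    """Run the error-correcting update over one training sequence."""
    w = [0.0] * n_cards if weights is None else list(weights)
    lr = float(learning_rate)
    for ci, o in zip(combo_seq, outcomes):
        mem = members[ci]
        v = 0.5
        for j in mem:
            v += w[j]
        step = lr * (o - v)
        for j in mem:
            w[j] += step
    return w


def choice_p_sun(
    weights: Sequence[float], members: Sequence[tuple[int, ...]], temperature: float
) -> np.ndarray:
    """Per-combination P(respond SUN) under the logistic choice rule."""
    wsum = np.array([sum(weights[j] for j in mem) for mem in members])
    if temperature == 0.0:
        return np.where(wsum > 0, 1.0, np.where(wsum < 0, 0.0, 0.5))
    return 1.0 / (1.0 + np.exp(-wsum / temperature))


def simulate_test_responses(
    p_sun_by_combo: np.ndarray,
    combo_idx: np.ndarray,
    lapse_prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    p = p_sun_by_combo[combo_idx]
    resp = np.where(rng.random(len(p)) < p, SUN, RAIN).astype(np.int8)
    if lapse_prob > 0:
        resp[rng.random(len(p)) < lapse_prob] = NO_RESPONSE
    return resp


def _flip_in_place(responses: np.ndarray) -> None:
    sun = responses == SUN
    rain = responses == RAIN
    responses[sun] = RAIN
    responses[rain] = SUN


@dataclass
class ParticipantSim:
    """One simulated participant's internal state and session logs."""

    participant_id: str
    params: LearnerParams
    weights: list[float]
    logs: dict[str, SessionLog]
    test_score: TestScore
    members: list[tuple[int, ...]]
    reversed_sessions: list[str] = field(default_factory=list)


def simulate_training_session(
    pid: str,
    card_set: CardSet,
    combos: Sequence[Combination],
    params: LearnerParams,
    n_trials: int,
    n_blocks: int,
    rng: np.random.Generator,
    phase: str = PHASE_TRAINING,
    weights: Sequence[float] | None = None,
) -> tuple[SessionLog, list[float]]:
    members = _member_indices(card_set, combos)
    idx, blocks = training_combo_arrays(len(combos), n_trials, n_blocks, rng)
    p = np.array([c.p_sun_combined for c in combos])[idx]
    outcomes = sample_outcomes(p, rng)
    w = train_weights(members, idx.tolist(), outcomes.tolist(), params.learning_rate,
                      card_set.n_cards, weights)
    responses = outcomes.copy()
    responses[rng.random(n_trials) >= params.compliance] = NO_RESPONSE
    log = SessionLog(
        participant_id=pid,
        phase=phase,
        set_id=card_set.set_id,
        combo_idx=idx,
        displayed=outcomes,
        response=responses,
        block=blocks,
    )
    return log, w


def simulate_test_session(
    pid: str,
    card_set: CardSet,
    combos: Sequence[Combination],
    weights: Sequence[float],
    params: LearnerParams,
    n_trials: int,
    rng: np.random.Generator,
    phase: str = PHASE_TEST,
) -> SessionLog:
    members = _member_indices(card_set, combos)
    idx = test_combo_arrays(len(combos), n_trials, rng)
    p_by_combo = choice_p_sun(weights, members, params.temperature)
    responses = simulate_test_responses(p_by_combo, idx, params.lapse_prob, rng)
    return SessionLog(
        participant_id=pid,
        phase=phase,
        set_id=card_set.set_id,
        combo_idx=idx,
        displayed=np.full(n_trials, NO_RESPONSE, dtype=np.int8),
        response=responses,
    )


def simulate_participant(
    pid: str, params: LearnerParams, cfg: CohortConfig, rng: np.random.Generator
) -> ParticipantSim:
    """Initial training + immediate test for one participant."""
    combos = enumerate_combinations(cfg.card_set_1)
    training, w = simulate_training_session(
        pid, cfg.card_set_1, combos, params, cfg.n_training, cfg.n_blocks, rng
    )
    test = simulate_test_session(
        pid, cfg.card_set_1, combos, w, params, cfg.n_test, rng, PHASE_TEST
    )
    reversed_sessions = []
    if params.reversal_prob > 0 and rng.random() < params.reversal_prob:
        _flip_in_place(test.response)
        reversed_sessions.append(PHASE_TEST)
    score = score_test(test, combos, cfg.alpha)
    return ParticipantSim(
        participant_id=pid,
        params=params,
        weights=w,
        logs={PHASE_TRAINING: training, PHASE_TEST: test},
        test_score=score,
        members=_member_indices(cfg.card_set_1, combos),
        reversed_sessions=reversed_sessions,
    )


# -- retest effect injection ----------------------------------------------

def quantize_direct_changes(
    targets: np.ndarray, base_correct: int, n_trials: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Snap target adjusted-point changes to the test's integer-count grid.

    Returns (new correct counts, realized adjusted-point changes,
    truncation flags). One trial is worth 200/n adjusted points.
    """
    delta_counts = np.rint(np.asarray(targets, dtype=float) * n_trials / 200.0)
    new = base_correct + delta_counts
    clipped = np.clip(new, 0, n_trials)
    truncated = clipped != new
    realized = 200.0 * (clipped - base_correct) / n_trials
    return clipped.astype(int), realized, truncated


@dataclass
class InjectionTruth:
    target_change: float | None
    realized_change: float | None
    truncated: bool
    mode: str


def inject_retest_effect(
    sim: ParticipantSim,
    effect: GroupEffect,
    cfg: CohortConfig,
    rng: np.random.Generator,
    combos: Sequence[Combination],
) -> tuple[SessionLog, InjectionTruth]:
    """Build the retest session with the group's effect applied.

    DIRECT mode constructs responses hitting the quantized target count
    exactly (lapses are not drawn: the count is the controlled quantity);
    MECHANISTIC perturbs the learned weights and simulates the retest.
    """
    if effect.mode == MODE_MECHANISTIC:
        w = [effect.decay * wi for wi in sim.weights]
        if effect.jitter > 0:
            w = [wi + rng.normal(0.0, effect.jitter) for wi in w]
        log = simulate_test_session(
            sim.participant_id, cfg.card_set_1, combos, w, sim.params,
            cfg.n_test, rng, PHASE_RETEST,
        )
        return log, InjectionTruth(None, None, False, effect.mode)

    target = float(rng.normal(effect.delta_mean, effect.delta_sd))
    idx = test_combo_arrays(len(combos), cfg.n_test, rng)
    optimal = np.array([c.optimal_outcome for c in combos], dtype=np.int8)[idx]
    scoreable = np.flatnonzero(optimal != TIE)
    n_scoreable = len(scoreable)
    new_correct, realized, truncated = quantize_direct_changes(
        np.array([target]), sim.test_score.n_correct, n_scoreable
    )
    n_correct = int(new_correct[0])
    responses = np.empty(cfg.n_test, dtype=np.int8)
    # TIE trials (if the configured card sets create any) get an arbitrary key
    responses[optimal == TIE] = SUN
    correct_pos = rng.permutation(scoreable)[:n_correct]
    wrong = np.ones(cfg.n_test, dtype=bool)
    wrong[correct_pos] = False
    responses[~wrong] = optimal[~wrong]
    wrong &= optimal != TIE
    responses[wrong] = (1 - optimal[wrong]).astype(np.int8)
    log = SessionLog(
        participant_id=sim.participant_id,
        phase=PHASE_RETEST,
        set_id=cfg.card_set_1.set_id,
        combo_idx=idx,
        displayed=np.full(cfg.n_test, NO_RESPONSE, dtype=np.int8),
        response=responses,
    )
    return log, InjectionTruth(target, float(realized[0]), bool(truncated[0]), effect.mode)


def calibrate_mechanistic_decay(
    target_delta: float,
    cfg: CohortConfig,
    n_probe: int = 200,
    seed: int = 0,
    decays: Sequence[float] | None = None,
) -> float:
    """Grid-search the weight-decay factor whose mean retest change is closest
    to ``target_delta`` (adjusted points), by forward simulation."""
    decays = np.linspace(0.4, 1.0, 25) if decays is None else np.asarray(decays, float)
    combos = enumerate_combinations(cfg.card_set_1)
    rng = as_rng(seed)
    sims = [simulate_participant(f"c{i}", cfg.learner, cfg, rng) for i in range(n_probe)]
    best, best_err = 1.0, math.inf
    for d in decays:
        changes = []
        for sim in sims:
            eff = GroupEffect("probe", mode=MODE_MECHANISTIC, decay=float(d))
            log, _ = inject_retest_effect(sim, eff, cfg, rng, combos)
            s = score_test(log, combos, cfg.alpha)
            changes.append(100.0 * (s.adjusted - sim.test_score.adjusted))
        err = abs(float(np.mean(changes)) - target_delta)
        if err < best_err:
            best, best_err = float(d), err
    return best


# -- cohort ----------------------------------------------------------------

@dataclass
class CohortResult:
    logs: list[SessionLog]
    truth: list[dict]
    decisions: list[rnd.AllocationDecision]
    config: CohortConfig
    seed: int

    def truth_frame(self):
        import pandas as pd

        return pd.DataFrame(self.truth)


def simulate_cohort(cfg: CohortConfig, seed: int = 0) -> CohortResult:
    """Simulate a full cohort: enrollment order, training/test, prospective
    group assignment on the baseline adjusted score, protocol phases, and
    retest with the assigned group's effect. Pure function of the seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(cfg.n_total + 2)
    alloc = rnd.Allocator(
        cfg.group_labels,
        cfg.size_slack,
        cfg.randomizer_objective,
        rng_seed=np.random.default_rng(children[-2]),
    )
    special_rng = np.random.default_rng(children[-1])
    perm = special_rng.permutation(cfg.n_total)
    a, b, c = cfg.n_noncompliant, cfg.n_nonlearner, cfg.n_reverser
    noncompliant = set(perm[:a].tolist())
    nonlearner = set(perm[a : a + b].tolist())
    reverser = set(perm[a + b : a + b + c].tolist())

    combos1 = enumerate_combinations(cfg.card_set_1)
    combos2 = enumerate_combinations(cfg.card_set_2)
    logs: list[SessionLog] = []
    truth: list[dict] = []
    for i in range(cfg.n_total):
        pid = f"P{i + 1:03d}"
        rng = np.random.default_rng(children[i])
        params = cfg.learner
        if i in noncompliant:
            params = replace(params, compliance=0.90)
        if i in nonlearner:
            params = replace(params, learning_rate=0.0)
        sim = simulate_participant(pid, params, cfg, rng)
        baseline = 100.0 * sim.test_score.adjusted
        decision = alloc.assign(baseline, pid)
        group = decision.chosen

        if cfg.include_protocol_phases and "+R" in group:
            order = rng.permutation(len(combos1)).astype(np.int16)
            n_cards = np.array([combos1[int(ci)].n_cards for ci in order], dtype=np.int8)
            logs_react = SessionLog(
                participant_id=pid,
                phase=PHASE_REACTIVATION,
                set_id=cfg.card_set_1.set_id,
                combo_idx=order,
                displayed=np.full(len(order), NO_RESPONSE, dtype=np.int8),
                response=n_cards.copy(),
                expected_response=n_cards,
            )
            sim.logs[PHASE_REACTIVATION] = logs_react
        if cfg.include_protocol_phases and "+I" in group:
            itrain, w2 = simulate_training_session(
                pid, cfg.card_set_2, combos2, params, cfg.n_training, cfg.n_blocks, rng,
                phase=PHASE_INTERFERENCE_TRAINING,
            )
            itest = simulate_test_session(
                pid, cfg.card_set_2, combos2, w2, params, cfg.n_test, rng,
                PHASE_INTERFERENCE_TEST,
            )
            sim.logs[PHASE_INTERFERENCE_TRAINING] = itrain
            sim.logs[PHASE_INTERFERENCE_TEST] = itest

        effect = cfg.group_effects[group]
        retest, inj = inject_retest_effect(sim, effect, cfg, rng, combos1)
        reversed_retest = False
        if i in reverser:
            reversed_retest = True
        elif params.reversal_prob > 0 and rng.random() < params.reversal_prob:
            reversed_retest = True
        if reversed_retest:
            _flip_in_place(retest.response)
            sim.reversed_sessions.append(PHASE_RETEST)
        sim.logs[PHASE_RETEST] = retest

        logs.extend(sim.logs.values())
        truth.append(
            {
                "participant_id": pid,
                "group": group,
                "baseline_adjusted": baseline,
                "target_change": inj.target_change,
                "realized_change": inj.realized_change,
                "truncated": inj.truncated,
                "effect_mode": inj.mode,
                "reversed_sessions": ",".join(sim.reversed_sessions),
                "noncompliant": i in noncompliant,
                "nonlearner": i in nonlearner,
                "reverser": i in reverser,
            }
        )
    return CohortResult(logs=logs, truth=truth, decisions=alloc.decisions, config=cfg, seed=seed)


def recovery_report(
    truth: Sequence[dict],
    scores: Sequence,
    exclusion_reports: Sequence,
    group_effects: dict[str, GroupEffect],
) -> dict:
    """Compare pipeline estimates against the injected ground truth.

    Reports per-group bias (estimated minus injected mean change, retained
    participants only), the RMSE across groups, and confusion counts for
    the repair rule (injected whole-session reversals vs repaired
    sessions) and the chance-exclusion rule (injected non-learners vs
    at-chance exclusions).
    """
    by_pid_truth = {t["participant_id"]: t for t in truth}
    excluded = {r.participant_id for r in exclusion_reports if r.excluded}
    per_group: dict[str, dict] = {}
    groups: dict[str, list[float]] = {}
    for s in scores:
        t = by_pid_truth[s.participant_id]
        if s.participant_id in excluded or s.retest is None:
            continue
        groups.setdefault(t["group"], []).append(
            100.0 * (s.retest.adjusted - s.test.adjusted)
        )
    sq = []
    for g, changes in sorted(groups.items()):
        est = float(np.mean(changes))
        injected = group_effects[g].delta_mean
        bias = est - injected
        per_group[g] = {
            "n_retained": len(changes),
            "estimated_mean_change": est,
            "injected_mean_change": injected,
            "bias": bias,
        }
        sq.append(bias**2)
    repaired = {
        s.participant_id for s in scores if s.repaired_sessions
    }
    injected_rev = {
        t["participant_id"] for t in truth if t["reversed_sessions"]
    }
    nonlearners = {t["participant_id"] for t in truth if t["nonlearner"]}
    at_chance = {
        r.participant_id
        for r in exclusion_reports
        if any(reason.startswith("AT_CHANCE") for reason in r.reasons)
    }
    all_pids = set(by_pid_truth)
    return {
        "per_group": per_group,
        "rmse_mean_change": float(np.sqrt(np.mean(sq))) if sq else math.nan,
        "repair": {
            "injected": len(injected_rev),
            "repaired": len(repaired),
            "true_positive": len(repaired & injected_rev),
            "false_positive": len(repaired - injected_rev),
            "missed": len(injected_rev - repaired),
        },
        "chance_exclusion": {
            "injected_nonlearners": len(nonlearners),
            "at_chance_excluded": len(at_chance),
            "true_positive": len(at_chance & nonlearners),
            "false_positive": len(at_chance - nonlearners),
            "missed": len(nonlearners - at_chance),
            "n_total": len(all_pids),
        },
    }
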