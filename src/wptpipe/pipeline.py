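"""End-to-end pipeline: simulate -> score (repair, exclusions) -> analyze.

The scoring stage groups trial logs by participant, computes training
compliance, runs the key-reversal repair pass over the initial test and
retest, applies the exclusion rules to the post-repair scores, and emits
a per-participant score table. The analysis stage groups retained
participants by assigned condition and builds the study report (per-group
change statistics plus omnibus ANOVA and LSD post hocs). Every run can
write a manifest (config hash, seeds, file list) sufficient to
regenerate its outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .cohort import CohortConfig, CohortResult, recovery_report, simulate_cohort
from .logs import DataError, SessionLog
from .scoring import (
    ExclusionReport,
    ParticipantScores,
    apply_exclusions,
    detect_and_repair_reversal,
    score_test,
    score_training_compliance,
)
from .stats import StudyReport, build_summary_table
from .task import (
    Combination,
    PHASE_INTERFERENCE_TEST,
    PHASE_RETEST,
    PHASE_TEST,
    PHASE_TRAINING,
    enumerate_combinations,
)


def combos_by_set(cfg: CohortConfig) -> dict[int, list[Combination]]:
    return {
        cfg.card_set_1.set_id: enumerate_combinations(cfg.card_set_1),
        cfg.card_set_2.set_id: enumerate_combinations(cfg.card_set_2),
    }


def score_cohort(
    logs: Sequence[SessionLog],
    combos: Mapping[int, Sequence[Combination]],
    alpha: float = 0.05,
) -> tuple[list[ParticipantScores], list[ExclusionReport]]:
    """Score every participant's sessions, repair reversals, apply exclusions."""
    by_pid: dict[str, dict[str, SessionLog]] = {}
    order: list[str] = []
    for log in logs:
        if log.participant_id not in by_pid:
            order.append(log.participant_id)
        by_pid.setdefault(log.participant_id, {})[log.phase] = log
    scores: list[ParticipantScores] = []
    for pid in order:
        sessions = by_pid[pid]
        if PHASE_TRAINING not in sessions:
            raise DataError(f"participant {pid}: no training log")
        if PHASE_TEST not in sessions:
            raise DataError(f"participant {pid}: no initial test log")
        compliance = score_training_compliance(sessions[PHASE_TRAINING])
        phases = [PHASE_TEST] + ([PHASE_RETEST] if PHASE_RETEST in sessions else [])
        test_logs = [sessions[ph] for ph in phases]
        set1 = combos[test_logs[0].set_id]
        _, repaired_scores = detect_and_repair_reversal(test_logs, set1, alpha)
        repaired_sessions = [
            ph for ph, sc in zip(phases, repaired_scores) if sc.repaired
        ]
        itest = None
        if PHASE_INTERFERENCE_TEST in sessions:
            ilog = sessions[PHASE_INTERFERENCE_TEST]
            itest = score_test(ilog, combos[ilog.set_id], alpha)
        scores.append(
            ParticipantScores(
                participant_id=pid,
                training_compliance=compliance,
                test=repaired_scores[0],
                retest=repaired_scores[1] if len(repaired_scores) > 1 else None,
                interference_test=itest,
                repaired_sessions=repaired_sessions,
            )
        )
    reports = apply_exclusions(scores)
    return scores, reports


def scores_to_frame(
    scores: Sequence[ParticipantScores],
    reports: Sequence[ExclusionReport],
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    rep_by_pid = {r.participant_id: r for r in reports}
    rows = []
    for s in scores:
        r = rep_by_pid[s.participant_id]
        row = {
            "participant_id": s.participant_id,
            "group": (groups or {}).get(s.participant_id, ""),
            "training_compliance": s.training_compliance,
            "test_raw": s.test.raw,
            "test_adjusted": s.test.adjusted,
            "test_at_chance": s.test.at_chance,
            "test_repaired": s.test.repaired,
            "retest_raw": s.retest.raw if s.retest else float("nan"),
            "retest_adjusted": s.retest.adjusted if s.retest else float("nan"),
            "retest_at_chance": s.retest.at_chance if s.retest else False,
            "retest_repaired": s.retest.repaired if s.retest else False,
            "excluded": r.excluded,
            "exclusion_reasons": ";".join(r.reasons),
        }
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_scores(scores_df: pd.DataFrame, alpha: float = 0.05) -> StudyReport:
    """Build the study report from a score table with group assignments.

    Uses retained (non-excluded) participants with both tests, converting
    adjusted fractions to the report's percentage-point scale.
    """
    if "group" not in scores_df.columns:
        raise DataError("score table lacks a 'group' column")
    df = scores_df[~scores_df["excluded"].astype(bool)].dropna(subset=["retest_adjusted"])
    group_scores = {}
    for label, grp in df.groupby("group", sort=False):
        if label == "":
            continue
        group_scores[str(label)] = (
            100.0 * grp["test_adjusted"].to_numpy(dtype=float),
            100.0 * grp["retest_adjusted"].to_numpy(dtype=float),
        )
    return build_summary_table(group_scores, alpha)


@dataclass
class StudyResult:
    cohort: CohortResult
    scores: list[ParticipantScores]
    exclusions: list[ExclusionReport]
    scores_df: pd.DataFrame
    report: StudyReport
    recovery: dict


def run_study(cfg: CohortConfig, seed: int = 0) -> StudyResult:
    """Full in-memory study replication: simulate, score, analyze, recover."""
    cohort = simulate_cohort(cfg, seed)
    combos = combos_by_set(cfg)
    scores, reports = score_cohort(cohort.logs, combos, cfg.alpha)
    groups = {t["participant_id"]: t["group"] for t in cohort.truth}
    scores_df = scores_to_frame(scores, reports, groups)
    report = analyze_scores(scores_df, cfg.alpha)
    recovery = recovery_report(cohort.truth, scores, reports, cfg.group_effects)
    return StudyResult(cohort, scores, reports, scores_df, report, recovery)


def config_hash(cfg_dict: Mapping) -> str:
    blob = json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_manifest(path, cfg_dict: Mapping, seed: int, files: Sequence[str]) -> dict:
    manifest = {
        "package": "wptpipe",
        "version": __version__,
        "config_hash": config_hash(cfg_dict),
        "config": dict(cfg_dict),
        "seed": seed,
        "files": list(files),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
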