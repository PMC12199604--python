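"""Prospective balanced randomization (minimization on a single baseline score).

Each newly scored participant is assigned, at enrollment time, to the
experimental group that minimizes the spread of group baseline means
while keeping group sizes balanced: only the currently smallest groups
are eligible (with ``size_slack=0`` sizes never differ by more than one),
and among those the chosen group minimizes, after a hypothetical
placement, the sum of squared deviations of the nonempty group means from
their grand mean (equivalently the variance of group means). Ties are
broken uniformly with a seeded RNG, preserving randomization validity.

The allocator keeps running sums so each assignment is O(k); state can be
checkpointed to JSON for crash-safe resumption, and a line-oriented JSON
request/response protocol lets external experiment software stream
enrollments (one ``{"participant_id": ..., "score": ...}`` object per
line, answered with ``{"participant_id": ..., "group": ...}``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence

import numpy as np

from .task import as_rng

DEFAULT_GROUPS = ("-R-I", "-R+I", "+R-I", "+R+I")

OBJECTIVE_VARIANCE = "variance"
OBJECTIVE_MAX_GAP = "max_gap"


@dataclass
class AllocationDecision:
    participant_id: str
    baseline_score: float
    eligible_groups: list[str]
    objective_per_group: dict[str, float]
    chosen: str
    tie_broken: bool


def _spread(means: Sequence[float], objective: str) -> float:
    if len(means) <= 1:
        return 0.0
    if objective == OBJECTIVE_MAX_GAP:
        return max(means) - min(means)
    grand = sum(means) / len(means)
    return sum((m - grand) ** 2 for m in means)


class Allocator:
    """Streaming minimization allocator over k groups."""

    def __init__(
        self,
        group_labels: Sequence[str] = DEFAULT_GROUPS,
        size_slack: int = 0,
        objective: str = OBJECTIVE_VARIANCE,
        rng_seed: int | np.random.Generator | None = None,
    ) -> None:
        if len(group_labels) < 2:
            raise ValueError("need at least 2 groups")
        if len(set(group_labels)) != len(group_labels):
            raise ValueError("duplicate group labels")
        if size_slack < 0:
            raise ValueError("size_slack must be >= 0")
        if objective not in (OBJECTIVE_VARIANCE, OBJECTIVE_MAX_GAP):
            raise ValueError(f"unknown objective {objective!r}")
        self.group_labels = tuple(group_labels)
        self.size_slack = int(size_slack)
        self.objective = objective
        self.members: dict[str, list[float]] = {g: [] for g in self.group_labels}
        self._rng = as_rng(rng_seed)
        self._sums = {g: 0.0 for g in self.group_labels}
        self._counts = {g: 0 for g in self.group_labels}
        self.decisions: list[AllocationDecision] = []

    # -- state ------------------------------------------------------------

    def group_sizes(self) -> dict[str, int]:
        return dict(self._counts)

    def group_means(self) -> dict[str, float]:
        return {
            g: (self._sums[g] / c if (c := self._counts[g]) else math.nan)
            for g in self.group_labels
        }

    def to_state(self) -> dict:
        return {
            "group_labels": list(self.group_labels),
            "size_slack": self.size_slack,
            "objective": self.objective,
            "members": {g: list(v) for g, v in self.members.items()},
            "rng_state": self._rng.bit_generator.state,
        }

    @classmethod
    def from_state(cls, state: Mapping) -> "Allocator":
        alloc = cls(
            group_labels=state["group_labels"],
            size_slack=state["size_slack"],
            objective=state["objective"],
        )
        for g, vals in state["members"].items():
            alloc.members[g] = [float(v) for v in vals]
            alloc._sums[g] = float(sum(vals))
            alloc._counts[g] = len(vals)
        alloc._rng.bit_generator.state = state["rng_state"]
        return alloc

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_state(), fh)

    @classmethod
    def load(cls, path) -> "Allocator":
        with open(path) as fh:
            return cls.from_state(json.load(fh))

    # -- assignment -------------------------------------------------------

    def assign(self, baseline_score: float, participant_id: str = "") -> AllocationDecision:
        """Place one participant; returns the full decision record."""
        score = float(baseline_score)
        min_size = min(self._counts.values())
        eligible = [
            g for g in self.group_labels if self._counts[g] <= min_size + self.size_slack
        ]
        objectives: dict[str, float] = {}
        for g in eligible:
            means = []
            for h in self.group_labels:
                c = self._counts[h] + (1 if h == g else 0)
                if c:
                    s = self._sums[h] + (score if h == g else 0.0)
                    means.append(s / c)
            objectives[g] = _spread(means, self.objective)
        best = min(objectives.values())
        tol = 1e-12 * (1.0 + abs(best))
        winners = [g for g in eligible if objectives[g] <= best + tol]
        tie_broken = len(winners) > 1
        chosen = winners[int(self._rng.integers(len(winners)))] if tie_broken else winners[0]
        self.members[chosen].append(score)
        self._sums[chosen] += score
        self._counts[chosen] += 1
        decision = AllocationDecision(
            participant_id=participant_id,
            baseline_score=score,
            eligible_groups=eligible,
            objective_per_group=objectives,
            chosen=chosen,
            tie_broken=tie_broken,
        )
        self.decisions.append(decision)
        return decision


def uniform_assign(
    counts: dict[str, int], labels: Sequence[str], size_slack: int, rng: np.random.Generator
) -> str:
    """Uniform randomization under the same size constraint (comparison arm)."""
    min_size = min(counts.values())
    eligible = [g for g in labels if counts[g] <= min_size + size_slack]
    return eligible[int(rng.integers(len(eligible)))]


@dataclass
class BalanceReport:
    """Max pairwise group-mean gap per replicate, prospective vs uniform."""

    n_participants: int
    reps: int
    prospective_gaps: np.ndarray
    uniform_gaps: np.ndarray
    mean_gap_prospective: float = field(init=False)
    mean_gap_uniform: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_gap_prospective = float(np.mean(self.prospective_gaps))
        self.mean_gap_uniform = float(np.mean(self.uniform_gaps))


def _max_gap(members: Mapping[str, Sequence[float]]) -> float:
    means = [float(np.mean(v)) for v in members.values() if len(v)]
    return (max(means) - min(means)) if len(means) > 1 else 0.0


def simulate_balance(
    n_participants: int = 68,
    reps: int = 1000,
    rng_seed: int | np.random.Generator | None = None,
    score_mean: float = 0.81,
    score_sd: float = 0.10,
    group_labels: Sequence[str] = DEFAULT_GROUPS,
    size_slack: int = 0,
    objective: str = OBJECTIVE_VARIANCE,
) -> BalanceReport:
    """Compare prospective allocation against uniform randomization.

    For each replicate the same stream of baseline scores is allocated
    (a) by the minimization algorithm and (b) uniformly among the
    smallest groups, and the maximum pairwise difference of group
    baseline means is recorded for each.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = as_rng(rng_seed)
    pro = np.empty(reps)
    uni = np.empty(reps)
    for r in range(reps):
        scores = rng.normal(score_mean, score_sd, n_participants)
        alloc = Allocator(group_labels, size_slack, objective, rng_seed=rng)
        u_members: dict[str, list[float]] = {g: [] for g in group_labels}
        u_counts = {g: 0 for g in group_labels}
        for s in scores:
            alloc.assign(s)
            g = uniform_assign(u_counts, group_labels, size_slack, rng)
            u_members[g].append(float(s))
            u_counts[g] += 1
        pro[r] = _max_gap(alloc.members)
        uni[r] = _max_gap(u_members)
    return BalanceReport(n_participants, reps, pro, uni)


# -- line protocol ---------------------------------------------------------

def handle_request(allocator: Allocator, request: Mapping) -> dict:
    """One enrollment request: {"participant_id", "score"} -> {"group"}."""
    try:
        pid = str(request["participant_id"])
        score = float(request["score"])
    except (KeyError, TypeError, ValueError) as exc:
        return {"error": f"bad request: {exc}"}
    decision = allocator.assign(score, pid)
    return {"participant_id": pid, "group": decision.chosen}


def handle_line(allocator: Allocator, line: str) -> str:
    try:
        request = json.loads(line)
    except json.JSONDecodeError as exc:
        return json.dumps({"error": f"bad JSON: {exc}"})
    if not isinstance(request, dict):
        return json.dumps({"error": "request must be a JSON object"})
    return json.dumps(handle_request(allocator, request))


def serve(
    allocator: Allocator,
    instream: IO[str],
    outstream: IO[str],
    checkpoint_path=None,
) -> None:
    """Answer one JSON request per input line; checkpoint after each if asked."""
    for line in instream:
        line = line.strip()
        if not line:
            continue
        outstream.write(handle_line(allocator, line) + "\n")
        outstream.flush()
        if checkpoint_path is not None:
            allocator.save(checkpoint_path)
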