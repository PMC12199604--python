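"""Session logs: the trial-level record one participant produces per phase.

Internally a log is a compact set of numpy arrays (combination index,
displayed outcome, response); the CSV schema used for interchange is one
row per trial with columns::

    participant_id, phase, card_set, trial_index, block, cards,
    displayed_outcome, response, expected_response

``trial_index`` and ``block`` are 1-based in the CSV (0-based in memory);
``cards`` is the combination key, e.g. ``"1+3"``; outcomes and responses
are ``SUN`` / ``RAIN`` labels (reactivation responses are the number keys
``1``-``3``); a missing response is an empty field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .task import (
    Combination,
    LABEL_OUTCOMES,
    NO_RESPONSE,
    OUTCOME_LABELS,
    PHASES,
    PHASE_REACTIVATION,
    TRAINING_PHASES,
)

LOG_COLUMNS = [
    "participant_id",
    "phase",
    "card_set",
    "trial_index",
    "block",
    "cards",
    "displayed_outcome",
    "response",
    "expected_response",
]


class DataError(ValueError):
    """Malformed or inconsistent trial-log data."""


@dataclass
class SessionLog:
    """One participant's trials for a single phase.

    ``combo_idx`` indexes the canonical combination list of the session's
    card set. ``displayed`` is -1 outside training phases; ``response``
    is -1 for unanswered trials (and holds the pressed number key, 1-3,
    for reactivation sessions).
    """

    participant_id: str
    phase: str
    set_id: int
    combo_idx: np.ndarray
    displayed: np.ndarray
    response: np.ndarray
    block: np.ndarray | None = None
    expected_response: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise DataError(f"unknown phase {self.phase!r}")
        n = len(self.combo_idx)
        for name in ("displayed", "response"):
            if len(getattr(self, name)) != n:
                raise DataError(f"{name} length mismatch in {self.participant_id}/{self.phase}")

    def __len__(self) -> int:
        return len(self.combo_idx)

    def copy(self) -> "SessionLog":
        return replace(
            self,
            combo_idx=self.combo_idx.copy(),
            displayed=self.displayed.copy(),
            response=self.response.copy(),
            block=None if self.block is None else self.block.copy(),
            expected_response=(
                None if self.expected_response is None else self.expected_response.copy()
            ),
        )


def logs_to_frame(
    logs: Sequence[SessionLog], combos_by_set: Mapping[int, Sequence[Combination]]
) -> pd.DataFrame:
    """Flatten session logs into the interchange CSV schema (one row per trial)."""
    rows = {c: [] for c in LOG_COLUMNS}
    for log in logs:
        combos = combos_by_set[log.set_id]
        keys = [combos[int(i)].key for i in log.combo_idx]
        n = len(log)
        rows["participant_id"].extend([log.participant_id] * n)
        rows["phase"].extend([log.phase] * n)
        rows["card_set"].extend([log.set_id] * n)
        rows["trial_index"].extend(range(1, n + 1))
        if log.block is None:
            rows["block"].extend([""] * n)
        else:
            rows["block"].extend(int(b) + 1 for b in log.block)
        rows["cards"].extend(keys)
        rows["displayed_outcome"].extend(OUTCOME_LABELS[int(d)] for d in log.displayed)
        if log.phase == PHASE_REACTIVATION:
            rows["response"].extend("" if r < 0 else str(int(r)) for r in log.response)
        else:
            rows["response"].extend(OUTCOME_LABELS[int(r)] for r in log.response)
        if log.expected_response is None:
            rows["expected_response"].extend([""] * n)
        else:
            rows["expected_response"].extend(int(e) for e in log.expected_response)
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def _parse_response(phase: str, value: str, line: int) -> int:
    if value == "":
        return NO_RESPONSE
    if phase == PHASE_REACTIVATION:
        try:
            return int(value)
        except ValueError:
            raise DataError(f"line {line}: bad reactivation response {value!r}") from None
    try:
        return LABEL_OUTCOMES[value]
    except KeyError:
        raise DataError(f"line {line}: bad response {value!r}") from None


def frame_to_logs(
    df: pd.DataFrame, combos_by_set: Mapping[int, Sequence[Combination]]
) -> list[SessionLog]:
    """Parse an interchange frame back into session logs.

    Errors carry the offending CSV line number (header = line 1).
    """
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"missing columns: {missing}")
    if df.empty:
        raise DataError("empty trial log")
    df = df.fillna("")
    key_maps = {
        sid: {c.key: i for i, c in enumerate(combos)} for sid, combos in combos_by_set.items()
    }
    logs: list[SessionLog] = []
    for (pid, phase, set_id), grp in df.groupby(
        ["participant_id", "phase", "card_set"], sort=False
    ):
        set_id = int(set_id)
        if phase not in PHASES:
            raise DataError(f"line {int(grp.index[0]) + 2}: unknown phase {phase!r}")
        if set_id not in key_maps:
            raise DataError(f"line {int(grp.index[0]) + 2}: unknown card_set {set_id}")
        key_map = key_maps[set_id]
        grp = grp.sort_values("trial_index")
        combo_idx = np.empty(len(grp), dtype=np.int16)
        displayed = np.empty(len(grp), dtype=np.int8)
        response = np.empty(len(grp), dtype=np.int8)
        blocks = np.full(len(grp), -1, dtype=np.int16)
        expected = np.full(len(grp), -1, dtype=np.int8)
        has_block = False
        has_expected = False
        for j, (ridx, row) in enumerate(grp.iterrows()):
            line = int(ridx) + 2
            cards = str(row["cards"])
            if cards not in key_map:
                raise DataError(f"line {line}: unknown combination {cards!r} for set {set_id}")
            combo_idx[j] = key_map[cards]
            disp = str(row["displayed_outcome"])
            if disp not in LABEL_OUTCOMES:
                raise DataError(f"line {line}: bad displayed_outcome {disp!r}")
            displayed[j] = LABEL_OUTCOMES[disp]
            if (phase in TRAINING_PHASES) != (displayed[j] != NO_RESPONSE):
                raise DataError(
                    f"line {line}: displayed outcome must be present exactly in training phases"
                )
            response[j] = _parse_response(str(phase), str(row["response"]), line)
            b = str(row["block"])
            if b != "":
                try:
                    blocks[j] = int(float(b)) - 1
                except ValueError:
                    raise DataError(f"line {line}: bad block {b!r}") from None
                has_block = True
            e = str(row["expected_response"])
            if e != "":
                expected[j] = int(float(e))
                has_expected = True
        logs.append(
            SessionLog(
                participant_id=str(pid),
                phase=str(phase),
                set_id=set_id,
                combo_idx=combo_idx,
                displayed=displayed,
                response=response,
                block=blocks if has_block else None,
                expected_response=expected if has_expected else None,
            )
        )
    return logs


def read_logs_csv(path, combos_by_set) -> list[SessionLog]:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty file") from None
    df["card_set"] = df["card_set"].astype(int) if "card_set" in df.columns else 1
    df["trial_index"] = df["trial_index"].astype(int)
    return frame_to_logs(df, combos_by_set)


def write_logs_csv(path, logs, combos_by_set) -> None:
    logs_to_frame(logs, combos_by_set).to_csv(path, index=False)
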