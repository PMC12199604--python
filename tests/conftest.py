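import numpy as np
import pytest

from wptpipe.logs import SessionLog
from wptpipe.task import (
    NO_RESPONSE,
    PHASE_TEST,
    PHASE_TRAINING,
    TIE,
    default_card_set,
    enumerate_combinations,
)


@pytest.fixture(scope="session")
def card_set():
    return default_card_set(1)


@pytest.fixture(scope="session")
def combos(card_set):
    return enumerate_combinations(card_set)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def make_test_log(combos, n_trials, n_correct, n_unanswered=0, pid="P1", phase=PHASE_TEST):
    """Test log with an exact correct count: first trials optimal, then wrong,
    then unanswered (cycling through the combination list)."""
    idx = (np.arange(n_trials) % len(combos)).astype(np.int16)
    optimal = np.array([c.optimal_outcome for c in combos], dtype=np.int8)[idx]
    assert not np.any(optimal == TIE), "helper assumes a tie-free card set"
    resp = (1 - optimal).astype(np.int8)
    resp[:n_correct] = optimal[:n_correct]
    if n_unanswered:
        resp[n_trials - n_unanswered:] = NO_RESPONSE
    return SessionLog(
        participant_id=pid,
        phase=phase,
        set_id=1,
        combo_idx=idx,
        displayed=np.full(n_trials, NO_RESPONSE, dtype=np.int8),
        response=resp,
    )


def make_training_log(combos, n_trials, n_matches, n_unanswered=0, pid="P1"):
    """Training log where the first n_matches responses echo the displayed outcome."""
    idx = (np.arange(n_trials) % len(combos)).astype(np.int16)
    displayed = (np.arange(n_trials) % 2).astype(np.int8)
    resp = displayed.copy()
    resp[n_matches:] = (1 - displayed[n_matches:]).astype(np.int8)
    if n_unanswered:
        resp[n_matches : n_matches + n_unanswered] = NO_RESPONSE
    return SessionLog(
        participant_id=pid,
        phase=PHASE_TRAINING,
        set_id=1,
        combo_idx=idx,
        displayed=displayed,
        response=resp,
        block=(np.arange(n_trials) // max(1, n_trials // 4)).astype(np.int16),
    )
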