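"""Weather Prediction Task (WPT) engine.

The WPT is a probabilistic category-learning task: on each trial 1-3 of a
set of 4 cue cards are shown and the participant predicts "sun" or "rain".
Each card carries a fixed probability of predicting sun; the probability
attached to a multi-card combination is derived from the individual cards
by the independent-cue odds product (naive Bayes with a uniform prior over
the two outcomes), the standard construction for this paradigm:

    odds(sun) = prod_i p_i / (1 - p_i),   P(sun) = odds / (1 + odds)

Training trials display a probabilistically sampled outcome; test trials
display none and are scored against the higher-probability ("optimal")
outcome. A combination whose combined probability is exactly 0.5 has no
optimal outcome and carries the first-class value TIE.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

# Outcome / response codes. NO_RESPONSE marks an unanswered trial.
RAIN = 0
SUN = 1
TIE = 2
NO_RESPONSE = -1

OUTCOME_LABELS = {RAIN: "RAIN", SUN: "SUN", TIE: "TIE", NO_RESPONSE: ""}
LABEL_OUTCOMES = {"RAIN": RAIN, "SUN": SUN, "TIE": TIE, "": NO_RESPONSE}

PHASE_TRAINING = "TRAINING"
PHASE_TEST = "TEST"
PHASE_REACTIVATION = "REACTIVATION"
PHASE_INTERFERENCE_TRAINING = "INTERFERENCE_TRAINING"
PHASE_INTERFERENCE_TEST = "INTERFERENCE_TEST"
PHASE_RETEST = "RETEST"

PHASES = (
    PHASE_TRAINING,
    PHASE_TEST,
    PHASE_REACTIVATION,
    PHASE_INTERFERENCE_TRAINING,
    PHASE_INTERFERENCE_TEST,
    PHASE_RETEST,
)
TRAINING_PHASES = frozenset({PHASE_TRAINING, PHASE_INTERFERENCE_TRAINING})
TEST_PHASES = frozenset({PHASE_TEST, PHASE_RETEST, PHASE_INTERFERENCE_TEST})


class ConfigurationError(ValueError):
    """Invalid task configuration (card counts, trial counts, ...)."""


class ContradictoryEvidenceError(ValueError):
    """A combination mixes a certain-sun (p=1) and a certain-rain (p=0) card."""


def as_rng(seed: int | np.random.Generator | np.random.SeedSequence | None) -> np.random.Generator:
    """Coerce a seed (or pass an existing Generator through) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class CueCard:
    """One cue card: an identifier within its set and its P(sun)."""

    card_id: int
    p_sun: float
    label: str = ""
    set_id: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_sun <= 1.0:
            raise ConfigurationError(f"card {self.card_id}: p_sun={self.p_sun} outside [0, 1]")


@dataclass(frozen=True)
class CardSet:
    """A stimulus set. The standard task uses exactly 4 cards per set."""

    cards: tuple[CueCard, ...]
    set_id: int = 1

    def __post_init__(self) -> None:
        ids = [c.card_id for c in self.cards]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"duplicate card_ids in set {self.set_id}: {ids}")
        if not self.cards:
            raise ConfigurationError("empty card set")

    @property
    def n_cards(self) -> int:
        return len(self.cards)

    def p_suns(self) -> tuple[float, ...]:
        return tuple(c.p_sun for c in self.cards)


# Per-card P(sun) values for the two default stimulus sets. Chosen so that
# no 1-3 card combination is a TIE under the odds-product rule while keeping
# the classic strong/weak cue structure; overridable in any study config.
DEFAULT_P_SUN = {1: (0.80, 0.60, 0.45, 0.25), 2: (0.75, 0.55, 0.40, 0.20)}
CATEGORY_LABELS = ("animal", "vehicle", "light", "device")


def default_card_set(set_id: int = 1) -> CardSet:
    """The package's default 4-card stimulus set (set 1 or set 2)."""
    try:
        probs = DEFAULT_P_SUN[set_id]
    except KeyError:
        raise ConfigurationError(f"no default card set with set_id={set_id}") from None
    cards = tuple(
        CueCard(card_id=i + 1, p_sun=p, label=CATEGORY_LABELS[i], set_id=set_id)
        for i, p in enumerate(probs)
    )
    return CardSet(cards=cards, set_id=set_id)


def card_set_from_probs(p_suns: Sequence[float], set_id: int = 1) -> CardSet:
    cards = tuple(
        CueCard(card_id=i + 1, p_sun=float(p), label=f"card{i + 1}", set_id=set_id)
        for i, p in enumerate(p_suns)
    )
    return CardSet(cards=cards, set_id=set_id)


def complement_card_set(card_set: CardSet) -> CardSet:
    """Replace every card's p_sun with 1 - p_sun (swaps the sun/rain roles)."""
    return CardSet(
        cards=tuple(replace(c, p_sun=1.0 - c.p_sun) for c in card_set.cards),
        set_id=card_set.set_id,
    )


def combine_probability(p_suns: Sequence[float]) -> float:
    """Combined P(sun) for 1-3 independently informative cue cards.

    Single card: its own p_sun. Multiple cards: odds product,
    ``odds = prod p_i/(1-p_i)``, result ``odds/(1+odds)``. A card with
    p_sun exactly 0 (or 1) forces the result to 0 (or 1); a combination
    containing both is contradictory evidence and raises.
    """
    ps = [float(p) for p in p_suns]
    if not 1 <= len(ps) <= 3:
        raise ConfigurationError(f"a combination shows 1-3 cards, got {len(ps)}")
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"p_sun={p} outside [0, 1]")
    has_zero = any(p == 0.0 for p in ps)
    has_one = any(p == 1.0 for p in ps)
    if has_zero and has_one:
        raise ContradictoryEvidenceError(
            "combination mixes a certain-sun (p=1) and a certain-rain (p=0) card"
        )
    if has_one:
        return 1.0
    if has_zero:
        return 0.0
    odds = 1.0
    for p in ps:
        odds *= p / (1.0 - p)
    return odds / (1.0 + odds)


def optimal_outcome_for(p_sun_combined: float) -> int:
    """SUN if p > 0.5, RAIN if p < 0.5, TIE exactly at 0.5 (never coerced)."""
    if p_sun_combined > 0.5:
        return SUN
    if p_sun_combined < 0.5:
        return RAIN
    return TIE


@dataclass(frozen=True)
class Combination:
    """A 1-3 card subset with its derived probability and optimal outcome."""

    card_ids: tuple[int, ...]
    p_sun_combined: float
    optimal_outcome: int

    @property
    def n_cards(self) -> int:
        return len(self.card_ids)

    @property
    def key(self) -> str:
        """Human-readable id, e.g. ``"1+3"``."""
        return "+".join(str(i) for i in self.card_ids)


def make_combination(cards: Iterable[CueCard]) -> Combination:
    cards = sorted(cards, key=lambda c: c.card_id)
    ids = tuple(c.card_id for c in cards)
    p = combine_probability([c.p_sun for c in cards])
    return Combination(card_ids=ids, p_sun_combined=p, optimal_outcome=optimal_outcome_for(p))


def enumerate_combinations(card_set: CardSet, strict: bool = True) -> list[Combination]:
    """All 1-3 card subsets in canonical order (by size, then card ids).

    The standard 4-card set yields 14 combinations. With ``strict=False``
    the enumeration generalizes to hypothetical sets of other sizes.
    """
    if strict and card_set.n_cards != 4:
        raise ConfigurationError(
            f"standard task requires exactly 4 cards per set, got {card_set.n_cards}"
        )
    cards = sorted(card_set.cards, key=lambda c: c.card_id)
    out: list[Combination] = []
    for size in (1, 2, 3):
        if size > len(cards):
            break
        for subset in itertools.combinations(cards, size):
            out.append(make_combination(subset))
    return out


@dataclass(frozen=True)
class TrialSpec:
    """One trial: phase, position, stimulus, and (training only) the outcome."""

    phase: str
    index: int
    combination: Combination
    block: int | None = None
    displayed_outcome: int | None = None
    expected_response: int | None = None  # reactivation: number of cards shown


def sample_outcome(combination: Combination, rng: np.random.Generator) -> int:
    """Sample SUN with probability p_sun_combined, else RAIN."""
    return SUN if rng.random() < combination.p_sun_combined else RAIN


# ---------------------------------------------------------------------------
# Array-level sequence generation (fast path used by the cohort simulator).
# Public generate_* wrappers return TrialSpec lists.
# ---------------------------------------------------------------------------

def training_combo_arrays(
    n_combos: int, n_trials: int, n_blocks: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Blockwise near-balanced combination order for a training session.

    Each block holds ``floor(per_block / n_combos)`` copies of every
    combination; leftover slots rotate through a seeded permutation of the
    combinations across blocks, so session totals also differ by at most
    one (for 200 trials / 4 blocks / 14 combinations: per-block counts in
    {3, 4} and totals in {14, 15}).
    """
    if n_trials % n_blocks:
        raise ConfigurationError(f"n_trials={n_trials} not divisible by n_blocks={n_blocks}")
    per_block = n_trials // n_blocks
    base = per_block // n_combos
    if base < 1:
        raise ConfigurationError(
            f"block size {per_block} cannot cover all {n_combos} combinations"
        )
    extras = per_block - base * n_combos
    perm = rng.permutation(n_combos)
    idx_parts = []
    block_parts = []
    for b in range(n_blocks):
        block_idx = np.repeat(np.arange(n_combos, dtype=np.int16), base)
        if extras:
            extra_idx = perm[(np.arange(extras) + b * extras) % n_combos].astype(np.int16)
            block_idx = np.concatenate([block_idx, extra_idx])
        rng.shuffle(block_idx)
        idx_parts.append(block_idx)
        block_parts.append(np.full(per_block, b, dtype=np.int16))
    return np.concatenate(idx_parts), np.concatenate(block_parts)


def test_combo_arrays(n_combos: int, n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """Near-uniform combination order for a test session.

    Each combination appears ``floor(n_trials / n_combos)`` times; the
    remaining slots are drawn without replacement from distinct
    combinations, and the whole order is shuffled.
    """
    if n_trials < n_combos:
        raise ConfigurationError(
            f"test needs at least one trial per combination ({n_combos}), got {n_trials}"
        )
    base = n_trials // n_combos
    rem = n_trials - base * n_combos
    idx = np.repeat(np.arange(n_combos, dtype=np.int16), base)
    if rem:
        idx = np.concatenate([idx, rng.choice(n_combos, size=rem, replace=False).astype(np.int16)])
    rng.shuffle(idx)
    return idx


def sample_outcomes(p_sun: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return (rng.random(len(p_sun)) < p_sun).astype(np.int8)


def generate_training_sequence(
    card_set: CardSet,
    n_trials: int = 200,
    n_blocks: int = 4,
    rng_seed: int | np.random.Generator | None = None,
    phase: str = PHASE_TRAINING,
) -> list[TrialSpec]:
    """Training sequence with blockwise-balanced combinations and sampled outcomes."""
    if phase not in TRAINING_PHASES:
        raise ConfigurationError(f"{phase!r} is not a training phase")
    rng = as_rng(rng_seed)
    combos = enumerate_combinations(card_set)
    idx, blocks = training_combo_arrays(len(combos), n_trials, n_blocks, rng)
    p = np.array([c.p_sun_combined for c in combos])[idx]
    outcomes = sample_outcomes(p, rng)
    return [
        TrialSpec(
            phase=phase,
            index=i,
            combination=combos[int(ci)],
            block=int(b),
            displayed_outcome=int(o),
        )
        for i, (ci, b, o) in enumerate(zip(idx, blocks, outcomes))
    ]


def generate_test_sequence(
    card_set: CardSet,
    n_trials: int = 100,
    rng_seed: int | np.random.Generator | None = None,
    phase: str = PHASE_TEST,
) -> list[TrialSpec]:
    """Test sequence: near-uniform combination coverage, no displayed outcome."""
    if phase not in TEST_PHASES:
        raise ConfigurationError(f"{phase!r} is not a test phase")
    rng = as_rng(rng_seed)
    combos = enumerate_combinations(card_set)
    idx = test_combo_arrays(len(combos), n_trials, rng)
    return [
        TrialSpec(phase=phase, index=i, combination=combos[int(ci)])
        for i, ci in enumerate(idx)
    ]


def generate_reactivation_sequence(
    card_set: CardSet, rng_seed: int | np.random.Generator | None = None
) -> list[TrialSpec]:
    """Reactivation: every combination once, shuffled, no outcome.

    The expected response is the number of cards shown (a card-counting
    cover task that re-exposes the learned stimuli).
    """
    rng = as_rng(rng_seed)
    combos = enumerate_combinations(card_set)
    order = rng.permutation(len(combos))
    return [
        TrialSpec(
            phase=PHASE_REACTIVATION,
            index=i,
            combination=combos[int(ci)],
            expected_response=combos[int(ci)].n_cards,
        )
        for i, ci in enumerate(order)
    ]
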