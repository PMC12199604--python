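"""Scoring, chance band, reversal repair, exclusions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_test_log, make_training_log
from wptpipe.logs import DataError
from wptpipe.scoring import (
    ExclusionReport,
    ParticipantScores,
    REASON_AT_CHANCE_TEST,
    REASON_LOW_TRAINING_COMPLIANCE,
    adjust,
    apply_exclusions,
    chance_range,
    detect_and_repair_reversal,
    flip_responses,
    score_test,
    score_training_compliance,
    two_sided_binom_p,
)
from wptpipe.task import (
    NO_RESPONSE,
    RAIN,
    SUN,
    complement_card_set,
    default_card_set,
    enumerate_combinations,
)


def exact_binom_two_sided(x, n):
    """Oracle: exact tail sums with integer arithmetic."""
    lower = sum(math.comb(n, k) for k in range(0, x + 1))
    upper = sum(math.comb(n, k) for k in range(x, n + 1))
    return min(1.0, 2 * min(lower, upper) / 2**n)


class TestAdjust:
    @pytest.mark.parametrize("raw,expected", [(0.5, 0.0), (1.0, 1.0), (0.795, 0.59), (0.0, -1.0)])
    def test_examples(self, raw, expected):
        assert adjust(raw) == pytest.approx(expected)

    @given(a=st.floats(0, 1), b=st.floats(0, 1))
    @settings(max_examples=50, derandomize=True)
    def test_affine_monotone(self, a, b):
        if a <= b:
            assert adjust(a) <= adjust(b)
        assert adjust((a + b) / 2) == pytest.approx((adjust(a) + adjust(b)) / 2, abs=1e-12)


class TestTrainingCompliance:
    def test_perfect_and_low(self, combos):
        assert score_training_compliance(make_training_log(combos, 200, 200)) == 1.0
        assert score_training_compliance(make_training_log(combos, 200, 190)) == pytest.approx(0.95)

    def test_boundary_inclusive_with_nonresponses(self, combos):
        # 8 non-responses, remainder matching: 192/200 = 0.96 is NOT below 96%
        log = make_training_log(combos, 200, 192, n_unanswered=8)
        c = score_training_compliance(log)
        assert c == pytest.approx(0.96)
        assert not c < 0.96

    def test_empty_log_rejected(self):
        from wptpipe.logs import SessionLog

        empty = SessionLog(
            participant_id="P1",
            phase="TRAINING",
            set_id=1,
            combo_idx=np.empty(0, np.int16),
            displayed=np.empty(0, np.int8),
            response=np.empty(0, np.int8),
        )
        with pytest.raises(DataError):
            score_training_compliance(empty)


class TestScoreTest:
    def test_raw_and_adjusted(self, combos):
        s = score_test(make_test_log(combos, 100, 60), combos)
        assert (s.n_trials, s.n_correct) == (100, 60)
        assert s.raw == pytest.approx(0.60)
        assert s.adjusted == pytest.approx(0.20)

    def test_nonresponses_count_incorrect(self, combos):
        # 60 optimal among the 90 answered; 10 unanswered -> raw still 0.60
        s = score_test(make_test_log(combos, 100, 60, n_unanswered=10), combos)
        assert s.n_answered == 90
        assert s.raw == pytest.approx(0.60)

    def test_unknown_combination_rejected(self, combos):
        log = make_test_log(combos, 20, 10)
        log.combo_idx[3] = 99
        with pytest.raises(DataError):
            score_test(log, combos)

    def test_tie_trials_excluded(self):
        cs = default_card_set(1)
        combos = enumerate_combinations(cs)
        # a synthetic TIE combination spliced into the lookup table
        from wptpipe.task import Combination, TIE

        combos_tie = combos + [Combination((1, 2, 3), 0.5, TIE)]
        log = make_test_log(combos, 28, 14)
        log.combo_idx[:4] = len(combos_tie) - 1  # first four trials become TIE stimuli
        s = score_test(log, combos_tie)
        assert s.n_tie_excluded == 4
        assert s.n_trials == 24


class TestChanceRange:
    def test_n100_band_matches_exact_oracle(self):
        lo, hi = chance_range(100, 0.05)
        assert (lo, hi) == (40, 60)
        for x in range(101):
            inside = lo <= x <= hi
            assert inside == (exact_binom_two_sided(x, 100) > 0.05)

    @pytest.mark.parametrize("n", [1, 7, 30, 57])
    def test_band_matches_oracle_various_n(self, n):
        lo, hi = chance_range(n, 0.05)
        for x in range(n + 1):
            assert (lo <= x <= hi) == (exact_binom_two_sided(x, n) > 0.05)

    def test_center_at_chance(self, combos):
        s = score_test(make_test_log(combos, 100, 50), combos)
        assert s.chance_p == pytest.approx(1.0)
        assert s.at_chance

    def test_n1_everything_at_chance(self):
        assert chance_range(1, 0.05) == (0, 1)

    def test_alpha_validation(self):
        with pytest.raises(DataError):
            chance_range(100, 1.5)

    def test_p_value_matches_oracle(self):
        for x, n in [(40, 100), (61, 100), (3, 10)]:
            assert two_sided_binom_p(x, n) == pytest.approx(exact_binom_two_sided(x, n))


class TestReversalRepair:
    def test_reversed_session_flagged_and_repaired(self, combos):
        log = make_test_log(combos, 100, 30)
        repaired, scores = detect_and_repair_reversal([log], combos)
        assert scores[0].repaired and scores[0].reversed_flag
        assert scores[0].raw == pytest.approx(0.70)

    def test_within_band_untouched(self, combos):
        log = make_test_log(combos, 100, 55)
        _, scores = detect_and_repair_reversal([log], combos)
        assert not scores[0].repaired
        assert scores[0].raw == pytest.approx(0.55)

    def test_low_but_not_reversed_untouched(self, combos):
        # 35 correct with 30 unanswered: flipped score 35+... stays in band
        log = make_test_log(combos, 100, 35, n_unanswered=30)
        _, scores = detect_and_repair_reversal([log], combos)
        assert not scores[0].repaired

    def test_repair_is_involution_and_preserves_answers(self, combos, rng):
        log = make_test_log(combos, 100, 47, n_unanswered=13)
        rng.shuffle(log.response)
        twice = flip_responses(flip_responses(log))
        assert np.array_equal(twice.response, log.response)
        assert (flip_responses(log).response == NO_RESPONSE).sum() == (
            log.response == NO_RESPONSE
        ).sum()

    def test_commutes_with_complement_symmetry(self, combos, rng):
        """Relabeling SUN<->RAIN plus complementing every card probability
        leaves scores and reversal flags unchanged."""
        cs = default_card_set(1)
        flipped_combos = enumerate_combinations(complement_card_set(cs))
        for n_correct in (25, 50, 80):
            log = make_test_log(combos, 100, n_correct, n_unanswered=5)
            mirrored = flip_responses(log)
            _, s1 = detect_and_repair_reversal([log], combos)
            _, s2 = detect_and_repair_reversal([mirrored], flipped_combos)
            assert s1[0].n_correct == s2[0].n_correct
            assert s1[0].repaired == s2[0].repaired


class TestExclusions:
    def _scores(self, combos, compliance, test_correct, retest_correct=75):
        return ParticipantScores(
            participant_id="P1",
            training_compliance=compliance,
            test=score_test(make_test_log(combos, 100, test_correct), combos),
            retest=score_test(make_test_log(combos, 100, retest_correct), combos),
        )

    def test_low_compliance_excluded(self, combos):
        r = apply_exclusions([self._scores(combos, 0.95, 80)])[0]
        assert r.excluded and r.reasons == [REASON_LOW_TRAINING_COMPLIANCE]

    def test_boundary_compliance_retained(self, combos):
        r = apply_exclusions([self._scores(combos, 0.96, 80)])[0]
        assert not r.excluded

    def test_at_chance_test_excluded(self, combos):
        r = apply_exclusions([self._scores(combos, 1.0, 55)])[0]
        assert r.excluded and REASON_AT_CHANCE_TEST in r.reasons

    def test_repaired_session_retained(self, combos):
        log = make_test_log(combos, 100, 30)  # reversed: repairs to 70
        _, scores = detect_and_repair_reversal([log], combos)
        ps = ParticipantScores(
            participant_id="P1",
            training_compliance=1.0,
            test=scores[0],
            repaired_sessions=["TEST"],
        )
        r = apply_exclusions([ps])[0]
        assert not r.excluded
        assert r.repaired_sessions == ["TEST"]
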