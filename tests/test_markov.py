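"""Transition counting, MLE probabilities, windowed matrices, group comparison."""
import numpy as np
import pytest

from sleepssm import (
    Hypnogram,
    SleepDiary,
    Stage,
    compare_transition,
    subjective_sl_matrix,
    transition_counts,
    transition_matrix,
)
from sleepssm.errors import ComparisonError, StructureError
from sleepssm.hypnogram import STAGE_ORDER, restrict_window
from sleepssm.markov import TransitionMatrix
from sleepssm.synthetic import ONSET_CHAIN_HIGH, generate_hypnogram

from conftest import STAGES, random_hypnogram

IDX = {s: i for i, s in enumerate(STAGE_ORDER)}


def seq(*labels):
    return [Stage(l) for l in labels]


def tm_from_probs(rows):
    """Build a TransitionMatrix from a dict {from: row-list}; others missing."""
    probs = np.full((5, 5), np.nan)
    visits = np.zeros(5, dtype=int)
    for frm, row in rows.items():
        probs[IDX[Stage(frm)]] = row
        visits[IDX[Stage(frm)]] = 10
    return TransitionMatrix(probs=probs, row_visits=visits)


class TestCounts:
    def test_hand_count(self):
        tc = transition_counts(seq("W", "N1", "W", "N1", "N1", "N2"))
        assert tc.counts[IDX[Stage.W], IDX[Stage.N1]] == 2
        assert tc.counts[IDX[Stage.N1], IDX[Stage.W]] == 1
        assert tc.counts[IDX[Stage.N1], IDX[Stage.N1]] == 1
        assert tc.counts[IDX[Stage.N1], IDX[Stage.N2]] == 1
        assert tc.n_transitions == 5

    def test_self_transitions(self):
        tc = transition_counts(seq("W", "W", "W"))
        assert tc.counts[IDX[Stage.W], IDX[Stage.W]] == 2
        assert tc.counts.sum() == 2

    def test_too_short_rejected(self):
        with pytest.raises(StructureError):
            transition_counts(seq("W"))

    def test_row_sums_equal_non_terminal_visit_counts(self, rng):
        for _ in range(200):
            hyp = random_hypnogram(rng, int(rng.integers(2, 60)))
            tc = transition_counts(hyp.epochs)
            labels = hyp.labels()[:-1]  # non-terminal positions
            for s in STAGES:
                assert tc.counts[IDX[s]].sum() == np.sum(labels == s.value)


class TestMatrix:
    def test_normalisation(self):
        tc = transition_counts(seq("N1", "N1", "N2", "N1", "W"))
        tm = transition_matrix(tc)
        np.testing.assert_allclose(
            tm.probs[IDX[Stage.N1]], [1 / 3, 1 / 3, 1 / 3, 0, 0]
        )

    def test_unvisited_row_missing_not_zero(self):
        tm = transition_matrix(transition_counts(seq("W", "N1", "W")))
        assert tm.is_missing(Stage.N3)
        assert np.isnan(tm.probs[IDX[Stage.N3]]).all()

    def test_rows_stochastic(self, rng):
        for _ in range(50):
            hyp = random_hypnogram(rng, 40)
            tm = transition_matrix(transition_counts(hyp.epochs))
            for i in range(5):
                if tm.row_visits[i] > 0:
                    assert tm.probs[i].sum() == pytest.approx(1.0, abs=1e-12)

    def test_mle_consistency_improves_with_length(self):
        errs = []
        for n in (100, 1000, 10000):
            hyp = generate_hypnogram(ONSET_CHAIN_HIGH, n + 1, Stage.W, seed=5)
            tm = transition_matrix(transition_counts(hyp.epochs))
            visited = tm.row_visits > 0
            err = np.nanmax(np.abs(tm.probs[visited] - ONSET_CHAIN_HIGH[visited]))
            errs.append(err)
        assert errs[2] < errs[0]
        assert errs[2] <= 0.05


class TestSubjectiveWindow:
    def diary(self, sl_min):
        return SleepDiary("s", "23:30", sl_min, 400.0)

    def test_composition_example(self):
        hyp = Hypnogram((Stage.W, Stage.N1, Stage.W, Stage.N1))
        tm = subjective_sl_matrix(hyp, self.diary(2.0))
        assert tm.prob(Stage.N1, Stage.W) == 1.0
        assert tm.prob(Stage.W, Stage.N1) == 1.0

    def test_too_short_window_missing(self):
        hyp = Hypnogram((Stage.W, Stage.N1, Stage.W, Stage.N1))
        with pytest.warns(UserWarning, match="matrix missing"):
            assert subjective_sl_matrix(hyp, self.diary(0.4)) is None

    def test_equals_composition_of_primitives(self, rng):
        for _ in range(100):
            hyp = random_hypnogram(rng, int(rng.integers(4, 80)))
            sl = float(rng.uniform(1.0, hyp.duration_min))
            tm = subjective_sl_matrix(hyp, self.diary(sl))
            window = restrict_window(hyp, 0.0, sl)
            if len(window) < 2:
                assert tm is None
                continue
            expected = transition_matrix(transition_counts(window.epochs))
            np.testing.assert_array_equal(tm.row_visits, expected.row_visits)
            np.testing.assert_allclose(tm.probs, expected.probs)

    def test_windowing_containment(self, rng):
        # transitions counted in the subjective window never involve epochs
        # starting at or after SL_subj
        hyp = random_hypnogram(rng, 40)
        sl = 7.3
        tm = subjective_sl_matrix(hyp, self.diary(sl))
        n_window = len(restrict_window(hyp, 0.0, sl))
        assert tm.row_visits.sum() == n_window - 1


class TestCompareTransition:
    def test_complete_separation(self):
        a = [tm_from_probs({"N1": [1.0, 0, 0, 0, 0]}), tm_from_probs({"N1": [0.8, 0.2, 0, 0, 0]})]
        b = [tm_from_probs({"N1": [0.0, 1, 0, 0, 0]}), tm_from_probs({"N1": [0.1, 0.9, 0, 0, 0]})]
        comp = compare_transition(a, b, Stage.N1, Stage.W)
        assert comp.test.rank_biserial == 1.0
        assert comp.test.u_stat == 4

    def test_identical_groups_p_one(self):
        a = [tm_from_probs({"N1": [0.3, 0.7, 0, 0, 0]}) for _ in range(3)]
        comp = compare_transition(a, list(a), Stage.N1, Stage.W)
        assert comp.test.p_two_sided == pytest.approx(1.0)
        assert comp.test.rank_biserial == 0.0

    def test_missing_rows_excluded_and_counted(self):
        a = [tm_from_probs({"N1": [0.5, 0.5, 0, 0, 0]}), tm_from_probs({"W": [1, 0, 0, 0, 0]})]
        b = [tm_from_probs({"N1": [0.2, 0.8, 0, 0, 0]})]
        comp = compare_transition(a, b, Stage.N1, Stage.W)
        assert comp.n_a == 1 and comp.n_excluded_a == 1
        assert comp.n_b == 1 and comp.n_excluded_b == 0

    def test_all_missing_group_errors(self):
        a = [tm_from_probs({"W": [1, 0, 0, 0, 0]})]
        b = [tm_from_probs({"N1": [0.2, 0.8, 0, 0, 0]})]
        with pytest.raises(ComparisonError, match="group A"):
            compare_transition(a, b, Stage.N1, Stage.W)
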