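"""Sequence container, transition-model fitting, jump conversion, words."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microsyntax import (
    DegenerateSequenceError,
    MicrostateSequence,
    SequenceLengthError,
    fit_transition_model,
    to_jump_sequence,
    word_histogram,
)
from microsyntax.sequence import labels_from_letters, labels_to_letters

label_sequences = st.lists(st.integers(0, 3), min_size=2, max_size=60)


class TestMicrostateSequence:
    def test_rejects_out_of_alphabet_labels(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            MicrostateSequence([0, 2], 2)

    def test_rejects_adjacent_duplicates_in_jump_kind(self):
        with pytest.raises(ValueError, match="adjacent"):
            MicrostateSequence([0, 1, 1], 2, kind="jump")

    def test_rejects_empty(self):
        with pytest.raises(DegenerateSequenceError):
            MicrostateSequence([], 2)

    def test_letter_round_trip(self):
        assert labels_to_letters(labels_from_letters("ACDB")) == "ACDB"
        seq = MicrostateSequence.from_letters("ABBA", 2)
        assert list(seq.labels) == [0, 1, 1, 0]


class TestFitTransitionModel:
    def test_hand_counted_pairs(self, toy_model):
        # three adjacent pairs of [0,0,1,1]: (0,0), (0,1), (1,1)
        np.testing.assert_allclose(toy_model.P, [[1 / 3, 1 / 3], [0, 1 / 3]])
        np.testing.assert_allclose(toy_model.p, [2 / 3, 1 / 3])
        np.testing.assert_allclose(toy_model.T, [[0.5, 0.5], [0, 1]])
        assert toy_model.n_transitions == 3
        toy_model.validate()

    def test_single_state_chain_flags_unvisited_rows(self):
        model = fit_transition_model(MicrostateSequence([2, 2, 2, 2], 3))
        np.testing.assert_allclose(model.p, [0, 0, 1])
        np.testing.assert_allclose(model.T[2], [0, 0, 1])
        assert set(model.zero_rows) == {0, 1}
        assert np.all(model.T[:2] == 0)

    def test_too_short(self):
        with pytest.raises(SequenceLengthError):
            fit_transition_model(MicrostateSequence([0], 2))

    def test_recovers_generating_matrix_at_scale(self, jump_chain_long):
        seq, T_true = jump_chain_long
        model = fit_transition_model(seq)
        assert np.abs(model.T - T_true).max() < 0.02

    @settings(deadline=None)
    @given(label_sequences)
    def test_identity_P_equals_p_times_T(self, labels):
        model = fit_transition_model(MicrostateSequence(labels, 4))
        np.testing.assert_allclose(model.P, model.p[:, None] * model.T, rtol=1e-14, atol=0)
        np.testing.assert_allclose(model.P.sum(axis=1), model.p)
        assert abs(model.P.sum() - 1) < 1e-12


class TestToJumpSequence:
    def test_worked_example_with_durations(self):
        text = "A" * 6 + "C" * 6 + "D" * 9 + "B" * 5 + "A" * 5 + "C" * 7 + "D" * 4 + "B" * 5 + "A" * 3
        seq = MicrostateSequence.from_letters(text, 4)
        assert to_jump_sequence(seq, drop_edge_segments=False).to_letters() == "ACDBACDBA"
        assert to_jump_sequence(seq, drop_edge_segments=True).to_letters() == "CDBACDB"

    def test_single_run_collapses_to_one_label(self):
        out = to_jump_sequence(MicrostateSequence([0, 0, 0], 2), drop_edge_segments=False)
        assert list(out.labels) == [0]

    def test_edge_exclusion_can_empty_the_sequence(self):
        with pytest.raises(DegenerateSequenceError):
            to_jump_sequence(MicrostateSequence([0, 0, 1], 2), drop_edge_segments=True)

    def test_rejects_jump_input(self):
        with pytest.raises(ValueError):
            to_jump_sequence(MicrostateSequence([0, 1], 2, kind="jump"))

    @settings(deadline=None)
    @given(label_sequences)
    def test_collapsing_is_idempotent_in_effect(self, labels):
        seq = MicrostateSequence(labels, 4)
        jump = to_jump_sequence(seq, drop_edge_segments=False)
        again = MicrostateSequence(jump.labels, 4)  # re-read as continuous
        assert list(to_jump_sequence(again, drop_edge_segments=False).labels) == list(jump.labels)


class TestWordHistogram:
    def test_enumerated_windows(self):
        hist = word_histogram(MicrostateSequence([0, 1, 0, 1], 2), 2)
        assert hist.counts == {(0, 1): 2, (1, 0): 1}
        assert hist.total == 3

    def test_k_one_is_label_histogram(self):
        hist = word_histogram(MicrostateSequence([0, 1, 0, 1], 2), 1)
        assert hist.counts == {(0,): 2, (1,): 2}

    def test_k_equal_length_single_word(self):
        hist = word_histogram(MicrostateSequence([0, 1, 2], 3), 3)
        assert hist.counts == {(0, 1, 2): 1}
        assert hist.total == 1

    def test_k_beyond_length(self):
        with pytest.raises(SequenceLengthError):
            word_histogram(MicrostateSequence([0, 1], 2), 3)

    @settings(deadline=None)
    @given(label_sequences, st.integers(1, 5))
    def test_total_is_n_minus_k_plus_one(self, labels, k):
        if k > len(labels):
            return
        hist = word_histogram(MicrostateSequence(labels, 4), k)
        assert hist.total == len(labels) - k + 1
        assert sum(hist.counts.values()) == hist.total
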