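"""Entropy-rate and sample-entropy estimators against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microsyntax import (
    MicrostateSequence,
    SequenceLengthError,
    UndefinedSampleEntropyError,
    entropy_rate,
    sample_entropy,
    sample_entropy_zero,
    syntax_profile,
)
from microsyntax.entropy import _se_counts

from _oracles import naive_entropy_rate, naive_sample_entropy

label_sequences = st.lists(st.integers(0, 3), min_size=6, max_size=120)


class TestEntropyRate:
    def test_alternating_sequence_is_deterministic(self):
        seq = MicrostateSequence([0, 1] * 50, 2)
        assert entropy_rate(seq, 1) == 0.0

    def test_hand_derived_pair_histogram(self):
        # pair rows (1/2,1/2) and (1/3,2/3), weights 4/7 and 3/7
        seq = MicrostateSequence([0, 0, 1, 1, 0, 0, 1, 1], 2)
        expected = 4 / 7 * 1.0 + 3 / 7 * (-(1 / 3) * np.log2(1 / 3) - (2 / 3) * np.log2(2 / 3))
        assert entropy_rate(seq, 1) == pytest.approx(expected, abs=1e-12)

    def test_k_zero_is_shannon_entropy_of_labels(self):
        seq = MicrostateSequence([0, 0, 1], 2)
        assert entropy_rate(seq, 0) == pytest.approx(-(2 / 3) * np.log2(2 / 3) - (1 / 3) * np.log2(1 / 3))

    def test_iid_uniform_approaches_log2K(self, rng):
        seq = MicrostateSequence(rng.integers(0, 4, size=100_000), 4)
        assert entropy_rate(seq, 3) == pytest.approx(2.0, abs=0.02)

    def test_too_short(self):
        with pytest.raises(SequenceLengthError):
            entropy_rate(MicrostateSequence([0, 1, 0], 2), 2)

    @settings(deadline=None, max_examples=60)
    @given(label_sequences, st.integers(0, 4))
    def test_matches_explicit_conditional_entropy_oracle(self, labels, k):
        if len(labels) < k + 2:
            return
        seq = MicrostateSequence(labels, 4)
        assert entropy_rate(seq, k) == pytest.approx(naive_entropy_rate(labels, k), abs=1e-10)


class TestSampleEntropy:
    @pytest.mark.parametrize(
        "labels, k, expected",
        [
            ([0, 1, 0, 1, 0], 1, 0.0),  # A = B = 2
            ([0, 1, 0, 2], 1, np.inf),  # one recurrence, successor differs
        ],
    )
    def test_enumerated_examples(self, labels, k, expected):
        K = max(labels) + 1
        assert sample_entropy(MicrostateSequence(labels, K), k) == expected

    def test_no_recurrence_is_undefined_not_infinite(self):
        with pytest.raises(UndefinedSampleEntropyError):
            sample_entropy(MicrostateSequence([0, 1, 2, 3], 4), 1)

    def test_pair_counts_match_naive_enumeration_example(self):
        seq = MicrostateSequence([0, 1, 0, 1, 1, 0, 1], 2)
        assert _se_counts(seq, 2) == naive_sample_entropy(seq.labels, 2)

    @settings(deadline=None, max_examples=60)
    @given(label_sequences, st.integers(1, 4))
    def test_matches_pair_enumeration_oracle(self, labels, k):
        if len(labels) < k + 2:
            return
        seq = MicrostateSequence(labels, 4)
        A, B = naive_sample_entropy(labels, k)
        assert _se_counts(seq, k) == (A, B)
        if B == 0:
            with pytest.raises(UndefinedSampleEntropyError):
                sample_entropy(seq, k)
        elif A == 0:
            assert sample_entropy(seq, k) == np.inf
        else:
            assert sample_entropy(seq, k) == pytest.approx(-np.log2(A / B), abs=1e-12)


class TestSampleEntropyZero:
    @pytest.mark.parametrize(
        "labels, K, expected",
        [
            ([0, 1], 2, 1.0),  # p = (1/2, 1/2)
            ([0, 0, 0], 2, 0.0),  # constant
            ([0, 0, 1], 2, -np.log2(5 / 9)),  # p = (2/3, 1/3)
        ],
    )
    def test_renyi2_of_label_frequencies(self, labels, K, expected):
        assert sample_entropy_zero(MicrostateSequence(labels, K)) == pytest.approx(expected)


class TestSyntaxProfile:
    def test_deterministic_alternation_gives_zero_curves(self):
        profile = syntax_profile(MicrostateSequence([0, 1] * 40, 2), 3)
        assert np.all(profile.er[1:] == 0)
        assert np.all(profile.se[1:] == 0)

    def test_values_bounded_by_log2K(self, rng):
        seq = MicrostateSequence(rng.integers(0, 4, size=2000), 4)
        profile = syntax_profile(seq, 4)
        finite = profile.se[np.isfinite(profile.se)]
        assert np.all(profile.er >= 0) and np.all(profile.er <= 2 + 1e-12)
        assert np.all(finite >= 0) and np.all(finite <= 2 + 0.1)

    @settings(deadline=None, max_examples=60)
    @given(label_sequences)
    def test_er_curve_is_non_increasing_on_any_input(self, labels):
        kmax = min(4, len(labels) - 2)
        profile = syntax_profile(MicrostateSequence(labels, 4), kmax)
        assert np.all(np.diff(profile.er) <= 1e-12)

    def test_undersampled_profile_warns(self, rng):
        seq = MicrostateSequence(rng.integers(0, 4, size=200), 4)
        with pytest.warns(UserWarning, match="biased"):
            profile = syntax_profile(seq, 4)
        assert profile.warnings

    def test_undefined_se_slots_are_marked_not_dropped(self):
        seq = MicrostateSequence([0, 1, 2, 3, 0, 1, 2, 3], 4)
        with pytest.warns(UserWarning):
            profile = syntax_profile(seq, 5)
        assert "undefined" in profile.se_status
        assert np.isnan(profile.se[profile.se_status.index("undefined")])

    def test_serialization_round_trip(self, rng):
        import json

        seq = MicrostateSequence(rng.integers(0, 3, size=500), 3)
        profile = syntax_profile(seq, 3)
        data = json.loads(profile.to_json())
        assert data["K"] == 3 and len(data["er"]) == 4
        frame = profile.to_frame()
        assert list(frame.columns) == ["k", "er", "se", "er_mc0", "er_mc1", "se_mc0", "se_mc1"]
        assert len(frame) == 4
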