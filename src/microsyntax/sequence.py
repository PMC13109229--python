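"""Label sequences and first-order Markov summaries.

An EEG microstate analysis compresses multichannel EEG into a sequence of
class labels (conventionally A, B, C, D -> 0..K-1).  Two representations are
used throughout the package:

* a *continuous* sequence keeps one label per sample and therefore retains
  state durations;
* a *jump* sequence collapses runs of identical labels and retains only the
  order of state changes.

This module holds the sequence container, the first-order summary statistics
(state distribution ``p``, conditional transition matrix ``T`` and joint
transition matrix ``P`` with ``P[i, j] = p[i] * T[i, j]``), the
continuous-to-jump conversion, and overlapping word (k-gram) histograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DegenerateSequenceError, ModelError, SequenceLengthError

__all__ = [
    "MicrostateSequence",
    "TransitionModel",
    "WordHistogram",
    "fit_transition_model",
    "to_jump_sequence",
    "word_histogram",
    "labels_from_letters",
    "labels_to_letters",
]

CONTINUOUS = "continuous"
JUMP = "jump"


def labels_from_letters(text: Iterable[str]) -> np.ndarray:
    """Map letters A, B, C, ... to integers 0, 1, 2, ... (case-insensitive)."""
    out = []
    for ch in text:
        ch = ch.strip()
        if not ch:
            continue
        if len(ch) != 1 or not ch.isalpha():
            raise ValueError(f"not a single letter label: {ch!r}")
        out.append(ord(ch.upper()) - ord("A"))
    return np.asarray(out, dtype=np.int64)


def labels_to_letters(labels: Sequence[int]) -> str:
    """Inverse of :func:`labels_from_letters` (0 -> 'A', 1 -> 'B', ...)."""
    return "".join(chr(ord("A") + int(x)) for x in labels)


@dataclass
class MicrostateSequence:
    """A finite sequence of integer labels over a K-letter alphabet.

    Parameters
    ----------
    labels:
        Integer labels in ``[0, n_states - 1]``, length >= 1.
    n_states:
        Alphabet size K.
    kind:
        ``"continuous"`` (per-sample labels) or ``"jump"`` (no two adjacent
        labels equal).
    sampling_rate_hz:
        Optional sampling rate; only meaningful for continuous sequences.
    subject_id:
        Optional free-text identifier carried through reports.
    """

    labels: np.ndarray
    n_states: int
    kind: str = CONTINUOUS
    sampling_rate_hz: float | None = None
    subject_id: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels, dtype=np.int64)
        if arr.ndim != 1 or arr.size < 1:
            raise DegenerateSequenceError("labels must be a non-empty 1-D sequence")
        if self.n_states < 1:
            raise ValueError("n_states must be a positive integer")
        if arr.min() < 0 or arr.max() >= self.n_states:
            raise ValueError(
                f"labels must lie in [0, {self.n_states - 1}]; "
                f"found range [{arr.min()}, {arr.max()}]"
            )
        if self.kind not in (CONTINUOUS, JUMP):
            raise ValueError(f"kind must be 'continuous' or 'jump', got {self.kind!r}")
        if self.kind == JUMP and arr.size > 1 and np.any(arr[1:] == arr[:-1]):
            raise ValueError("jump sequences cannot contain adjacent duplicate labels")
        if self.sampling_rate_hz is not None and self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        object.__setattr__(self, "labels", arr)

    def __len__(self) -> int:
        return int(self.labels.size)

    @classmethod
    def from_letters(
        cls, text: str, n_states: int | None = None, kind: str = CONTINUOUS, **kw
    ) -> "MicrostateSequence":
        labels = labels_from_letters(text)
        if n_states is None:
            n_states = int(labels.max()) + 1
        return cls(labels, n_states, kind=kind, **kw)

    def to_letters(self) -> str:
        return labels_to_letters(self.labels)

    def runs(self) -> tuple[np.ndarray, np.ndarray]:
        """Run-length encoding: (run labels, run lengths)."""
        arr = self.labels
        change = np.flatnonzero(arr[1:] != arr[:-1])
        starts = np.concatenate(([0], change + 1))
        ends = np.concatenate((change + 1, [arr.size]))
        return arr[starts], ends - starts


@dataclass
class TransitionModel:
    """First-order summary of a label sequence.

    ``p`` is the state distribution, ``T`` the row-stochastic conditional
    transition matrix and ``P`` the joint matrix of adjacent pairs, linked by
    ``P[i, j] = p[i] * T[i, j]``.  ``p`` is defined as the row marginal of the
    empirical pair counts (not the label frequency over all n samples) so the
    identity is exact on finite data; the two differ by at most one count.
    States never visited as a pair origin have an all-zero T row and are
    listed in ``zero_rows``.
    """

    p: np.ndarray
    T: np.ndarray
    P: np.ndarray
    n_transitions: int
    zero_rows: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    @property
    def n_states(self) -> int:
        return int(self.p.size)

    def validate(self, atol: float = 1e-9) -> None:
        """Raise :class:`ModelError` if the model invariants are violated."""
        K = self.n_states
        if self.T.shape != (K, K) or self.P.shape != (K, K):
            raise ModelError("T and P must be K x K")
        if np.any(self.P < -atol) or np.any(self.T < -atol):
            raise ModelError("negative probabilities")
        if abs(self.P.sum() - 1.0) > 1e-6:
            raise ModelError("entries of P must sum to 1")
        rows = self.T.sum(axis=1)
        active = self.p > 0
        if np.any(np.abs(rows[active] - 1.0) > 1e-6):
            raise ModelError("rows of T with p_i > 0 must sum to 1")
        if not np.allclose(self.P, self.p[:, None] * self.T, atol=atol):
            raise ModelError("P != p * T")
        if not np.allclose(self.P.sum(axis=1), self.p, atol=atol):
            raise ModelError("p is not the row marginal of P")


def fit_transition_model(seq: MicrostateSequence) -> TransitionModel:
    """Estimate (p, T, P) from the adjacent ordered pairs of a sequence.

    Raises
    ------
    SequenceLengthError
        If the sequence has fewer than 2 samples (no transitions).
    """
    n = len(seq)
    if n < 2:
        raise SequenceLengthError("need at least 2 samples to fit a transition model")
    K = seq.n_states
    pairs = seq.labels[:-1] * K + seq.labels[1:]
    counts = np.bincount(pairs, minlength=K * K).reshape(K, K).astype(np.float64)
    n_transitions = n - 1
    P = counts / n_transitions
    p = P.sum(axis=1)
    T = np.zeros_like(P)
    active = p > 0
    T[active] = P[active] / p[active, None]
    zero_rows = np.flatnonzero(~active)
    return TransitionModel(p=p, T=T, P=P, n_transitions=n_transitions, zero_rows=zero_rows)


def to_jump_sequence(
    seq: MicrostateSequence, drop_edge_segments: bool = True
) -> MicrostateSequence:
    """Collapse adjacent duplicate labels of a continuous sequence.

    When ``drop_edge_segments`` is true (the default, matching the usual
    preprocessing of back-fitted microstate sequences, whose first and last
    runs are truncated by the recording window), the first and last run of the
    continuous sequence are removed before collapsing.

    Raises
    ------
    DegenerateSequenceError
        If nothing remains after edge exclusion.
    """
    if seq.kind != CONTINUOUS:
        raise ValueError("to_jump_sequence expects a continuous sequence")
    run_labels, _ = seq.runs()
    if drop_edge_segments:
        run_labels = run_labels[1:-1]
    if run_labels.size == 0:
        raise DegenerateSequenceError(
            "sequence is empty after removing the first and last segment"
        )
    return MicrostateSequence(
        run_labels,
        seq.n_states,
        kind=JUMP,
        sampling_rate_hz=None,
        subject_id=seq.subject_id,
    )


@dataclass
class WordHistogram:
    """Counts of overlapping length-k words (chronological label order)."""

    k: int
    counts: Mapping[tuple[int, ...], int]
    total: int


def word_histogram(seq: MicrostateSequence, k: int) -> WordHistogram:
    """Histogram of all overlapping windows of length ``k``.

    The total is ``len(seq) - k + 1``.
    """
    n = len(seq)
    if k < 1:
        raise ValueError("k must be a positive integer")
    if k > n:
        raise SequenceLengthError(f"word length k={k} exceeds sequence length {n}")
    windows = np.lib.stride_tricks.sliding_window_view(seq.labels, k)
    uniq, cnt = np.unique(windows, axis=0, return_counts=True)
    counts = {tuple(int(x) for x in row): int(c) for row, c in zip(uniq, cnt)}
    return WordHistogram(k=k, counts=counts, total=n - k + 1)
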