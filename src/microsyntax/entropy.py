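"""Empirical entropy-rate and sample-entropy estimators for label sequences.

Two scalar families quantify higher-order syntax of a discrete sequence:

* ``ER(k)`` — the plug-in conditional entropy H(X_{t+1} | last k labels),
  i.e. short-range predictability given a length-k history ("word");
* ``SE(k)`` — the sample entropy -log2 Pr(successors match | two length-k
  words match), a whole-sequence recurrence statistic.  For discrete
  sequences a collision is exact word equality; no tolerance radius is
  needed.

All logarithms are base 2; results are in bits.  The convention
0 * log 0 = 0 applies throughout.

SE(k) is computed by pair counting over all unordered position pairs t < s
whose k-word AND successor both exist, so the match count B and the
extension count A are taken over the same pair population; A = 0 with B > 0
yields +infinity, B = 0 raises :class:`UndefinedSampleEntropyError`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SequenceLengthError, UndefinedSampleEntropyError
from .markov import er_first_order, se_first_order, zero_order_levels
from .sequence import MicrostateSequence, fit_transition_model

__all__ = [
    "entropy_rate",
    "sample_entropy",
    "sample_entropy_zero",
    "syntax_profile",
    "SyntaxProfile",
]

SE_OK = "ok"
SE_INFINITE = "infinite"
SE_UNDEFINED = "undefined"
SE_RENYI2 = "renyi2-approx"


def _word_codes(labels: np.ndarray, k: int, n_states: int) -> np.ndarray:
    """Integer codes of all overlapping length-k windows (chronological).

    Uses a base-K positional encoding when K**k fits in int64, otherwise
    falls back to row-wise uniquing.
    """
    if k == 1:
        return labels
    windows = np.lib.stride_tricks.sliding_window_view(labels, k)
    if n_states**k < 2**62:
        powers = n_states ** np.arange(k - 1, -1, -1, dtype=np.int64)
        return windows @ powers
    # fall back: dense re-encoding of unique rows
    _, inverse = np.unique(windows, axis=0, return_inverse=True)
    return inverse


def _entropy_bits(counts: np.ndarray) -> float:
    counts = counts[counts > 0]
    total = counts.sum()
    p = counts / total
    return float(-(p * np.log2(p)).sum())


def _code_counts(codes: np.ndarray) -> np.ndarray:
    # np.unique is robust for sparse code spaces; bincount would allocate K**k
    _, counts = np.unique(codes, return_counts=True)
    return counts


def entropy_rate(seq: MicrostateSequence, k: int) -> float:
    """Plug-in entropy rate ER(k) in bits.

    ``k = 0`` returns the Shannon entropy of the label histogram.  For
    ``k >= 1`` the estimate is the difference of block entropies
    H(k+1-words) - H(k-words), with the k-word histogram taken over the
    prefix positions of the (k+1)-windows so that the difference is exactly
    the plug-in conditional entropy.
    """
    n = len(seq)
    if k < 0:
        raise ValueError("k must be non-negative")
    if n < k + 2:
        raise SequenceLengthError(f"need at least k + 2 = {k + 2} samples, got {n}")
    if k == 0:
        return _entropy_bits(np.bincount(seq.labels, minlength=seq.n_states))
    joint = _code_counts(_word_codes(seq.labels, k + 1, seq.n_states))
    prefix = _code_counts(_word_codes(seq.labels[:-1], k, seq.n_states))
    return max(0.0, _entropy_bits(joint) - _entropy_bits(prefix))


def _se_counts(seq: MicrostateSequence, k: int) -> tuple[int, int]:
    """(A, B) pair counts for SE(k).

    B counts unordered pairs of positions with equal k-words, restricted to
    positions that have a successor; A counts the subset whose successors
    also match, i.e. pairs of equal (k+1)-words.  Both reduce to sums of
    C(count, 2) over word histograms.
    """
    n = len(seq)
    if k < 1:
        raise ValueError("k must be a positive integer")
    if n < k + 2:
        raise SequenceLengthError(f"need at least k + 2 = {k + 2} samples, got {n}")
    ext = _code_counts(_word_codes(seq.labels, k + 1, seq.n_states))
    tmpl = _code_counts(_word_codes(seq.labels[:-1], k, seq.n_states))
    A = int((ext * (ext - 1) // 2).sum())
    B = int((tmpl * (tmpl - 1) // 2).sum())
    return A, B


def sample_entropy(seq: MicrostateSequence, k: int) -> float:
    """Discrete sample entropy SE(k) = -log2(A/B) in bits.

    Returns ``+inf`` when templates recur but no recurrence extends (A = 0);
    raises :class:`UndefinedSampleEntropyError` when no k-word recurs at all
    (B = 0).
    """
    A, B = _se_counts(seq, k)
    if B == 0:
        raise UndefinedSampleEntropyError(f"no word of length k={k} recurs")
    if A == 0:
        return float("inf")
    return float(-np.log2(A / B)) + 0.0  # normalize -0.0


def sample_entropy_zero(seq: MicrostateSequence) -> float:
    """Order-2 Renyi (collision) entropy -log2 sum_i p_i^2 of the label
    frequencies, the natural k = 0 stand-in for the sample-entropy curve."""
    counts = np.bincount(seq.labels, minlength=seq.n_states)
    p = counts / counts.sum()
    return float(-np.log2((p * p).sum()))


@dataclass
class SyntaxProfile:
    """ER(k) and SE(k) curves for k = 0..kmax plus Markov baselines.

    ``er`` and ``se`` are in bits.  ``se_status[k]`` distinguishes regular
    values, +infinity (no extending recurrence), undefined (no recurrence,
    stored as NaN) and the Renyi-2 approximation stored at slot 0.  The four
    baselines are the closed-form zero-/first-order Markov levels computed
    from the sequence's own fitted (p, T, P).
    """

    kmax: int
    er: np.ndarray
    se: np.ndarray
    se_status: list[str]
    er_theory_mc0: float
    er_theory_mc1: float
    se_theory_mc0: float
    se_theory_mc1: float
    n_samples: int
    n_states: int
    kind: str
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def clean(x: float) -> float | str | None:
            if np.isnan(x):
                return None
            if np.isinf(x):
                return "inf"
            return float(x)

        return {
            "K": self.n_states,
            "n_samples": self.n_samples,
            "kind": self.kind,
            "kmax": self.kmax,
            "er": [float(x) for x in self.er],
            "se": [clean(x) for x in self.se],
            "se_status": list(self.se_status),
            "baselines": {
                "er_mc0": self.er_theory_mc0,
                "er_mc1": self.er_theory_mc1,
                "se_mc0": self.se_theory_mc0,
                "se_mc1": self.se_theory_mc1,
            },
            "warnings": list(self.warnings),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-k table with empirical curves and flat baselines."""
        k = np.arange(self.kmax + 1)
        return pd.DataFrame(
            {
                "k": k,
                "er": self.er,
                "se": self.se,
                "er_mc0": self.er_theory_mc0,
                "er_mc1": self.er_theory_mc1,
                "se_mc0": self.se_theory_mc0,
                "se_mc1": self.se_theory_mc1,
            }
        )


def syntax_profile(
    seq: MicrostateSequence, kmax: int, bias_guard_factor: float = 10.0
) -> SyntaxProfile:
    """Empirical ER/SE curves for k = 0..kmax with theoretical baselines.

    The ER vector is computed as the conditional-entropy chain of a single
    empirical distribution over (kmax+1)-windows (the length-(k+1) suffix
    marginals of those windows), which makes ER(k) exactly non-increasing in
    k; it differs from per-k calls to :func:`entropy_rate` by O(kmax/n).

    A reliability warning is recorded for every k with
    ``n < bias_guard_factor * K**(k+1)`` (undersampled word histogram: the
    plug-in ER is then biased low, see docs/methods.md).
    """
    n = len(seq)
    if kmax < 1:
        raise ValueError("kmax must be a positive integer")
    if n < kmax + 2:
        raise SequenceLengthError(f"need at least kmax + 2 = {kmax + 2} samples, got {n}")
    K = seq.n_states
    labels = seq.labels
    warn_list: list[str] = []

    er = np.empty(kmax + 1)
    # shared window population: windows ending at positions kmax .. n-1
    for k in range(kmax + 1):
        joint = _code_counts(_word_codes(labels[kmax - k :], k + 1, K))
        if k == 0:
            er[0] = _entropy_bits(joint)
        else:
            prefix = _code_counts(_word_codes(labels[kmax - k : -1], k, K))
            er[k] = max(0.0, _entropy_bits(joint) - _entropy_bits(prefix))

    se = np.empty(kmax + 1)
    se_status = [SE_RENYI2]
    se[0] = sample_entropy_zero(seq)
    for k in range(1, kmax + 1):
        try:
            v = sample_entropy(seq, k)
            se[k] = v
            se_status.append(SE_INFINITE if np.isinf(v) else SE_OK)
        except UndefinedSampleEntropyError:
            se[k] = np.nan
            se_status.append(SE_UNDEFINED)
            warn_list.append(f"SE({k}) undefined: no word of length {k} recurs")

    for k in range(1, kmax + 1):
        if n < bias_guard_factor * K ** (k + 1):
            warn_list.append(
                f"ER({k})/SE({k}) may be biased: n={n} < "
                f"{bias_guard_factor:g} * K^(k+1) = {bias_guard_factor * K ** (k + 1):g}"
            )
            break  # one guard message covers all larger k

    model = fit_transition_model(seq)
    er0, se0 = zero_order_levels(model.p)
    profile = SyntaxProfile(
        kmax=kmax,
        er=er,
        se=se,
        se_status=se_status,
        er_theory_mc0=er0,
        er_theory_mc1=er_first_order(model),
        se_theory_mc0=se0,
        se_theory_mc1=se_first_order(model),
        n_samples=n,
        n_states=K,
        kind=seq.kind,
        warnings=warn_list,
    )
    for w in warn_list:
        warnings.warn(w, stacklevel=2)
    return profile
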