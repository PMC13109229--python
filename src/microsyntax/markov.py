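"""Closed-form entropy-rate and sample-entropy levels for Markov chains.

For a first-order Markov chain with state distribution ``p``, conditional
transition matrix ``T`` and joint matrix ``P = diag(p) T``, the finite
entropy-rate coefficients are flat in the word length k and equal the
conditional entropy

    ER = -E(log2 T) = -sum_ij P_ij log2 T_ij          (bits),

while the sample-entropy coefficients are approximated, under the assumption
that word collisions at different recurrence lags are independent, by the
collision probability of one transition:

    SE ~= -log2 E(T) = -log2 sum_ij P_ij T_ij         (bits).

Concavity of the logarithm (Jensen) gives ER >= SE for every valid model.
For a zero-order (i.i.d.) chain the two levels reduce to the Shannon entropy
H(p) and the order-2 Renyi (collision) entropy -log2 sum_i p_i^2.

The independence approximation behind the SE level has no closed-form error
bound; its accuracy is assessed numerically against Markov surrogates (see
the flat-curve tests and docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ModelError
from .sequence import TransitionModel

__all__ = [
    "er_first_order",
    "se_first_order",
    "zero_order_levels",
    "verify_inequality",
    "InequalityReport",
]


def _xlog2x_sum(P: np.ndarray, T: np.ndarray) -> float:
    # -sum P log2 T with the 0 * log 0 = 0 convention (P_ij = 0 => T_ij may be 0)
    mask = P > 0
    return float(-(P[mask] * np.log2(T[mask])).sum())


def er_first_order(model: TransitionModel) -> float:
    """Theoretical entropy rate -E(log2 T) of a first-order chain, in bits."""
    model.validate()
    return _xlog2x_sum(model.P, model.T)


def se_first_order(model: TransitionModel) -> float:
    """Approximate sample entropy -log2 E(T) of a first-order chain, in bits."""
    model.validate()
    s = float((model.P * model.T).sum())
    if s <= 0:
        raise ModelError("sum P_ij T_ij = 0: no transition mass")
    return float(-np.log2(s))


def zero_order_levels(p: np.ndarray) -> tuple[float, float]:
    """(Shannon, Renyi-2) entropy of a distribution ``p``, in bits.

    These are the zero-order Markov levels of the entropy-rate and
    sample-entropy curves respectively.
    """
    p = np.asarray(p, dtype=np.float64)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("p must be a probability vector")
    pos = p[p > 0]
    er0 = float(-(pos * np.log2(pos)).sum())
    se0 = float(-np.log2((p * p).sum()))
    return er0, se0


@dataclass
class InequalityReport:
    er1: float
    se1: float
    gap: float


def verify_inequality(model: TransitionModel) -> InequalityReport:
    """Jensen gap ER - SE >= 0 for a first-order model."""
    er1 = er_first_order(model)
    se1 = se_first_order(model)
    return InequalityReport(er1=er1, se1=se1, gap=er1 - se1)
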