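"""Markov chain surrogate sequences.

Surrogates implement the null hypotheses against which higher-order syntax
is tested: a zero-order surrogate shares the state distribution ``p`` of the
source sequence (equivalently ``T_ij = p_j``), a first-order surrogate
shares both ``p`` and the transition matrix ``T``.  Surrogates have the same
number of samples as the source unless an explicit length override is given
(e.g. to generate the long-surrogate variant that removes small-sample bias
in jump-sequence entropy rates).

Sampling is inverse-CDF: the initial state is drawn from ``p`` and each
subsequent state from the T row of the previous state, driven by a seeded
NumPy Generator.  The reproducibility contract is: identical (spec, seed)
=> identical sequence on the same NumPy stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GenerationError, ModelError
from .sequence import JUMP, MicrostateSequence, fit_transition_model

__all__ = ["SurrogateSpec", "make_spec", "sample", "sample_chain"]


@dataclass
class SurrogateSpec:
    """Fitted parameters and target shape of a Markov surrogate."""

    order: int
    p: np.ndarray
    T: np.ndarray
    length: int
    seed: int
    kind: str
    n_states: int
    subject_id: str | None = None

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "p": [float(x) for x in self.p],
            "T": [[float(x) for x in row] for row in self.T],
            "length": self.length,
            "seed": self.seed,
            "kind": self.kind,
            "K": self.n_states,
            "subject_id": self.subject_id,
        }


def make_spec(
    seq: MicrostateSequence,
    order: int,
    seed: int,
    length_override: int | None = None,
) -> SurrogateSpec:
    """Fit a surrogate specification from a sequence.

    Order 0 keeps only ``p`` (rows of T all equal p); order 1 keeps the full
    transition matrix.  Jump sequences admit only first-order surrogates:
    an order-0 draw would produce adjacent duplicates, which a jump sequence
    cannot contain.
    """
    if order not in (0, 1):
        raise ValueError("surrogate order must be 0 or 1")
    if order == 0 and seq.kind == JUMP:
        raise ValueError(
            "jump sequences only have first-order surrogates "
            "(an order-0 chain would revisit the same label consecutively)"
        )
    model = fit_transition_model(seq)
    if order == 0:
        T = np.tile(model.p, (seq.n_states, 1))
    else:
        T = model.T.copy()
    length = int(length_override) if length_override is not None else len(seq)
    if length < 2:
        raise ValueError("surrogate length must be at least 2")
    return SurrogateSpec(
        order=order,
        p=model.p.copy(),
        T=T,
        length=length,
        seed=int(seed),
        kind=seq.kind,
        n_states=seq.n_states,
        subject_id=seq.subject_id,
    )


def sample_chain(
    p: np.ndarray,
    T: np.ndarray,
    length: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a first-order Markov chain by inverse-CDF sampling.

    The initial state comes from ``p``; state i with an all-zero T row is a
    dead end and raises :class:`GenerationError` if visited.
    """
    p = np.asarray(p, dtype=np.float64)
    T = np.asarray(T, dtype=np.float64)
    K = p.size
    if T.shape != (K, K):
        raise ModelError("T must be K x K")
    row_sums = T.sum(axis=1)
    dead = row_sums <= 0
    cum = np.cumsum(T, axis=1)
    # guard against cumulative rounding: force the last edge to 1 for live rows
    cum[~dead, -1] = 1.0
    cp = np.cumsum(p)
    cp[-1] = 1.0
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    state = int(np.searchsorted(cp, u[0], side="right"))
    out[0] = state
    for t in range(1, length):
        if dead[state]:
            raise GenerationError(
                f"state {state} has an all-zero transition row; cannot continue"
            )
        state = int(np.searchsorted(cum[state], u[t], side="right"))
        out[t] = state
    return out


def sample(spec: SurrogateSpec, seed: int | None = None) -> MicrostateSequence:
    """Generate the surrogate sequence described by ``spec``.

    ``seed`` overrides ``spec.seed`` when given (convenient for drawing
    several surrogates from one fitted spec).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = sample_chain(spec.p, spec.T, spec.length, rng)
    return MicrostateSequence(
        labels,
        spec.n_states,
        kind=spec.kind,
        subject_id=spec.subject_id,
    )
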