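"""Synthetic label sequences with known syntactic order.

These generators provide positive and negative controls for the whole
pipeline without any external data:

* Markov chains of order 0, 1 and 2 (:func:`generate_chain`) — an order-m
  chain must sit exactly on the order-m baseline and below it for smaller
  conditioning depth;
* microstate-like continuous sequences (:func:`generate_microstate_like`)
  whose jump skeleton follows a given zero-diagonal matrix and whose run
  lengths are geometric (the maximum-entropy dwell law of a first-order
  chain), emulating the scale of resting-state recordings (K = 4, 1e5
  samples at 500 Hz, i.e. 200 s, collapsing to jump sequences of a few
  thousand labels);
* quasi-periodic cycles with substitution noise
  (:func:`generate_quasiperiodic`).

What these sequences do NOT emulate: topographic maps, volume-conduction
noise, non-stationary drift, or smoothing artefacts of real EEG pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .sequence import CONTINUOUS, JUMP, MicrostateSequence, labels_from_letters
from .surrogates import sample_chain

__all__ = [
    "GeneratorConfig",
    "generate_chain",
    "generate_microstate_like",
    "generate_quasiperiodic",
    "microstate_like_transition_matrix",
    "random_jump_matrix",
    "second_order_jump_table",
]


def _validate_stochastic(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=np.float64)
    if np.any(M < 0) or np.any(np.abs(M.sum(axis=-1) - 1.0) > 1e-8):
        raise ConfigError(f"{name} rows must be probability vectors")
    return M


@dataclass
class GeneratorConfig:
    """Parameters of a Markov chain of order 0, 1 or 2.

    ``p`` is required for order 0 and used as the initial distribution
    otherwise (default uniform); ``T`` (K x K) is required for order 1;
    ``T2`` (K x K x K, indexed [second-last, last, next]) for order 2, with
    optional ``initial_pair`` distribution (K x K, default from p x T
    collapse of T2 is NOT attempted — uniform pairs unless given).
    """

    n_states: int
    length: int
    order: int
    seed: int
    p: np.ndarray | None = None
    T: np.ndarray | None = None
    T2: np.ndarray | None = None
    initial_pair: np.ndarray | None = None
    kind: str = CONTINUOUS
    subject_id: str | None = None

    def __post_init__(self) -> None:
        if self.order not in (0, 1, 2):
            raise ConfigError("order must be 0, 1 or 2")
        if self.length < self.order + 1 or self.length < 1:
            raise ConfigError("length too short for the requested order")
        K = self.n_states
        if self.order == 0:
            if self.p is None:
                raise ConfigError("order 0 requires p")
        elif self.order == 1:
            if self.T is None:
                raise ConfigError("order 1 requires T")
            if np.asarray(self.T).shape != (K, K):
                raise ConfigError("T must be K x K")
        else:
            if self.T2 is None:
                raise ConfigError("order 2 requires T2")
            if np.asarray(self.T2).shape != (K, K, K):
                raise ConfigError("T2 must be K x K x K")


def generate_chain(config: GeneratorConfig) -> MicrostateSequence:
    """Sample a Markov chain of the configured order (seeded, reproducible)."""
    rng = np.random.default_rng(config.seed)
    K, n = config.n_states, config.length
    if config.order == 0:
        p = _validate_stochastic(config.p, "p")
        labels = rng.choice(K, size=n, p=p)
    elif config.order == 1:
        T = _validate_stochastic(config.T, "T")
        p = (
            _validate_stochastic(config.p, "p")
            if config.p is not None
            else np.full(K, 1.0 / K)
        )
        labels = sample_chain(p, T, n, rng)
    else:
        T2 = _validate_stochastic(config.T2, "T2")
        if config.initial_pair is not None:
            pair_p = _validate_stochastic(config.initial_pair.ravel(), "initial_pair")
        elif config.kind == JUMP:
            # uniform over off-diagonal pairs so the start respects the jump invariant
            pair_p = (1.0 - np.eye(K)).ravel() / (K * (K - 1))
        else:
            pair_p = np.full(K * K, 1.0 / (K * K))
        labels = np.empty(n, dtype=np.int64)
        first = int(rng.choice(K * K, p=pair_p))
        labels[0], labels[1] = divmod(first, K)
        cum = np.cumsum(T2, axis=-1)
        cum[..., -1] = 1.0
        u = rng.random(n)
        for t in range(2, n):
            labels[t] = int(
                np.searchsorted(cum[labels[t - 2], labels[t - 1]], u[t], side="right")
            )
    kind = config.kind
    if kind == JUMP and np.any(labels[1:] == labels[:-1]):
        raise ConfigError("generated chain violates the jump constraint; check diagonals")
    return MicrostateSequence(labels, K, kind=kind, subject_id=config.subject_id)


def generate_microstate_like(
    n_states: int,
    T_jump: np.ndarray,
    dwell_mean_samples: float,
    length: int,
    fs_hz: float,
    seed: int,
    dwell_law: str = "geometric",
) -> MicrostateSequence:
    """Continuous sequence with geometric dwell times over a jump skeleton.

    Runs alternate between states drawn from the zero-diagonal ``T_jump``
    and last a geometric number of samples with the given mean.  The result
    is equivalent to a first-order continuous chain with transition matrix
    ``(1 - 1/d) I + (1/d) T_jump``.  ``dwell_law="uniform"`` draws run
    lengths uniformly on [1, 2*d - 1] instead (same mean, non-geometric),
    which makes the continuous sequence non-Markovian while leaving the jump
    skeleton first-order — a useful negative control.
    """
    T_jump = _validate_stochastic(T_jump, "T_jump")
    if np.any(np.diag(T_jump) != 0):
        raise ConfigError("T_jump must have a zero diagonal")
    if dwell_mean_samples < 1:
        raise ConfigError("dwell_mean_samples must be >= 1")
    rng = np.random.default_rng(seed)
    n_runs = int(np.ceil(length / dwell_mean_samples * 1.5)) + 16
    states = sample_chain(np.full(n_states, 1.0 / n_states), T_jump, n_runs, rng)
    def draw_dwells(size: int) -> np.ndarray:
        if dwell_law == "geometric":
            return rng.geometric(1.0 / dwell_mean_samples, size=size)
        if dwell_law == "uniform":
            hi = max(1, int(round(2 * dwell_mean_samples - 1)))
            return rng.integers(1, hi + 1, size=size)
        raise ConfigError(f"unknown dwell_law {dwell_law!r}")

    dwells = draw_dwells(n_runs)
    while dwells.sum() < length:  # pragma: no cover - safety margin almost always enough
        extra = sample_chain(np.full(n_states, 1.0 / n_states), T_jump, n_runs, rng)
        states = np.concatenate([states, extra])
        dwells = np.concatenate([dwells, draw_dwells(n_runs)])
    labels = np.repeat(states, dwells)[:length]
    return MicrostateSequence(labels, n_states, kind=CONTINUOUS, sampling_rate_hz=fs_hz)


def generate_quasiperiodic(
    n_states: int,
    cycle: str | np.ndarray,
    noise_prob: float,
    length: int,
    seed: int,
) -> MicrostateSequence:
    """Repeat a jump-valid cycle, substituting random other labels with
    probability ``noise_prob`` per step.

    The noiseless case reproduces the cycle exactly (e.g. cycle ACDB of
    length 9 -> ACDBACDBA).  The result is kind "jump" when no adjacent
    duplicates occur (always true at noise 0), else "continuous".
    """
    if isinstance(cycle, str):
        cyc = labels_from_letters(cycle)
    else:
        cyc = np.asarray(cycle, dtype=np.int64)
    if cyc.size < 1 or np.any(cyc < 0) or np.any(cyc >= n_states):
        raise ConfigError("cycle labels must lie in [0, K-1]")
    if cyc.size > 1 and (np.any(cyc[1:] == cyc[:-1]) or cyc[0] == cyc[-1]):
        raise ConfigError("cycle must be jump-valid (no adjacent repeats, incl. wrap)")
    if not (0 <= noise_prob < 1):
        raise ConfigError("noise_prob must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    reps = int(np.ceil(length / cyc.size))
    labels = np.tile(cyc, reps)[:length]
    if noise_prob > 0:
        flip = rng.random(length) < noise_prob
        # uniform over the other K-1 labels
        offset = rng.integers(1, n_states, size=length)
        labels = np.where(flip, (labels + offset) % n_states, labels)
    kind = JUMP if (length < 2 or not np.any(labels[1:] == labels[:-1])) else CONTINUOUS
    return MicrostateSequence(labels, n_states, kind=kind)


def microstate_like_transition_matrix(
    n_states: int = 4,
    dwell_mean_samples: float = 12.0,
    T_jump: np.ndarray | None = None,
) -> np.ndarray:
    """Continuous-chain transition matrix (1 - 1/d) I + (1/d) T_jump.

    The default mean dwell of 12 samples reproduces the ~11.7 : 1 ratio
    between 1e5-sample continuous recordings and their few-thousand-label
    jump sequences seen in resting-state microstate data.
    """
    if T_jump is None:
        T_jump = random_jump_matrix(n_states, seed=0)
    T_jump = _validate_stochastic(T_jump, "T_jump")
    a = 1.0 / dwell_mean_samples
    return (1 - a) * np.eye(n_states) + a * T_jump


def random_jump_matrix(n_states: int, seed: int, concentration: float = 2.0) -> np.ndarray:
    """Random zero-diagonal row-stochastic matrix (Dirichlet rows)."""
    rng = np.random.default_rng(seed)
    T = np.zeros((n_states, n_states))
    for i in range(n_states):
        row = rng.dirichlet(np.full(n_states - 1, concentration))
        T[i, np.arange(n_states) != i] = row
    return T


def second_order_jump_table(n_states: int = 4, strength: float = 0.7) -> np.ndarray:
    """A genuinely second-order, zero-diagonal conditional table.

    The preferred successor after (i, j) is determined by the SECOND-last
    label i (the cyclically next state after i that differs from j) and is
    taken with probability ``strength``; the remaining mass spreads evenly
    over the other admissible labels.  Its first-order collapse is far less
    predictable, so ER(k) for k >= 2 falls well below the fitted first-order
    level — the positive control for higher-order syntax detection.
    """
    if not (0 < strength < 1):
        raise ConfigError("strength must lie in (0, 1)")
    K = n_states
    T2 = np.zeros((K, K, K))
    for i in range(K):
        for j in range(K):
            preferred = (i + 1) % K
            if preferred == j:
                preferred = (i + 2) % K
            others = [l for l in range(K) if l != j and l != preferred]
            T2[i, j, preferred] = strength
            for l in others:
                T2[i, j, l] = (1 - strength) / len(others)
    return T2
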