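"""Normalized syntax measures.

The raw ER/SE curves of two groups often differ by a near-constant offset
while sharing their shape.  The normalized measures rescale an empirical
entropy coefficient h against the theoretical zero-order (h0) and
first-order (h1) Markov levels of the same sequence so that

* sigma = 0  <=>  zero-order behaviour (continuous sequences only, h = h0),
* sigma = 1  <=>  first-order behaviour (h = h1),
* sigma > 1  <=>  more syntactic structure than a first-order chain (h < h1).

Continuous sequences use the two-point anchoring

    sigma_C(h) = log(h / h0) / log(h1 / h0),

which is invariant to the logarithm base.  Jump sequences have no zero-order
model (adjacent labels cannot repeat), so only the first-order anchor exists:

    sigma_J(h) = 1 + log2(h1 / h).

sigma_J is base-dependent; base 2 is fixed so one sigma unit above 1 means
one extra bit of predictability relative to the first-order level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .entropy import SyntaxProfile
from .errors import DomainError
from .sequence import CONTINUOUS, JUMP

__all__ = ["sigma_continuous", "sigma_jump", "normalized_profile", "NormalizedProfile"]


def _check_baselines_continuous(h0: float, h1: float) -> None:
    if not (0 < h1 < h0):
        raise DomainError(f"need 0 < h1 < h0, got h0={h0}, h1={h1}")


def sigma_continuous(h: float, h0: float, h1: float) -> float:
    """Normalized syntax of a continuous sequence; domain 0 < h <= h0."""
    _check_baselines_continuous(h0, h1)
    if not (0 < h <= h0):
        raise DomainError(f"h must lie in (0, h0]; got h={h}, h0={h0}")
    return math.log(h / h0) / math.log(h1 / h0) + 0.0  # normalize -0.0


def sigma_jump(h: float, h1: float) -> float:
    """Normalized syntax of a jump sequence; domain 0 < h <= h1."""
    if h1 <= 0:
        raise DomainError(f"h1 must be positive, got {h1}")
    if h <= 0:
        raise DomainError(f"h must be positive, got {h}")
    return 1.0 + math.log2(h1 / h)


@dataclass
class NormalizedProfile:
    """sigma values over k = 1..kmax for one metric (ER or SE)."""

    metric: str
    kind: str
    h0: float | None
    h1: float
    sigma: np.ndarray  # index 0 <-> k = 1
    k_values: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "kind": self.kind,
            "h0": self.h0,
            "h1": self.h1,
            "k": [int(k) for k in self.k_values],
            "sigma": [None if np.isnan(s) else float(s) for s in self.sigma],
            "warnings": list(self.warnings),
        }


def normalized_profile(
    profile: SyntaxProfile, metric: str, kind: str | None = None
) -> NormalizedProfile:
    """Apply sigma_C or sigma_J to the empirical curve of a profile.

    ``h0``/``h1`` are the closed-form Markov levels stored in the profile
    (computed from the sequence's own fitted p and T).  Inside a profile the
    domain checks are relaxed: sampling noise can push an empirical h a
    fraction of a percent above its theoretical anchor (the formulas then
    return values marginally below 0 resp. 1, which is the honest answer).
    Non-finite entropy slots map to NaN with a warning; h = 0 (perfectly
    predictable input) maps to +inf with a warning rather than an error.
    """
    metric = metric.upper()
    if metric not in ("ER", "SE"):
        raise ValueError("metric must be 'ER' or 'SE'")
    if kind is None:
        kind = profile.kind
    if kind not in (CONTINUOUS, JUMP):
        raise ValueError("kind must be 'continuous' or 'jump'")

    if metric == "ER":
        h0, h1 = profile.er_theory_mc0, profile.er_theory_mc1
        values = profile.er[1:]
    else:
        h0, h1 = profile.se_theory_mc0, profile.se_theory_mc1
        values = profile.se[1:]

    warn_list: list[str] = []
    if kind == CONTINUOUS:
        _check_baselines_continuous(h0, h1)
        denom = math.log(h1 / h0)
    elif h1 <= 0:
        raise DomainError(f"h1 must be positive, got {h1}")

    k_values = np.arange(1, profile.kmax + 1)
    sigma = np.full(values.shape, np.nan)
    for i, h in enumerate(values):
        k = i + 1
        if not np.isfinite(h):
            warn_list.append(f"sigma undefined at k={k}: entropy is {h}")
            continue
        if h <= 0:
            sigma[i] = np.inf
            warn_list.append(
                f"sigma at k={k} is +inf: entropy 0 (perfectly predictable input)"
            )
            continue
        if kind == CONTINUOUS:
            sigma[i] = math.log(h / h0) / denom
        else:
            sigma[i] = 1.0 + math.log2(h1 / h)

    for w in warn_list:
        warnings.warn(w, stacklevel=2)
    return NormalizedProfile(
        metric=metric,
        kind=kind,
        h0=h0 if kind == CONTINUOUS else None,
        h1=h1,
        sigma=sigma,
        k_values=k_values,
        warnings=warn_list,
    )
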