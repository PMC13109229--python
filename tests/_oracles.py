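"""Independent brute-force oracles used to pin down the estimators.

These deliberately use naive enumeration (O(n^2) pair scans, explicit word
dictionaries) and stay independent of the histogram/coding implementation
they check.
"""

from collections import Counter
from math import log2

import numpy as np


def naive_sample_entropy(labels, k):
    """SE(k) by exhaustive enumeration of all unordered position pairs.

    Positions t run over starts of k-words that still have a successor.
    Returns (A, B): matching pairs whose successors also match, and all
    matching pairs.
    """
    labels = list(labels)
    n = len(labels)
    starts = range(n - k)  # word labels[t:t+k], successor labels[t+k]
    A = B = 0
    for t in starts:
        for s in starts:
            if s <= t:
                continue
            if labels[t : t + k] == labels[s : s + k]:
                B += 1
                if labels[t + k] == labels[s + k]:
                    A += 1
    return A, B


def naive_entropy_rate(labels, k):
    """ER(k) by direct evaluation of the conditional-entropy sum over an
    explicitly enumerated (k+1)-word joint distribution."""
    labels = list(labels)
    n = len(labels)
    if k == 0:
        counts = Counter(labels)
        return -sum(c / n * log2(c / n) for c in counts.values())
    joint = Counter(tuple(labels[t : t + k + 1]) for t in range(n - k))
    prefix = Counter(tuple(w[:-1]) for w in joint.elements())
    total = sum(joint.values())
    er = 0.0
    for w, c in joint.items():
        pr_joint = c / total
        pr_cond = c / prefix[w[:-1]]
        er -= pr_joint * log2(pr_cond)
    return er


def random_stochastic_matrix(K, rng):
    """Row-stochastic matrix with Dirichlet(1) rows."""
    return rng.dirichlet(np.ones(K), size=K)
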