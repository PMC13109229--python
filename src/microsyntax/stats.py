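"""Group-level statistics for syntax curves.

Within a group, per-subject entropy coefficients are compared against their
matched Markov surrogates with the Wilcoxon signed-rank test (dependent
samples).  Between two groups (possibly of unequal size) the Mann-Whitney
U-test is used.  Within one family — one (metric, sequence kind, comparison)
triple — the raw p-values are corrected across the tested word lengths
(default k = 1..6) with the Benjamini-Hochberg false-discovery-rate
procedure; families are never pooled across metrics or kinds.  Significance
is declared at alpha = 0.05 on the adjusted values, two-sided throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupComparisonResult",
    "paired_surrogate_test",
    "group_compare",
    "bh_fdr",
]

DEFAULT_ALPHA = 0.05


def bh_fdr(p_values: np.ndarray, alpha: float = DEFAULT_ALPHA) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, reject flags at ``alpha``).  Adjusted values
    are monotone over the order statistics and never below the raw values.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


@dataclass
class GroupComparisonResult:
    """Per-k test results for one (metric, kind, comparison) family."""

    metric: str
    kind: str
    comparison: str
    k_values: np.ndarray
    statistic: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    significant: np.ndarray
    alpha: float = DEFAULT_ALPHA
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def clean(arr):
            return [None if not np.isfinite(x) else float(x) for x in arr]

        return {
            "metric": self.metric,
            "kind": self.kind,
            "comparison": self.comparison,
            "alpha": self.alpha,
            "k": [int(k) for k in self.k_values],
            "statistic": clean(self.statistic),
            "p_raw": clean(self.p_raw),
            "p_fdr": clean(self.p_fdr),
            "significant": [bool(s) for s in self.significant],
            "warnings": list(self.warnings),
        }


def _finalize(
    metric: str,
    kind: str,
    comparison: str,
    k_values: np.ndarray,
    stat: np.ndarray,
    p_raw: np.ndarray,
    alpha: float,
    warn_list: list[str],
) -> GroupComparisonResult:
    """BH-adjust the valid slots of a family; degenerate slots stay NaN."""
    p_fdr = np.full_like(p_raw, np.nan)
    significant = np.zeros(p_raw.size, dtype=bool)
    valid = np.isfinite(p_raw)
    if valid.any():
        adj, rej = bh_fdr(p_raw[valid], alpha)
        p_fdr[valid] = adj
        significant[valid] = rej
    result = GroupComparisonResult(
        metric=metric,
        kind=kind,
        comparison=comparison,
        k_values=k_values,
        statistic=stat,
        p_raw=p_raw,
        p_fdr=p_fdr,
        significant=significant,
        alpha=alpha,
        warnings=warn_list,
    )
    for w in warn_list:
        warnings.warn(w, stacklevel=3)
    return result


def _as_matrix(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be a 2-D (subjects x k) array")
    return arr


def paired_surrogate_test(
    real: np.ndarray,
    surr: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    k_values: np.ndarray | None = None,
    metric: str = "ER",
    kind: str = "continuous",
) -> GroupComparisonResult:
    """Wilcoxon signed-rank test of real vs surrogate values, per k.

    ``real`` and ``surr`` are (n_subjects, n_k) arrays paired by row.  Pairs
    with a missing value (NaN/inf, e.g. undefined SE slots) are dropped with
    a warning.  A k whose differences are all zero (or with no usable pairs)
    is marked degenerate (NaN p) and excluded from the FDR family.
    """
    real = _as_matrix(real, "real")
    surr = _as_matrix(surr, "surr")
    if real.shape != surr.shape:
        raise ValueError("real and surr must have identical shapes (paired data)")
    n_subj, n_k = real.shape
    warn_list: list[str] = []
    if n_subj < 5:
        warn_list.append(f"only {n_subj} paired subjects; Wilcoxon test is unreliable")
    if k_values is None:
        k_values = np.arange(1, n_k + 1)
    stat = np.full(n_k, np.nan)
    p_raw = np.full(n_k, np.nan)
    for j in range(n_k):
        ok = np.isfinite(real[:, j]) & np.isfinite(surr[:, j])
        dropped = n_subj - int(ok.sum())
        if dropped:
            warn_list.append(f"k={k_values[j]}: dropped {dropped} pairs with missing values")
        x, y = real[ok, j], surr[ok, j]
        if x.size < 2 or np.all(x == y):
            warn_list.append(f"k={k_values[j]}: degenerate (all differences zero or too few pairs)")
            continue
        res = sps.wilcoxon(x, y, alternative="two-sided", zero_method="wilcox")
        stat[j], p_raw[j] = res.statistic, res.pvalue
    return _finalize(metric, kind, "real-vs-surrogate", np.asarray(k_values), stat, p_raw, alpha, warn_list)


def group_compare(
    group_a: np.ndarray,
    group_b: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    k_values: np.ndarray | None = None,
    metric: str = "ER",
    kind: str = "continuous",
) -> GroupComparisonResult:
    """Mann-Whitney U-test between two independent groups, per k.

    Group sizes may differ.  Missing values are dropped per k with a
    warning; a k leaving fewer than 2 subjects in either group is marked
    degenerate.
    """
    a = _as_matrix(group_a, "group_a")
    b = _as_matrix(group_b, "group_b")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the same k grid")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    n_k = a.shape[1]
    warn_list: list[str] = []
    if k_values is None:
        k_values = np.arange(1, n_k + 1)
    stat = np.full(n_k, np.nan)
    p_raw = np.full(n_k, np.nan)
    for j in range(n_k):
        x = a[np.isfinite(a[:, j]), j]
        y = b[np.isfinite(b[:, j]), j]
        dropped = (a.shape[0] - x.size) + (b.shape[0] - y.size)
        if dropped:
            warn_list.append(f"k={k_values[j]}: dropped {dropped} subjects with missing values")
        if x.size < 2 or y.size < 2:
            warn_list.append(f"k={k_values[j]}: degenerate (too few subjects)")
            continue
        res = sps.mannwhitneyu(x, y, alternative="two-sided")
        stat[j], p_raw[j] = res.statistic, res.pvalue
    return _finalize(metric, kind, "group-vs-group", np.asarray(k_values), stat, p_raw, alpha, warn_list)
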