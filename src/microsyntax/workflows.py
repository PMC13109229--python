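"""End-to-end analysis workflows behind the command-line interface.

These functions orchestrate the per-subject pipeline the way a group study
uses it: fit first-order models, compute ER/SE profiles and normalized
sigma curves, draw matched Markov surrogates, and run the within-group
(real vs surrogate, Wilcoxon) and between-group (Mann-Whitney) tests with
BH-FDR correction per (metric, kind, comparison) family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .entropy import SyntaxProfile, syntax_profile
from .normalize import normalized_profile
from .sequence import CONTINUOUS, JUMP, MicrostateSequence, to_jump_sequence
from .stats import GroupComparisonResult, group_compare, paired_surrogate_test
from .surrogates import make_spec, sample

__all__ = ["analyze_sequence", "compare_groups", "subject_metrics", "GroupPanel"]

METRICS = ("ER", "SE")


def analyze_sequence(
    seq: MicrostateSequence,
    kmax: int = 6,
    drop_edge_segments: bool = True,
) -> dict:
    """Profile + normalized sigma report for one sequence.

    Continuous inputs additionally get a panel for their derived jump
    sequence (edge runs removed by default before collapsing).
    """
    panels = {}
    for kind, s in _panels(seq, drop_edge_segments):
        profile = syntax_profile(s, kmax)
        panels[kind] = {
            "profile": profile.to_dict(),
            "sigma": {m: normalized_profile(profile, m).to_dict() for m in METRICS},
        }
    return {
        "subject_id": seq.subject_id,
        "K": seq.n_states,
        "kind": seq.kind,
        "n_samples": len(seq),
        "kmax": kmax,
        "drop_edge_segments": drop_edge_segments,
        "label_mapping": {chr(ord("A") + i): i for i in range(seq.n_states)},
        "panels": panels,
    }


def _panels(seq: MicrostateSequence, drop_edge_segments: bool):
    yield seq.kind, seq
    if seq.kind == CONTINUOUS:
        yield JUMP, to_jump_sequence(seq, drop_edge_segments=drop_edge_segments)


def subject_metrics(
    seqs: list[MicrostateSequence],
    kmax: int,
    n_surrogates: int,
    rng: np.random.Generator,
    drop_edge_segments: bool = True,
) -> dict:
    """Per-subject ER/SE/sigma matrices and their surrogate counterparts.

    Returns a nested dict ``out[kind][name]`` of (n_subjects, kmax) arrays
    (k = 1..kmax columns), with ``name`` in er / se / sigma_er / sigma_se /
    er_surr / se_surr.  One first-order surrogate of equal length is drawn
    per subject by default; with ``n_surrogates > 1`` the surrogate value is
    the mean across draws.
    """
    out: dict[str, dict[str, np.ndarray]] = {}
    for seq in seqs:
        for kind, s in _panels(seq, drop_edge_segments):
            profile = syntax_profile(s, kmax)
            spec = make_spec(s, order=1, seed=0)
            surr_er = np.zeros(kmax)
            surr_se = np.zeros(kmax)
            for _ in range(n_surrogates):
                sprof = syntax_profile(
                    sample(spec, seed=int(rng.integers(2**31))), kmax
                )
                surr_er += sprof.er[1:]
                surr_se += sprof.se[1:]
            rows = out.setdefault(kind, {})
            for name, vals in (
                ("er", profile.er[1:]),
                ("se", profile.se[1:]),
                ("sigma_er", normalized_profile(profile, "ER").sigma),
                ("sigma_se", normalized_profile(profile, "SE").sigma),
                ("er_surr", surr_er / n_surrogates),
                ("se_surr", surr_se / n_surrogates),
            ):
                rows.setdefault(name, []).append(np.asarray(vals, dtype=float))
    return {
        kind: {name: np.vstack(rows) for name, rows in named.items()}
        for kind, named in out.items()
    }


@dataclass
class GroupPanel:
    kind: str
    metric: str
    within_a: GroupComparisonResult
    within_b: GroupComparisonResult
    between_raw: GroupComparisonResult
    between_sigma: GroupComparisonResult


def compare_groups(
    seqs_a: list[MicrostateSequence],
    seqs_b: list[MicrostateSequence],
    group_a: str = "A",
    group_b: str = "B",
    kmax: int = 6,
    n_surrogates: int = 1,
    alpha: float = 0.05,
    seed: int = 0,
    drop_edge_segments: bool = True,
) -> tuple[dict, pd.DataFrame]:
    """Full two-cohort comparison (the four-panel figure workflow).

    For every sequence kind and metric: Wilcoxon real-vs-surrogate within
    each group, Mann-Whitney between groups on raw coefficients and on the
    normalized sigma curves, each family BH-corrected across k = 1..kmax.
    Returns (report dict, tidy DataFrame).
    """
    rng = np.random.default_rng(seed)
    mat_a = subject_metrics(seqs_a, kmax, n_surrogates, rng, drop_edge_segments)
    mat_b = subject_metrics(seqs_b, kmax, n_surrogates, rng, drop_edge_segments)
    panels: list[GroupPanel] = []
    for kind in mat_a:
        if kind not in mat_b:
            continue
        for metric in METRICS:
            key = metric.lower()
            panels.append(
                GroupPanel(
                    kind=kind,
                    metric=metric,
                    within_a=paired_surrogate_test(
                        mat_a[kind][key], mat_a[kind][f"{key}_surr"],
                        alpha=alpha, metric=metric, kind=kind,
                    ),
                    within_b=paired_surrogate_test(
                        mat_b[kind][key], mat_b[kind][f"{key}_surr"],
                        alpha=alpha, metric=metric, kind=kind,
                    ),
                    between_raw=group_compare(
                        mat_a[kind][key], mat_b[kind][key],
                        alpha=alpha, metric=metric, kind=kind,
                    ),
                    between_sigma=group_compare(
                        mat_a[kind][f"sigma_{key}"], mat_b[kind][f"sigma_{key}"],
                        alpha=alpha, metric=metric, kind=kind,
                    ),
                )
            )
    rows = []
    report: dict = {
        "group_a": group_a,
        "group_b": group_b,
        "n_a": len(seqs_a),
        "n_b": len(seqs_b),
        "kmax": kmax,
        "n_surrogates": n_surrogates,
        "alpha": alpha,
        "seed": seed,
        "drop_edge_segments": drop_edge_segments,
        "panels": [],
    }
    for panel in panels:
        entry = {"kind": panel.kind, "metric": panel.metric}
        for name, res in (
            (f"within_{group_a}", panel.within_a),
            (f"within_{group_b}", panel.within_b),
            ("between_raw", panel.between_raw),
            ("between_sigma", panel.between_sigma),
        ):
            entry[name] = res.to_dict()
            for j, k in enumerate(res.k_values):
                rows.append(
                    {
                        "kind": panel.kind,
                        "metric": panel.metric,
                        "comparison": name,
                        "k": int(k),
                        "statistic": res.statistic[j],
                        "p_raw": res.p_raw[j],
                        "p_fdr": res.p_fdr[j],
                        "significant": bool(res.significant[j]),
                    }
                )
        report["panels"].append(entry)
    return report, pd.DataFrame(rows)
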