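"""Mutation-class group comparison: differential expression, signatures,
cross-cohort concordance and disease-free survival.

Patients with a single driver-gene mutation are partitioned by protein
consequence into five groups — extensions and truncations in the +1 and
-1 frames, and all other mutations.  The dominant group (+1-frame
extensions) is compared against the union of the remaining mutant groups:
per-gene median fold change with a two-sided Wilcoxon rank-sum p-value,
a top-k signature, direction concordance between two cohorts' results,
and a Kaplan–Meier / log-rank (Mantel–Cox) survival comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .consequence import ConsequenceClass, ProteinConsequence
from .io import ClinicalRecord, Cohort

__all__ = [
    "GroupLabel",
    "GroupAssignment",
    "DifferentialResult",
    "Signature",
    "SurvivalResult",
    "assign_groups",
    "rank_sum_test",
    "median_fold_change",
    "differential_expression",
    "derive_signature",
    "sign_concordance",
    "logrank_test",
    "survival_by_group",
]


class GroupLabel(str, Enum):
    ext_plus1 = "ext_plus1"
    ext_minus1 = "ext_minus1"
    trunc_plus1 = "trunc_plus1"
    trunc_minus1 = "trunc_minus1"
    other_mutant = "other_mutant"


@dataclass
class GroupAssignment:
    """Per-sample labels; the comparison is ext_plus1 vs. everything else."""

    labels: dict[str, GroupLabel]

    @property
    def case_samples(self) -> list[str]:
        return sorted(s for s, l in self.labels.items() if l == GroupLabel.ext_plus1)

    @property
    def control_samples(self) -> list[str]:
        return sorted(s for s, l in self.labels.items() if l != GroupLabel.ext_plus1)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {l.value: 0 for l in GroupLabel}
        for l in self.labels.values():
            out[l.value] += 1
        return out


@dataclass(frozen=True)
class DifferentialResult:
    gene: str
    median_case: float
    median_control: float
    fold_change: float
    direction: str  # up | down | flat
    p_value: float

    @property
    def log2_fold_change(self) -> float:
        if self.fold_change <= 0:
            return float("-inf")
        return math.log2(self.fold_change)


@dataclass
class Signature:
    genes: list[str]
    directions: list[str]
    k: int
    source_cohort: str = ""

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate genes in signature")
        if len(self.genes) > self.k:
            raise ValueError("signature larger than k")


@dataclass
class SurvivalResult:
    logrank_chi2: float
    p_value: float
    n_events: dict[str, int]
    n_subjects: dict[str, int]
    km_curves: dict[str, pd.DataFrame]  # columns: time, survival


def assign_groups(
    consequences: Mapping[str, ProteinConsequence]
) -> GroupAssignment:
    """Deterministic group label per sample from its protein consequence."""
    labels: dict[str, GroupLabel] = {}
    for sample, pc in consequences.items():
        if pc.consequence_class == ConsequenceClass.frameshift_extension:
            labels[sample] = (
                GroupLabel.ext_plus1 if pc.frame_shift == 1 else GroupLabel.ext_minus1
            )
        elif pc.consequence_class == ConsequenceClass.frameshift_truncation:
            labels[sample] = (
                GroupLabel.trunc_plus1
                if pc.frame_shift == 1
                else GroupLabel.trunc_minus1
            )
        else:
            labels[sample] = GroupLabel.other_mutant
    return GroupAssignment(labels=labels)


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 12
) -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann–Whitney rank-sum test.

    Exact enumeration when the combined sample size is at most
    ``exact_max_n`` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  Returns the
    Mann–Whitney U of ``x`` and the two-sided p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    if x.size + y.size <= exact_max_n and no_ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def median_fold_change(
    x: Sequence[float], y: Sequence[float], pseudocount: float = 0.0
) -> tuple[float, str]:
    """(median(x)+c) / (median(y)+c) and its direction (up/down/flat)."""
    mx = float(np.median(np.asarray(x, dtype=float))) + pseudocount
    my = float(np.median(np.asarray(y, dtype=float))) + pseudocount
    if mx == my:
        return 1.0, "flat"
    if my == 0.0:
        return float("inf"), "up"
    fc = mx / my
    return fc, ("up" if fc > 1 else "down")


def differential_expression(
    cohort: Cohort,
    assignment: GroupAssignment,
    genes: Sequence[str] | None = None,
    pseudocount: float = 0.0,
) -> list[DifferentialResult]:
    """Per-gene ext_plus1-vs-rest comparison over the assigned samples."""
    case = assignment.case_samples
    control = assignment.control_samples
    if not case or not control:
        raise ValueError("both case and control groups must be non-empty")
    gene_list = list(genes) if genes is not None else cohort.expression.genes
    results = []
    for gene in gene_list:
        xv = cohort.expression.gene_values(gene, case)
        yv = cohort.expression.gene_values(gene, control)
        fc, direction = median_fold_change(xv, yv, pseudocount)
        _, p = rank_sum_test(xv, yv)
        results.append(
            DifferentialResult(
                gene=gene,
                median_case=float(np.median(xv)),
                median_control=float(np.median(yv)),
                fold_change=fc,
                direction=direction,
                p_value=p,
            )
        )
    return results


def derive_signature(
    results: Sequence[DifferentialResult], k: int = 50, source_cohort: str = ""
) -> Signature:
    """Top-k genes by ascending p, ties by |log2 FC| descending, then gene id."""
    if k <= 0:
        raise ValueError("k must be positive")
    if not results:
        raise ValueError("no differential results to rank")

    def sort_key(r: DifferentialResult):
        lfc = abs(r.log2_fold_change) if np.isfinite(r.log2_fold_change) else np.inf
        return (r.p_value, -lfc, r.gene)

    ranked = sorted(results, key=sort_key)[:k]
    return Signature(
        genes=[r.gene for r in ranked],
        directions=[r.direction for r in ranked],
        k=k,
        source_cohort=source_cohort,
    )


def sign_concordance(
    a: Sequence[DifferentialResult], b: Sequence[DifferentialResult]
) -> tuple[int, int]:
    """(shared genes, shared genes with the same direction).

    A flat direction counts as concordant only when flat in both.
    """
    da = {r.gene: r.direction for r in a}
    db = {r.gene: r.direction for r in b}
    shared = sorted(set(da) & set(db))
    concordant = sum(1 for g in shared if da[g] == db[g])
    return len(shared), concordant


def logrank_test(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence[str],
) -> SurvivalResult:
    """Two-group log-rank (Mantel–Cox) test with Kaplan–Meier curves.

    ``groups`` must contain exactly two distinct labels, each with at
    least one subject; at least one event overall is required.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    if len(labels) != 2:
        raise ValueError(f"expected exactly two groups, got {labels}")
    masks = {l: groups == l for l in labels}
    for l in labels:
        if masks[l].sum() == 0:
            raise ValueError(f"group {l!r} has no subjects")
    if events.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(
        times[masks[labels[0]]],
        times[masks[labels[1]]],
        event_observed_A=events[masks[labels[0]]],
        event_observed_B=events[masks[labels[1]]],
    )
    curves = {}
    for l in labels:
        kmf = KaplanMeierFitter()
        kmf.fit(times[masks[l]], events[masks[l]], label=l)
        sf = kmf.survival_function_.reset_index()
        sf.columns = ["time", "survival"]
        curves[l] = sf
    return SurvivalResult(
        logrank_chi2=float(res.test_statistic),
        p_value=float(res.p_value),
        n_events={l: int(events[masks[l]].sum()) for l in labels},
        n_subjects={l: int(masks[l].sum()) for l in labels},
        km_curves=curves,
    )


def survival_by_group(
    clinical: Sequence[ClinicalRecord],
    assignment: GroupAssignment,
) -> SurvivalResult:
    """DFS comparison of ext_plus1 vs. all other mutant samples."""
    case = set(assignment.case_samples)
    control = set(assignment.control_samples)
    times, events, grp = [], [], []
    for rec in clinical:
        if rec.sample_id in case:
            grp.append("ext_plus1")
        elif rec.sample_id in control:
            grp.append("other")
        else:
            continue
        times.append(rec.dfs_time)
        events.append(rec.dfs_event)
    return logrank_test(times, events, grp)
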