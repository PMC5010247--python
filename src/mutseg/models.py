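"""Model/Results interface over the pipeline stages.

Each analysis is exposed as a model object constructed from data whose
``fit()`` returns a results object carrying the estimates and a
``summary()`` table, in the style of statistical modelling packages:

* :class:`SegmentationModel` — changepoint model for one ordered series;
* :class:`TranscriptomeScan` — response-gene scan of a whole cohort;
* :class:`GroupComparison` — consequence groups, differential expression,
  signature and survival for a driver gene.

The underlying operations remain available as plain functions in the
stage modules; these classes orchestrate them and collect outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .consequence import (
    ProteinConsequence,
    TranscriptModel,
    classify_consequence,
    consequence_table,
)
from .groups import (
    DifferentialResult,
    GroupAssignment,
    Signature,
    SurvivalResult,
    assign_groups,
    derive_signature,
    differential_expression,
    survival_by_group,
)
from .io import Cohort, single_mutation_patients
from .response import (
    BreakpointDensity,
    ResponseGeneRecord,
    ScanSummary,
    breakpoint_density,
    records_to_frame,
    scan_transcriptome,
)
from .segmentation import (
    OrderedSeries,
    SegmentationParams,
    SegmentationResult,
    segment,
)

__all__ = [
    "SegmentationModel",
    "SegmentationResults",
    "TranscriptomeScan",
    "ScanResults",
    "GroupComparison",
    "GroupResults",
]


class SegmentationModel:
    """Changepoint model for a single ordered series."""

    def __init__(
        self,
        series: OrderedSeries | Sequence[float],
        params: SegmentationParams | None = None,
    ):
        self.series = series
        self.params = params or SegmentationParams()

    def fit(self) -> "SegmentationResults":
        return SegmentationResults(segment(self.series, self.params), self.series)


@dataclass
class SegmentationResults:
    result: SegmentationResult
    series: OrderedSeries | Sequence[float]

    @property
    def breakpoints(self) -> list[int]:
        return self.result.breakpoints

    @property
    def n_breakpoints(self) -> int:
        return self.result.n_breakpoints

    def summary(self) -> str:
        lines = [
            "Segmentation results",
            f"  segments:    {len(self.result.segments)}",
            f"  breakpoints: {self.result.breakpoints}",
            f"  top |Z|:     {self.result.statistic_T:.3f}",
        ]
        for seg, p in zip(
            self.result.segments, self.result.split_pvalues + [None] * 10
        ):
            lines.append(
                f"    [{seg.start:>4}, {seg.end:>4}]  mean={seg.mean:.2f}"
            )
        if self.result.split_pvalues:
            lines.append(
                "  split p-values: "
                + ", ".join(f"{p:.4g}" for p in self.result.split_pvalues)
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Ranked series with fitted segment means (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        y = np.asarray(
            self.series.values
            if isinstance(self.series, OrderedSeries)
            else self.series,
            dtype=float,
        )
        ax.plot(np.arange(1, len(y) + 1), y, "o", ms=3, alpha=0.6)
        for seg in self.result.segments:
            ax.hlines(seg.mean, seg.start, seg.end, color="C3", lw=2)
        ax.set_xlabel("sample (mutation-position order)")
        ax.set_ylabel("expression midrank")
        return ax


class TranscriptomeScan:
    """Response-gene scan: every expressed gene against one driver."""

    def __init__(
        self,
        cohort: Cohort,
        driver: str,
        params: SegmentationParams | None = None,
        genes: Sequence[str] | None = None,
        min_nonzero_fraction: float = 0.2,
    ):
        self.cohort = cohort
        self.driver = driver
        self.params = params or SegmentationParams()
        self.genes = genes
        self.min_nonzero_fraction = min_nonzero_fraction

    def fit(self) -> "ScanResults":
        records, summary = scan_transcriptome(
            self.cohort,
            self.driver,
            self.params,
            genes=self.genes,
            min_nonzero_fraction=self.min_nonzero_fraction,
        )
        return ScanResults(records=records, scan_summary=summary, cohort=self.cohort)


@dataclass
class ScanResults:
    records: list[ResponseGeneRecord]
    scan_summary: ScanSummary
    cohort: Cohort

    @property
    def response_genes(self) -> list[str]:
        return [r.gene for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    def breakpoint_density(
        self, gene_span: tuple[float, float], **kwargs
    ) -> BreakpointDensity:
        return breakpoint_density(self.records, gene_span, **kwargs)

    def summary(self) -> str:
        s = self.scan_summary
        return "\n".join(
            [
                f"Response-gene scan: driver {s.driver}",
                f"  mutation-bearing samples: {s.n_samples}",
                f"  genes scanned:  {s.n_genes_total} "
                f"({s.n_genes_filtered} filtered, {s.n_genes_segmented} segmented)",
                f"  response genes: {s.n_response_genes}",
            ]
        )


class GroupComparison:
    """Extension-vs-other analysis for one driver gene.

    Classifies each single-mutation patient's variant on the transcript,
    assigns consequence groups, and on fit() computes the differential
    table, the top-k signature and (when clinical data are present) the
    DFS log-rank comparison.
    """

    def __init__(
        self,
        cohort: Cohort,
        transcript: TranscriptModel,
        driver: str,
        signature_size: int = 50,
        pseudocount: float = 0.0,
    ):
        self.cohort = cohort
        self.transcript = transcript
        self.driver = driver
        self.signature_size = signature_size
        self.pseudocount = pseudocount

    def fit(self) -> "GroupResults":
        singles = single_mutation_patients(self.cohort.mutations, self.driver)
        if not singles:
            raise ValueError(f"no single-mutation samples for {self.driver!r}")
        consequences = {
            sid: classify_consequence(self.transcript, m)
            for sid, m in singles.items()
        }
        assignment = assign_groups(consequences)
        differential: list[DifferentialResult] = []
        signature: Signature | None = None
        survival: SurvivalResult | None = None
        if assignment.case_samples and assignment.control_samples:
            differential = differential_expression(
                self.cohort, assignment, pseudocount=self.pseudocount
            )
            signature = derive_signature(
                differential, k=self.signature_size, source_cohort=self.driver
            )
            if self.cohort.clinical:
                try:
                    survival = survival_by_group(self.cohort.clinical, assignment)
                except ValueError:
                    survival = None
        return GroupResults(
            consequences=consequences,
            assignment=assignment,
            differential=differential,
            signature=signature,
            survival=survival,
            consequence_frame=consequence_table(
                list(singles.values()), self.transcript
            ),
        )


@dataclass
class GroupResults:
    consequences: Mapping[str, ProteinConsequence]
    assignment: GroupAssignment
    differential: list[DifferentialResult]
    signature: Signature | None
    survival: SurvivalResult | None
    consequence_frame: pd.DataFrame

    def differential_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [r.gene for r in self.differential],
                "median_case": [r.median_case for r in self.differential],
                "median_control": [r.median_control for r in self.differential],
                "fold_change": [r.fold_change for r in self.differential],
                "log2_fold_change": [r.log2_fold_change for r in self.differential],
                "direction": [r.direction for r in self.differential],
                "p_value": [r.p_value for r in self.differential],
            }
        )

    def summary(self) -> str:
        counts = self.assignment.counts()
        lines = ["Group comparison (ext_plus1 vs. other mutants)"]
        lines.append(
            "  groups: "
            + ", ".join(f"{k}={v}" for k, v in counts.items() if v)
        )
        if self.differential:
            top = sorted(self.differential, key=lambda r: r.p_value)[:5]
            lines.append("  top differential genes:")
            for r in top:
                lines.append(
                    f"    {r.gene:>10}  FC={r.fold_change:6.3f} "
                    f"({r.direction:4s})  p={r.p_value:.3g}"
                )
        if self.survival is not None:
            lines.append(
                f"  DFS log-rank: chi2={self.survival.logrank_chi2:.3f}, "
                f"p={self.survival.p_value:.4f} "
                f"(events: {self.survival.n_events})"
            )
        return "\n".join(lines)

    def plot_km(self, ax=None):
        """Kaplan–Meier curves of the two comparison groups."""
        import matplotlib.pyplot as plt

        if self.survival is None:
            raise ValueError("no survival result to plot")
        if ax is None:
            _, ax = plt.subplots()
        for label, curve in self.survival.km_curves.items():
            ax.step(curve["time"], curve["survival"], where="post", label=label)
        ax.set_xlabel("months")
        ax.set_ylabel("disease-free survival")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax
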