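"""Transcriptome-wide response-gene scan.

Patients carrying exactly one retained mutation in a driver gene are
ordered by the (ranked) position of that mutation; each expressed gene's
midranked expression over those patients forms an ordered series that is
segmented.  A gene whose series shows at least one segmentation
breakpoint is a *response gene*.  Breakpoint indices are mapped back to
genomic coordinates (midpoint between the flanking mutations) and
summarised as kernel density estimates along the driver gene, separately
for genes with a single breakpoint and genes with several.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Cohort, single_mutation_patients
from .segmentation import (
    OrderedSeries,
    SegmentationParams,
    derive_seed,
    midrank,
    segment,
)

log = logging.getLogger(__name__)

__all__ = [
    "ResponseGeneRecord",
    "BreakpointDensity",
    "ScanSummary",
    "build_series",
    "scan_transcriptome",
    "map_breakpoint",
    "breakpoint_density",
    "mutation_density",
    "signature_scan",
    "records_to_frame",
]


@dataclass
class ResponseGeneRecord:
    gene: str
    n_breakpoints: int
    breakpoint_indices: list[int]
    breakpoint_coords: list[float]
    top_split_p: float

    def __post_init__(self) -> None:
        if not (
            self.n_breakpoints
            == len(self.breakpoint_indices)
            == len(self.breakpoint_coords)
            >= 1
        ):
            raise ValueError("inconsistent breakpoint counts")


@dataclass
class BreakpointDensity:
    grid: np.ndarray
    density_single: np.ndarray
    density_multi: np.ndarray
    bandwidth: float
    empty_single: bool = False
    empty_multi: bool = False


@dataclass
class ScanSummary:
    driver: str
    n_samples: int
    n_genes_total: int
    n_genes_filtered: int
    n_genes_segmented: int
    n_response_genes: int
    params: SegmentationParams | None = None

    def to_dict(self) -> dict:
        d = {
            "driver": self.driver,
            "n_samples": self.n_samples,
            "n_genes_total": self.n_genes_total,
            "n_genes_filtered": self.n_genes_filtered,
            "n_genes_segmented": self.n_genes_segmented,
            "n_response_genes": self.n_response_genes,
        }
        if self.params is not None:
            d["params"] = {
                "alpha": self.params.alpha,
                "nperm": self.params.nperm,
                "min_width": self.params.min_width,
                "seed": self.params.seed,
            }
        return d


def build_series(
    cohort: Cohort,
    driver: str,
    gene: str,
    min_width: int = 5,
) -> OrderedSeries:
    """Ordered series of one gene's midranked expression.

    Samples are those with exactly one retained driver mutation, ordered
    by mutation genomic position (ties broken by sample id, stable).
    Series shorter than 2*min_width are returned flagged unsegmentable.
    """
    singles = single_mutation_patients(cohort.mutations, driver)
    if not singles:
        raise ValueError(f"no single-mutation samples for driver {driver!r}")
    if gene not in cohort.expression:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    ordered = sorted(
        singles.items(), key=lambda kv: (kv[1].genomic_position, kv[0])
    )
    labels = [s for s, _ in ordered]
    positions = np.array([m.genomic_position for _, m in ordered])
    expr = cohort.expression.gene_values(gene, labels)
    values = midrank(expr)
    series = OrderedSeries(
        values=values,
        labels=labels,
        positions=positions,
        gene=gene,
        segmentable=len(labels) >= 2 * min_width,
    )
    return series


def map_breakpoint(series: OrderedSeries, k: int) -> float:
    """Genomic coordinate of the boundary after index k (1-based).

    Midpoint between the flanking mutation positions; equal positions map
    to the shared value.
    """
    n = len(series)
    if not (1 <= k < n):
        raise ValueError(f"breakpoint index {k} out of range for n={n}")
    a = float(series.positions[k - 1])
    b = float(series.positions[k])
    return (a + b) / 2.0


def _expressed(values: np.ndarray, min_nonzero_fraction: float) -> bool:
    return float(np.mean(values > 0)) >= min_nonzero_fraction


def scan_transcriptome(
    cohort: Cohort,
    driver: str,
    params: SegmentationParams,
    genes: Sequence[str] | None = None,
    min_nonzero_fraction: float = 0.2,
) -> tuple[list[ResponseGeneRecord], ScanSummary]:
    """Segment every expressed gene against the driver's mutation order.

    ``genes`` restricts the scan (e.g. to a signature); default is the
    whole expression matrix.  A gene qualifies as expressed when at least
    ``min_nonzero_fraction`` of the mutation-bearing samples have nonzero
    expression.  Per-gene segmentation seeds derive deterministically
    from ``params.seed`` and the gene name.
    """
    singles = single_mutation_patients(cohort.mutations, driver)
    if not singles:
        raise ValueError(f"no single-mutation samples for driver {driver!r}")
    gene_list = list(genes) if genes is not None else cohort.expression.genes
    records: list[ResponseGeneRecord] = []
    n_filtered = 0
    n_segmented = 0
    for gene in gene_list:
        series = build_series(cohort, driver, gene, params.min_width)
        if not _expressed(
            cohort.expression.gene_values(gene, series.labels),
            min_nonzero_fraction,
        ):
            n_filtered += 1
            continue
        if not series.segmentable:
            n_filtered += 1
            continue
        gene_params = SegmentationParams(
            alpha=params.alpha,
            nperm=params.nperm,
            min_width=params.min_width,
            seed=derive_seed(params.seed, "gene", gene),
        )
        n_segmented += 1
        result = segment(series, gene_params)
        if result.n_breakpoints >= 1:
            coords = [map_breakpoint(series, k) for k in result.breakpoints]
            records.append(
                ResponseGeneRecord(
                    gene=gene,
                    n_breakpoints=result.n_breakpoints,
                    breakpoint_indices=list(result.breakpoints),
                    breakpoint_coords=coords,
                    top_split_p=min(result.split_pvalues),
                )
            )
    summary = ScanSummary(
        driver=driver,
        n_samples=len(singles),
        n_genes_total=len(gene_list),
        n_genes_filtered=n_filtered,
        n_genes_segmented=n_segmented,
        n_response_genes=len(records),
        params=params,
    )
    return records, summary


def _gaussian_kde_on_grid(
    points: np.ndarray, grid: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Average of Gaussian kernels, renormalised to unit trapezoid mass."""
    diffs = (grid[:, None] - points[None, :]) / bandwidth
    dens = np.exp(-0.5 * diffs**2).sum(axis=1) / (
        points.size * bandwidth * np.sqrt(2 * np.pi)
    )
    mass = np.trapezoid(dens, grid)
    if mass > 0:
        dens = dens / mass
    return dens


def _silverman_bandwidth(points: np.ndarray, span: float, floor_frac: float) -> float:
    floor = floor_frac * span
    if points.size < 2:
        return max(floor, 1.0)
    sd = float(np.std(points, ddof=1))
    iqr = float(np.subtract(*np.percentile(points, [75, 25])))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        return max(floor, 1.0)
    bw = 0.9 * scale * points.size ** (-0.2)
    return max(bw, floor, 1e-9)


def breakpoint_density(
    records: Sequence[ResponseGeneRecord],
    gene_span: tuple[float, float],
    grid_size: int = 512,
    bandwidth: float | None = None,
    bandwidth_floor_fraction: float = 0.01,
) -> BreakpointDensity:
    """Breakpoint KDEs along the driver gene.

    Two Gaussian kernel density estimates over a regular grid spanning
    the gene: one from breakpoints of single-breakpoint genes, one from
    breakpoints of multi-breakpoint genes.  Bandwidth defaults to
    Silverman's rule with a floor of 1% of the gene span.
    """
    start, end = gene_span
    if not end > start:
        raise ValueError("invalid gene span")
    grid = np.linspace(start, end, grid_size)
    single = np.array(
        [c for r in records if r.n_breakpoints == 1 for c in r.breakpoint_coords]
    )
    multi = np.array(
        [c for r in records if r.n_breakpoints >= 2 for c in r.breakpoint_coords]
    )
    allpts = np.concatenate([single, multi]) if (single.size + multi.size) else np.empty(0)
    bw = (
        bandwidth
        if bandwidth is not None
        else _silverman_bandwidth(allpts, end - start, bandwidth_floor_fraction)
    )
    dens_single = (
        _gaussian_kde_on_grid(single, grid, bw)
        if single.size
        else np.zeros_like(grid)
    )
    dens_multi = (
        _gaussian_kde_on_grid(multi, grid, bw)
        if multi.size
        else np.zeros_like(grid)
    )
    return BreakpointDensity(
        grid=grid,
        density_single=dens_single,
        density_multi=dens_multi,
        bandwidth=bw,
        empty_single=single.size == 0,
        empty_multi=multi.size == 0,
    )


def mutation_density(
    positions: Sequence[int],
    gene_span: tuple[float, float],
    grid_size: int = 512,
    bandwidth: float | None = None,
    bandwidth_floor_fraction: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, float]:
    """KDE of mutation positions along the gene: (grid, density, bandwidth)."""
    start, end = gene_span
    if not end > start:
        raise ValueError("invalid gene span")
    grid = np.linspace(start, end, grid_size)
    pts = np.asarray(positions, dtype=float)
    bw = (
        bandwidth
        if bandwidth is not None
        else _silverman_bandwidth(pts, end - start, bandwidth_floor_fraction)
    )
    dens = _gaussian_kde_on_grid(pts, grid, bw) if pts.size else np.zeros_like(grid)
    return grid, dens, bw


def signature_scan(
    cohort: Cohort,
    driver: str,
    signature: Sequence[str],
    params: SegmentationParams,
    min_nonzero_fraction: float = 0.2,
) -> pd.DataFrame:
    """Response-gene calls restricted to a gene signature.

    Genes absent from the expression matrix are reported unresolvable
    and excluded from the qualifying denominator.
    """
    resolvable = [g for g in signature if g in cohort.expression]
    missing = [g for g in signature if g not in cohort.expression]
    if missing:
        log.info("signature_scan: %d/%d genes unresolvable: %s",
                 len(missing), len(signature), ", ".join(missing))
    if resolvable:
        records, _ = scan_transcriptome(
            cohort, driver, params, genes=resolvable,
            min_nonzero_fraction=min_nonzero_fraction,
        )
    else:
        records = []
    called = {r.gene: r for r in records}
    rows = []
    for g in signature:
        if g in called:
            rows.append({"gene": g, "resolvable": True, "called": True,
                         "n_breakpoints": called[g].n_breakpoints})
        elif g in cohort.expression:
            rows.append({"gene": g, "resolvable": True, "called": False,
                         "n_breakpoints": 0})
        else:
            rows.append({"gene": g, "resolvable": False, "called": False,
                         "n_breakpoints": 0})
    return pd.DataFrame(rows, columns=["gene", "resolvable", "called", "n_breakpoints"])


def records_to_frame(records: Sequence[ResponseGeneRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "n_breakpoints": [r.n_breakpoints for r in records],
            "breakpoint_indices": [
                ",".join(map(str, r.breakpoint_indices)) for r in records
            ],
            "breakpoint_coords": [
                ",".join(f"{c:g}" for c in r.breakpoint_coords) for r in records
            ],
            "top_split_p": [r.top_split_p for r in records],
        }
    )
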