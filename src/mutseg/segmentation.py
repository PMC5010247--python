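"""Circular binary segmentation with permutation split significance.

The engine behind response-gene calling: an ordered series (ranked
expression of one gene over patients ordered by ranked mutation position)
is recursively split wherever an arc-vs-complement mean-difference
statistic is larger than expected under random permutation.

The statistic for an arc (i, j] of a series y of length n is

    Z(i, j) = (mean_arc - mean_complement) / (s * sqrt(1/k + 1/(n-k)))

with k = j - i and s the overall sample standard deviation; it is
invariant under affine rescaling of y.  A split is accepted when its
permutation p-value (add-one estimator, never exactly zero) is at or
below ``alpha``; every piece a split produces must have at least
``min_width`` observations.  Splitting recurses on each resulting piece.
No post-hoc pruning or undo step is applied.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "OrderedSeries",
    "SegmentationParams",
    "Segment",
    "SegmentationResult",
    "midrank",
    "arc_statistic",
    "max_statistic",
    "permutation_pvalue",
    "segment",
    "derive_seed",
]


@dataclass
class OrderedSeries:
    """Values of one gene over samples ordered by mutation position.

    ``positions`` (non-decreasing) is the ordering key — typically the
    genomic mutation positions; ``values`` are midranked expression.
    """

    values: np.ndarray
    labels: list[str]
    positions: np.ndarray
    gene: str = ""
    segmentable: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.positions = np.asarray(self.positions)
        if not (len(self.values) == len(self.labels) == len(self.positions)):
            raise ValueError("values, labels and positions must be parallel")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("positions must be non-decreasing")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SegmentationParams:
    """Tuning knobs of the split test.

    Defaults follow the strict settings used for cohort-scale scans:
    alpha = 0.005, nperm = 20000, min_width = 5.
    """

    alpha: float = 0.005
    nperm: int = 20000
    min_width: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.nperm < 1 or self.min_width < 1:
            raise ValueError("nperm and min_width must be positive")
        if self.alpha * (self.nperm + 1) < 1.0:
            raise ValueError(
                "alpha * (nperm + 1) < 1: permutation resolution too coarse "
                "to ever reject"
            )


@dataclass(frozen=True)
class Segment:
    start: int  # 1-based inclusive
    end: int
    mean: float

    @property
    def width(self) -> int:
        return self.end - self.start + 1


@dataclass
class SegmentationResult:
    segments: list[Segment]
    breakpoints: list[int]  # boundary after index k (1-based), sorted
    split_pvalues: list[float]
    statistic_T: float
    params: SegmentationParams | None = None

    @property
    def n_breakpoints(self) -> int:
        return len(self.breakpoints)

    def validate(self, n: int) -> None:
        assert self.segments[0].start == 1 and self.segments[-1].end == n
        for a, b in zip(self.segments, self.segments[1:]):
            assert b.start == a.end + 1
        assert self.breakpoints == sorted(self.breakpoints)
        assert len(self.breakpoints) == len(self.segments) - 1


def midrank(v: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties receiving the mean of their rank range."""
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        return np.empty(0)
    if not np.all(np.isfinite(v)):
        raise ValueError("midrank requires finite values")
    return rankdata(v, method="average")


def derive_seed(seed: int, *tokens: str | int) -> int:
    """Deterministic child seed for a named stochastic stage (< 2^31)."""
    acc = zlib.crc32(str(int(seed)).encode())
    for tok in tokens:
        acc = zlib.crc32(str(tok).encode(), acc)
    return acc & 0x7FFFFFFF


def _candidate_arcs(n: int, min_width: int) -> tuple[np.ndarray, np.ndarray]:
    """All admissible (i, j) arc boundaries for a series of length n.

    The arc is (i, j], 0 <= i < j <= n, complement non-empty.  Interior
    arcs (i > 0 and j < n) induce three linear pieces of widths i, j-i
    and n-j; boundary-touching arcs induce two pieces.  Every induced
    piece must have width >= min_width.
    """
    ii, jj = np.meshgrid(np.arange(0, n), np.arange(1, n + 1), indexing="ij")
    ii = ii.ravel()
    jj = jj.ravel()
    keep = ii < jj
    ii, jj = ii[keep], jj[keep]
    k = jj - ii
    valid = k < n  # complement non-empty
    interior = (ii > 0) & (jj < n)
    left_ok = (ii == 0) | (ii >= min_width)
    right_ok = (jj == n) | (n - jj >= min_width)
    arc_ok = k >= min_width
    comp_ok = np.where(interior, True, (n - k) >= min_width)
    valid &= left_ok & right_ok & arc_ok & comp_ok
    return ii[valid], jj[valid]


def arc_statistic(y: Sequence[float], i: int, j: int) -> float:
    """Z(i, j) for the arc (i, j] against its complement (see module docs)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not (0 <= i < j <= n):
        raise ValueError(f"invalid arc boundaries ({i}, {j}) for n={n}")
    k = j - i
    if k == n:
        raise ValueError("arc complement is empty")
    s = float(np.std(y, ddof=1)) if n > 1 else 0.0
    if s == 0.0:
        return 0.0
    arc_mean = float(np.mean(y[i:j]))
    comp_mean = (float(np.sum(y)) - float(np.sum(y[i:j]))) / (n - k)
    return (arc_mean - comp_mean) / (s * np.sqrt(1.0 / k + 1.0 / (n - k)))


def _max_stat_from_cumsum(
    S: np.ndarray, s: float, ii: np.ndarray, jj: np.ndarray, n: int
) -> tuple[int, int, float]:
    """Maximizer of |Z| over the candidate arcs, given cumsum S (len n+1)."""
    k = jj - ii
    arc_sum = S[jj] - S[ii]
    total = S[n]
    z = (arc_sum / k - (total - arc_sum) / (n - k)) / (
        s * np.sqrt(1.0 / k + 1.0 / (n - k))
    )
    az = np.abs(z)
    best = np.max(az)
    # deterministic tie-break: smallest i, then smallest j
    cand = np.flatnonzero(az == best)
    order = np.lexsort((jj[cand], ii[cand]))
    pick = cand[order[0]]
    return int(ii[pick]), int(jj[pick]), float(best)


def max_statistic(
    y: Sequence[float], min_width: int = 5
) -> tuple[int | None, int | None, float]:
    """Best-scoring admissible arc: (i*, j*, T) with T = max |Z|.

    Returns (None, None, 0.0) when the series is too short (n < 2*min_width)
    or has zero variance.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * min_width:
        return None, None, 0.0
    s = float(np.std(y, ddof=1))
    if s == 0.0:
        return None, None, 0.0
    ii, jj = _candidate_arcs(n, min_width)
    if ii.size == 0:
        return None, None, 0.0
    S = np.concatenate(([0.0], np.cumsum(y)))
    return _max_stat_from_cumsum(S, s, ii, jj, n)


def permutation_pvalue(
    y: Sequence[float],
    T_obs: float,
    params: SegmentationParams,
    rng: np.random.Generator,
    _block: int = 256,
) -> float:
    """Add-one permutation p-value: (1 + #{T(pi) >= T_obs}) / (nperm + 1).

    Permutation maxima are computed vectorised in blocks; the estimator
    never returns exactly zero.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    s = float(np.std(y, ddof=1)) if n > 1 else 0.0
    if s == 0.0 or n < 2 * params.min_width:
        return 1.0
    ii, jj = _candidate_arcs(n, params.min_width)
    if ii.size == 0:
        return 1.0
    k = (jj - ii).astype(float)
    denom = s * np.sqrt(1.0 / k + 1.0 / (n - k))
    exceed = 0
    remaining = params.nperm
    while remaining > 0:
        b = min(_block, remaining)
        remaining -= b
        perms = rng.permuted(np.broadcast_to(y, (b, n)).copy(), axis=1)
        S = np.concatenate(
            (np.zeros((b, 1)), np.cumsum(perms, axis=1)), axis=1
        )
        arc_sum = S[:, jj] - S[:, ii]
        total = S[:, -1][:, None]
        z = (arc_sum / k - (total - arc_sum) / (n - k)) / denom
        t_perm = np.max(np.abs(z), axis=1)
        exceed += int(np.sum(t_perm >= T_obs))
    return (1 + exceed) / (params.nperm + 1)


def _segment_recursive(
    y: np.ndarray,
    lo: int,  # 0-based offset of this piece in the full series
    params: SegmentationParams,
    boundaries: list[int],
    pvalues: list[float],
    top_stats: list[float],
    depth: int,
) -> None:
    n = len(y)
    if n < 2 * params.min_width:
        return
    i, j, T = max_statistic(y, params.min_width)
    if depth == 0:
        top_stats.append(T)
    if i is None:
        return
    rng = np.random.default_rng(derive_seed(params.seed, "piece", lo, lo + n))

    p = permutation_pvalue(y, T, params, rng)
    if p > params.alpha:
        return
    pvalues.append(p)
    cuts = [c for c in (i, j) if 0 < c < n]
    for c in cuts:
        boundaries.append(lo + c)
    pieces = []
    prev = 0
    for c in cuts + [n]:
        pieces.append((prev, c))
        prev = c
    for a, b in pieces:
        _segment_recursive(
            y[a:b], lo + a, params, boundaries, pvalues, top_stats, depth + 1
        )


def segment(
    series: OrderedSeries | Sequence[float], params: SegmentationParams
) -> SegmentationResult:
    """Recursive segmentation of an ordered series.

    Tests the whole series; when the permutation p-value of the best arc
    is at or below alpha, splits at the arc's interior boundaries and
    recurses on each piece.  Pieces narrower than 2*min_width are never
    tested.  Fully reproducible from ``params.seed``.
    """
    if isinstance(series, OrderedSeries):
        y = np.asarray(series.values, dtype=float)
    else:
        y = np.asarray(series, dtype=float)
    n = len(y)
    if n == 0:
        raise ValueError("cannot segment an empty series")
    if not np.all(np.isfinite(y)):
        raise ValueError("series values must be finite")
    boundaries: list[int] = []
    pvalues: list[float] = []
    top_stats: list[float] = [0.0]
    if n > 1:
        top_stats = []
        _segment_recursive(y, 0, params, boundaries, pvalues, top_stats, 0)
        if not top_stats:
            top_stats = [0.0]
    boundaries.sort()
    segments = []
    edges = [0] + boundaries + [n]
    for a, b in zip(edges, edges[1:]):
        segments.append(Segment(start=a + 1, end=b, mean=float(np.mean(y[a:b]))))
    result = SegmentationResult(
        segments=segments,
        breakpoints=boundaries,
        split_pvalues=pvalues,
        statistic_T=top_stats[0],
        params=params,
    )
    result.validate(n)
    return result
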