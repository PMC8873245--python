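"""Chronological segmentation of multivariate elemental series.

A transect is split into contiguous partitions by recursive binary
splitting on the ordered index: each split places the breakpoint that
minimises the total within-segment sum of squared Euclidean deviations
from segment means, computed on per-element z-scores so that elements of
different magnitudes contribute comparably.  Splitting stops when the best
available split's relative cost reduction falls below a penalty, when a
partition cap is reached, or when no split respects the minimum segment
length.  Partition fingerprints are means of the original (unstandardised)
concentrations.

Index convention: half-open ``[start, end)``, 0-based, on the oriented
(core -> edge) series, so the first partition abuts the core and the last
abuts the capture surface.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass

import numpy as np

from .transect_io import ElementalTransect

__all__ = [
    "Partition",
    "PartitionSet",
    "segment_series",
    "segment_transect",
    "partition_fingerprints",
    "exhaustive_segment",
    "segment_cost",
]


@dataclass(frozen=True)
class Partition:
    start: int
    end: int  # half-open [start, end)
    fingerprint: np.ndarray
    n_points: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("partition must have end > start")
        if self.n_points != self.end - self.start:
            raise ValueError("n_points inconsistent with [start, end)")


@dataclass
class PartitionSet:
    fish_id: str
    partitions: list[Partition]
    cost: float
    standardization: dict  # per-element mean/sd used for the cost

    def __post_init__(self) -> None:
        if not self.partitions:
            raise ValueError("PartitionSet needs at least one partition")
        prev_end = 0
        for p in self.partitions:
            if p.start != prev_end:
                raise ValueError("partitions must tile the series contiguously")
            prev_end = p.end

    @property
    def breakpoints(self) -> list[int]:
        """Interior breakpoints (starts of partitions 1..k-1)."""
        return [p.start for p in self.partitions[1:]]

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)

    @property
    def series_length(self) -> int:
        return self.partitions[-1].end


def _zscore(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    safe = np.where(sd > 0, sd, 1.0)
    return (x - mu) / safe, mu, sd


class _CostModel:
    """O(1) within-segment SSE queries via prefix sums."""

    def __init__(self, z: np.ndarray) -> None:
        n = len(z)
        self.cs = np.vstack([np.zeros(z.shape[1]), np.cumsum(z, axis=0)])
        self.cs2 = np.vstack([np.zeros(z.shape[1]), np.cumsum(z**2, axis=0)])
        self.n = n

    def cost(self, a: int, b: int) -> float:
        """SSE of segment [a, b) around its own mean, summed over elements."""
        length = b - a
        s = self.cs[b] - self.cs[a]
        s2 = self.cs2[b] - self.cs2[a]
        return float(np.sum(s2 - s**2 / length))

    def best_split(self, a: int, b: int, min_len: int) -> tuple[int, float] | None:
        """Breakpoint in (a, b) minimising cost(a,m)+cost(m,b); ties -> smallest index."""
        candidates = range(a + min_len, b - min_len + 1)
        best = None
        for m in candidates:
            c = self.cost(a, m) + self.cost(m, b)
            if best is None or c < best[1] - 1e-12:
                best = (m, c)
        return best


def segment_series(
    values: np.ndarray,
    min_seg_len: int = 5,
    max_partitions: int = 6,
    penalty: float = 0.05,
) -> tuple[list[int], float]:
    """Recursive binary segmentation of a (n_points, n_elements) array.

    Returns (interior breakpoints sorted ascending, final cost on the
    z-scored values).  Splits greedily, always taking the split with the
    largest cost reduction next, and stops when the best reduction falls
    below ``penalty`` times the initial total cost.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.ndim != 2:
        raise ValueError("values must be 2-D (points x elements)")
    if values.shape[1] == 0:
        raise ValueError("empty element subset")
    if min_seg_len < 2:
        raise ValueError("min_seg_len must be >= 2")
    n = len(values)
    z, _, _ = _zscore(values)
    model = _CostModel(z)
    total0 = model.cost(0, n)

    segments: list[tuple[int, int]] = [(0, n)]
    if n < 2 * min_seg_len or total0 <= 0:
        return [], total0

    # max-heap of candidate splits keyed by cost reduction
    heap: list[tuple[float, int, int, int]] = []

    def push(a: int, b: int) -> None:
        found = model.best_split(a, b, min_seg_len)
        if found is None:
            return
        m, split_cost = found
        gain = model.cost(a, b) - split_cost
        heapq.heappush(heap, (-gain, a, b, m))

    push(0, n)
    threshold = penalty * total0
    while heap and len(segments) < max_partitions:
        neg_gain, a, b, m = heapq.heappop(heap)
        if (a, b) not in segments:
            continue  # stale entry
        if -neg_gain < threshold or -neg_gain <= 0:
            break
        segments.remove((a, b))
        segments.extend([(a, m), (m, b)])
        push(a, m)
        push(m, b)

    segments.sort()
    bps = [a for a, _ in segments[1:]]
    bps = _refine_breakpoints(model, bps, n, min_seg_len)
    bounds = [0, *bps, n]
    cost = sum(model.cost(a, b) for a, b in zip(bounds[:-1], bounds[1:]))
    return bps, cost


def _refine_breakpoints(
    model: _CostModel, bps: list[int], n: int, min_seg_len: int, max_sweeps: int = 20
) -> list[int]:
    """Cyclic local polish: re-optimise each breakpoint conditional on its
    neighbours until stable.  Fixes the occasional one-off placement of the
    first greedy cut without changing the partition count."""
    bps = list(bps)
    for _ in range(max_sweeps):
        moved = False
        for i in range(len(bps)):
            a = bps[i - 1] if i > 0 else 0
            b = bps[i + 1] if i + 1 < len(bps) else n
            found = model.best_split(a, b, min_seg_len)
            if found is not None and found[0] != bps[i]:
                bps[i] = found[0]
                moved = True
        if not moved:
            break
    return bps


def segment_transect(
    transect: ElementalTransect,
    min_seg_len: int = 5,
    max_partitions: int = 6,
    penalty: float = 0.05,
    elements: list[str] | None = None,
) -> PartitionSet:
    """Segment an oriented transect and attach partition fingerprints.

    The cost is computed on the z-scored subset of ``elements`` (defaults
    to all retained elements); fingerprints are means of the original
    concentrations over every element the transect carries.
    """
    if transect.orientation != "core_to_edge":
        raise ValueError(
            f"fish {transect.fish_id!r}: transect must be oriented core_to_edge"
        )
    if elements is not None:
        if not elements:
            raise ValueError("empty element subset")
        work = transect.restrict_elements(elements)
    else:
        work = transect
    z_input = work.concentrations
    _, mu, sd = _zscore(z_input)
    breakpoints, cost = segment_series(
        z_input, min_seg_len=min_seg_len, max_partitions=max_partitions, penalty=penalty
    )
    bounds = [0, *breakpoints, transect.n_points]
    partitions = [
        Partition(
            start=a,
            end=b,
            fingerprint=transect.concentrations[a:b].mean(axis=0),
            n_points=b - a,
        )
        for a, b in zip(bounds[:-1], bounds[1:])
    ]
    return PartitionSet(
        fish_id=transect.fish_id,
        partitions=partitions,
        cost=cost,
        standardization={
            "elements": list(work.elements),
            "mean": mu.tolist(),
            "sd": sd.tolist(),
        },
    )


def partition_fingerprints(pset: PartitionSet, series: np.ndarray) -> np.ndarray:
    """(n_partitions, n_elements) matrix of per-partition means of ``series``."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if pset.series_length != len(series):
        raise ValueError("partition set does not tile this series")
    return np.vstack([series[p.start : p.end].mean(axis=0) for p in pset.partitions])


def segment_cost(values: np.ndarray, breakpoints: list[int]) -> float:
    """Within-segment SSE of a tiling on the z-scored values (shared cost
    definition for the exhaustive oracle)."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    z, _, _ = _zscore(values)
    model = _CostModel(z)
    bounds = [0, *sorted(breakpoints), len(values)]
    return sum(model.cost(a, b) for a, b in zip(bounds[:-1], bounds[1:]))


def exhaustive_segment(
    values: np.ndarray,
    n_partitions: int,
    min_seg_len: int = 2,
) -> tuple[list[int], float]:
    """Globally optimal tiling into exactly ``n_partitions`` segments by
    enumerating every breakpoint placement.  Test/oracle use only."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = len(values)
    z, _, _ = _zscore(values)
    model = _CostModel(z)
    if n_partitions == 1:
        return [], model.cost(0, n)
    best: tuple[list[int], float] | None = None
    for bps in itertools.combinations(range(min_seg_len, n - min_seg_len + 1), n_partitions - 1):
        bounds = [0, *bps, n]
        if any(b - a < min_seg_len for a, b in zip(bounds[:-1], bounds[1:])):
            continue
        c = sum(model.cost(a, b) for a, b in zip(bounds[:-1], bounds[1:]))
        if best is None or c < best[1] - 1e-12:
            best = (list(bps), c)
    if best is None:
        raise ValueError("no feasible tiling under min_seg_len")
    return best
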