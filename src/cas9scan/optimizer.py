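"""Grid-search training of the segment weights against validated sites.

The objective is the number of top-N (default 1000) ranked predictions
fully contained in a gold-standard interval (the same full-containment
semantics as the evaluation module).  Candidate enumeration is
weight-independent, so candidates are enumerated once and rescored at each
grid point.  The grid is evaluated exhaustively; whenever the optimum sits
on a parameter's upper boundary that parameter's range is extended with
uniform spacing, until the objective at the extension frontier has dropped
by at least ``stop_drop`` (default 10) from the best value seen.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .chromatin import DNaseBinTrack, finalize_scores, read_bed_intervals
from .genome_search import CandidateSite
from .scoring import DEFAULT_SCHEME, SegmentScheme, WeightSet, score_candidates

__all__ = [
    "GridSpec",
    "GoldStandardSet",
    "GridSearchResult",
    "objective_top_n_overlap",
    "grid_search",
    "train_chromatin_weight",
]


@dataclass(frozen=True)
class GridSpec:
    """Value lists for the three segment weights plus expansion/stopping
    controls.  Defaults follow the training protocol: an initial 0..20
    range, extension by the grid spacing, stop once the frontier objective
    drops by 10 from the best seen, objective over the top 1000 ranked
    predictions."""

    s1_values: tuple[float, ...] = (0, 5, 10, 15, 20)
    s2_values: tuple[float, ...] = (0, 5, 10, 15, 20)
    s3_values: tuple[float, ...] = (0, 5, 10, 15, 20)
    expansion_step: float | None = None  # None -> per-axis grid spacing
    stop_drop: float = 10
    top_n: int = 1000
    max_rounds: int = 50

    def __post_init__(self) -> None:
        for name in ("s1_values", "s2_values", "s3_values"):
            vals = tuple(float(v) for v in getattr(self, name))
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            if any(v < 0 for v in vals):
                raise ValueError(f"{name} must be non-negative")
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, vals)

    def axis_values(self) -> tuple[tuple[float, ...], ...]:
        return (self.s1_values, self.s2_values, self.s3_values)

    def axis_step(self, axis: int) -> float:
        vals = self.axis_values()[axis]
        if self.expansion_step is not None:
            return float(self.expansion_step)
        if len(vals) > 1:
            return vals[-1] - vals[-2]
        return max(vals[0], 1.0)


class GoldStandardSet:
    """A named collection of validated genomic intervals with fast
    containment queries (intervals may overlap)."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]], name: str = "gold"):
        self.name = name
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"invalid gold interval {chrom}:{start}-{end}")
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end)
            self._n += 1

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "GoldStandardSet":
        return cls(read_bed_intervals(path), name=name or Path(path).stem)

    def __len__(self) -> int:
        return self._n

    def contains(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) is 100% contained in some gold interval."""
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        return any(iv.begin <= start and end <= iv.end for iv in tree.overlap(start, end))


def objective_top_n_overlap(
    candidates: Sequence[CandidateSite],
    weights: WeightSet,
    gold: GoldStandardSet,
    top_n: int = 1000,
    scheme: SegmentScheme = DEFAULT_SCHEME,
    track: DNaseBinTrack | None = None,
) -> int:
    """Score and rank ``candidates`` under ``weights``, then count how many
    of the top ``top_n`` predictions are fully contained in a gold
    interval.  Each prediction counts once; two predictions inside one gold
    interval count twice (the counting unit is the prediction)."""
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    ranked = finalize_scores(score_candidates(candidates, weights, scheme), track, weights)
    return sum(
        1 for s in ranked[:top_n] if gold.contains(s.chrom, s.start, s.end)
    )


@dataclass(frozen=True)
class GridSearchResult:
    best_weights: WeightSet
    table: pd.DataFrame  # columns s1, s2, s3, objective
    warning: str | None = None

    def write_table(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def grid_search(
    candidates: Sequence[CandidateSite],
    gold: GoldStandardSet,
    grid: GridSpec,
    base_weights: WeightSet,
    scheme: SegmentScheme = DEFAULT_SCHEME,
    track: DNaseBinTrack | None = None,
) -> GridSearchResult:
    """Exhaustive grid search over (s1, s2, s3) with boundary expansion.

    Evaluates the top-N containment objective at every point of the
    Cartesian product of the axis value lists.  While the arg-max lies on
    the current maximum of some axis, that axis is extended by its spacing
    and the new points are evaluated, until the best objective achievable
    at the axis frontier has dropped by >= ``stop_drop`` from the best seen
    (or ``max_rounds`` extensions have been made).  Ties break to the
    lexicographically smallest (s1, s2, s3).
    """
    axes: list[list[float]] = [list(v) for v in grid.axis_values()]
    # a single-value axis is a pinned parameter, never extended
    stopped = [len(v) < 2 for v in axes]
    cache: dict[tuple[float, float, float], int] = {}

    def evaluate(point: tuple[float, float, float]) -> int:
        if point not in cache:
            w = replace(base_weights, s1=point[0], s2=point[1], s3=point[2])
            cache[point] = objective_top_n_overlap(
                candidates, w, gold, top_n=grid.top_n, scheme=scheme, track=track
            )
        return cache[point]

    for point in itertools.product(*axes):
        evaluate(point)

    for _ in range(grid.max_rounds):
        best_point = min(cache, key=lambda p: (-cache[p], p))
        best_obj = cache[best_point]
        to_extend = [
            ax
            for ax in range(3)
            if not stopped[ax] and best_point[ax] == axes[ax][-1]
        ]
        if not to_extend:
            break
        for ax in to_extend:
            axes[ax].append(axes[ax][-1] + grid.axis_step(ax))
        new_points = [
            p
            for p in itertools.product(*axes)
            if any(p[ax] == axes[ax][-1] for ax in to_extend)
        ]
        for point in new_points:
            evaluate(point)
        for ax in to_extend:
            frontier = max(
                cache[p] for p in cache if p[ax] == axes[ax][-1]
            )
            if best_obj - frontier >= grid.stop_drop:
                stopped[ax] = True

    best_point = min(cache, key=lambda p: (-cache[p], p))
    warning = None
    if cache[best_point] == 0:
        warning = "objective was zero over the entire grid"
    table = pd.DataFrame(
        [(p[0], p[1], p[2], obj) for p, obj in sorted(cache.items())],
        columns=["s1", "s2", "s3", "objective"],
    )
    best = replace(
        base_weights, s1=best_point[0], s2=best_point[1], s3=best_point[2]
    )
    return GridSearchResult(best_weights=best, table=table, warning=warning)


def train_chromatin_weight(
    candidates: Sequence[CandidateSite],
    gold: GoldStandardSet,
    track: DNaseBinTrack,
    d_values: Sequence[float],
    base_weights: WeightSet,
    top_n: int = 1000,
    scheme: SegmentScheme = DEFAULT_SCHEME,
) -> tuple[float, pd.DataFrame]:
    """One-dimensional grid search over the chromatin weight d with the
    segment weights held fixed.  Ties break to the smallest d."""
    if not d_values:
        raise ValueError("d_values must be non-empty")
    rows = []
    for d in d_values:
        w = replace(base_weights, d=float(d))
        obj = objective_top_n_overlap(
            candidates, w, gold, top_n=top_n, scheme=scheme, track=track
        )
        rows.append((float(d), obj))
    table = pd.DataFrame(rows, columns=["d", "objective"])
    best_d = min(rows, key=lambda r: (-r[1], r[0]))[0]
    return best_d, table
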