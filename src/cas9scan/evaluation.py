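"""Benchmark harness for ranked off-target predictions.

Two instruments: (1) top-N overlap of a ranked prediction list with a
gold-standard interval set, using full-containment semantics (a prediction
counts only if 100% of it lies inside a gold interval, the `bedtools
intersect -f 1` convention, with the fraction applied to the prediction);
(2) a random-placement enrichment test asking whether a set of sites
preferentially falls in genomic bins accessible in many cell types, with
an empirical p-value from length-matched random region sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chromatin import DNaseBinTrack
from .optimizer import GoldStandardSet
from .scoring import ScoredSite

__all__ = [
    "top_n_overlap",
    "overlap_curve",
    "EnrichmentResult",
    "random_region_enrichment",
]

Interval = tuple[str, int, int]


def _as_interval(p) -> Interval:
    if isinstance(p, ScoredSite):
        return (p.chrom, p.start, p.end)
    chrom, start, end = p[0], int(p[1]), int(p[2])
    return (chrom, start, end)


def top_n_overlap(
    predictions: Sequence, gold: GoldStandardSet, n: int
) -> int:
    """Count how many of the top ``n`` predictions are fully contained in a
    gold interval.

    ``predictions`` must already be ranked (best first); elements are
    ScoredSite or (chrom, start, end) tuples.  A prediction contained in
    several overlapping gold intervals counts once.  ``n`` larger than the
    list saturates.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    count = 0
    for p in predictions[:n]:
        chrom, start, end = _as_interval(p)
        if gold.contains(chrom, start, end):
            count += 1
    return count


def overlap_curve(
    predictions: Sequence, gold: GoldStandardSet, n_values: Iterable[int]
) -> pd.DataFrame:
    """Top-N overlap at each requested N, as a (n, overlap) table.  The
    curve is monotonically non-decreasing in n."""
    rows = [(int(n), top_n_overlap(predictions, gold, int(n))) for n in n_values]
    return pd.DataFrame(rows, columns=["n", "overlap"])


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of the random-region enrichment simulation.

    ``per_bin`` tabulates, for each cell-type-frequency stratum of the
    track, the observed fraction of sites overlapping it alongside the
    simulated mean and standard deviation.  ``statistic`` is the mean
    per-site cell-type count X; ``p_value`` is the one-sided empirical
    probability (with add-one correction) of a random placement reaching
    the observed statistic.
    """

    per_bin: pd.DataFrame  # columns x_min, x_max, observed, sim_mean, sim_sd
    statistic: float
    sim_statistics: np.ndarray
    p_value: float
    n_simulations: int


def _site_x(track: DNaseBinTrack, chrom: str, start: int, end: int) -> int:
    chrom_bins = track.bins.get(chrom)
    if not chrom_bins:
        return 0
    return max(
        (chrom_bins.get(i, 0) for i in track.bin_range(start, end)), default=0
    )


def _fractions(
    xs: np.ndarray, edges: Sequence[tuple[int, int]]
) -> np.ndarray:
    return np.array(
        [np.mean((xs >= lo) & (xs <= hi)) for lo, hi in edges], dtype=float
    )


def random_region_enrichment(
    sites: Sequence[Interval],
    track: DNaseBinTrack,
    genome_sizes: dict[str, int],
    n_simulations: int = 1000,
    seed: int | None = None,
    freq_edges: Sequence[tuple[int, int]] | None = None,
) -> EnrichmentResult:
    """Test whether ``sites`` are enriched in highly accessible bins.

    Each simulation places len(sites) length-matched regions uniformly at
    random (chromosome chosen proportional to its length).  For each
    frequency stratum (default: n_cell_types split into five equal X
    ranges, plus X = 0 implicitly excluded) the observed overlap fraction
    is compared to the simulated distribution.  The global statistic is the
    mean per-site X; the one-sided empirical p-value uses the add-one
    correction p = (1 + #{sim >= obs}) / (n_simulations + 1).
    """
    if n_simulations <= 0:
        raise ValueError("n_simulations must be positive")
    if not sites:
        raise ValueError("at least one site is required")
    lengths = [end - start for _, start, end in sites]
    chroms = sorted(genome_sizes)
    max_len = max(lengths)
    usable = [c for c in chroms if genome_sizes[c] >= max_len]
    if not usable:
        raise ValueError("genome too small to place length-matched regions")
    weights = np.array([genome_sizes[c] for c in usable], dtype=float)
    weights /= weights.sum()

    if freq_edges is None:
        n_ct = max(track.n_cell_types, 1)
        step = max(n_ct // 5, 1)
        freq_edges = []
        lo = 1
        while lo <= n_ct:
            hi = min(lo + step - 1, n_ct)
            freq_edges.append((lo, hi))
            lo = hi + 1

    obs_x = np.array(
        [_site_x(track, c, s, e) for c, s, e in sites], dtype=float
    )
    observed_stat = float(obs_x.mean())
    observed_frac = _fractions(obs_x, freq_edges)

    rng = np.random.default_rng(seed)
    sim_stats = np.empty(n_simulations, dtype=float)
    sim_fracs = np.empty((n_simulations, len(freq_edges)), dtype=float)
    for sim in range(n_simulations):
        xs = np.empty(len(sites), dtype=float)
        picks = rng.choice(len(usable), size=len(sites), p=weights)
        for i, (pick, length) in enumerate(zip(picks, lengths)):
            chrom = usable[pick]
            start = int(rng.integers(0, genome_sizes[chrom] - length + 1))
            xs[i] = _site_x(track, chrom, start, start + length)
        sim_stats[sim] = xs.mean()
        sim_fracs[sim] = _fractions(xs, freq_edges)

    p_value = (1 + int(np.sum(sim_stats >= observed_stat))) / (n_simulations + 1)
    per_bin = pd.DataFrame(
        {
            "x_min": [lo for lo, _ in freq_edges],
            "x_max": [hi for _, hi in freq_edges],
            "observed": observed_frac,
            "sim_mean": sim_fracs.mean(axis=0),
            "sim_sd": sim_fracs.std(axis=0, ddof=0),
        }
    )
    return EnrichmentResult(
        per_bin=per_bin,
        statistic=observed_stat,
        sim_statistics=sim_stats,
        p_value=p_value,
        n_simulations=n_simulations,
    )
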