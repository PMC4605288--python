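"""Multi-cell-type chromatin accessibility track and final-score ranking.

Open-chromatin (DNase I hypersensitivity) peak sets from many cell types
are collapsed onto fixed-width genomic bins; each bin carries X, the number
of cell types with at least one peak overlapping it by >= 1 bp.  A
candidate site inherits the maximum X over the bins it overlaps, earns the
additive bonus S_d = coefficient * X * d (coefficient 0.0113 from the
empirical accessibility/binding trend, d the mode's trained chromatin
weight) and is finally ranked by S_f = S + S_d.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .genome_search import CandidateSite, PAM_PRIORITY
from .scoring import ScoredSite, WeightSet

__all__ = [
    "DNaseBinTrack",
    "ScoredSite",
    "read_bed_intervals",
    "build_bin_track",
    "site_cell_type_count",
    "dnase_score",
    "finalize_scores",
]

Interval = tuple[str, int, int]

DEFAULT_BIN_WIDTH = 200


def read_bed_intervals(path: str | Path) -> list[Interval]:
    """Read intervals from a BED3+ file (extra columns ignored, comment and
    track lines skipped).  Malformed lines raise with file/line context."""
    out: list[Interval] = []
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            out.append((fields[0], start, end))
    return out


@dataclass
class DNaseBinTrack:
    """Binned accessibility counts: per chromosome, bin index -> X (number
    of cell types whose peaks touch the bin).  Zero-count bins are not
    stored."""

    bin_width: int = DEFAULT_BIN_WIDTH
    bins: dict[str, dict[int, int]] = field(default_factory=dict)
    n_cell_types: int = 0

    def x_at(self, chrom: str, bin_index: int) -> int:
        return self.bins.get(chrom, {}).get(bin_index, 0)

    def bin_range(self, start: int, end: int) -> range:
        """Indices of the bins overlapping [start, end)."""
        return range(start // self.bin_width, (end - 1) // self.bin_width + 1)

    def to_bedgraph(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            for chrom in sorted(self.bins):
                for idx in sorted(self.bins[chrom]):
                    s = idx * self.bin_width
                    fh.write(f"{chrom}\t{s}\t{s + self.bin_width}\t{self.bins[chrom][idx]}\n")


def build_bin_track(
    peak_sets: Sequence[str | Path | Iterable[Interval]],
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> DNaseBinTrack:
    """Build a binned track from per-cell-type peak sets.

    Each element of ``peak_sets`` is one cell type: either a BED file path
    or an iterable of (chrom, start, end).  A cell type contributes at most
    1 to a bin's X regardless of how many of its peaks touch the bin.
    """
    if not peak_sets:
        raise ValueError("at least one peak set is required")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    bins: dict[str, dict[int, int]] = {}
    for peaks in peak_sets:
        if isinstance(peaks, (str, Path)):
            peaks = read_bed_intervals(peaks)
        covered: dict[str, set[int]] = {}
        for chrom, start, end in peaks:
            if start < 0 or start >= end:
                raise ValueError(f"invalid peak interval {chrom}:{start}-{end}")
            covered.setdefault(chrom, set()).update(
                range(start // bin_width, (end - 1) // bin_width + 1)
            )
        for chrom, idxs in covered.items():
            chrom_bins = bins.setdefault(chrom, {})
            for idx in idxs:
                chrom_bins[idx] = chrom_bins.get(idx, 0) + 1
    return DNaseBinTrack(bin_width=bin_width, bins=bins, n_cell_types=len(peak_sets))


def site_cell_type_count(
    site: CandidateSite,
    track: DNaseBinTrack,
    reduce: Literal["max", "mean"] = "max",
) -> int | float:
    """Cell-type count X assigned to a site: the max (default) or mean X
    over the bins overlapping [start, end); 0 when the chromosome is absent
    from the track."""
    chrom_bins = track.bins.get(site.chrom)
    if not chrom_bins:
        return 0
    xs = [chrom_bins.get(i, 0) for i in track.bin_range(site.start, site.end)]
    if reduce == "max":
        return max(xs, default=0)
    if reduce == "mean":
        return sum(xs) / len(xs) if xs else 0
    raise ValueError(f"unknown reduction {reduce!r}")


def dnase_score(X: int | float, weights: WeightSet) -> float:
    """Chromatin bonus S_d = coefficient * X * d (coefficient 0.0113 by
    default)."""
    if X < 0:
        raise ValueError("cell-type count X must be >= 0")
    return weights.dnase_coefficient * X * weights.d


def _rank_key(s: ScoredSite):
    return (-s.S_f, PAM_PRIORITY[s.pam_class], s.chrom, s.start, s.strand)


def finalize_scores(
    sites: Iterable[ScoredSite],
    track: DNaseBinTrack | None,
    weights: WeightSet,
    reduce: Literal["max", "mean"] = "max",
) -> list[ScoredSite]:
    """Add chromatin bonuses and return the ranked list.

    Without a track (non-human runs) S_f = S and the ranking uses the base
    score alone.  Sorting is by descending S_f with a deterministic
    tie-break: PAM class priority (GGG > NGG > NNG), then chromosome,
    start, strand.  Ranks are assigned 1..N.
    """
    scored: list[ScoredSite] = []
    for s in sites:
        if track is None:
            scored.append(s.with_chromatin(X=0, S_d=0.0))
        else:
            X = site_cell_type_count(s.site, track, reduce=reduce)
            scored.append(s.with_chromatin(X=X, S_d=dnase_score(X, weights)))
    scored.sort(key=_rank_key)
    return [s.with_rank(i + 1) for i, s in enumerate(scored)]
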