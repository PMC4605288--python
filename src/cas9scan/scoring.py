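"""Segmented match/mismatch scoring of candidate sites.

The 20-nt protospacer is split into three segments (default 5, 5 and 10 bp)
with per-segment weights s1, s2, s3.  Each matching position in segment i
contributes +s_i; an isolated mismatch contributes -s_i/2; a mismatch
inside a run of two or more consecutive mismatches contributes the full
-s_i.  A run that straddles a segment boundary is penalized at every one of
its positions by the (negative) mean of the s values of the segments it
spans.  The base score is therefore

    S = sum_i [ n_i * s_i - m_i * s_i - k_i * s_i / 2 ]

with n, m, k the per-segment counts of matches, consecutive mismatches
(counted per position) and single mismatches, plus the boundary-mean rule.

Trained default weights: binding mode s1=5, s2=70, s3=50 (chromatin weight
d=20, mismatch budget 9); cleavage mode s1=20, s2=60, s3=50 (d=10, budget
6).  Segment 1 is PAM-distal by default; the orientation is switchable
because the distal-vs-proximal reading of the segment order is genuinely
ambiguous in the source experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from .genome_search import CandidateSite, Mode, PamClass

__all__ = [
    "WeightSet",
    "SegmentScheme",
    "MismatchClassification",
    "ScoredSite",
    "BINDING_WEIGHTS",
    "CLEAVAGE_WEIGHTS",
    "default_weights",
    "classify_mismatches",
    "base_score",
    "score_candidates",
]

DNASE_COEFFICIENT = 0.0113


@dataclass(frozen=True)
class WeightSet:
    """Per-segment scores plus the chromatin weight for one prediction mode.

    ``s1``..``s3`` are both the match reward and the consecutive-mismatch
    penalty magnitude for their segment (isolated mismatches cost half).
    ``d`` scales the chromatin-accessibility bonus ``S_d =
    dnase_coefficient * X * d`` where X is the number of cell types calling
    the site accessible.
    """

    s1: float
    s2: float
    s3: float
    d: float = 0.0
    mismatch_limit: int = 9
    dnase_coefficient: float = DNASE_COEFFICIENT
    mode_label: str = ""

    def __post_init__(self) -> None:
        if min(self.s1, self.s2, self.s3) < 0 or self.d < 0:
            raise ValueError("segment scores and chromatin weight must be >= 0")

    @property
    def segment_scores(self) -> tuple[float, float, float]:
        return (self.s1, self.s2, self.s3)


BINDING_WEIGHTS = WeightSet(
    s1=5, s2=70, s3=50, d=20, mismatch_limit=9, mode_label="binding"
)
CLEAVAGE_WEIGHTS = WeightSet(
    s1=20, s2=60, s3=50, d=10, mismatch_limit=6, mode_label="cleavage"
)


def default_weights(mode: Mode | str) -> WeightSet:
    """Trained default weights for a prediction mode."""
    return BINDING_WEIGHTS if Mode(mode) is Mode.BINDING else CLEAVAGE_WEIGHTS


@dataclass(frozen=True)
class SegmentScheme:
    """Partition of the 20 protospacer positions into scoring segments.

    ``lengths`` are listed 5'->3' when ``orientation`` is
    ``pam_distal_first`` (the default: segment 1 covers the 5 PAM-distal
    positions); ``pam_proximal_first`` applies them from the PAM end
    instead.
    """

    lengths: tuple[int, int, int] = (5, 5, 10)
    orientation: Literal["pam_distal_first", "pam_proximal_first"] = "pam_distal_first"

    def __post_init__(self) -> None:
        if len(self.lengths) != 3 or any(l <= 0 for l in self.lengths):
            raise ValueError("three positive segment lengths required")
        if sum(self.lengths) != 20:
            raise ValueError("segment lengths must sum to 20")

    def segment_of(self) -> tuple[int, ...]:
        """Segment index (0, 1, 2) of each protospacer position, 5'->3'."""
        out: list[int] = []
        for i, l in enumerate(self.lengths):
            out.extend([i] * l)
        if self.orientation == "pam_proximal_first":
            out.reverse()
        return tuple(out)


DEFAULT_SCHEME = SegmentScheme()


@dataclass(frozen=True)
class MismatchClassification:
    """Positions partitioned into matches, single mismatches and members of
    runs of >= 2 consecutive mismatches."""

    labels: tuple[str, ...]  # per position: match | single | consecutive
    runs: tuple[tuple[int, int], ...]  # [start, end) spans of runs len >= 2
    n: int  # matches
    m: int  # consecutive-mismatch positions
    k: int  # single mismatches


def classify_mismatches(mismatch_mask: Sequence[bool]) -> MismatchClassification:
    """Partition a 20-position mismatch mask into matches, isolated
    mismatches and consecutive-mismatch runs (maximal runs of length >= 2;
    every position in such a run counts toward m)."""
    mask = tuple(bool(b) for b in mismatch_mask)
    if len(mask) != 20:
        raise ValueError(f"mismatch mask must have 20 positions, got {len(mask)}")
    labels = ["match"] * 20
    runs: list[tuple[int, int]] = []
    i = 0
    while i < 20:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < 20 and mask[j]:
            j += 1
        if j - i == 1:
            labels[i] = "single"
        else:
            for p in range(i, j):
                labels[p] = "consecutive"
            runs.append((i, j))
        i = j
    return MismatchClassification(
        labels=tuple(labels),
        runs=tuple(runs),
        n=labels.count("match"),
        m=labels.count("consecutive"),
        k=labels.count("single"),
    )


def base_score(
    mismatch_mask: Sequence[bool],
    weights: WeightSet,
    scheme: SegmentScheme = DEFAULT_SCHEME,
) -> float:
    """Base score S of a mismatch mask under a weight set.

    Matches earn +s_i, isolated mismatches -s_i/2, consecutive mismatches
    -s_i, and every position of a run that spans a segment boundary is
    charged the mean of the spanned segments' s values.  Scores may be
    negative; no rounding is applied.
    """
    cls = classify_mismatches(mismatch_mask)
    seg = scheme.segment_of()
    s = weights.segment_scores
    score = 0.0
    for pos, label in enumerate(cls.labels):
        if label == "match":
            score += s[seg[pos]]
        elif label == "single":
            score -= s[seg[pos]] / 2.0
    for start, end in cls.runs:
        spanned = sorted({seg[p] for p in range(start, end)})
        penalty = sum(s[i] for i in spanned) / len(spanned)
        score -= penalty * (end - start)
    return score


@dataclass(frozen=True)
class ScoredSite:
    """A candidate site with its base score S, chromatin bonus S_d, final
    score S_f = S + S_d, cell-type count X and (once ranked) rank."""

    site: CandidateSite
    S: float
    X: int = 0
    S_d: float = 0.0
    S_f: float = 0.0
    rank: int | None = None

    @property
    def chrom(self) -> str:
        return self.site.chrom

    @property
    def start(self) -> int:
        return self.site.start

    @property
    def end(self) -> int:
        return self.site.end

    @property
    def strand(self) -> str:
        return self.site.strand

    @property
    def pam_class(self) -> PamClass:
        return self.site.pam_class

    def with_chromatin(self, X: int, S_d: float) -> "ScoredSite":
        return replace(self, X=X, S_d=S_d, S_f=self.S + S_d)

    def with_rank(self, rank: int) -> "ScoredSite":
        return replace(self, rank=rank)


def score_candidates(
    sites: Iterable[CandidateSite],
    weights: WeightSet,
    scheme: SegmentScheme = DEFAULT_SCHEME,
) -> list[ScoredSite]:
    """Order-preserving map of :func:`base_score` over candidate sites.

    Chromatin fields are initialized to zero (S_d = 0, S_f = S); use the
    chromatin module to fill them in and rank.
    """
    out: list[ScoredSite] = []
    for site in sites:
        try:
            S = base_score(site.mismatch_mask, weights, scheme)
        except ValueError as exc:
            raise ValueError(
                f"scoring failed for site {site.chrom}:{site.start}-{site.end}"
                f"({site.strand}): {exc}"
            ) from exc
        out.append(ScoredSite(site=site, S=S, S_f=S))
    return out
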