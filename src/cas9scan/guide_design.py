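"""sgRNA design: scan a short region for NGG-adjacent protospacers and
rank the candidates by genome-wide predicted off-target burden.

A guide's burden is the sum of final scores S_f over every candidate locus
except its single best-scoring perfect (0-mismatch) on-target hit, so a
guide whose imperfect matches are few and poorly scored ranks first.
Extra perfect hits (a non-unique guide) count toward the burden.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .chromatin import DNaseBinTrack, finalize_scores
from .genome_search import (
    GuideQuery,
    Mode,
    PamClass,
    PamPolicy,
    classify_pam,
    enumerate_candidates,
    reverse_complement,
)
from .scoring import (
    DEFAULT_SCHEME,
    ScoredSite,
    SegmentScheme,
    WeightSet,
    default_weights,
    score_candidates,
)

__all__ = ["ProtospacerHit", "GuideReport", "find_protospacers", "rank_guides"]

MAX_REGION_LENGTH = 250


@dataclass(frozen=True)
class ProtospacerHit:
    """A candidate protospacer found in a design region.  ``position`` is
    the 0-based start of the 20-mer on the region's forward coordinates;
    ``sequence`` and ``pam`` are read 5'->3' on ``strand``."""

    position: int
    strand: str
    sequence: str
    pam: str


def find_protospacers(region: str) -> list[ProtospacerHit]:
    """All 20-mers in ``region`` (both strands) whose adjacent 3-mer is an
    NGG-class PAM (GGG included; NNG excluded), ordered by (position,
    strand).

    The region must be 23..250 nt over ACGTN; shorter than 23 nt yields an
    empty list only if at least 23 nt — below that no guide fits, so the
    spec'd minimum is enforced softly by returning nothing.
    """
    region = region.strip().upper()
    if len(region) > MAX_REGION_LENGTH:
        raise ValueError(
            f"design region must be at most {MAX_REGION_LENGTH} nt, got {len(region)}"
        )
    if any(c not in "ACGTN" for c in region):
        raise ValueError("design region must be over the ACGTN alphabet")
    hits: list[ProtospacerHit] = []
    L = len(region)
    if L < 23:
        return hits
    for i in range(L - 22):
        pam = region[i + 20 : i + 23]
        if classify_pam(pam) in (PamClass.GGG, PamClass.NGG):
            hits.append(ProtospacerHit(i, "+", region[i : i + 20], pam))
    for s in range(3, L - 19):
        pam = reverse_complement(region[s - 3 : s])
        if classify_pam(pam) in (PamClass.GGG, PamClass.NGG):
            hits.append(
                ProtospacerHit(s, "-", reverse_complement(region[s : s + 20]), pam)
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


@dataclass(frozen=True)
class GuideReport:
    """Per-guide design summary: off-target burden, whether a perfect
    genomic hit exists, and the top-scoring off-target candidates."""

    guide: ProtospacerHit
    burden: float
    n_candidates: int
    has_on_target: bool
    on_target: ScoredSite | None
    top_off_targets: tuple[ScoredSite, ...]
    rank: int | None = None


def _burden(ranked: list[ScoredSite]) -> tuple[float, ScoredSite | None]:
    """Sum of S_f excluding the single best-ranked perfect hit (the
    presumed on-target); additional perfect hits are burden."""
    on_target = next(
        (s for s in ranked if s.site.n_mismatches == 0), None
    )
    total = sum(s.S_f for s in ranked if s is not on_target)
    return total, on_target


def rank_guides(
    guides: list[ProtospacerHit],
    genome: Mapping[str, str],
    mode: Mode | str = Mode.CLEAVAGE,
    weights: WeightSet | None = None,
    scheme: SegmentScheme = DEFAULT_SCHEME,
    track: DNaseBinTrack | None = None,
    policy: PamPolicy = PamPolicy(),
    top_k: int = 5,
) -> list[GuideReport]:
    """Rank design candidates ascending by off-target burden.

    For each guide the full prediction pipeline runs (enumeration, base
    scoring, chromatin bonus, ranking); the burden sums S_f over every
    candidate but the best perfect hit.  Guides without any perfect genomic
    hit are flagged (``has_on_target=False``) and ranked by the burden over
    all their hits.  Ties break by (burden, position, strand).
    """
    if weights is None:
        weights = default_weights(mode)
    reports: list[GuideReport] = []
    for hit in guides:
        query = GuideQuery(hit.sequence, Mode(mode), label=f"pos{hit.position}{hit.strand}")
        candidates = enumerate_candidates(genome, query, policy)
        ranked = finalize_scores(score_candidates(candidates, weights, scheme), track, weights)
        burden, on_target = _burden(ranked)
        off = tuple(s for s in ranked if s is not on_target)[:top_k]
        reports.append(
            GuideReport(
                guide=hit,
                burden=burden,
                n_candidates=len(ranked),
                has_on_target=on_target is not None,
                on_target=on_target,
                top_off_targets=off,
            )
        )
    reports.sort(key=lambda r: (r.burden, r.guide.position, r.guide.strand))
    return [
        GuideReport(**{**r.__dict__, "rank": i + 1}) for i, r in enumerate(reports)
    ]
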